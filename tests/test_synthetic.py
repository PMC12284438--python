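"""Synthetic generators: tree morphometry, oracle independence, inflow."""

import numpy as np
import pytest

from pulmo1d import wall
from pulmo1d.synthetic import (
    PHRemodelConfig,
    TreeGenConfig,
    apply_ph_remodeling,
    generate_inflow,
    generate_tree,
    generate_uniaxial_data,
    tree_morphometry,
)
from pulmo1d.wall import ConstitutiveParams


class TestTreeGeneration:
    def test_symmetric_counts(self):
        # a 4-generation binary tree has 2^4 - 1 = 15 segments, 8 terminals
        tree = generate_tree(TreeGenConfig(n_generations=4))
        assert len(tree.segments) == 15
        assert len(tree.terminal_ids) == 8

    def test_five_generations_has_31_segments_16_terminals(self):
        tree = generate_tree(TreeGenConfig(n_generations=5))
        assert len(tree.segments) == 31
        assert len(tree.terminal_ids) == 16

    def test_geometric_radius_sequence(self):
        cfg = TreeGenConfig(n_generations=4, radius_ratio=0.8, root_radius=1.0)
        tree = generate_tree(cfg)
        gen3 = [s for s in tree.segments if tree.generation(s.id) == 3]
        assert all(s.radius == pytest.approx(0.512) for s in gen3)
        assert all(s.length == pytest.approx(cfg.length_to_radius * s.radius)
                   for s in tree.segments if s.parent_id is not None)

    def test_seed_determinism(self):
        cfg = TreeGenConfig(n_generations=4, asymmetry=0.3, seed=7)
        r1 = [s.radius for s in generate_tree(cfg).segments]
        r2 = [s.radius for s in generate_tree(cfg).segments]
        r3 = [s.radius for s in generate_tree(TreeGenConfig(
            n_generations=4, asymmetry=0.3, seed=8)).segments]
        assert r1 == r2
        assert r1 != r3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TreeGenConfig(radius_ratio=1.2)
        with pytest.raises(ValueError):
            TreeGenConfig(n_generations=1)
        with pytest.raises(ValueError):
            TreeGenConfig(asymmetry=0.6)


class TestPHRemodeling:
    def test_identity_remodeling(self):
        tree = generate_tree(TreeGenConfig(n_generations=4))
        cfg = PHRemodelConfig(prune_fraction=0.0, distal_narrowing=1.0,
                              wall_thickening=1.0)
        out = apply_ph_remodeling(tree, cfg)
        assert sorted(s.id for s in out.segments) == sorted(s.id for s in tree.segments)
        assert {s.id: s.radius for s in out.segments} == \
            {s.id: s.radius for s in tree.segments}

    def test_prune_half_of_16_terminals_leaves_8(self):
        tree = generate_tree(TreeGenConfig(n_generations=5))
        out = apply_ph_remodeling(tree, PHRemodelConfig(prune_fraction=0.5,
                                                        distal_narrowing=1.0))
        assert len(tree.terminal_ids) == 16
        assert len(out.terminal_ids) == 8

    def test_overpruning_rejected(self):
        tree = generate_tree(TreeGenConfig(n_generations=2))
        with pytest.raises(ValueError, match="fewer than 2"):
            apply_ph_remodeling(tree, PHRemodelConfig(prune_fraction=0.6))

    def test_narrowing_below_threshold_and_thickening(self):
        tree = generate_tree(TreeGenConfig(n_generations=4))
        thr = 0.1
        out = apply_ph_remodeling(tree, PHRemodelConfig(
            prune_fraction=0.0, distal_narrowing=0.8, radius_threshold=thr))
        for s in tree.segments:
            s2 = out.segment(s.id)
            if s.radius < thr:
                assert s2.radius == pytest.approx(0.8 * s.radius)
            else:
                assert s2.radius == s.radius
            assert s2.wall_ratio == pytest.approx(min(0.95, 1.3 * s.wall_ratio))

    def test_remodeled_histogram_shifts_to_larger_radii(self):
        tree = generate_tree(TreeGenConfig(n_generations=5))
        out = apply_ph_remodeling(tree, PHRemodelConfig(
            prune_fraction=0.4, distal_narrowing=1.0, seed=3))
        edges = np.linspace(0.06, 0.21, 7)
        before = tree_morphometry(tree, radius_edges=edges)["radius_fraction"]
        after = tree_morphometry(out, radius_edges=edges)["radius_fraction"]
        assert after[0] < before[0]            # fewer smallest vessels
        assert after[-3:].sum() > before[-3:].sum()  # larger share of big ones


class TestMorphometry:
    def test_fractions_sum_to_one(self):
        tree = generate_tree(TreeGenConfig(n_generations=4, asymmetry=0.2, seed=5))
        m = tree_morphometry(tree)
        assert m["radius_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert m["length_fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_tree_mass_at_generation_radii(self):
        cfg = TreeGenConfig(n_generations=3, radius_ratio=0.7, root_radius=1.0)
        tree = generate_tree(cfg)
        m = tree_morphometry(tree, n_bins=50)
        occupied = np.nonzero(m["radius_fraction"])[0]
        assert occupied.size == 3  # one bin per generation


class TestUniaxialOracle:
    def test_reference_stretch_is_stress_free(self, control_params):
        circ, long = generate_uniaxial_data(control_params, n_points=10)
        assert circ.stress[0] == 0.0 and long.stress[0] == 0.0

    def test_oracle_agrees_with_plane_stress_reduction(self, rng):
        """Energy-minimization oracle vs the stress-balance solve: two
        independent routes to the same uniaxial response."""
        worst = 0.0
        for _ in range(20):
            p = ConstitutiveParams(
                c=float(rng.uniform(3, 40)), k1=float(rng.uniform(0, 400)),
                k2=float(rng.uniform(0.5, 18)), beta=float(rng.uniform(15, 75)),
            )
            circ, long = generate_uniaxial_data(p, n_points=8)
            for ds in (circ, long):
                lam = wall.stretch_from_green(ds.strain[1:])
                model = wall.cauchy_to_second_pk(
                    wall.uniaxial_curve(ds.direction, lam, p), lam)
                rel = np.max(np.abs(model - ds.stress[1:])
                             / np.maximum(np.abs(model), 1e-9))
                worst = max(worst, float(rel))
        assert worst < 1e-6

    def test_anisotropy_visible_off_45_degrees(self, control_params):
        circ, long = generate_uniaxial_data(control_params, n_points=20)
        assert not np.allclose(circ.stress, long.stress, rtol=0.02)

    def test_noise_is_seeded_and_multiplicative(self, control_params):
        a = generate_uniaxial_data(control_params, noise_sd_rel=0.02, seed=1)
        b = generate_uniaxial_data(control_params, noise_sd_rel=0.02, seed=1)
        c = generate_uniaxial_data(control_params, noise_sd_rel=0.02, seed=2)
        assert np.array_equal(a[0].stress, b[0].stress)
        assert not np.array_equal(a[0].stress, c[0].stress)


class TestInflow:
    def test_cycle_volume_matches_stroke_volume(self):
        w = generate_inflow(heart_rate=330, stroke_volume=0.25)
        assert w.cycle_volume() == pytest.approx(0.25, abs=1e-10)

    def test_no_regurgitation(self):
        w = generate_inflow()
        assert np.all(w.values >= 0)

    def test_period_from_heart_rate(self):
        assert generate_inflow(heart_rate=300).period == pytest.approx(0.2)

    def test_invalid_ejection_fraction(self):
        with pytest.raises(ValueError):
            generate_inflow(ejection_fraction_of_cycle=1.2)
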