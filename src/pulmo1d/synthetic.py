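"""Synthetic inputs: vascular trees, uniaxial test data, inflow waveforms.

Every generator is a pure function of its configuration and seed.  The
uniaxial generator is an independent oracle: it solves the incompressible
uniaxial boundary-value problem by direct minimization of the strain-energy
density over the free lateral stretch (Lagrange multiplier eliminated) and
differentiates the energy, never calling the stress-tensor code in
:mod:`pulmo1d.wall` - agreement between the two routes is itself a test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .fitting import UniaxialDataset
from .tree import VesselSegment, VascularTree
from .wall import ConstitutiveParams
from .waveform import Waveform

__all__ = [
    "TreeGenConfig",
    "PHRemodelConfig",
    "generate_tree",
    "apply_ph_remodeling",
    "tree_morphometry",
    "generate_uniaxial_data",
    "generate_inflow",
]

#: wall thickening multiplier conventionally applied to PH trees
PH_WALL_THICKENING = 1.3


@dataclass(frozen=True)
class TreeGenConfig:
    """Self-similar binary tree morphometry (rat pulmonary scale defaults).

    Children of a vessel of radius r get radii r*radius_ratio*(1 +/- a) with
    a drawn uniformly in [0, asymmetry); lengths are length_to_radius times
    the radius.
    """

    n_generations: int = 5
    root_radius: float = 0.2   # cm, rat MPA
    root_length: float = 0.6   # cm
    radius_ratio: float = 0.78
    length_to_radius: float = 3.0
    asymmetry: float = 0.0
    wall_ratio: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.radius_ratio < 1:
            raise ValueError(f"radius_ratio must be in (0,1), got {self.radius_ratio}")
        if self.n_generations < 2:
            raise ValueError(f"n_generations must be >= 2, got {self.n_generations}")
        if not 0 <= self.asymmetry < 0.5:
            raise ValueError(f"asymmetry must be in [0, 0.5), got {self.asymmetry}")


@dataclass(frozen=True)
class PHRemodelConfig:
    """Morphometric remodeling: distal pruning and narrowing.

    ``prune_fraction`` is the fraction of terminals whose sibling pair is
    collapsed into its parent (each removal retires one terminal); radii
    below ``radius_threshold`` are multiplied by ``distal_narrowing``.
    """

    prune_fraction: float = 0.25
    distal_narrowing: float = 0.85
    radius_threshold: float = 0.05  # cm
    wall_thickening: float = PH_WALL_THICKENING
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prune_fraction < 1:
            raise ValueError(f"prune_fraction must be in [0,1), got {self.prune_fraction}")
        if not 0 < self.distal_narrowing <= 1:
            raise ValueError(f"distal_narrowing must be in (0,1], got {self.distal_narrowing}")


def generate_tree(cfg: TreeGenConfig) -> VascularTree:
    """Deterministic (seeded) self-similar binary tree."""
    rng = np.random.default_rng(cfg.seed)
    segments = [
        VesselSegment("s0", None, cfg.root_length, cfg.root_radius, cfg.wall_ratio)
    ]
    frontier = [segments[0]]
    counter = 1
    for _ in range(cfg.n_generations - 1):
        next_frontier = []
        for parent in frontier:
            a = cfg.asymmetry * rng.uniform() if cfg.asymmetry > 0 else 0.0
            for sign in (+1.0, -1.0):
                r = parent.radius * cfg.radius_ratio * (1.0 + sign * a)
                seg = VesselSegment(
                    f"s{counter}", parent.id, cfg.length_to_radius * r, r, cfg.wall_ratio
                )
                segments.append(seg)
                next_frontier.append(seg)
                counter += 1
        frontier = next_frontier
    return VascularTree(tuple(segments))


def apply_ph_remodeling(tree: VascularTree, cfg: PHRemodelConfig) -> VascularTree:
    """Prune terminal sibling pairs and narrow (and thicken) distal vessels.

    The number of pair removals is round(prune_fraction * n_terminals); each
    removal deletes a sibling terminal pair and re-terminates the parent, so
    the terminal count drops by one per removal (newly exposed terminals may
    be pruned in later draws).  Seeded and deterministic.
    """
    rng = np.random.default_rng(cfg.seed)
    segs = {s.id: s for s in tree.segments}
    children: dict[str, list[str]] = {}
    for s in tree.segments:
        if s.parent_id is not None:
            children.setdefault(s.parent_id, []).append(s.id)

    def terminal_pairs():
        pairs = []
        for pid, kids in children.items():
            if len(kids) == 2 and all(k not in children for k in kids):
                pairs.append(pid)
        return sorted(pairs)

    n_terminals = sum(1 for s in segs.values() if s.id not in children)
    n_remove = int(round(cfg.prune_fraction * n_terminals))
    if n_terminals - n_remove < 2:
        raise ValueError(
            f"pruning {n_remove} of {n_terminals} terminals would leave fewer than 2"
        )
    for _ in range(n_remove):
        pairs = terminal_pairs()
        if not pairs:
            break
        pid = pairs[rng.integers(len(pairs))]
        for kid in children.pop(pid):
            del segs[kid]

    out = []
    for s in segs.values():
        if s.radius < cfg.radius_threshold:
            s = VesselSegment(
                s.id, s.parent_id, s.length, s.radius * cfg.distal_narrowing,
                min(0.95, s.wall_ratio * cfg.wall_thickening), s.n_grid,
            )
        elif cfg.wall_thickening != 1.0:
            s = VesselSegment(
                s.id, s.parent_id, s.length, s.radius,
                min(0.95, s.wall_ratio * cfg.wall_thickening), s.n_grid,
            )
        out.append(s)
    return VascularTree(tuple(out))


def tree_morphometry(tree: VascularTree, n_bins: int = 10, radius_edges=None, length_edges=None):
    """Normalized histograms (fractions summing to 1) of radius and length.

    Returns a dict with 'radius_edges', 'radius_fraction', 'length_edges',
    'length_fraction'.
    """
    radii = np.array([s.radius for s in tree.segments])
    lengths = np.array([s.length for s in tree.segments])
    if radius_edges is None:
        radius_edges = np.linspace(0.0, radii.max() * 1.001, n_bins + 1)
    if length_edges is None:
        length_edges = np.linspace(0.0, lengths.max() * 1.001, n_bins + 1)
    r_counts, radius_edges = np.histogram(radii, bins=radius_edges)
    l_counts, length_edges = np.histogram(lengths, bins=length_edges)
    return {
        "radius_edges": radius_edges,
        "radius_fraction": r_counts / r_counts.sum(),
        "length_edges": length_edges,
        "length_fraction": l_counts / l_counts.sum(),
    }


# ---------------------------------------------------------------------------
# independent uniaxial oracle
# ---------------------------------------------------------------------------

def _energy(lr, lt, lz, params: ConstitutiveParams, tension_only: bool) -> float:
    """H-O strain-energy density (kPa): neo-Hookean matrix + fiber pair."""
    b = math.radians(params.beta)
    alpha = (lt * math.cos(b)) ** 2 + (lz * math.sin(b)) ** 2 - 1.0
    if tension_only and alpha < 0.0:
        w_fib = 0.0
    else:
        w_fib = (params.k1 / params.k2) * math.expm1(params.k2 * alpha * alpha)
    return 0.5 * params.c * (lr * lr + lt * lt + lz * lz - 3.0) + w_fib


def _oracle_stress(direction: str, lam: float, params: ConstitutiveParams,
                   tension_only: bool) -> float:
    """Cauchy stress along the loading direction by energy minimization.

    The free lateral stretch minimizes W at fixed loading stretch (with the
    radial stretch eliminated through incompressibility); the loading stress
    follows from the envelope theorem, sigma = lam * dW/dlam at the minimizer.
    """
    if lam == 1.0:
        return 0.0
    b = math.radians(params.beta)

    if direction == "longitudinal":
        def w_of(s, la=lam):
            return _energy(1.0 / (la * s), s, la, params, tension_only)
    else:
        def w_of(s, la=lam):
            return _energy(1.0 / (la * s), la, s, params, tension_only)

    res = minimize_scalar(w_of, bounds=(1e-3, 1.5), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(
            f"oracle lateral minimization failed at {direction} lam={lam}: {res}"
        )

    # refine the interior minimum as the root of the analytic energy gradient
    def dw_ds(s, la=lam):
        lr = 1.0 / (la * s)
        if direction == "longitudinal":
            alpha = (s * math.cos(b)) ** 2 + (la * math.sin(b)) ** 2 - 1.0
            fib_dir = 2.0 * s * math.cos(b) ** 2
        else:
            alpha = (la * math.cos(b)) ** 2 + (s * math.sin(b)) ** 2 - 1.0
            fib_dir = 2.0 * s * math.sin(b) ** 2
        out = params.c * (s - lr * lr / s)
        if alpha > 0.0 or not tension_only:
            out += 2.0 * params.k1 * alpha * math.exp(params.k2 * alpha * alpha) * fib_dir
        return out

    lo, hi = 1e-4, 2.0
    try:
        s = float(brentq(dw_ds, lo, hi, xtol=1e-16, rtol=1e-15))
    except ValueError:
        s = float(res.x)  # gradient did not bracket; keep the scan minimum

    # envelope theorem: differentiate W in the loading stretch at fixed lateral
    lr = 1.0 / (lam * s)
    if direction == "longitudinal":
        alpha = (s * math.cos(b)) ** 2 + (lam * math.sin(b)) ** 2 - 1.0
        fiber_active = (alpha > 0.0) or not tension_only
        dw = params.c * (lam - lr * lr / lam)
        if fiber_active:
            dw += (2.0 * params.k1 * alpha * math.exp(params.k2 * alpha * alpha)
                   * 2.0 * lam * math.sin(b) ** 2)
    else:
        alpha = (lam * math.cos(b)) ** 2 + (s * math.sin(b)) ** 2 - 1.0
        fiber_active = (alpha > 0.0) or not tension_only
        dw = params.c * (lam - lr * lr / lam)
        if fiber_active:
            dw += (2.0 * params.k1 * alpha * math.exp(params.k2 * alpha * alpha)
                   * 2.0 * lam * math.cos(b) ** 2)
    return lam * dw


def generate_uniaxial_data(
    params: ConstitutiveParams,
    max_stretch: float = 1.5,
    n_points: int = 25,
    noise_sd_rel: float = 0.0,
    seed: int | None = None,
    tension_only: bool = True,
) -> tuple[UniaxialDataset, UniaxialDataset]:
    """Circumferential and longitudinal 2nd-PK vs Green-strain datasets.

    Stretch samples run from 1 to ``max_stretch``; optional multiplicative
    Gaussian noise (relative s.d. ``noise_sd_rel``) is seeded.
    """
    if not max_stretch > 1:
        raise ValueError(f"max_stretch must be > 1, got {max_stretch}")
    lams = np.linspace(1.0, max_stretch, n_points)
    rng = np.random.default_rng(seed)
    out = []
    for direction in ("circumferential", "longitudinal"):
        cauchy = np.array([_oracle_stress(direction, la, params, tension_only) for la in lams])
        pk2 = cauchy / lams**2
        if noise_sd_rel > 0:
            pk2 = pk2 * (1.0 + noise_sd_rel * rng.standard_normal(pk2.shape))
        pk2 = np.maximum(pk2, 0.0)
        strain = 0.5 * (lams**2 - 1.0)
        out.append(UniaxialDataset(direction, strain, pk2))
    return out[0], out[1]


def generate_inflow(
    heart_rate: float = 330.0,
    stroke_volume: float = 0.25,
    ejection_fraction_of_cycle: float = 0.4,
    n_samples: int = 256,
) -> Waveform:
    """Half-sine right-ventricular ejection pulse, zero in diastole.

    Per-cycle volume equals ``stroke_volume`` exactly under the waveform's
    own discrete quadrature; flow is non-negative everywhere (no
    regurgitation).  ``heart_rate`` in bpm, volume in mL.
    """
    if not 0 < ejection_fraction_of_cycle < 1:
        raise ValueError(
            f"ejection_fraction_of_cycle must be in (0,1), got {ejection_fraction_of_cycle}"
        )
    period = 60.0 / heart_rate
    t = np.arange(n_samples) * (period / n_samples)
    t_ej = ejection_fraction_of_cycle * period
    v = np.where(t < t_ej, np.sin(np.pi * np.minimum(t, t_ej) / t_ej), 0.0)
    dt = period / n_samples
    v *= stroke_volume / (v.sum() * dt)
    return Waveform(t, v, period)
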