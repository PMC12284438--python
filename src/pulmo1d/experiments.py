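"""In-silico remodeling experiments: calibration, scenario matrix, deconvolution.

The control model is calibrated so the simulated main-pulmonary-artery pulse
pressure (and optionally the mean pressure) matches measured targets; the
pulmonary-hypertension state is then decomposed into hypothetical single-
mechanism states - proximal/distal stiffening (S_p, S_d), distal resistance
(R_d), and reduced stroke volume - whose pulse-pressure and impedance changes
quantify each remodeling event's contribution and their interaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import impedance as _imp
from .solver import SimulationConfig, SolverError, WindkesselParams, extract_waveforms, simulate
from .tree import VascularTree
from .wall import ConstitutiveParams, apply_stiffness_scaling
from .waveform import Waveform

logger = logging.getLogger(__name__)

__all__ = [
    "RemodelingScenario",
    "ScenarioResult",
    "CalibrationResult",
    "allocate_windkessel",
    "scale_flow_to_co",
    "calibrate_baseline",
    "build_scenario_matrix",
    "run_scenarios",
    "interaction_index",
]

#: canonical scenario labels
CTL = "CTL"
CTL_PH_FLOW = "CTL PH-flow"
SP_ONLY = "Sp only"
SD_ONLY = "Sd only"
S_UP = "S up"
RD_UP = "Rd up"
S_RD_UP = "S up + Rd up"
S_RD_UP_PH_FLOW = "S up + Rd up PH-flow"


@dataclass(frozen=True)
class RemodelingScenario:
    """One hypothetical remodeling state.

    s_p scales the wall constants (c, k1) of every 1D segment; s_d_scale
    divides every terminal compliance (distal stiffening); r_d_scale
    multiplies every terminal resistance; flow selects the inflow waveform.
    """

    label: str
    s_p: float = 1.0
    s_d_scale: float = 1.0
    r_d_scale: float = 1.0
    flow: str = "control"

    def __post_init__(self) -> None:
        for name in ("s_p", "s_d_scale", "r_d_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.flow not in ("control", "ph"):
            raise ValueError(f"flow must be 'control' or 'ph', got {self.flow!r}")


@dataclass(frozen=True)
class ScenarioResult:
    """MPA metrics of one scenario run."""

    label: str
    delta_mpa_pressure: float
    systolic: float
    diastolic: float
    z0: float
    zc: float
    converged: bool

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class CalibrationResult:
    r_total: float          # mmHg.s/mL, parallel total of terminal R1+R2
    c_total: float          # mL/mmHg, summed terminal compliance
    wk_map: dict
    achieved_delta: float   # mmHg
    achieved_mean: float    # mmHg
    n_simulations: int


def allocate_windkessel(tree: VascularTree, r_total: float, c_total: float,
                        rule: str = "murray") -> dict:
    """Distribute total distal resistance/compliance over the terminals.

    'murray': terminal conductance (and compliance) proportional to r^3, so
    the parallel resistance equals ``r_total`` and compliances sum to
    ``c_total``; 'equal': uniform split.  R1 = R2 = half of each terminal's
    total resistance.
    """
    terms = tree.terminal_ids
    if rule == "murray":
        wgt = np.array([tree.segment(t).radius ** 3 for t in terms])
    elif rule == "equal":
        wgt = np.ones(len(terms))
    else:
        raise ValueError(f"unknown allocation rule {rule!r}")
    wgt = wgt / wgt.sum()
    out = {}
    for t, w in zip(terms, wgt):
        r_term = r_total / w
        out[t] = WindkesselParams.from_rd(0.5 * r_term, c_total * w)
    return out


def scale_flow_to_co(waveform: Waveform, cardiac_output: float) -> Waveform:
    """Scale a flow waveform so its per-cycle volume matches a cardiac output.

    ``cardiac_output`` in mL/min; the target cycle volume is CO.T/60.  Shape
    is preserved (uniform multiplicative scaling).
    """
    vol = waveform.cycle_volume()
    if abs(vol) < 1e-12:
        raise ValueError("cannot scale a zero-mean flow waveform to a cardiac output")
    target = cardiac_output * waveform.period / 60.0
    return waveform.scaled(target / vol)


def _mpa_metrics(result, convention: str = "pulse", f_max: float = 250.0):
    p, q = extract_waveforms(result, result.tree.root_id, "proximal")
    spec = _imp.impedance_spectrum(p, q, convention=convention)
    return {
        "delta": _imp.delta_mpa_pressure(p),
        "systolic": float(np.max(p.values)),
        "diastolic": float(np.min(p.values)),
        "mean": p.mean(),
        "z0": _imp.z0(spec),
        "zc": _imp.zc(spec, f_max),
    }


def calibrate_baseline(
    tree: VascularTree,
    inflow: Waveform,
    target_delta_mpa: float,
    params: ConstitutiveParams,
    config: SimulationConfig | None = None,
    target_mean_mpa: float | None = None,
    c_total: float = 0.012,
    r_init: float | None = None,
    rule: str = "murray",
    rel_tol: float = 0.01,
    max_outer: int = 5,
) -> CalibrationResult:
    """Choose baseline Windkessel values matching measured MPA pressures.

    With only a pulse-pressure target the total compliance is held at
    ``c_total`` and the total distal resistance is solved by secant
    iteration.  With ``target_mean_mpa`` also given, resistance is solved
    against the mean pressure and compliance against the pulse pressure,
    alternating (at most ``max_outer`` passes) - the mean responds almost
    purely to resistance and the pulse mostly to compliance.  ``r_init``
    seeds the resistance search (an already-matched model recalibrates to
    itself).
    """
    if not target_delta_mpa > 0:
        raise ValueError("target pulse pressure must be > 0")
    cfg = config or SimulationConfig(warm_start=True)
    if not cfg.warm_start:
        cfg = replace(cfg, warm_start=True)
    qbar = inflow.mean()
    if qbar <= 0:
        raise ValueError("inflow must have positive mean flow")

    n_sim = 0
    metrics_cache: dict = {}

    def run(r_tot: float, c_tot: float):
        nonlocal n_sim
        key = (round(r_tot, 10), round(c_tot, 12))
        if key in metrics_cache:
            return metrics_cache[key]
        wk = allocate_windkessel(tree, r_tot, c_tot, rule)
        res = simulate(tree, wk, inflow, params, cfg)
        n_sim += 1
        m = _mpa_metrics(res)
        metrics_cache[key] = m
        logger.info("calibration sim %d: R=%.3f C=%.5f -> mean %.2f delta %.2f",
                    n_sim, r_tot, c_tot, m["mean"], m["delta"])
        return m

    def secant(f, x0, x1, target, max_eval=6):
        """Drive the monotone response f(x) to ``target`` within rel_tol."""
        y0, y1 = f(x0), f(x1)
        for _ in range(max_eval):
            if abs(y1 - target) <= rel_tol * target:
                return x1
            if y1 == y0:
                break
            x2 = x1 + (target - y1) * (x1 - x0) / (y1 - y0)
            x2 = max(x2, 0.05 * x1)
            x0, y0, x1 = x1, y1, x2
            y1 = f(x1)
        if abs(y1 - target) > 5 * rel_tol * target:
            raise RuntimeError(
                f"calibration could not reach the target: achieved {y1:.4g} "
                f"for target {target:.4g} (last parameter {x1:.4g})"
            )
        return x1

    if target_mean_mpa is not None:
        r_tot = r_init if r_init is not None else max(target_mean_mpa / qbar * 0.9, 1e-3)
        c_tot = c_total
        m = run(r_tot, c_tot)
        for _ in range(max_outer):
            r_tot = secant(lambda r: run(r, c_tot)["mean"], r_tot, 1.1 * r_tot,
                           target_mean_mpa)
            c_tot = secant(lambda c: run(r_tot, c)["delta"], c_tot, 1.2 * c_tot,
                           target_delta_mpa)
            m = run(r_tot, c_tot)
            if (abs(m["mean"] - target_mean_mpa) <= rel_tol * target_mean_mpa
                    and abs(m["delta"] - target_delta_mpa) <= rel_tol * target_delta_mpa):
                break
    else:
        c_tot = c_total
        r0 = r_init if r_init is not None else max(target_delta_mpa / qbar * 0.5, 1e-3)
        r_tot = secant(lambda r: run(r, c_tot)["delta"], r0, 1.3 * r0,
                       target_delta_mpa)
        m = run(r_tot, c_tot)

    return CalibrationResult(
        r_total=r_tot, c_total=c_tot,
        wk_map=allocate_windkessel(tree, r_tot, c_tot, rule),
        achieved_delta=m["delta"], achieved_mean=m["mean"], n_simulations=n_sim,
    )


def build_scenario_matrix(s_p: float = 2.0, s_d_scale: float = 2.0,
                          r_d_scale: float = 3.0,
                          include_single_factors: bool = True) -> list:
    """The hypothetical remodeling states, control through full PH.

    Scales < 1 are allowed (with a warning) but point away from the PH
    direction.  The combined-stiffness state raises S_p and S_d together and
    leaves R_d at baseline; the full state raises all three, with and
    without the PH inflow.
    """
    for name, v in (("s_p", s_p), ("s_d_scale", s_d_scale), ("r_d_scale", r_d_scale)):
        if v < 1.0:
            logger.warning("%s = %.3g < 1 is opposite to the PH direction", name, v)
    out = [
        RemodelingScenario(CTL),
        RemodelingScenario(CTL_PH_FLOW, flow="ph"),
        RemodelingScenario(S_UP, s_p=s_p, s_d_scale=s_d_scale),
        RemodelingScenario(RD_UP, r_d_scale=r_d_scale),
        RemodelingScenario(S_RD_UP, s_p=s_p, s_d_scale=s_d_scale, r_d_scale=r_d_scale),
        RemodelingScenario(S_RD_UP_PH_FLOW, s_p=s_p, s_d_scale=s_d_scale,
                           r_d_scale=r_d_scale, flow="ph"),
    ]
    if include_single_factors:
        out[2:2] = [
            RemodelingScenario(SP_ONLY, s_p=s_p),
            RemodelingScenario(SD_ONLY, s_d_scale=s_d_scale),
        ]
    assert len({s.label for s in out}) == len(out)
    return out


def run_scenarios(
    scenarios,
    tree: VascularTree,
    baseline_wk: dict,
    inflows: dict,
    params: ConstitutiveParams,
    config: SimulationConfig | None = None,
    convention: str = "pulse",
    f_max: float = 250.0,
) -> list:
    """Simulate every scenario and report MPA pulse pressure and impedance.

    ``inflows`` maps 'control' (and, if used, 'ph') to flow waveforms.
    Failures are isolated: a scenario that does not run yields a
    non-converged result with NaN metrics and the batch continues.
    """
    cfg = config or SimulationConfig(warm_start=True)
    out = []
    for sc in scenarios:
        try:
            wall_sc = apply_stiffness_scaling(params, sc.s_p)
            wk_sc = {
                tid: WindkesselParams(
                    wk.R1 * sc.r_d_scale, wk.R2 * sc.r_d_scale,
                    wk.Cd / sc.s_d_scale, allow_unequal=wk.allow_unequal,
                )
                for tid, wk in baseline_wk.items()
            }
            res = simulate(tree, wk_sc, inflows[sc.flow], wall_sc, cfg)
            m = _mpa_metrics(res, convention, f_max)
            out.append(ScenarioResult(
                label=sc.label, delta_mpa_pressure=m["delta"],
                systolic=m["systolic"], diastolic=m["diastolic"],
                z0=m["z0"], zc=m["zc"], converged=res.converged,
            ))
            logger.info("scenario %-22s delta=%.2f Z0=%.3f Zc=%.3f (converged=%s)",
                        sc.label, m["delta"], m["z0"], m["zc"], res.converged)
        except (SolverError, ValueError, KeyError) as exc:
            logger.error("scenario %s failed: %s", sc.label, exc)
            out.append(ScenarioResult(sc.label, math.nan, math.nan, math.nan,
                                      math.nan, math.nan, False))
    return out


def interaction_index(results, baseline_label: str, single_labels,
                      combined_label: str, metric: str = "delta_mpa_pressure") -> float:
    """Non-additivity of remodeling mechanisms for one metric.

    I = (combined - baseline) - sum(single_i - baseline).  Zero for a
    perfectly additive (linear) system; nonzero values signal interaction
    between mechanisms.  Invariant to adding a constant to every metric.
    """
    by_label = {r.label: r for r in results}
    try:
        base = by_label[baseline_label].metric(metric)
        comb = by_label[combined_label].metric(metric)
        singles = [by_label[lb].metric(metric) for lb in single_labels]
    except KeyError as exc:
        raise KeyError(f"missing scenario label {exc}") from None
    return (comb - base) - sum(s - base for s in singles)
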