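"""Estimation of Holzapfel-Ogden wall parameters from uniaxial test data.

Circumferential and longitudinal 2nd-Piola-Kirchhoff vs Green-Lagrange curves
are fitted jointly: every strain sample is converted to a stretch, the
plane-stress uniaxial reduction predicts the surviving Cauchy stress, and the
squared 2nd-PK misfit over both directions (equal per-point weights) is
minimized by bounded trust-region least squares from a seeded Latin-hypercube
multi-start.  Also provides the ex-vivo summary metrics: tangent stiffness of
the stress-strain curve at a given strain and the stress at 50% stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import wall
from .wall import ConstitutiveParams

__all__ = [
    "UniaxialDataset",
    "FitOptions",
    "FitResult",
    "predict_pk2",
    "fit_constitutive",
    "stiffness_at_strain",
    "peak_stress",
]

_DIRECTIONS = ("circumferential", "longitudinal")


@dataclass(frozen=True)
class UniaxialDataset:
    """One direction's uniaxial test: Green strain vs 2nd-PK stress (kPa)."""

    direction: str
    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")
        e = np.asarray(self.strain, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", e)
        object.__setattr__(self, "stress", s)
        if e.ndim != 1 or s.shape != e.shape:
            raise ValueError("strain and stress must be 1D arrays of equal length")
        if np.any(e < 0):
            raise ValueError("Green strain must be non-negative")
        if np.any(np.diff(e) <= 0):
            raise ValueError("strain samples must be strictly increasing")
        if np.any(s < -1e-12):
            raise ValueError("2nd-PK stress must be non-negative in tension")


@dataclass(frozen=True)
class FitOptions:
    """Multi-start nonlinear least-squares settings.

    Bounds: c in (0, 1e3] kPa, k1 in [0, 1e4] kPa, k2 in (0, 1e2],
    beta in [0, 90] degrees.  12 Latin-hypercube starts, fixed seed.
    """

    n_starts: int = 12
    seed: int = 1633548
    tension_only: bool = True
    bounds_lo: tuple = (1e-3, 0.0, 1e-3, 0.0)
    bounds_hi: tuple = (1e3, 1e4, 1e2, 90.0)
    xtol: float = 1e-14
    ftol: float = 1e-14


@dataclass(frozen=True)
class FitResult:
    params: ConstitutiveParams
    residual_sse: float
    n_restarts_converged: int
    per_direction_rmse: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_sse < 0:
            raise ValueError("residual SSE must be >= 0")


def predict_pk2(
    params: ConstitutiveParams,
    direction: str,
    strain: np.ndarray,
    tension_only: bool = True,
) -> np.ndarray:
    """Model 2nd-PK stress (kPa) at Green strains via the uniaxial reduction."""
    lam = wall.stretch_from_green(np.asarray(strain, dtype=float))
    sigma = wall.uniaxial_curve(direction, lam, params, tension_only)
    return wall.cauchy_to_second_pk(sigma, lam)


def _residuals(x, circ, long, tension_only):
    params = ConstitutiveParams(c=x[0], k1=x[1], k2=x[2], beta=x[3])
    try:
        r_c = predict_pk2(params, "circumferential", circ.strain, tension_only) - circ.stress
        r_l = predict_pk2(params, "longitudinal", long.strain, tension_only) - long.stress
    except (OverflowError, RuntimeError):
        # out-of-range trial point: return a large finite residual
        return np.full(circ.strain.size + long.strain.size, 1e6)
    return np.concatenate([r_c, r_l])


def fit_constitutive(
    circ: UniaxialDataset,
    long: UniaxialDataset,
    options: FitOptions | None = None,
) -> FitResult:
    """Jointly fit (c, k1, k2, beta) to both loading directions.

    Both datasets must reach Green strain >= 0.6 so the exponential fiber
    regime is represented.  Returns the best of the multi-start minima;
    raises RuntimeError with per-start diagnostics if no start converges.
    """
    if circ.direction != "circumferential" or long.direction != "longitudinal":
        raise ValueError("datasets must be (circumferential, longitudinal) in that order")
    for ds in (circ, long):
        if ds.strain[-1] < 0.6:
            raise ValueError(
                f"{ds.direction} data must cover Green strain >= 0.6, "
                f"reaches only {ds.strain[-1]:.3g}"
            )
    opts = options or FitOptions()
    lo = np.asarray(opts.bounds_lo)
    hi = np.asarray(opts.bounds_hi)

    # Latin hypercube in (log c, log k1, log k2, beta)
    sampler = qmc.LatinHypercube(d=4, seed=opts.seed)
    u = sampler.random(opts.n_starts)
    log_lo = np.log10([1.0, 1.0, 0.1, 1.0])
    log_hi = np.log10([300.0, 3e3, 50.0, 1.0])
    starts = np.empty_like(u)
    starts[:, :3] = 10 ** (log_lo[:3] + u[:, :3] * (log_hi[:3] - log_lo[:3]))
    starts[:, 3] = 5.0 + u[:, 3] * 80.0

    best = None
    n_ok = 0
    diagnostics = []
    for x0 in starts:
        try:
            sol = least_squares(
                _residuals, x0, bounds=(lo, hi),
                args=(circ, long, opts.tension_only),
                method="trf", x_scale=[10.0, 100.0, 5.0, 45.0],
                xtol=opts.xtol, ftol=opts.ftol, gtol=1e-14, max_nfev=400,
            )
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not sol.success and not np.isfinite(sol.cost):
            diagnostics.append(f"start {x0}: {sol.message}")
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit restarts failed:\n" + "\n".join(diagnostics))

    params = ConstitutiveParams(c=best.x[0], k1=best.x[1], k2=best.x[2], beta=best.x[3])
    nc = circ.strain.size
    rmse = {
        "circumferential": float(np.sqrt(np.mean(best.fun[:nc] ** 2))),
        "longitudinal": float(np.sqrt(np.mean(best.fun[nc:] ** 2))),
    }
    return FitResult(
        params=params,
        residual_sse=float(2.0 * best.cost),
        n_restarts_converged=n_ok,
        per_direction_rmse=rmse,
    )


def stiffness_at_strain(data: UniaxialDataset, e_star: float = 0.6) -> float:
    """Slope (kPa) of the stress-strain curve at Green strain ``e_star``.

    A local quadratic is fitted over the 5 samples nearest ``e_star`` and
    differentiated there; ``e_star`` must lie inside the sampled range.
    """
    e, s = data.strain, data.stress
    if not e[0] <= e_star <= e[-1]:
        raise ValueError(f"E*={e_star} outside sampled range [{e[0]}, {e[-1]}]")
    if e.size < 5:
        raise ValueError("need at least 5 samples for the local quadratic fit")
    idx = np.argsort(np.abs(e - e_star))[:5]
    coeff = np.polyfit(e[idx] - e_star, s[idx], 2)
    return float(coeff[1])  # d/dE at E* of a*(E-E*)^2 + b*(E-E*) + c


def peak_stress(data: UniaxialDataset, stretch_star: float = 1.5) -> float:
    """Stress (kPa) interpolated at the strain equivalent of ``stretch_star``.

    E* = (stretch^2 - 1)/2, i.e. 0.625 for the conventional 50% stretch.
    """
    e_star = float(wall.green_strain(stretch_star))
    if data.strain[-1] < e_star:
        raise ValueError(
            f"data reaches E={data.strain[-1]:.3g} < required {e_star:.3g} "
            f"(stretch {stretch_star})"
        )
    return float(np.interp(e_star, data.strain, data.stress))
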