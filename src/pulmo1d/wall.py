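"""Holzapfel-Ogden arterial wall mechanics.

Single-layer incompressible wall with one symmetric pair of fiber families at
an effective angle ``beta`` to the vessel's longitudinal axis.  The isochoric
Cauchy stress splits into a neo-Hookean ground matrix of stiffness ``c`` and
an exponentially stiffening fiber contribution ``(k1, k2)`` driven by the
fiber invariant

    alpha = lambda_theta^2 cos^2(beta) + lambda_z^2 sin^2(beta) - 1.

Fibers carry load only in tension (``alpha > 0``) by default; the switch is
exposed on every operation.  The transmural equilibrium integral of
``(sigma_theta - sigma_r)/r`` across the deformed wall yields the nonlinear
pressure-area (tube) law that closes the 1D flow equations.

Stresses are in kPa, geometry in cm, pressures at the interface in mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from ._units import KPA_TO_MMHG

__all__ = [
    "ConstitutiveParams",
    "StretchState",
    "WallGeometry",
    "fiber_invariant",
    "isochoric_stress",
    "uniaxial_response",
    "uniaxial_curve",
    "cauchy_to_second_pk",
    "green_strain",
    "stretch_from_green",
    "transmural_pressure",
    "area_from_pressure",
    "reference_area",
    "apply_stiffness_scaling",
    "tangent_stiffness",
    "linear_tube_law",
]

# exp() overflow guard for the fiber term; exp(700) is the float64 ceiling
_MAX_FIBER_EXPONENT = 250.0


@dataclass(frozen=True)
class ConstitutiveParams:
    """Material constants of the single-layer H-O wall.

    c : ground-matrix stiffness (kPa), > 0
    k1 : fiber stiffness (kPa), >= 0
    k2 : fiber exponent (dimensionless), > 0
    beta : effective fiber angle (degrees), in [0, 90]
    """

    c: float
    k1: float
    k2: float
    beta: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"ground-matrix stiffness c must be > 0, got {self.c}")
        if self.k1 < 0:
            raise ValueError(f"fiber stiffness k1 must be >= 0, got {self.k1}")
        if not self.k2 > 0:
            raise ValueError(f"fiber exponent k2 must be > 0, got {self.k2}")
        if not 0.0 <= self.beta <= 90.0:
            raise ValueError(f"fiber angle beta must be in [0, 90] deg, got {self.beta}")


@dataclass(frozen=True)
class StretchState:
    """Principal stretches (r, theta, z); incompressible by construction.

    ``p`` is the hydrostatic-pressure Lagrange multiplier (kPa); it is None
    until a boundary-condition solve (e.g. a uniaxial reduction) fixes it.
    """

    lambda_r: float
    lambda_theta: float
    lambda_z: float
    p: float | None = None

    def __post_init__(self) -> None:
        for name in ("lambda_r", "lambda_theta", "lambda_z"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        j = self.lambda_r * self.lambda_theta * self.lambda_z
        if abs(j - 1.0) > 1e-8:
            raise ValueError(f"incompressibility violated: J = {j!r}")

    @classmethod
    def from_theta_z(cls, lambda_theta: float, lambda_z: float, p: float | None = None) -> "StretchState":
        """Build a state from the in-plane stretches, radial stretch from J=1."""
        return cls(1.0 / (lambda_theta * lambda_z), lambda_theta, lambda_z, p)


@dataclass(frozen=True)
class WallGeometry:
    """Reference (zero transmural pressure) wall geometry, cm."""

    r0: float
    h0: float

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"reference radius r0 must be > 0, got {self.r0}")
        if not self.h0 > 0:
            raise ValueError(f"wall thickness h0 must be > 0, got {self.h0}")
        if not self.h0 < self.r0:
            raise ValueError(
                f"thin-to-moderate wall required (h0 < r0), got h0={self.h0}, r0={self.r0}"
            )

    @classmethod
    def from_ratio(cls, r0: float, wall_ratio: float = 0.10) -> "WallGeometry":
        return cls(r0, wall_ratio * r0)


def fiber_invariant(stretch: StretchState, beta: float) -> float:
    """Fiber invariant alpha = lt^2 cos^2(beta) + lz^2 sin^2(beta) - 1.

    May be negative (fiber families shorter than their reference length).
    """
    b = math.radians(beta)
    return (
        stretch.lambda_theta**2 * math.cos(b) ** 2
        + stretch.lambda_z**2 * math.sin(b) ** 2
        - 1.0
    )


def _fiber_scalar(alpha, k1: float, k2: float, tension_only: bool):
    """4 k1 alpha exp(k2 alpha^2), with the tension-only switch; array-safe."""
    alpha = np.asarray(alpha, dtype=float)
    a = np.where(alpha > 0.0, alpha, 0.0) if tension_only else alpha
    expo = k2 * a * a
    if np.any(expo > _MAX_FIBER_EXPONENT):
        raise OverflowError(
            f"fiber exponent k2*alpha^2 = {float(np.max(expo)):.3g} exceeds the "
            f"overflow guard ({_MAX_FIBER_EXPONENT}); offending alpha = "
            f"{float(alpha.flat[int(np.argmax(expo))]):.6g}"
        )
    return 4.0 * k1 * a * np.exp(expo)


def isochoric_stress(
    stretch: StretchState, params: ConstitutiveParams, tension_only: bool = True
) -> tuple[float, float, float]:
    """Isochoric (deviatoric) normal Cauchy stresses (kPa) in (r, theta, z).

    The three components sum to zero by construction.  Raises OverflowError
    when the fiber exponent would overflow, naming the offending stretch.
    """
    lr, lt, lz = stretch.lambda_r, stretch.lambda_theta, stretch.lambda_z
    b = math.radians(params.beta)
    mt2 = (lt * math.cos(b)) ** 2  # theta-component^2 of the deformed fiber
    mz2 = (lz * math.sin(b)) ** 2
    alpha = mt2 + mz2 - 1.0
    try:
        fib = float(_fiber_scalar(alpha, params.k1, params.k2, tension_only))
    except OverflowError as exc:
        raise OverflowError(f"{exc}; stretch state = {stretch}") from None
    i1_3 = (lr * lr + lt * lt + lz * lz) / 3.0
    tr_fib_3 = (mt2 + mz2) / 3.0
    s_rr = params.c * (lr * lr - i1_3) + fib * (0.0 - tr_fib_3)
    s_tt = params.c * (lt * lt - i1_3) + fib * (mt2 - tr_fib_3)
    s_zz = params.c * (lz * lz - i1_3) + fib * (mz2 - tr_fib_3)
    return s_rr, s_tt, s_zz


def _delta_theta_r(lt, lz, params: ConstitutiveParams, tension_only: bool):
    """sigma_bar_theta - sigma_bar_r for arrays of in-plane stretches (kPa).

    Closed form: c (lt^2 - lr^2) + 4 k1 alpha (lt cos beta)^2 exp(k2 alpha^2),
    with lr = 1/(lt lz).
    """
    lt = np.asarray(lt, dtype=float)
    lz = np.asarray(lz, dtype=float)
    b = math.radians(params.beta)
    lr = 1.0 / (lt * lz)
    alpha = (lt * math.cos(b)) ** 2 + (lz * math.sin(b)) ** 2 - 1.0
    fib = _fiber_scalar(alpha, params.k1, params.k2, tension_only)
    return params.c * (lt * lt - lr * lr) + fib * (lt * math.cos(b)) ** 2


def _delta_z_r(lt, lz, params: ConstitutiveParams, tension_only: bool):
    """sigma_bar_z - sigma_bar_r (kPa), arrays."""
    lt = np.asarray(lt, dtype=float)
    lz = np.asarray(lz, dtype=float)
    b = math.radians(params.beta)
    lr = 1.0 / (lt * lz)
    alpha = (lt * math.cos(b)) ** 2 + (lz * math.sin(b)) ** 2 - 1.0
    fib = _fiber_scalar(alpha, params.k1, params.k2, tension_only)
    return params.c * (lz * lz - lr * lr) + fib * (lz * math.sin(b)) ** 2


def _solve_lateral(direction: str, lam, params: ConstitutiveParams, tension_only: bool):
    """Vectorized solve of the free lateral stretch under uniaxial loading.

    Longitudinal loading (lambda_z = lam): sigma_rr = sigma_theta = 0 forces
    sigma_bar_theta - sigma_bar_r = 0, a monotone-increasing function of the
    free lambda_theta.  Circumferential loading is the mirror case.
    Newton from the isotropic guess lam^-1/2, bisection fallback.
    """
    lam_in = np.asarray(lam, dtype=float)
    lam = np.atleast_1d(lam_in)
    if direction == "longitudinal":
        def g(s, la=lam):
            return np.atleast_1d(_delta_theta_r(s, la, params, tension_only))
    elif direction == "circumferential":
        def g(s, la=lam):
            return np.atleast_1d(_delta_z_r(la, s, params, tension_only))
    else:
        raise ValueError(f"unknown loading direction {direction!r}")

    s = lam**-0.5
    h = 1e-7
    converged = np.zeros(lam.shape, dtype=bool)
    tol = 1e-12 * (params.c + params.k1 + 1.0)
    for _ in range(60):
        val = g(s)
        converged = np.abs(val) < tol
        if np.all(converged):
            break
        deriv = (g(s + h) - g(s - h)) / (2.0 * h)
        step = np.where(converged, 0.0, val / np.where(deriv == 0.0, 1.0, deriv))
        step = np.clip(step, -0.2, 0.2)  # keep Newton inside the physical branch
        s = np.clip(s - step, 1e-4, 2.0)
    if not np.all(converged):
        # bisection fallback on the stragglers (g is monotone increasing in s)
        for i in np.nonzero(~converged)[0]:
            li = lam[i]

            def gi(x, la=li):
                if direction == "longitudinal":
                    return float(_delta_theta_r(x, la, params, tension_only))
                return float(_delta_z_r(la, x, params, tension_only))

            lo = 0.05
            while gi(lo) > 0 and lo > 1e-7:
                lo *= 0.3  # fiber-dominated regimes push the root very low
            try:
                s[i] = brentq(gi, lo, 2.0, xtol=1e-16, rtol=1e-15)
            except ValueError as exc:
                raise RuntimeError(
                    f"lateral-stretch solve failed for {direction} loading at "
                    f"lam={li}: residual {gi(s[i]):.3g} kPa"
                ) from exc
    return s.reshape(lam_in.shape)


def uniaxial_curve(
    direction: str,
    lams: np.ndarray,
    params: ConstitutiveParams,
    tension_only: bool = True,
) -> np.ndarray:
    """Cauchy stress (kPa) along the loading direction for an array of stretches."""
    lams = np.asarray(lams, dtype=float)
    lat = _solve_lateral(direction, lams, params, tension_only)
    if direction == "longitudinal":
        return np.asarray(_delta_z_r(lat, lams, params, tension_only))
    return np.asarray(_delta_theta_r(lams, lat, params, tension_only))


def uniaxial_response(
    direction: str,
    lam: float,
    params: ConstitutiveParams,
    tension_only: bool = True,
) -> tuple[float, StretchState]:
    """Uniaxial plane-stress reduction at a single stretch.

    Solves the two zero-lateral-Cauchy-stress conditions together with
    incompressibility and returns (surviving Cauchy stress in kPa, the solved
    StretchState carrying the hydrostatic multiplier p).
    """
    if lam < 1.0:
        raise ValueError(f"uniaxial response is defined for tension (lam >= 1), got {lam}")
    lat = float(_solve_lateral(direction, np.asarray(float(lam)), params, tension_only))
    if direction == "longitudinal":
        state = StretchState.from_theta_z(lat, float(lam))
    else:
        state = StretchState.from_theta_z(float(lam), lat)
    s_rr, s_tt, s_zz = isochoric_stress(state, params, tension_only)
    p = -s_rr  # sigma_rr = p + sigma_bar_rr = 0
    stress = s_zz + p if direction == "longitudinal" else s_tt + p
    state = replace(state, p=p)
    return float(stress), state


def green_strain(lam):
    """Green-Lagrange strain E = (lam^2 - 1)/2."""
    lam = np.asarray(lam, dtype=float)
    return 0.5 * (lam * lam - 1.0)


def stretch_from_green(strain):
    """Inverse of ``green_strain``."""
    strain = np.asarray(strain, dtype=float)
    return np.sqrt(2.0 * strain + 1.0)


def cauchy_to_second_pk(sigma, lam):
    """Convert uniaxial Cauchy stress to 2nd-Piola-Kirchhoff (incompressible).

    S = sigma / lam^2, paired with Green strain E = (lam^2 - 1)/2.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    return np.asarray(sigma, dtype=float) / (lam * lam)


# 16-point Gauss-Legendre nodes/weights on [-1, 1] for the transmural integral
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)


def transmural_pressure(
    lumen_area: float,
    geom: WallGeometry,
    params: ConstitutiveParams,
    lambda_z: float = 1.0,
    tension_only: bool = True,
) -> float:
    """Transmural pressure (mmHg) at a deformed lumen area (cm^2).

    The circumferential stretch profile through the wall follows from wall
    incompressibility at fixed axial stretch; the radial-equilibrium integral
    of (sigma_bar_theta - sigma_bar_r)/r runs from the deformed inner to the
    deformed outer radius (16-point Gauss-Legendre).  Exactly zero at the
    reference area when lambda_z = 1.
    """
    if not lumen_area > 0:
        raise ValueError(f"lumen area must be > 0, got {lumen_area}")
    ri2 = lumen_area / math.pi
    ri = math.sqrt(ri2)
    wall_ref = (geom.r0 + geom.h0) ** 2 - geom.r0**2
    ro = math.sqrt(ri2 + wall_ref / lambda_z)
    # map GL nodes to [ri, ro]
    r = 0.5 * (ro - ri) * _GL_X + 0.5 * (ro + ri)
    w = 0.5 * (ro - ri) * _GL_W
    big_r2 = geom.r0**2 + lambda_z * (r * r - ri2)  # reference radius^2
    lt = r / np.sqrt(big_r2)
    try:
        integrand = _delta_theta_r(lt, lambda_z, params, tension_only) / r
    except OverflowError as exc:
        raise OverflowError(
            f"transmural integrand overflow at lumen_area={lumen_area} cm^2 "
            f"with params={params}: {exc}"
        ) from None
    p_kpa = float(np.sum(w * integrand))
    return p_kpa * KPA_TO_MMHG


def reference_area(
    geom: WallGeometry,
    params: ConstitutiveParams,
    lambda_z: float = 1.0,
    tension_only: bool = True,
) -> float:
    """Lumen area (cm^2) at zero transmural pressure.

    Equals pi r0^2 when lambda_z = 1; otherwise found by inversion.
    """
    a0 = math.pi * geom.r0**2
    if lambda_z == 1.0:
        return a0
    return area_from_pressure(0.0, geom, params, lambda_z, tension_only)


def area_from_pressure(
    pressure: float,
    geom: WallGeometry,
    params: ConstitutiveParams,
    lambda_z: float = 1.0,
    tension_only: bool = True,
) -> float:
    """Invert the tube law: lumen area (cm^2) at a transmural pressure (mmHg).

    The tube law is strictly increasing in area, so the root is unique;
    bracketing failure reports the attempted interval.
    """
    a0 = math.pi * geom.r0**2

    def f(a):
        return transmural_pressure(a, geom, params, lambda_z, tension_only) - pressure

    lo, hi = 0.3 * a0, 3.0 * a0
    flo, fhi = f(lo), f(hi)
    n_expand = 0
    while flo * fhi > 0 and n_expand < 40:
        if flo > 0:
            lo *= 0.7
            flo = f(lo)
        else:
            hi *= 1.3
            fhi = f(hi)
        n_expand += 1
    if flo * fhi > 0:
        raise ValueError(
            f"could not bracket area for P={pressure} mmHg in "
            f"[{lo:.3g}, {hi:.3g}] cm^2 (tube-law values "
            f"[{flo + pressure:.3g}, {fhi + pressure:.3g}] mmHg)"
        )
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-13))


def apply_stiffness_scaling(params: ConstitutiveParams, s_p: float) -> ConstitutiveParams:
    """Proximal stiffness scaling: c -> S_p c, k1 -> S_p k1; k2, beta unchanged."""
    if not s_p > 0:
        raise ValueError(f"stiffness scale S_p must be > 0, got {s_p}")
    return replace(params, c=s_p * params.c, k1=s_p * params.k1)


def tangent_stiffness(
    geom: WallGeometry,
    params: ConstitutiveParams,
    lambda_z: float = 1.0,
    tension_only: bool = True,
) -> float:
    """dP/dA (mmHg/cm^2) of the nonlinear tube law at its reference area.

    One-sided (inflation) difference: with tension-only fibers the law has a
    slope kink at the reference area, and the inflation branch is the one a
    linearized law should match.
    """
    a_ref = reference_area(geom, params, lambda_z, tension_only)
    h = 1e-6 * a_ref
    return (
        transmural_pressure(a_ref + h, geom, params, lambda_z, tension_only)
        - transmural_pressure(a_ref, geom, params, lambda_z, tension_only)
    ) / h


def linear_tube_law(lumen_area: float, geom: WallGeometry, effective_stiffness: float,
                    reference_lumen_area: float | None = None) -> float:
    """Linearized tube law P = k (A - A_ref), mmHg.

    ``effective_stiffness`` (mmHg/cm^2) is conventionally the tangent of the
    nonlinear law at the reference area, so the two laws agree for small
    deformations and diverge at large ones.
    """
    if not effective_stiffness > 0:
        raise ValueError(f"effective stiffness must be > 0, got {effective_stiffness}")
    a_ref = math.pi * geom.r0**2 if reference_lumen_area is None else reference_lumen_area
    return effective_stiffness * (lumen_area - a_ref)
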