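"""Axisymmetric inflation mechanics of the clamped chip membrane.

The chip well is a thin circular elastomer membrane of radius ``a``,
thickness ``t`` and modulus ``E``, clamped at its rim and inflated by a
uniform hydraulic pressure ``p`` into a dome.  The membrane carries two
principal stresses: the *meridional* stress along lines running from the
apex to the rim, and the *hoop* stress along circles of latitude.  They
satisfy the Laplace membrane-equilibrium relation

    sigma_m / rho_1 + sigma_h / rho_2 = p / t

with ``rho_1, rho_2`` the principal curvature radii of the deformed
surface.  At the apex axisymmetry forces isotropy (``sigma_m = sigma_h``);
at the clamped rim the in-plane radial displacement vanishes, which pins
the hoop strain to zero and makes the meridional stress exceed the hoop
stress there.  The meridional-to-hoop ratio therefore grows from 100 % at
the centre to roughly ``1/nu`` × 100 % at the edge — the stress gradient
that drives region-dependent cell behaviour on the chip.

Two solvers are provided:

``solve_inflation``
    The production solver: finite-rotation axisymmetric membrane ODEs
    (exact deformed-surface curvatures, arbitrary slope) integrated from
    the apex with shooting on the apex stretch.  Constitutive law is an
    incompressible neo-Hookean membrane by default (appropriate for PDMS)
    or a small-strain Hookean membrane.

``hencky_profile``
    An independent small-deflection oracle: the classical Hencky
    power-series solution of the Föppl–von Kármán membrane problem
    (no bending, no pretension, clamped edge), valid for apex
    deflections small compared to the well radius.  It shares no code
    with the shooting solver and is used to cross-check it.

Units throughout: mm, kPa (tensions kPa·mm), pressures kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "MembraneSpec",
    "StressProfile",
    "RegionSummary",
    "SolverError",
    "solve_inflation",
    "solve_for_apex_height",
    "region_partition",
    "laplace_residual",
    "hencky_profile",
    "HenckyProfile",
]


class SolverError(RuntimeError):
    """Raised when the membrane boundary-value iteration fails to converge."""


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry, material and load of one clamped circular membrane.

    Exactly one of ``pressure_kpa`` / ``target_apex_height_mm`` must be
    given.  ``poisson`` is clamped to 0.4999 for numerical stability and
    only used by the linear material; the neo-Hookean membrane is
    incompressible by construction.
    """

    radius_mm: float = 4.0
    thickness_um: float = 100.0
    youngs_kpa: float = 530.0
    poisson: float = 0.49
    pressure_kpa: float | None = None
    target_apex_height_mm: float | None = None
    material: Literal["neo-hookean", "linear"] = "neo-hookean"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.thickness_um <= 0 or self.youngs_kpa <= 0:
            raise ValueError("radius, thickness and modulus must be positive")
        if not (0 <= self.poisson <= 0.5):
            raise ValueError(f"Poisson ratio out of range: {self.poisson}")
        object.__setattr__(self, "poisson", min(self.poisson, 0.4999))
        given = (self.pressure_kpa is not None) + (self.target_apex_height_mm is not None)
        if given != 1:
            raise ValueError(
                "exactly one of pressure_kpa / target_apex_height_mm must be set"
            )
        if self.material not in ("neo-hookean", "linear"):
            raise ValueError(f"unknown material {self.material!r}")

    @property
    def thickness_mm(self) -> float:
        return self.thickness_um * 1e-3


@dataclass(frozen=True)
class RegionSummary:
    """Area-weighted stress summary of one annular region of the well."""

    region: str
    r_inner_mm: float
    r_outer_mm: float
    mean_meridional_kpa: float
    mean_hoop_kpa: float
    ratio_percent: float  # 100 * mean meridional / mean hoop


@dataclass
class StressProfile:
    """Radial stress/deflection profile of one converged inflation state.

    ``r_mm`` is the material (undeformed, well-plane) radial station from
    0 to the well radius; ``r_deformed_mm`` the deformed radial position.
    Stresses are membrane tensions divided by the reference thickness.
    """

    r_mm: np.ndarray
    sigma_meridional_kpa: np.ndarray
    sigma_hoop_kpa: np.ndarray
    deflection_mm: np.ndarray
    slope_rad: np.ndarray
    stretch_meridional: np.ndarray
    stretch_hoop: np.ndarray
    r_deformed_mm: np.ndarray
    pressure_kpa: float
    spec: MembraneSpec
    apex_height_mm: float = field(init=False)
    wrinkled: bool = field(init=False)

    def __post_init__(self) -> None:
        self.apex_height_mm = float(self.deflection_mm[0])
        # Hoop tension dropping to zero signals wrinkling near the clamp;
        # reported, not modelled with tension-field theory.
        self.wrinkled = bool(np.any(self.sigma_hoop_kpa < 0))


# ---------------------------------------------------------------------------
# Constitutive laws: membrane tensions (force / deformed length) and partials
# ---------------------------------------------------------------------------


def _tensions(spec: MembraneSpec, lam1, lam2):
    t = spec.thickness_mm
    if spec.material == "linear":
        c = spec.youngs_kpa * t / (1.0 - spec.poisson**2)
        e1, e2 = lam1 - 1.0, lam2 - 1.0
        return c * (e1 + spec.poisson * e2), c * (e2 + spec.poisson * e1)
    mu_t = spec.youngs_kpa / 3.0 * t
    inv = 1.0 / (lam1**3 * lam2**3)
    return mu_t * (lam1 / lam2 - inv), mu_t * (lam2 / lam1 - inv)


def _tension_partials(spec: MembraneSpec, lam1, lam2):
    """(dT1/dlam1, dT1/dlam2) for the meridional tension."""
    t = spec.thickness_mm
    if spec.material == "linear":
        c = spec.youngs_kpa * t / (1.0 - spec.poisson**2)
        return c, c * spec.poisson
    mu_t = spec.youngs_kpa / 3.0 * t
    d11 = mu_t * (1.0 / lam2 + 3.0 / (lam1**4 * lam2**3))
    d12 = mu_t * (-lam1 / lam2**2 + 3.0 / (lam1**3 * lam2**4))
    return d11, d12


# ---------------------------------------------------------------------------
# Finite-rotation shooting solver
# ---------------------------------------------------------------------------

_SLOPE_LIMIT = 1.50  # rad; beyond this the shot has curled past a usable dome


def _rhs(rho, y, p, spec):
    r, th, lam1, z = y
    lam2 = r / rho
    t1, t2 = _tensions(spec, lam1, lam2)
    d11, d12 = _tension_partials(spec, lam1, lam2)
    s, c = math.sin(th), math.cos(th)
    dr = lam1 * c
    dz = lam1 * s
    dth = lam1 * (p - t2 * s / r) / t1
    dlam2 = (lam1 * c - lam2) / rho
    dlam1 = (lam1 * (t2 - t1) * c / r - d12 * dlam2) / d11
    return (dr, dth, dlam1, dz)


def _shoot(lam0, p, spec, dense=False, t_eval=None):
    """Integrate apex -> rim for a trial apex stretch; return the solution."""
    a = spec.radius_mm
    eps = 1e-8 * a
    t0, _ = _tensions(spec, lam0, lam0)
    if t0 <= 0:
        raise ValueError("apex stretch gives non-positive tension")
    y0 = (lam0 * eps, p * lam0 * eps / (2.0 * t0), lam0, 0.0)

    def curl(rho, y, *_):
        return y[1] - _SLOPE_LIMIT

    curl.terminal = True
    sol = solve_ivp(
        _rhs,
        (eps, a),
        y0,
        args=(p, spec),
        method="RK45",
        rtol=1e-10,
        atol=1e-12,
        dense_output=dense,
        t_eval=t_eval,
        events=curl,
    )
    if sol.status < 0:
        raise SolverError(f"membrane integration failed: {sol.message}")
    return sol


def _find_apex_stretch(p, spec):
    """Shooting: apex stretch such that the deformed rim lands at r = a."""
    a = spec.radius_mm

    def residual(lam0):
        sol = _shoot(lam0, p, spec)
        return sol.y[0, -1] - a

    # Bracket: tiny apex strain -> membrane curls (rim radius short);
    # large apex strain -> membrane nearly flat and overstretched (rim long).
    lo_excess = 1e-9
    hi_excess = lo_excess
    f_lo = residual(1.0 + lo_excess)
    if f_lo > 0:
        raise SolverError("no inflation bracket: residual positive at zero strain")
    f_hi = f_lo
    for _ in range(80):
        hi_excess *= 2.0
        f_hi = residual(1.0 + hi_excess)
        if f_hi > 0:
            break
        lo_excess = hi_excess
    else:
        raise SolverError("failed to bracket the apex stretch")
    return brentq(
        residual, 1.0 + lo_excess, 1.0 + hi_excess, xtol=1e-13, rtol=1e-14, maxiter=200
    )


def _zero_profile(spec: MembraneSpec, n_grid: int) -> StressProfile:
    a = spec.radius_mm
    r = np.linspace(0.0, a, n_grid)
    zeros = np.zeros(n_grid)
    return StressProfile(
        r_mm=r,
        sigma_meridional_kpa=zeros.copy(),
        sigma_hoop_kpa=zeros.copy(),
        deflection_mm=zeros.copy(),
        slope_rad=zeros.copy(),
        stretch_meridional=np.ones(n_grid),
        stretch_hoop=np.ones(n_grid),
        r_deformed_mm=r.copy(),
        pressure_kpa=0.0,
        spec=spec,
    )


def solve_inflation(spec: MembraneSpec, n_grid: int = 400) -> StressProfile:
    """Solve the clamped-membrane inflation problem at a given pressure.

    Shooting on the apex stretch: the finite-rotation membrane ODEs are
    integrated from the apex outward and the apex stretch adjusted until
    the deformed rim meets the clamp at ``r = a`` (zero in-plane radial
    displacement).  Converged solutions satisfy the Laplace equilibrium
    relation pointwise (see :func:`laplace_residual`) and apex isotropy.

    Parameters
    ----------
    spec : MembraneSpec
        Must carry ``pressure_kpa``.
    n_grid : int
        Number of radial stations (>= 50) in the returned profile.

    Raises
    ------
    SolverError
        If the shooting iteration cannot be bracketed or fails.
    """
    if spec.pressure_kpa is None:
        raise ValueError("spec must carry pressure_kpa; use solve_for_apex_height "
                         "to match a target dome height")
    if n_grid < 50:
        raise ValueError("n_grid must be >= 50")
    p = spec.pressure_kpa
    if p < 0:
        raise ValueError("pressure must be nonnegative")
    if p == 0:
        return _zero_profile(spec, n_grid)

    a = spec.radius_mm
    lam0 = _find_apex_stretch(p, spec)
    rho = np.linspace(0.0, a, n_grid)
    eps = 1e-8 * a
    t_eval = np.clip(rho, eps, a)
    sol = _shoot(lam0, p, spec, t_eval=t_eval)
    if sol.t.size != n_grid:
        raise SolverError("integration terminated before the rim "
                          "(pressure beyond the representable dome range)")
    r_def, th, lam1, z = sol.y
    lam2 = r_def / t_eval
    # Apex station: exact limits by axisymmetry.
    r_def[0], th[0], lam2[0] = 0.0, 0.0, lam1[0]
    t1, t2 = _tensions(spec, lam1, lam2)
    h = z[-1]
    t = spec.thickness_mm
    return StressProfile(
        r_mm=rho,
        sigma_meridional_kpa=t1 / t,
        sigma_hoop_kpa=t2 / t,
        deflection_mm=h - z,
        slope_rad=th,
        stretch_meridional=lam1,
        stretch_hoop=lam2,
        r_deformed_mm=r_def,
        pressure_kpa=p,
        spec=spec,
    )


def solve_for_apex_height(
    spec: MembraneSpec, n_grid: int = 400, height_rtol: float = 1e-4
) -> tuple[float, StressProfile]:
    """Find the pressure whose inflated dome reaches a target apex height.

    Bisection (Brent) on pressure; the apex height is monotone in pressure
    over the sub-hemisphere range.  Returns ``(pressure_kpa, profile)``
    with the profile's apex height within ``height_rtol * a`` of target.
    """
    h_target = spec.target_apex_height_mm
    if h_target is None:
        raise ValueError("spec must carry target_apex_height_mm")
    a = spec.radius_mm
    if h_target < 0 or h_target >= a:
        raise ValueError(
            f"target apex height {h_target} mm unattainable for a {a} mm well "
            "(sub-hemisphere domes only)"
        )
    if h_target == 0:
        zspec = replace(spec, target_apex_height_mm=None, pressure_kpa=0.0)
        return 0.0, _zero_profile(zspec, n_grid)

    # Initial pressure scale from the small-deflection cube law
    # h ~ 0.65 a (p a / E t)^(1/3)  =>  p ~ (E t / a) (h / 0.65 a)^3.
    et = spec.youngs_kpa * spec.thickness_mm
    p_guess = et / a * (h_target / (0.65 * a)) ** 3

    def solved(p):
        pspec = replace(spec, target_apex_height_mm=None, pressure_kpa=p)
        return solve_inflation(pspec, n_grid=n_grid)

    p_lo, p_hi = p_guess, p_guess
    h_hi = solved(p_hi).apex_height_mm
    for _ in range(60):
        if h_hi >= h_target:
            break
        p_lo = p_hi
        p_hi *= 2.0
        h_hi = solved(p_hi).apex_height_mm
    else:
        raise SolverError("could not bracket the target apex height from above")
    h_lo = solved(p_lo).apex_height_mm
    for _ in range(60):
        if h_lo <= h_target:
            break
        p_hi = p_lo
        p_lo /= 2.0
        h_lo = solved(p_lo).apex_height_mm
    else:
        raise SolverError("could not bracket the target apex height from below")

    p_star = brentq(
        lambda p: solved(p).apex_height_mm - h_target,
        p_lo,
        p_hi,
        xtol=max(p_guess * 1e-10, 1e-14),
        rtol=1e-12,
        maxiter=200,
    )
    profile = solved(p_star)
    if abs(profile.apex_height_mm - h_target) > height_rtol * a:
        raise SolverError("apex-height match did not reach tolerance")
    return p_star, profile


# ---------------------------------------------------------------------------
# Diagnostics and region summaries
# ---------------------------------------------------------------------------


def laplace_residual(profile: StressProfile) -> np.ndarray:
    """Pointwise Laplace-equilibrium residual ``s_m k_1 + s_h k_2 - p/t``.

    The principal curvatures of the deformed surface are recomputed by
    finite differences of the stored slope angle (meridional curvature
    ``k_1 = d(theta)/ds`` along the deformed arc) and from ``k_2 =
    sin(theta)/r`` (hoop curvature), so the check is independent of the
    solver's internal equilibrium bookkeeping.  Returned in kPa/mm on the
    interior stations (endpoints excluded).
    """
    th = profile.slope_rad
    rho = profile.r_mm
    dth = np.gradient(th, rho)
    kappa1 = dth / profile.stretch_meridional
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa2 = np.sin(th) / profile.r_deformed_mm
    kappa2[0] = kappa1[0]
    t = profile.spec.thickness_mm
    res = (
        profile.sigma_meridional_kpa * kappa1
        + profile.sigma_hoop_kpa * kappa2
        - profile.pressure_kpa / t
    )
    return res[1:-1]


def region_partition(
    profile: StressProfile, bounds: tuple[float, float] | None = None
) -> dict[str, RegionSummary]:
    """Area-weighted stress means over the centre/slope/edge annuli.

    ``bounds = (r1, r2)`` are radii in well-plane mm splitting the well
    into A1 = [0, r1), A2 = [r1, r2), A3 = [r2, a]; default thirds of the
    well radius.  Means are weighted by the annular area element
    ``2 pi r dr``; the reported ratio is 100 x (mean meridional)/(mean
    hoop) per region.
    """
    a = profile.spec.radius_mm
    if bounds is None:
        bounds = (a / 3.0, 2.0 * a / 3.0)
    r1, r2 = bounds
    if not (0 < r1 < r2 < a):
        raise ValueError(f"region bounds must satisfy 0 < r1 < r2 < a, got {bounds}")

    def annulus_mean(values, lo, hi):
        grid = np.unique(np.concatenate([[lo, hi], profile.r_mm]))
        grid = grid[(grid >= lo) & (grid <= hi)]
        v = np.interp(grid, profile.r_mm, values)
        num = np.trapezoid(v * 2.0 * np.pi * grid, grid)
        den = np.pi * (hi**2 - lo**2)
        return num / den

    out: dict[str, RegionSummary] = {}
    for name, lo, hi in (("A1", 0.0, r1), ("A2", r1, r2), ("A3", r2, a)):
        m = annulus_mean(profile.sigma_meridional_kpa, lo, hi)
        hp = annulus_mean(profile.sigma_hoop_kpa, lo, hi)
        ratio = 100.0 * m / hp if hp > 0 else math.nan
        out[name] = RegionSummary(name, lo, hi, m, hp, ratio)
    return out


# ---------------------------------------------------------------------------
# Independent small-deflection oracle: Hencky power series (FvK membrane)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HenckyProfile:
    """Small-deflection membrane solution from the Hencky power series."""

    r_mm: np.ndarray
    sigma_meridional_kpa: np.ndarray
    sigma_hoop_kpa: np.ndarray
    deflection_mm: np.ndarray
    apex_deflection_mm: float
    pressure_kpa: float


def _hencky_coeffs(b0: float, n_terms: int) -> np.ndarray:
    """Series coefficients of s(x) = sum b_n x^(2n) for the Hencky ODE.

    The dimensionless radial-tension profile satisfies
    ``x^2 s'' + 3 x s' + x^2 / s^2 = 0``; expanding in even powers gives
    the recursion ``b_n = -c_(n-1) / (4 n (n+1))`` where ``c`` are the
    series coefficients of ``1/s^2``.
    """
    b = np.zeros(n_terms)
    d = np.zeros(n_terms)  # s^2
    c = np.zeros(n_terms)  # 1/s^2
    b[0] = b0
    d[0] = b0 * b0
    c[0] = 1.0 / d[0]
    for n in range(1, n_terms):
        b[n] = -c[n - 1] / (4.0 * n * (n + 1))
        d[n] = np.dot(b[: n + 1], b[n::-1])
        c[n] = -np.dot(c[:n], d[n:0:-1]) / d[0]
    return b


def hencky_profile(
    pressure_kpa: float,
    radius_mm: float = 4.0,
    thickness_um: float = 100.0,
    youngs_kpa: float = 530.0,
    poisson: float = 0.49,
    n_terms: int = 60,
    n_grid: int = 400,
) -> HenckyProfile:
    """Föppl–von Kármán (Hencky) series solution for small deflections.

    Classical power-series solution of the pretension-free clamped
    circular membrane under uniform pressure, with the edge condition of
    zero radial displacement (``N_theta = nu N_r`` at the rim).  Valid
    for apex deflections small relative to the radius; used as the
    independent oracle for :func:`solve_inflation`.
    """
    if pressure_kpa <= 0:
        raise ValueError("pressure must be positive")
    a, t = radius_mm, thickness_um * 1e-3
    et = youngs_kpa * t
    alpha = (et * pressure_kpa**2 * a**2 / 8.0) ** (1.0 / 3.0)

    def edge_bc(b0):
        b = _hencky_coeffs(b0, n_terms)
        n = np.arange(n_terms)
        return float(np.sum(2.0 * n * b) + (1.0 - poisson) * np.sum(b))

    b0 = brentq(edge_bc, 0.3, 10.0, xtol=1e-14, rtol=1e-15)
    b = _hencky_coeffs(b0, n_terms)
    if abs(b[-1]) > 1e-12 * abs(b[0]):
        raise SolverError("Hencky series did not converge; increase n_terms")

    x = np.linspace(0.0, 1.0, n_grid)
    powers = x[:, None] ** (2 * np.arange(n_terms))[None, :]
    s = powers @ b
    ns = np.arange(n_terms)
    sp = powers @ (2.0 * ns * b) / np.where(x > 0, x, 1.0)  # s'(x), x>0
    sp[0] = 0.0
    n_r = alpha * s
    n_th = alpha * (s + x * sp)
    # w'(x) = -p a^2 x / (2 alpha s); integrate inward from the rim.
    integrand = x / s
    w = np.zeros_like(x)
    w[:-1] = (
        pressure_kpa
        * a**2
        / (2.0 * alpha)
        * np.flip(np.cumsum(np.flip((integrand[1:] + integrand[:-1]) / 2.0 * np.diff(x)))).copy()
    )
    return HenckyProfile(
        r_mm=x * a,
        sigma_meridional_kpa=n_r / t,
        sigma_hoop_kpa=n_th / t,
        deflection_mm=w,
        apex_deflection_mm=float(w[0]),
        pressure_kpa=pressure_kpa,
    )
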