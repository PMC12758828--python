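"""Rheological velocity-profile models for pressure-driven tube flow.

Implements, in strict SI units, the five velocity/viscosity models used to
describe blood flow in cylindrical microchannels:

* Newtonian Poiseuille flow,
* power-law (Ostwald-de Waele) flow,
* Carreau shear-thinning flow (viscosity law plus a numerical tube-flow
  solver),
* the empirical double-parameter power (DPP) velocity shape, and
* the two-phase core-plasma model: a power-law red-blood-cell-rich core of
  radius R - delta surrounded by a Newtonian plasma annulus (the cell-free
  layer, CFL), with velocity continuity at the interface and no slip at the
  wall.

All profiles are returned on the positive-magnitude convention (speeds are
non-negative, maximal on the centerline), and shear rates are returned as
magnitudes.  ``r`` may be a scalar or array and is interpreted as a signed
radial coordinate; evaluation is even in ``r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import integrate

from .datatypes import (
    ChannelGeometry,
    DomainError,
    FlowCondition,
    NumericalError,
    ValidationError,
    VelocityProfile,
)

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "NewtonianParams",
    "PowerLawParams",
    "CarreauParams",
    "DPPParams",
    "CorePlasmaParams",
    "newtonian_velocity",
    "powerlaw_velocity",
    "carreau_viscosity",
    "carreau_shear_rate",
    "carreau_velocity",
    "carreau_velocity_profile",
    "dpp_velocity",
    "coreplasma_velocity",
    "coreplasma_shear_rate",
    "apparent_viscosity",
    "volumetric_flow",
    "evaluate_velocity",
    "model_kind_of",
    "PARAM_TYPES",
]


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NewtonianParams:
    """Constant-viscosity fluid: mu is the dynamic viscosity (Pa*s)."""

    mu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValidationError(f"mu must be > 0, got {self.mu}")


@dataclass(frozen=True)
class PowerLawParams:
    """Power-law fluid tau = K * gammadot**n.

    K_p is the consistency index (Pa*s^n); n_p the flow behavior index
    (n < 1 shear-thinning, n = 1 Newtonian, n > 1 shear-thickening).
    """

    K_p: float
    n_p: float

    def __post_init__(self) -> None:
        if not (self.K_p > 0):
            raise ValidationError(f"K_p must be > 0, got {self.K_p}")
        if not (0 < self.n_p <= 4):
            raise ValidationError(f"n_p must lie in (0, 4], got {self.n_p}")


@dataclass(frozen=True)
class CarreauParams:
    """Carreau viscosity law interpolating plateau viscosities.

    mu(gammadot) = mu_inf + (mu0 - mu_inf) * [1 + (lambda_c*gammadot)^2]^((n_c-1)/2)
    """

    mu0: float
    mu_inf: float
    lambda_c: float
    n_c: float

    def __post_init__(self) -> None:
        if not (self.mu_inf > 0):
            raise ValidationError(f"mu_inf must be > 0, got {self.mu_inf}")
        if not (self.mu0 >= self.mu_inf):
            raise ValidationError(
                f"mu0 must be >= mu_inf, got mu0={self.mu0}, mu_inf={self.mu_inf}"
            )
        if not (self.lambda_c >= 0):
            raise ValidationError(f"lambda_c must be >= 0, got {self.lambda_c}")
        if not (0 < self.n_c <= 1):
            raise ValidationError(f"n_c must lie in (0, 1], got {self.n_c}")


@dataclass(frozen=True)
class DPPParams:
    """Double-parameter power velocity shape u = Vmax(1-k1(r/R)^2)(1-(r/R)^k2).

    k1 sets the near-wall velocity gradient, k2 the core bluntness; this is a
    purely empirical fit and carries no viscosity information.
    """

    v_max: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.v_max > 0):
            raise ValidationError(f"v_max must be > 0, got {self.v_max}")
        if not (0 <= self.k1 <= 1):
            raise ValidationError(f"k1 must lie in [0, 1], got {self.k1}")
        if not (self.k2 > 0):
            raise ValidationError(f"k2 must be > 0, got {self.k2}")


@dataclass(frozen=True)
class CorePlasmaParams:
    """Two-phase core-plasma model parameters.

    mu_p : Newtonian viscosity of the plasma cell-free layer (Pa*s).
    K_cp, n_cp : power-law consistency and flow-behavior indices of the
        RBC-rich core.
    delta : cell-free-layer thickness (m); the core occupies |r| < R - delta.
    """

    mu_p: float
    K_cp: float
    n_cp: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.mu_p > 0):
            raise ValidationError(f"mu_p must be > 0, got {self.mu_p}")
        if not (self.K_cp > 0):
            raise ValidationError(f"K_cp must be > 0, got {self.K_cp}")
        if not (0 < self.n_cp <= 4):
            raise ValidationError(f"n_cp must lie in (0, 4], got {self.n_cp}")
        if not (self.delta >= 0):
            raise ValidationError(f"delta must be >= 0, got {self.delta}")


PARAM_TYPES = {
    "newtonian": NewtonianParams,
    "powerlaw": PowerLawParams,
    "carreau": CarreauParams,
    "dpp": DPPParams,
    "coreplasma": CorePlasmaParams,
}
_KIND_OF_TYPE = {cls: kind for kind, cls in PARAM_TYPES.items()}


def model_kind_of(params) -> str:
    """Return the model-kind label for a parameter record."""
    try:
        return _KIND_OF_TYPE[type(params)]
    except KeyError:
        raise ValidationError(f"unknown parameter record {type(params).__name__}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_radius(r: ArrayLike, R: float) -> np.ndarray:
    ra = np.abs(np.asarray(r, dtype=float))
    if np.any(ra > R * (1 + 1e-12)):
        raise DomainError(f"|r| exceeds tube radius R={R}")
    return np.minimum(ra, R)


def _wall_shear_stress(r_abs: np.ndarray, geom: ChannelGeometry, dp: float) -> np.ndarray:
    """Linear shear-stress distribution tau(r) = dP*r/(2L)."""
    return dp * r_abs / (2.0 * geom.length)


def _check_dp(dp: float) -> None:
    if not (dp > 0):
        raise ValidationError(f"pressure drop must be > 0, got {dp}")


# ---------------------------------------------------------------------------
# closed-form velocity profiles
# ---------------------------------------------------------------------------

def newtonian_velocity(
    r: ArrayLike, geom: ChannelGeometry, dp: float, p: NewtonianParams
) -> ArrayLike:
    """Poiseuille profile u(r) = dP (R^2 - r^2) / (4 mu L)."""
    _check_dp(dp)
    ra = _check_radius(r, geom.radius)
    u = dp * (geom.radius**2 - ra**2) / (4.0 * p.mu * geom.length)
    return u if np.ndim(r) else float(u)


def powerlaw_velocity(
    r: ArrayLike, geom: ChannelGeometry, dp: float, p: PowerLawParams
) -> ArrayLike:
    """Power-law tube flow profile.

    u(r) = (dP/(2 K L))^(1/n) * n/(n+1) * (R^((n+1)/n) - |r|^((n+1)/n))
    """
    _check_dp(dp)
    ra = _check_radius(r, geom.radius)
    n = p.n_p
    e = (n + 1.0) / n
    pref = (dp / (2.0 * p.K_p * geom.length)) ** (1.0 / n) * n / (n + 1.0)
    u = pref * (geom.radius**e - ra**e)
    return u if np.ndim(r) else float(u)


def dpp_velocity(r: ArrayLike, R: float, p: DPPParams) -> ArrayLike:
    """Empirical DPP shape u = Vmax (1 - k1 (r/R)^2)(1 - (|r|/R)^k2)."""
    if not (R > 0):
        raise ValidationError(f"R must be > 0, got {R}")
    ra = _check_radius(r, R)
    x = ra / R
    u = p.v_max * (1.0 - p.k1 * x**2) * (1.0 - x**p.k2)
    return u if np.ndim(r) else float(u)


def coreplasma_velocity(
    r: ArrayLike, geom: ChannelGeometry, dp: float, p: CorePlasmaParams
) -> ArrayLike:
    """Two-phase core-plasma velocity profile.

    CFL annulus (|r| >= R - delta): Newtonian Poiseuille in the plasma,
        u = dP (R^2 - r^2) / (4 mu_p L).
    Core (|r| < R - delta): power-law profile shifted to meet the annulus
    speed at the interface (velocity continuity),
        u = (dP/(2 K L))^(1/n) n/(n+1) [(R-d)^((n+1)/n) - |r|^((n+1)/n)]
            + dP (R^2 - (R-d)^2) / (4 mu_p L).

    Continuous at |r| = R - delta; u(R) = 0; monotone non-increasing in |r|.
    """
    _check_dp(dp)
    R, L = geom.radius, geom.length
    if not (p.delta < R):
        raise ValidationError(f"delta must be < R, got delta={p.delta}, R={R}")
    ra = _check_radius(r, R)
    rc = R - p.delta
    n = p.n_cp
    e = (n + 1.0) / n
    pref = (dp / (2.0 * p.K_cp * L)) ** (1.0 / n) * n / (n + 1.0)
    u_interface = dp * (R**2 - rc**2) / (4.0 * p.mu_p * L)
    u_cfl = dp * (R**2 - ra**2) / (4.0 * p.mu_p * L)
    u_core = pref * (rc**e - ra**e) + u_interface
    u = np.where(ra >= rc, u_cfl, u_core)
    return u if np.ndim(r) else float(u)


def coreplasma_shear_rate(
    r: ArrayLike, geom: ChannelGeometry, dp: float, p: CorePlasmaParams
) -> ArrayLike:
    """Shear-rate magnitude |du/dr| of the core-plasma profile.

    CFL annulus: dP |r| / (2 mu_p L);  core: (dP |r| / (2 K L))^(1/n).
    The shear stress tau = dP r/(2L) is continuous across the interface even
    though the shear rate jumps there (viscosity contrast).
    """
    _check_dp(dp)
    R, L = geom.radius, geom.length
    if not (p.delta < R):
        raise ValidationError(f"delta must be < R, got delta={p.delta}, R={R}")
    ra = _check_radius(r, R)
    rc = R - p.delta
    g_cfl = dp * ra / (2.0 * p.mu_p * L)
    g_core = (dp * ra / (2.0 * p.K_cp * L)) ** (1.0 / p.n_cp)
    g = np.where(ra >= rc, g_cfl, g_core)
    return g if np.ndim(r) else float(g)


# ---------------------------------------------------------------------------
# Carreau model
# ---------------------------------------------------------------------------

def carreau_viscosity(gamma: ArrayLike, p: CarreauParams) -> ArrayLike:
    """Carreau viscosity mu(gammadot); bounded in [mu_inf, mu0]."""
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise ValidationError("shear rate must be >= 0")
    mu = p.mu_inf + (p.mu0 - p.mu_inf) * (1.0 + (p.lambda_c * g) ** 2) ** (
        (p.n_c - 1.0) / 2.0
    )
    return mu if np.ndim(gamma) else float(mu)


def _carreau_gamma_from_stress(tau: np.ndarray, p: CarreauParams, rtol: float = 1e-12,
                               max_iter: int = 200) -> np.ndarray:
    """Invert mu(gamma)*gamma = tau for gamma, vectorized.

    mu(gamma)*gamma is strictly increasing in gamma, and since
    mu_inf <= mu(gamma) <= mu0 the root is bracketed by
    [tau/mu0, tau/mu_inf]; bisection on that bracket converges
    unconditionally.
    """
    tau = np.asarray(tau, dtype=float)
    lo = tau / p.mu0
    hi = tau / p.mu_inf
    if p.mu0 == p.mu_inf:
        return hi.copy()
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = carreau_viscosity(mid, p) * mid - tau
        hi = np.where(f >= 0, mid, hi)
        lo = np.where(f < 0, mid, lo)
        span = hi - lo
        scale = np.maximum(hi, 1e-300)
        if np.all(span <= rtol * scale):
            break
    else:
        worst = int(np.argmax((hi - lo) / np.maximum(hi, 1e-300)))
        raise NumericalError(
            f"Carreau shear-rate inversion did not converge (stress index {worst})"
        )
    return 0.5 * (lo + hi)


def carreau_shear_rate(
    r: ArrayLike, geom: ChannelGeometry, dp: float, p: CarreauParams
) -> ArrayLike:
    """Shear-rate magnitude at radius r from the local stress balance."""
    _check_dp(dp)
    ra = _check_radius(r, geom.radius)
    g = _carreau_gamma_from_stress(_wall_shear_stress(np.atleast_1d(ra), geom, dp), p)
    return g if np.ndim(r) else float(g[0])


def carreau_velocity(
    r: ArrayLike,
    geom: ChannelGeometry,
    dp: float,
    p: CarreauParams,
    num_nodes: int = 4001,
) -> ArrayLike:
    """Carreau tube-flow velocity by stress-balance inversion + quadrature.

    For fully developed flow the shear stress is tau(r) = dP*r/(2L)
    regardless of the constitutive law.  At each radius the shear rate is
    the unique root of mu(gamma)*gamma = tau(r); the velocity follows by
    integrating the shear rate inward from the no-slip wall,
    u(r) = int_r^R gamma(s) ds, evaluated by the trapezoid rule on a dense
    uniform grid of ``num_nodes`` points (>= 2000 recommended).
    """
    _check_dp(dp)
    if num_nodes < 3:
        raise ValidationError("num_nodes must be >= 3")
    R = geom.radius
    ra = np.atleast_1d(_check_radius(r, R))
    # the requested radii join the integration grid so u is read off exact
    # trapezoid nodes rather than re-interpolated
    s = np.union1d(np.linspace(0.0, R, num_nodes), ra)
    gamma = _carreau_gamma_from_stress(_wall_shear_stress(s, geom, dp), p)
    seg = 0.5 * (gamma[1:] + gamma[:-1]) * np.diff(s)
    u_from_wall = np.concatenate([[0.0], np.cumsum(seg[::-1])])[::-1]
    idx = np.searchsorted(s, ra)
    u = u_from_wall[np.minimum(idx, len(s) - 1)]
    u[ra >= R] = 0.0
    return u if np.ndim(r) else float(u[0])


def carreau_velocity_profile(
    grid: np.ndarray,
    geom: ChannelGeometry,
    dp: float,
    p: CarreauParams,
    num_nodes: int = 4001,
    condition: FlowCondition | None = None,
) -> VelocityProfile:
    """Evaluate the Carreau solver on a radial grid and wrap the result."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be 1-d and strictly increasing")
    u = carreau_velocity(grid, geom, dp, p, num_nodes=num_nodes)
    cond = condition if condition is not None else FlowCondition(delta_p=dp)
    return VelocityProfile(r=grid, u=np.maximum(u, 0.0), geometry=geom, condition=cond)


# ---------------------------------------------------------------------------
# Poiseuille inversion and flow rates
# ---------------------------------------------------------------------------

def apparent_viscosity(q: float, dp: float, geom: ChannelGeometry) -> float:
    """Apparent viscosity mu_app = pi R^4 dP / (8 Q L) (Poiseuille inversion)."""
    if not (q > 0):
        raise ValidationError(f"flow rate must be > 0, got {q}")
    _check_dp(dp)
    return math.pi * geom.radius**4 * dp / (8.0 * q * geom.length)


def volumetric_flow(params, geom: ChannelGeometry, dp: float) -> float:
    """Volumetric flow rate Q = 2 pi int_0^R u(r) r dr for any model.

    Closed forms are used for the Newtonian and power-law profiles;
    adaptive quadrature (relative tolerance 1e-9) otherwise.  DPP profiles
    carry no pressure dependence; ``dp`` is ignored for them.
    """
    R = geom.radius
    if isinstance(params, NewtonianParams):
        _check_dp(dp)
        return math.pi * dp * R**4 / (8.0 * params.mu * geom.length)
    if isinstance(params, PowerLawParams):
        _check_dp(dp)
        n = params.n_p
        return (
            math.pi
            * n
            / (3.0 * n + 1.0)
            * (dp / (2.0 * params.K_p * geom.length)) ** (1.0 / n)
            * R ** ((3.0 * n + 1.0) / n)
        )
    if isinstance(params, CorePlasmaParams):
        _check_dp(dp)

        def integrand(r):
            return coreplasma_velocity(r, geom, dp, params) * r

        val, err = integrate.quad(
            integrand, 0.0, R, points=[R - params.delta], epsrel=1e-9, limit=200
        )
        return 2.0 * math.pi * _quad_checked(val, err)
    if isinstance(params, CarreauParams):
        _check_dp(dp)
        # integrate by parts: 2 pi int u r dr = pi int gamma(s) s^2 ds
        def integrand(s):
            tau = np.atleast_1d(_wall_shear_stress(np.atleast_1d(s), geom, dp))
            return float(_carreau_gamma_from_stress(tau, params)[0]) * s**2

        val, err = integrate.quad(integrand, 0.0, R, epsrel=1e-9, limit=200)
        return math.pi * _quad_checked(val, err)
    if isinstance(params, DPPParams):

        def integrand(r):
            return dpp_velocity(r, R, params) * r

        val, err = integrate.quad(integrand, 0.0, R, epsrel=1e-9, limit=200)
        return 2.0 * math.pi * _quad_checked(val, err)
    raise ValidationError(f"unknown parameter record {type(params).__name__}")


def _quad_checked(val: float, err: float) -> float:
    if not np.isfinite(val) or (val != 0 and err > 1e-6 * abs(val)):
        raise NumericalError(f"quadrature failed (value={val}, error={err})")
    return val


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def evaluate_velocity(
    params,
    r: ArrayLike,
    geom: ChannelGeometry,
    dp: float,
    carreau_nodes: int = 4001,
) -> ArrayLike:
    """Evaluate any model's velocity at signed radii ``r``."""
    if isinstance(params, NewtonianParams):
        return newtonian_velocity(r, geom, dp, params)
    if isinstance(params, PowerLawParams):
        return powerlaw_velocity(r, geom, dp, params)
    if isinstance(params, CarreauParams):
        return carreau_velocity(r, geom, dp, params, num_nodes=carreau_nodes)
    if isinstance(params, DPPParams):
        return dpp_velocity(r, geom.radius, params)
    if isinstance(params, CorePlasmaParams):
        return coreplasma_velocity(r, geom, dp, params)
    raise ValidationError(f"unknown parameter record {type(params).__name__}")


def evaluate_shear_rate(
    params,
    r: ArrayLike,
    geom: ChannelGeometry,
    dp: float,
) -> ArrayLike:
    """Evaluate a model's shear-rate magnitude at signed radii ``r``.

    Closed-form for Newtonian, power-law, DPP and core-plasma; the stress
    balance inversion for Carreau.
    """
    R = geom.radius
    if isinstance(params, NewtonianParams):
        _check_dp(dp)
        ra = _check_radius(r, R)
        g = dp * ra / (2.0 * params.mu * geom.length)
        return g if np.ndim(r) else float(g)
    if isinstance(params, PowerLawParams):
        _check_dp(dp)
        ra = _check_radius(r, R)
        g = (dp * ra / (2.0 * params.K_p * geom.length)) ** (1.0 / params.n_p)
        return g if np.ndim(r) else float(g)
    if isinstance(params, CarreauParams):
        return carreau_shear_rate(r, geom, dp, params)
    if isinstance(params, DPPParams):
        ra = _check_radius(r, R)
        x = np.atleast_1d(ra / R)
        # |du/dr| of Vmax(1-k1 x^2)(1-x^k2), x = |r|/R
        k2 = params.k2
        xs = np.where(x > 0, x, 1.0)
        pow_term = np.where(
            x > 0, xs ** (k2 - 1.0), 1.0 if k2 == 1.0 else (0.0 if k2 > 1 else np.inf)
        )
        dudx = params.v_max * (
            2.0 * params.k1 * x * (1.0 - x**k2)
            + (1.0 - params.k1 * x**2) * k2 * pow_term
        )
        g = np.abs(dudx) / R
        return g if np.ndim(r) else float(g[0])
    if isinstance(params, CorePlasmaParams):
        return coreplasma_shear_rate(r, geom, dp, params)
    raise ValidationError(f"unknown parameter record {type(params).__name__}")
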