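"""Bounded nonlinear least-squares fitting of velocity-profile models.

Each rheological model is fitted to a measured (or simulated) velocity
profile by trust-region reflective least squares on the velocity residual
``u_obs - u_model(r)``.  Goodness of fit is summarized by the global RMS
velocity error and, when a cell-free-layer thickness is known, by regional
RMS errors over the RBC-rich core (|r| < R - delta) and the CFL annulus
(|r| >= R - delta).  When a measured shear-rate profile is supplied the
corresponding shear RMS errors are reported as well, using each model's
analytic shear rate (the stress-balance inversion for Carreau).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import ShearRateProfile, ValidationError, VelocityProfile
from . import models as m

__all__ = [
    "FitOptions",
    "FitResult",
    "ComparisonTable",
    "rms_error",
    "regional_rms",
    "fit_model",
    "compare_models",
    "DEFAULT_MODELS",
    "REFERENCE_VISCOSITY",
]

DEFAULT_MODELS = ("carreau", "coreplasma", "dpp", "newtonian", "powerlaw")

#: fallback initial viscosity when no measured flow rate is available
#: (the conventional nominal blood viscosity of 3.5 cP)
REFERENCE_VISCOSITY = 3.5e-3

# number of free parameters per model kind (default options)
_N_FREE = {"newtonian": 1, "powerlaw": 2, "carreau": 4, "dpp": 3, "coreplasma": 3}


@dataclass(frozen=True)
class FitOptions:
    """Options controlling a model fit.

    weighted : use 1/sd^2 weights (requires the profile to carry sd).
    free_delta : let the core-plasma CFL thickness float in (0, R) instead
        of fixing it to the supplied/optical value.
    delta : explicit CFL thickness (m) for the core-plasma fit; defaults to
        the profile condition's optical delta_o.
    pin_mu_p : pin the plasma viscosity to the apparent viscosity instead of
        fitting it (the simpler reading of the initializer rule).
    carreau_starts : number of seeded multi-starts for the weakly identified
        Carreau fit (1 = single deterministic start).
    """

    weighted: bool = False
    free_delta: bool = False
    delta: Optional[float] = None
    pin_mu_p: bool = False
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 5000
    carreau_nodes: int = 4001
    carreau_starts: int = 1
    seed: int = 0


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus global and regional error diagnostics."""

    model_kind: str
    params: object
    rms_velocity: float
    residuals: np.ndarray
    converged: bool
    n_eval: int
    objective: float
    n_free: int
    core_rms_velocity: Optional[float] = None
    cfl_rms_velocity: Optional[float] = None
    rms_shear: Optional[float] = None
    core_rms_shear: Optional[float] = None
    cfl_rms_shear: Optional[float] = None


@dataclass(frozen=True)
class ComparisonTable:
    """Per-model fit results with deterministic RMS ranking."""

    results: tuple
    ranking: tuple  # model labels ordered best-first by rms_velocity

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            rows.append(
                {
                    "model": res.model_kind,
                    "rms_velocity": res.rms_velocity,
                    "rms_shear": res.rms_shear,
                    "core_rms_velocity": res.core_rms_velocity,
                    "cfl_rms_velocity": res.cfl_rms_velocity,
                    "n_free": res.n_free,
                    "converged": res.converged,
                }
            )
        df = pd.DataFrame(rows)
        order = {kind: i for i, kind in enumerate(self.ranking)}
        return df.sort_values(
            "model", key=lambda s: s.map(order), kind="stable"
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# error measures
# ---------------------------------------------------------------------------

def rms_error(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square error sqrt(mean((observed - predicted)^2))."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValidationError("observed and predicted must have equal length >= 1")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def regional_rms(
    profile: VelocityProfile, predicted: np.ndarray, delta: float
) -> tuple[Optional[float], Optional[float]]:
    """Split the RMS error into core and CFL contributions.

    Points with |r| >= R - delta belong to the CFL annulus, the rest to the
    core.  An empty region yields ``None``, not zero.
    """
    R = profile.geometry.radius
    if not (0 <= delta < R):
        raise ValidationError(f"delta must lie in [0, R), got {delta}")
    pred = np.asarray(predicted, dtype=float)
    if pred.shape != profile.u.shape:
        raise ValidationError("predicted must match the profile length")
    # delta = 0 means no CFL at all: every point, wall included, is core
    in_cfl = (np.abs(profile.r) >= R - delta) if delta > 0 else (
        np.zeros(len(profile), dtype=bool)
    )
    core_val = (
        rms_error(profile.u[~in_cfl], pred[~in_cfl]) if np.any(~in_cfl) else None
    )
    cfl_val = rms_error(profile.u[in_cfl], pred[in_cfl]) if np.any(in_cfl) else None
    return core_val, cfl_val


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _initial_viscosity(profile: VelocityProfile) -> float:
    cond = profile.condition
    if cond.mu_app is not None:
        return cond.mu_app
    if cond.flow_rate is not None:
        return m.apparent_viscosity(cond.flow_rate, cond.delta_p, profile.geometry)
    return REFERENCE_VISCOSITY


def _setup(profile: VelocityProfile, model_kind: str, options: FitOptions):
    """Return (x0, bounds, build, n_free) for the requested model.

    ``build(x)`` maps the optimizer vector to a parameter record.  The
    Carreau fit is internally parameterized as (mu_inf, dmu, lambda, n) with
    dmu = mu0 - mu_inf >= 0 so the plateau ordering is a bound, not a
    nonlinear constraint.
    """
    mu_init = _initial_viscosity(profile)
    R = profile.geometry.radius
    u_max = float(np.max(profile.u))
    if model_kind == "newtonian":
        x0 = [mu_init]
        lo, hi = [1e-6], [1.0]
        build = lambda x: m.NewtonianParams(mu=x[0])
    elif model_kind == "powerlaw":
        x0 = [mu_init, 1.0]
        lo, hi = [1e-8, 0.1], [10.0, 4.0]
        build = lambda x: m.PowerLawParams(K_p=x[0], n_p=x[1])
    elif model_kind == "carreau":
        x0 = [mu_init, 9.0 * mu_init, 3.31, 0.36]
        lo, hi = [1e-6, 0.0, 0.0, 1e-3], [1.0, 10.0, 100.0, 1.0]
        build = lambda x: m.CarreauParams(
            mu_inf=x[0], mu0=x[0] + x[1], lambda_c=x[2], n_c=x[3]
        )
    elif model_kind == "dpp":
        if u_max <= 0:
            raise ValidationError("cannot fit DPP to an all-zero profile")
        x0 = [u_max, 0.5, 2.0]
        lo, hi = [1e-12, 0.0, 1e-2], [10.0 * u_max, 1.0, 20.0]
        build = lambda x: m.DPPParams(v_max=x[0], k1=x[1], k2=x[2])
    elif model_kind == "coreplasma":
        delta = options.delta
        if delta is None:
            delta = profile.condition.delta_o
        if options.free_delta:
            d0 = delta if delta is not None and 0 < delta < R else 0.2 * R
            x0 = [mu_init, mu_init, 1.0, d0]
            lo = [1e-6, 1e-8, 0.1, 1e-9]
            hi = [1.0, 10.0, 4.0, R * (1.0 - 1e-9)]
            build = lambda x: m.CorePlasmaParams(
                mu_p=x[0], K_cp=x[1], n_cp=x[2], delta=x[3]
            )
        else:
            if delta is None:
                raise ValidationError(
                    "core-plasma fit needs a CFL thickness: supply options.delta, "
                    "set condition.delta_o, or request free_delta"
                )
            if not (0 <= delta < R):
                raise ValidationError(f"delta must lie in [0, R), got {delta}")
            if options.pin_mu_p:
                x0 = [mu_init, 1.0]
                lo, hi = [1e-8, 0.1], [10.0, 4.0]
                build = lambda x: m.CorePlasmaParams(
                    mu_p=mu_init, K_cp=x[0], n_cp=x[1], delta=delta
                )
            else:
                x0 = [mu_init, mu_init, 1.0]
                lo, hi = [1e-6, 1e-8, 0.1], [1.0, 10.0, 4.0]
                build = lambda x: m.CorePlasmaParams(
                    mu_p=x[0], K_cp=x[1], n_cp=x[2], delta=delta
                )
    else:
        raise ValidationError(f"unknown model kind {model_kind!r}")
    x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
    return x0, (np.asarray(lo), np.asarray(hi)), build, len(x0)


def fit_model(
    profile: VelocityProfile,
    model_kind: str,
    options: FitOptions | None = None,
    shear: ShearRateProfile | None = None,
) -> FitResult:
    """Fit one model to a velocity profile by bounded least squares.

    Deterministic given identical inputs and options.  Non-convergence is
    reported via ``converged=False`` with the best parameters found, never
    by raising.  A profile with fewer points than free parameters + 2 is
    rejected.
    """
    options = options or FitOptions()
    x0, bounds, build, n_free = _setup(profile, model_kind, options)
    if len(profile) < n_free + 2:
        raise ValidationError(
            f"{model_kind} fit needs >= {n_free + 2} points, got {len(profile)}"
        )
    geom, dp = profile.geometry, profile.condition.delta_p
    if options.weighted:
        if profile.sd is None:
            raise ValidationError("weighted fit requires per-point sd")
        w = 1.0 / np.where(profile.sd > 0, profile.sd, np.min(profile.sd[profile.sd > 0]))
    else:
        w = None

    def residual(x):
        # optimizer excursions to extreme (K, n) can overflow the power-law
        # prefactor; inf residuals just reject the step
        with np.errstate(over="ignore", invalid="ignore"):
            u_model = m.evaluate_velocity(
                build(x), profile.r, geom, dp, carreau_nodes=options.carreau_nodes
            )
        res = profile.u - u_model
        res = np.where(np.isfinite(res), res, 1e30)
        return res * w if w is not None else res

    starts = [x0]
    if model_kind == "carreau" and options.carreau_starts > 1:
        rng = np.random.default_rng(options.seed)
        lo, hi = bounds
        for _ in range(options.carreau_starts - 1):
            starts.append(lo + rng.random(n_free) * (hi - lo))

    best = None
    for start in starts:
        sol = least_squares(
            residual,
            start,
            bounds=bounds,
            method="trf",
            xtol=options.xtol,
            ftol=options.ftol,
            gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    params = build(best.x)
    u_fit = np.asarray(
        m.evaluate_velocity(params, profile.r, geom, dp,
                            carreau_nodes=options.carreau_nodes),
        dtype=float,
    )
    resid = profile.u - u_fit
    rms_v = rms_error(profile.u, u_fit)

    delta_for_split = None
    if isinstance(params, m.CorePlasmaParams):
        delta_for_split = params.delta
    elif profile.condition.delta_o is not None:
        delta_for_split = profile.condition.delta_o
    core_v = cfl_v = None
    if delta_for_split is not None and 0 <= delta_for_split < geom.radius:
        core_v, cfl_v = regional_rms(profile, u_fit, delta_for_split)

    rms_g = core_g = cfl_g = None
    if shear is not None:
        g_fit = np.asarray(m.evaluate_shear_rate(params, shear.r, geom, dp), dtype=float)
        rms_g = rms_error(shear.gamma, g_fit)
        if delta_for_split is not None and 0 <= delta_for_split < geom.radius:
            in_cfl = shear.r >= geom.radius - delta_for_split
            if np.any(~in_cfl):
                core_g = rms_error(shear.gamma[~in_cfl], g_fit[~in_cfl])
            if np.any(in_cfl):
                cfl_g = rms_error(shear.gamma[in_cfl], g_fit[in_cfl])

    return FitResult(
        model_kind=model_kind,
        params=params,
        rms_velocity=rms_v,
        residuals=resid,
        converged=bool(best.status > 0),
        n_eval=int(best.nfev),
        objective=float(2.0 * best.cost),
        n_free=n_free,
        core_rms_velocity=core_v,
        cfl_rms_velocity=cfl_v,
        rms_shear=rms_g,
        core_rms_shear=core_g,
        cfl_rms_shear=cfl_g,
    )


def compare_models(
    profile: VelocityProfile,
    model_kinds: Sequence[str] = DEFAULT_MODELS,
    options: FitOptions | None = None,
    shear: ShearRateProfile | None = None,
) -> ComparisonTable:
    """Fit several models to one profile and rank them by RMS velocity error.

    Ties are broken by fewer free parameters, then lexically by model name.
    A fit that fails validation for one model (e.g. core-plasma without a
    CFL thickness) does not abort the comparison; that model is dropped with
    the remaining rows intact.
    """
    if len(model_kinds) < 2:
        raise ValidationError("compare_models needs at least 2 models")
    results = []
    for kind in model_kinds:
        try:
            results.append(fit_model(profile, kind, options=options, shear=shear))
        except ValidationError:
            if kind not in m.PARAM_TYPES:
                raise
    if len(results) < 2:
        raise ValidationError("fewer than 2 models could be fitted")
    ranking = tuple(
        res.model_kind
        for res in sorted(
            results, key=lambda t: (t.rms_velocity, t.n_free, t.model_kind)
        )
    )
    return ComparisonTable(results=tuple(results), ranking=ranking)
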