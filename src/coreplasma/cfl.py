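"""Hydrodynamic cell-free-layer estimation from shear-rate profiles.

The boundary between the RBC-rich core and the plasma cell-free layer (CFL)
shows up in the shear-rate profile as an abrupt slope change: the plasma
annulus, being less viscous, deforms faster than the core at the same
stress.  The profile is approximated by two straight lines,

    gamma_1(r) = m1 * r                       for r <  r_ip  (core, through
                                              the origin by centerline
                                              symmetry),
    gamma_2(r) = m2 * (r - r_ip) + m1 * r_ip  for r >= r_ip  (CFL,
                                              continuous at the breakpoint),

and the breakpoint r_ip minimizing the summed squared residual, constrained
to 0 < r_ip <= R, is interpreted as the hydrodynamic core boundary.  The
hydrodynamic CFL thickness is delta_h = R - r_ip, and the shear rate at the
boundary is gamma_d = m1 * r_ip.

The search is an exhaustive scan over the interior data radii (closed-form
least-squares slopes at each candidate) followed by golden-section
refinement between the best candidate's neighbours — deterministic, no
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datatypes import (
    ShearRateProfile,
    ValidationError,
    VelocityProfile,
)

__all__ = [
    "CFLEstimate",
    "CFLComparison",
    "numerical_shear_rate",
    "fit_piecewise_shear",
    "intersection_shear_rate",
    "compare_cfl",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class CFLEstimate:
    """Two-slope changepoint fit of a shear-rate profile.

    m1, m2 : core and CFL slopes (1/(s*m)).
    r_ip : breakpoint radius (m); delta_h = R - r_ip; gamma_d = m1 * r_ip.
    sse : final sum of squared residuals.
    degenerate : True when the breakpoint is unidentifiable (single slope,
        or too few points on one side of every candidate); then r_ip = R and
        delta_h = 0 by convention.
    """

    m1: float
    m2: float
    r_ip: float
    delta_h: float
    gamma_d: float
    sse: float
    degenerate: bool
    radius: float

    def __post_init__(self) -> None:
        if not (0 < self.r_ip <= self.radius):
            raise ValidationError(f"r_ip must lie in (0, R], got {self.r_ip}")


@dataclass(frozen=True)
class CFLComparison:
    """Paired optical vs hydrodynamic CFL thickness (m)."""

    delta_o: float
    delta_h: float
    difference: float  # delta_o - delta_h; no sign assumption


# ---------------------------------------------------------------------------
# numerical differentiation
# ---------------------------------------------------------------------------

def fold_profile(profile: VelocityProfile) -> tuple[np.ndarray, np.ndarray]:
    """Fold a (possibly full-diameter) profile onto r >= 0.

    Mirrored points are merged; radii agreeing to within 1e-9 R are averaged
    together (this halves the noise of symmetric full-diameter scans).
    """
    r = np.abs(profile.r)
    u = profile.u
    order = np.argsort(r, kind="stable")
    r, u = r[order], u[order]
    tol = 1e-9 * profile.geometry.radius
    out_r, out_u = [], []
    i = 0
    while i < len(r):
        j = i + 1
        while j < len(r) and r[j] - r[i] <= tol:
            j += 1
        out_r.append(float(np.mean(r[i:j])))
        out_u.append(float(np.mean(u[i:j])))
        i = j
    return np.asarray(out_r), np.asarray(out_u)


def _local_poly_smooth(r: np.ndarray, u: np.ndarray, window: int, order: int = 2
                       ) -> np.ndarray:
    """Sliding local-polynomial smoother on a possibly non-uniform grid."""
    if window < 3 or window % 2 == 0:
        raise ValidationError("smoothing window must be odd and >= 3")
    half = window // 2
    out = np.empty_like(u)
    n = len(r)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        deg = min(order, hi - lo - 1)
        coef = np.polynomial.polynomial.polyfit(r[lo:hi] - r[i], u[lo:hi], deg)
        out[i] = coef[0]
    return out


def numerical_shear_rate(
    profile: VelocityProfile,
    smooth_window: int = 0,
    smooth_order: int = 2,
    fold: bool = True,
) -> ShearRateProfile:
    """Estimate |du/dr| from a velocity profile by finite differences.

    The profile is folded about the centerline first (optional), then
    differentiated with central differences on the non-uniform grid
    (one-sided at the ends).  ``smooth_window`` > 0 applies a local
    polynomial smoother to the speeds before differentiating (off by
    default).
    """
    if fold:
        r, u = fold_profile(profile)
    else:
        r, u = np.abs(profile.r), profile.u
        order = np.argsort(r, kind="stable")
        r, u = r[order], u[order]
    if len(r) < 5:
        raise ValidationError(
            f"need >= 5 distinct radii after folding, got {len(r)}"
        )
    if smooth_window:
        u = _local_poly_smooth(r, u, smooth_window, smooth_order)
    gamma = np.abs(np.gradient(u, r))
    return ShearRateProfile(r=r, gamma=gamma, source="numerical")


# ---------------------------------------------------------------------------
# piecewise-linear changepoint fit
# ---------------------------------------------------------------------------

def _two_slope_fit(r: np.ndarray, g: np.ndarray, r_ip: float
                   ) -> tuple[float, float, float]:
    """Closed-form least-squares slopes for a fixed breakpoint.

    Minimizes sum_core (g - m1 r)^2 + sum_cfl (g - m2 (r - r_ip) - m1 r_ip)^2
    over (m1, m2); linear normal equations.
    """
    core = r < r_ip
    cfl = ~core
    rc, gc = r[core], g[core]
    rf, gf = r[cfl] - r_ip, g[cfl]
    a11 = float(np.sum(rc**2)) + r_ip**2 * int(cfl.sum())
    a12 = r_ip * float(np.sum(rf))
    a22 = float(np.sum(rf**2))
    b1 = float(np.sum(gc * rc)) + r_ip * float(np.sum(gf))
    b2 = float(np.sum(gf * rf))
    det = a11 * a22 - a12 * a12
    if det > 1e-300 * max(a11 * a22, 1e-300):
        m1 = (b1 * a22 - b2 * a12) / det
        m2 = (a11 * b2 - a12 * b1) / det
    else:
        # CFL side carries no leverage (all points at r_ip): single slope
        m1 = b1 / a11 if a11 > 0 else 0.0
        m2 = m1
    pred = np.where(core, m1 * r, m2 * (r - r_ip) + m1 * r_ip)
    sse = float(np.sum((g - pred) ** 2))
    return m1, m2, sse


def fit_piecewise_shear(
    shear: ShearRateProfile,
    radius: float,
    min_side: int = 3,
    refine_tol: float = 1e-12,
) -> CFLEstimate:
    """Fit the two-slope changepoint model and estimate delta_h = R - r_ip.

    Candidates are the interior data radii with at least ``min_side`` points
    strictly on each side; the best candidate's neighbourhood is refined by
    golden-section search on the continuous objective, subject to the hard
    bound r_ip <= R.  When no valid candidate exists, or the two slopes are
    indistinguishable (a single straight line), the estimate is flagged
    degenerate with r_ip = R (delta_h = 0).
    """
    r, g = shear.r, shear.gamma
    if not (radius > 0) or np.max(r) > radius * (1 + 1e-9):
        raise ValidationError(
            f"radius must cover the data: R={radius}, max r={np.max(r)}"
        )
    n = len(r)
    cand_idx = [
        k for k in range(n)
        if np.sum(r < r[k]) >= min_side and np.sum(r >= r[k]) >= min_side and r[k] > 0
    ]
    if not cand_idx:
        m1, _, sse = _two_slope_fit(r, g, radius * (1 + 1e-9))
        return CFLEstimate(
            m1=m1, m2=m1, r_ip=radius, delta_h=0.0, gamma_d=m1 * radius,
            sse=sse, degenerate=True, radius=radius,
        )

    fits = [_two_slope_fit(r, g, r[k]) for k in cand_idx]
    best_i = int(np.argmin([f[2] for f in fits]))
    best_k = cand_idx[best_i]

    lo = r[cand_idx[best_i - 1]] if best_i > 0 else r[best_k]
    hi = r[cand_idx[best_i + 1]] if best_i < len(cand_idx) - 1 else r[best_k]
    hi = min(hi, radius)

    def objective(x: float) -> float:
        return _two_slope_fit(r, g, x)[2]

    a, b = lo, hi
    if b - a > refine_tol * radius:
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc, fd = objective(c), objective(d)
        for _ in range(200):
            if b - a <= refine_tol * radius:
                break
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - _GOLDEN * (b - a)
                fc = objective(c)
            else:
                a, c, fc = c, d, fd
                d = a + _GOLDEN * (b - a)
                fd = objective(d)
        r_ref = 0.5 * (a + b)
    else:
        r_ref = r[best_k]

    # keep whichever of {grid optimum, refined point} wins, bounded by R
    best_rip = min(r[best_k], radius)
    m1, m2, sse = _two_slope_fit(r, g, best_rip)
    m1r, m2r, sser = _two_slope_fit(r, g, min(r_ref, radius))
    if sser < sse:
        best_rip, m1, m2, sse = min(r_ref, radius), m1r, m2r, sser

    scale = max(abs(m1), abs(m2), 1e-300)
    degenerate = abs(m2 - m1) <= 1e-8 * scale
    if degenerate:
        return CFLEstimate(
            m1=m1, m2=m2, r_ip=radius, delta_h=0.0, gamma_d=m1 * radius,
            sse=sse, degenerate=True, radius=radius,
        )
    return CFLEstimate(
        m1=m1, m2=m2, r_ip=best_rip, delta_h=radius - best_rip,
        gamma_d=m1 * best_rip, sse=sse, degenerate=False, radius=radius,
    )


def intersection_shear_rate(est: CFLEstimate) -> Optional[float]:
    """Core-side shear rate m1 * r_ip at the hydrodynamic boundary.

    ``None`` for degenerate estimates (no identifiable boundary).
    """
    if est.degenerate:
        return None
    return est.m1 * est.r_ip


def compare_cfl(delta_o: float, est: CFLEstimate) -> CFLComparison:
    """Pair the optical and hydrodynamic CFL thicknesses."""
    if delta_o is None or not np.isfinite(delta_o):
        raise ValidationError("delta_o must be a finite value")
    return CFLComparison(
        delta_o=float(delta_o),
        delta_h=est.delta_h,
        difference=float(delta_o) - est.delta_h,
    )
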