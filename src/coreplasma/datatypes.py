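"""Shared containers and exceptions.

All quantities are strict SI (m, s, Pa, Pa*s, m^3/s).  Unit conversion to and
from the laboratory conventions (um, mbar, mm/s, uL/min, mPa*s) happens only
in :mod:`coreplasma.io`.

The radial coordinate ``r`` is signed, with the channel centerline at 0, so a
full-diameter profile spans negative and positive radii; model evaluation is
always even in ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class ValidationError(ValueError):
    """An input violates a physical or structural precondition."""


class DomainError(ValidationError):
    """A coordinate lies outside the physical domain (e.g. |r| > R)."""


class NumericalError(RuntimeError):
    """A solver or quadrature routine failed to converge."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Cylindrical microchannel geometry.

    Parameters
    ----------
    radius : float
        Inner radius R of the channel (m).
    length : float
        Axial length L over which the pressure drop acts (m).
    """

    radius: float
    length: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        if not (self.length > 0):
            raise ValidationError(f"length must be > 0, got {self.length}")
        if not (self.radius < self.length):
            raise ValidationError(
                "radius must be smaller than length (a tube, not a disk): "
                f"R={self.radius}, L={self.length}"
            )


@dataclass(frozen=True)
class FlowCondition:
    """Flow driving conditions and sample metadata for one acquisition.

    ``delta_p`` is the pressure drop over the channel length (Pa, positive =
    driving flow).  ``flow_rate`` is the measured volumetric flow (m^3/s), if
    available; ``delta_o`` the optically measured cell-free-layer thickness
    (m); ``mu_app`` an apparent viscosity (Pa*s) derived via the Poiseuille
    inversion.
    """

    delta_p: float
    flow_rate: Optional[float] = None
    hematocrit: float = 0.0
    medium: str = "other"
    delta_o: Optional[float] = None
    mu_app: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.delta_p > 0):
            raise ValidationError(f"delta_p must be > 0, got {self.delta_p}")
        if self.flow_rate is not None and not (self.flow_rate > 0):
            raise ValidationError(f"flow_rate must be > 0, got {self.flow_rate}")
        if not (0.0 <= self.hematocrit < 0.6):
            raise ValidationError(
                f"hematocrit must lie in [0, 0.6), got {self.hematocrit}"
            )
        if self.delta_o is not None and not (self.delta_o >= 0):
            raise ValidationError(f"delta_o must be >= 0, got {self.delta_o}")


@dataclass(frozen=True)
class VelocityProfile:
    """A radial velocity profile: the central measured/simulated object.

    Attributes
    ----------
    r : ndarray
        Signed radial positions (m), strictly increasing.
    u : ndarray
        Axial speeds (m/s), non-negative.
    sd : ndarray or None
        Optional per-point standard deviations (m/s).
    geometry, condition
        The channel and flow context the profile was acquired under.
    meta : dict
        Free-form provenance (e.g. clip counts from the synthetic generator).
    """

    r: np.ndarray
    u: np.ndarray
    geometry: ChannelGeometry
    condition: FlowCondition
    sd: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "u", u)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", sd)
        if r.ndim != 1 or u.ndim != 1 or len(r) != len(u):
            raise ValidationError("r and u must be 1-d arrays of equal length")
        if len(r) < 3:
            raise ValidationError(f"profile needs >= 3 points, got {len(r)}")
        if self.sd is not None:
            if self.sd.shape != r.shape:
                raise ValidationError("sd must match r in length")
            if not np.all(np.isfinite(self.sd)) or np.any(self.sd < 0):
                raise ValidationError("sd must be finite and >= 0")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(u))):
            raise ValidationError("profile contains non-finite values")
        if np.any(np.diff(r) <= 0):
            raise ValidationError("r must be strictly increasing")
        if np.any(u < 0):
            raise ValidationError("speeds must be >= 0")
        R = self.geometry.radius
        if np.any(np.abs(r) > R * (1 + 1e-12)):
            raise DomainError(f"|r| exceeds channel radius R={R}")

    def __len__(self) -> int:
        return len(self.r)

    @property
    def is_full_diameter(self) -> bool:
        return bool(self.r[0] < 0)


@dataclass(frozen=True)
class ShearRateProfile:
    """Folded (r >= 0) shear-rate magnitude profile |du/dr|(r)."""

    r: np.ndarray
    gamma: np.ndarray
    source: str = "numerical"  # "numerical" | "analytic"

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "gamma", g)
        if r.ndim != 1 or g.ndim != 1 or len(r) != len(g):
            raise ValidationError("r and gamma must be 1-d arrays of equal length")
        if len(r) < 4:
            raise ValidationError(f"shear profile needs >= 4 points, got {len(r)}")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(g))):
            raise ValidationError("shear profile contains non-finite values")
        if np.any(r < 0) or np.any(np.diff(r) <= 0):
            raise ValidationError("r must be >= 0 and strictly increasing")
        if np.any(g < 0):
            raise ValidationError("shear-rate magnitudes must be >= 0")
        if self.source not in ("numerical", "analytic"):
            raise ValidationError(f"unknown source label {self.source!r}")

    def __len__(self) -> int:
        return len(self.r)
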