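"""File formats, unit conversion and result serialization.

The library is strict-SI internally; every laboratory unit (um, mbar, mm/s,
uL/min, mPa*s) is converted exactly once, here.  Profiles travel as CSV with
the fixed header ``r_um,u_mm_per_s[,sd_mm_per_s]``; results travel as JSON
bundles with deterministic key order, full float precision, a software
version and an input checksum, so a bundle diff is meaningful.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .datatypes import (
    ChannelGeometry,
    FlowCondition,
    ValidationError,
    VelocityProfile,
)
from . import __version__
from .cfl import CFLComparison, CFLEstimate
from .fitting import FitResult

logger = logging.getLogger("coreplasma")

__all__ = [
    "um_to_m", "m_to_um", "mbar_to_pa", "pa_to_mbar",
    "mmps_to_mps", "mps_to_mmps", "ulmin_to_m3s", "m3s_to_ulmin",
    "mpas_to_pas", "pas_to_mpas",
    "read_profile", "write_profile", "ResultBundle",
    "write_results", "read_results", "file_checksum", "RunConfig",
]


# ---------------------------------------------------------------------------
# unit conversions (each pair exactly inverse)
# ---------------------------------------------------------------------------

def um_to_m(x):        return np.multiply(x, 1e-6)
def m_to_um(x):        return np.multiply(x, 1e6)
def mbar_to_pa(x):     return np.multiply(x, 100.0)      # 1 mbar = 100 Pa
def pa_to_mbar(x):     return np.multiply(x, 0.01)
def mmps_to_mps(x):    return np.multiply(x, 1e-3)
def mps_to_mmps(x):    return np.multiply(x, 1e3)
def ulmin_to_m3s(x):   return np.divide(np.multiply(x, 1e-9), 60.0)
def m3s_to_ulmin(x):   return np.multiply(np.multiply(x, 60.0), 1e9)
def mpas_to_pas(x):    return np.multiply(x, 1e-3)
def pas_to_mpas(x):    return np.multiply(x, 1e3)


# ---------------------------------------------------------------------------
# profile CSV dialect
# ---------------------------------------------------------------------------

_HEADER2 = ["r_um", "u_mm_per_s"]
_HEADER3 = ["r_um", "u_mm_per_s", "sd_mm_per_s"]


def read_profile(
    path, geometry: ChannelGeometry, condition: FlowCondition
) -> VelocityProfile:
    """Read a profile CSV (header ``r_um,u_mm_per_s[,sd_mm_per_s]``).

    Values convert to SI on the way in.  Rows are re-sorted by radius with a
    logged warning if the file was out of order.  Points overhanging the
    wall by < 2% of R (micro-PIV wall-localization uncertainty) are clamped
    to R with a logged count; a larger overhang is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"profile file not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file")
        header = [h.strip() for h in header]
        if header == _HEADER3:
            has_sd = True
        elif header == _HEADER2:
            has_sd = False
        else:
            raise ValidationError(
                f"{path}: bad header {header!r}; expected "
                f"{','.join(_HEADER3)} (sd column optional)"
            )
        rows = []
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}: row {i} has {len(row)} cells, expected {len(header)}"
                )
            vals = []
            for col, cell in zip(header, row):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: row {i}, column {col!r}: non-numeric cell {cell!r}"
                    )
                if not np.isfinite(v):
                    raise ValidationError(
                        f"{path}: row {i}, column {col!r}: non-finite value"
                    )
                vals.append(v)
            rows.append(vals)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    r = um_to_m(arr[:, 0])
    u = mmps_to_mps(arr[:, 1])
    sd = mmps_to_mps(arr[:, 2]) if has_sd else None

    R = geometry.radius
    over = np.abs(r) > R
    too_far = np.abs(r) > R * 1.02
    if np.any(too_far):
        bad = int(np.argmax(too_far))
        raise ValidationError(
            f"{path}: row {bad + 2}, column 'r_um': |r| exceeds R by more than 2%"
        )
    if np.any(over):
        logger.warning(
            "%s: clamped %d point(s) overhanging the wall by < 2%% of R",
            path, int(np.sum(over)),
        )
        r = np.clip(r, -R, R)

    order = np.argsort(r, kind="stable")
    if not np.all(order == np.arange(len(r))):
        logger.warning("%s: rows were not sorted by radius; reordering", path)
        r, u = r[order], u[order]
        sd = sd[order] if sd is not None else None
    return VelocityProfile(r=r, u=u, sd=sd, geometry=geometry, condition=condition)


def write_profile(profile: VelocityProfile, path) -> None:
    """Write a profile CSV in the dialect read by :func:`read_profile`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        has_sd = profile.sd is not None
        writer.writerow(_HEADER3 if has_sd else _HEADER2)
        for i in range(len(profile)):
            row = [repr(float(m_to_um(profile.r[i]))),
                   repr(float(mps_to_mmps(profile.u[i])))]
            if has_sd:
                row.append(repr(float(mps_to_mmps(profile.sd[i]))))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# result bundles
# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    raise ValidationError(f"cannot serialize {type(obj).__name__}")


@dataclasses.dataclass
class ResultBundle:
    """Everything one analysis run produced, ready for JSON round-tripping."""

    fits: list
    cfl: Optional[CFLEstimate] = None
    cfl_comparison: Optional[CFLComparison] = None
    apparent_viscosity: Optional[float] = None
    config: Optional[dict] = None
    input_checksum: Optional[str] = None
    version: str = __version__

    def to_dict(self) -> dict:
        out: dict = {"version": self.version}
        out["checksum"] = self.input_checksum
        out["fits"] = [_to_jsonable(f) for f in self.fits]
        # optional blocks are omitted entirely when absent, never null
        if self.cfl is not None:
            out["cfl"] = _to_jsonable(self.cfl)
        if self.cfl_comparison is not None:
            out["cfl_comparison"] = _to_jsonable(self.cfl_comparison)
        if self.apparent_viscosity is not None:
            out["apparent_viscosity"] = float(self.apparent_viscosity)
        if self.config is not None:
            out["config"] = _to_jsonable(self.config)
        return out


def file_checksum(path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(bundle: ResultBundle, path) -> None:
    """Serialize a bundle as JSON: sorted keys, full float precision."""
    doc = bundle.to_dict() if isinstance(bundle, ResultBundle) else bundle
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "radius_um", "length_mm", "dp_mbar", "q_ul_min", "delta_o_um",
    "hematocrit", "medium", "models", "weighted", "free_delta", "pin_mu_p",
    "smooth_window", "output", "seed",
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parsed run configuration; units converted once here at parse time."""

    geometry: ChannelGeometry
    condition: FlowCondition
    models: tuple = ("carreau", "coreplasma", "dpp", "newtonian", "powerlaw")
    weighted: bool = False
    free_delta: bool = False
    pin_mu_p: bool = False
    smooth_window: int = 0
    output: Optional[str] = None
    seed: int = 0
    raw: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("radius_um", "length_mm", "dp_mbar"):
            if key not in doc:
                raise ValidationError(f"{path}: missing required key {key!r}")
        geometry = ChannelGeometry(
            radius=float(um_to_m(doc["radius_um"])),
            length=float(doc["length_mm"]) * 1e-3,
        )
        condition = FlowCondition(
            delta_p=float(mbar_to_pa(doc["dp_mbar"])),
            flow_rate=(float(ulmin_to_m3s(doc["q_ul_min"]))
                       if doc.get("q_ul_min") is not None else None),
            hematocrit=float(doc.get("hematocrit", 0.0)),
            medium=str(doc.get("medium", "other")),
            delta_o=(float(um_to_m(doc["delta_o_um"]))
                     if doc.get("delta_o_um") is not None else None),
        )
        return cls(
            geometry=geometry,
            condition=condition,
            models=tuple(doc.get("models",
                                 ("carreau", "coreplasma", "dpp",
                                  "newtonian", "powerlaw"))),
            weighted=bool(doc.get("weighted", False)),
            free_delta=bool(doc.get("free_delta", False)),
            pin_mu_p=bool(doc.get("pin_mu_p", False)),
            smooth_window=int(doc.get("smooth_window", 0)),
            output=doc.get("output"),
            seed=int(doc.get("seed", 0)),
            raw=dict(doc),
        )
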