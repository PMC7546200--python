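"""Cumulative dose-volume histograms and disjoint dose-band metrics for the thyroid.

A cumulative DVH gives, for each dose level ``d`` (Gy), the percentage of the
gland's volume receiving at least ``d``.  The classical predictors
``V_x`` (volume fraction above x Gy, x = 10..60) are nested and therefore
strongly collinear; the band metrics ``V_a,b = V_a - V_b`` partition the
volume into disjoint 10-Gy dose bins and break that collinearity.  On a
continuous interpolated curve "more than x Gy" and "at least x Gy" coincide,
so no strictness convention is needed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DVHCurve",
    "VxVector",
    "BandVector",
    "ThyroidDosimetry",
    "DVHValidationError",
    "DVHParseError",
    "read_dvh_table",
    "write_dvh_table",
    "vx_at",
    "bands_from_vx",
    "dosimetry_from_curve",
]

VX_DOSES = (10, 20, 30, 40, 50, 60)


class DVHValidationError(ValueError):
    """A curve or derived metric violates a structural invariant."""


class DVHParseError(ValueError):
    """A DVH table file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: ``volume_fraction[i]`` % of volume receives >= ``dose_grid[i]`` Gy.

    The grid starts at 0 Gy (where the fraction is 100%), is strictly
    increasing, and the fractions are non-increasing in [0, 100].
    """

    dose_grid: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_grid, dtype=float)
        vol = np.asarray(self.volume_fraction, dtype=float)
        object.__setattr__(self, "dose_grid", dose)
        object.__setattr__(self, "volume_fraction", vol)
        if dose.ndim != 1 or vol.ndim != 1 or dose.size != vol.size:
            raise DVHValidationError("dose_grid and volume_fraction must be 1-D and equally long")
        if dose.size < 2:
            raise DVHValidationError("a DVH curve needs at least 2 points")
        if not np.isfinite(dose).all() or not np.isfinite(vol).all():
            raise DVHValidationError("non-finite values in DVH curve")
        if abs(dose[0]) > 1e-9:
            raise DVHValidationError(f"dose grid must start at 0 Gy, got {dose[0]!r}")
        if np.any(np.diff(dose) <= 0):
            raise DVHValidationError("dose grid must be strictly increasing")
        if abs(vol[0] - 100.0) > 1e-9:
            raise DVHValidationError(f"volume fraction at 0 Gy must be 100%, got {vol[0]!r}")
        if np.any(np.diff(vol) > 1e-9):
            raise DVHValidationError("cumulative volume fraction must be non-increasing")
        if vol.min() < -1e-9 or vol.max() > 100.0 + 1e-9:
            raise DVHValidationError("volume fractions must lie in [0, 100]")

    def __len__(self) -> int:
        return int(self.dose_grid.size)


@dataclass(frozen=True)
class VxVector:
    """Nested volume fractions above 10..60 Gy (percent)."""

    v10: float
    v20: float
    v30: float
    v40: float
    v50: float
    v60: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if not all(np.isfinite(vals)):
            raise DVHValidationError("non-finite V_x value")
        if vals[0] > 100.0 + 1e-9 or vals[-1] < -1e-9:
            raise DVHValidationError("V_x values must lie in [0, 100]")
        if np.any(np.diff(vals) > 1e-9):
            raise DVHValidationError(f"V_x must be non-increasing in x, got {vals}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.v10, self.v20, self.v30, self.v40, self.v50, self.v60)


@dataclass(frozen=True)
class BandVector:
    """Disjoint 10-Gy band fractions; together with the >60 Gy residual they sum to 100%."""

    v0_10: float
    v10_20: float
    v20_30: float
    v30_40: float
    v40_50: float
    v50_60: float
    residual_v60: float

    def __post_init__(self) -> None:
        vals = self.as_tuple() + (self.residual_v60,)
        if min(vals) < -1e-6:
            raise DVHValidationError(f"negative band fraction: {vals}")
        if abs(sum(vals) - 100.0) > 1e-6:
            raise DVHValidationError(f"bands + residual must sum to 100, got {sum(vals)!r}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.v0_10, self.v10_20, self.v20_30, self.v30_40, self.v40_50, self.v50_60)


@dataclass(frozen=True)
class ThyroidDosimetry:
    """All dose metrics for one thyroid: absolute volume, V_x, bands, aggregates."""

    volume_cm3: float
    vx: VxVector
    bands: BandVector
    v30_60: float = field(default=None)  # type: ignore[assignment]
    v40_60: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.volume_cm3) and self.volume_cm3 > 0):
            raise DVHValidationError(f"thyroid volume must be positive, got {self.volume_cm3!r}")
        if self.v30_60 is None:
            object.__setattr__(self, "v30_60", self.vx.v30 - self.vx.v60)
        if self.v40_60 is None:
            object.__setattr__(self, "v40_60", self.vx.v40 - self.vx.v60)
        if abs(self.v30_60 - (self.vx.v30 - self.vx.v60)) > 1e-6:
            raise DVHValidationError("v30_60 must equal v30 - v60")
        if abs(self.v40_60 - (self.vx.v40 - self.vx.v60)) > 1e-6:
            raise DVHValidationError("v40_60 must equal v40 - v60")


def read_dvh_table(path: str | Path, delimiter: str | None = None) -> DVHCurve:
    """Read a two-column (dose Gy, cumulative % volume) delimited text file.

    The delimiter is auto-detected (comma or tab) unless given.  A single
    header line is allowed and skipped.  Rows are sorted by dose; duplicated
    dose values are rejected.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            sep = delimiter
            if sep is None:
                sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2:
                raise DVHParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                dose, vol = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header line
                raise DVHParseError(f"{path}:{lineno}: non-numeric row {parts!r}") from None
            rows.append((dose, vol))
    if len(rows) < 2:
        raise DVHParseError(f"{path}: fewer than 2 data rows")
    rows.sort(key=lambda r: r[0])
    doses = np.array([r[0] for r in rows])
    if np.any(np.diff(doses) == 0):
        dup = doses[np.flatnonzero(np.diff(doses) == 0)[0]]
        raise DVHParseError(f"{path}: duplicate dose value {dup} Gy")
    return DVHCurve(doses, np.array([r[1] for r in rows]))


def write_dvh_table(curve: DVHCurve, path: str | Path, delimiter: str = ",") -> None:
    """Write a curve as (dose_gy, volume_pct) rows with a header line."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["dose_gy", "volume_pct"])
        for d, v in zip(curve.dose_grid, curve.volume_fraction):
            w.writerow([repr(float(d)), repr(float(v))])


def vx_at(curve: DVHCurve, x: float) -> float:
    """Volume percentage receiving more than ``x`` Gy, by linear interpolation.

    Doses beyond the last grid point return 0%; ``x = 0`` returns 100%.
    """
    if x < 0:
        raise DVHValidationError(f"dose must be non-negative, got {x}")
    return float(np.interp(x, curve.dose_grid, curve.volume_fraction, right=0.0))


def bands_from_vx(vx: VxVector | Sequence[float]) -> BandVector:
    """Disjoint band fractions by successive subtraction of the nested V_x.

    ``V_0,10 = 100 - V_10``; ``V_a,b = V_a - V_b``; the residual is ``V_60``.
    Monotonicity violations raise rather than being clipped.
    """
    if not isinstance(vx, VxVector):
        vx = VxVector(*vx)
    v = (100.0,) + vx.as_tuple()
    diffs = tuple(v[i] - v[i + 1] for i in range(6))
    return BandVector(*diffs, residual_v60=vx.v60)


def dosimetry_from_curve(curve: DVHCurve, volume_cm3: float) -> ThyroidDosimetry:
    """Evaluate V_10..V_60, the disjoint bands and the 30-60 / 40-60 aggregates."""
    if not (np.isfinite(volume_cm3) and volume_cm3 > 0):
        raise DVHValidationError(f"thyroid volume must be positive, got {volume_cm3!r}")
    vx = VxVector(*(vx_at(curve, float(x)) for x in VX_DOSES))
    return ThyroidDosimetry(volume_cm3=float(volume_cm3), vx=vx, bands=bands_from_vx(vx))
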