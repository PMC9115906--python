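"""Temperature-humidity index (THI) computation and climate-room programs.

The THI used throughout is the Livestock Weather Safety Index form

    THI = 0.8*TA + (RH/100)*(TA - 14.3) + 46.3

with TA the dry-bulb air temperature in deg C and RH the relative humidity
in percent.  The index is the de facto heat-stress indicator for lot-fed
cattle; the associated advisory categories are Normal (<=74),
Alert (74-78], Danger (78-83] and Emergency (>83).  The printed category
bands are integer bands with gaps; this module adopts half-open intervals
so every real THI value maps to exactly one category.

The module also builds the diurnal set-point program used for a thermal
Challenge period in climate-controlled rooms: temperature and humidity ramp
up hourly from a morning trough to a plateau, hold the plateau through the
afternoon, then ramp back down to the overnight trough.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "THICategory",
    "ClimateReading",
    "DiurnalProgram",
    "compute_thi",
    "classify_thi",
    "build_diurnal_program",
    "thi_of_means",
    "mean_of_thi",
    "read_climate_csv",
    "write_climate_csv",
    "annotate_climate",
]

#: TA (deg C) at which the humidity term of the THI vanishes.
THI_PIVOT_TA = 14.3


class THICategory(enum.IntEnum):
    """Livestock Weather Safety Index categories, ordered by severity."""

    NORMAL = 0
    ALERT = 1
    DANGER = 2
    EMERGENCY = 3

    def __str__(self) -> str:  # stable labels for CSV output
        return self.name.capitalize()


def compute_thi(ta, rh):
    """Compute the temperature-humidity index.

    Parameters
    ----------
    ta : float or array-like
        Dry-bulb air temperature, deg C.
    rh : float or array-like
        Relative humidity, percent (0-100).

    Returns
    -------
    float or ndarray
        THI, dimensionless.  ``0.8*ta + (rh/100)*(ta - 14.3) + 46.3``.
    """
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(~np.isfinite(ta)):
        raise ValidationError("air temperature must be finite")
    if np.any((rh < 0.0) | (rh > 100.0) | ~np.isfinite(rh)):
        bad = rh[np.asarray((rh < 0.0) | (rh > 100.0) | ~np.isfinite(rh))]
        offender = float(np.atleast_1d(bad)[0])
        raise ValidationError(
            f"relative humidity must lie in [0, 100]%: got {offender}"
        )
    thi = 0.8 * ta + (rh / 100.0) * (ta - THI_PIVOT_TA) + 46.3
    if thi.ndim == 0:
        return float(thi)
    return thi


def classify_thi(thi: float) -> THICategory:
    """Map a THI value to its heat-stress advisory category.

    Continuous extension of the printed integer bands with half-open
    intervals: Normal <=74, Alert (74, 78], Danger (78, 83],
    Emergency >83.
    """
    if not np.isfinite(thi):
        raise ValidationError(f"THI must be finite: got {thi}")
    if thi <= 74.0:
        return THICategory.NORMAL
    if thi <= 78.0:
        return THICategory.ALERT
    if thi <= 83.0:
        return THICategory.DANGER
    return THICategory.EMERGENCY


@dataclass(frozen=True)
class ClimateReading:
    """One timestamped room-climate record with its derived THI."""

    timestamp: datetime
    ta: float
    rh: float
    thi: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        expected = compute_thi(self.ta, self.rh)
        if self.thi is None:
            object.__setattr__(self, "thi", expected)
        elif abs(self.thi - expected) > 1e-9:
            raise ValidationError(
                f"stored THI {self.thi} disagrees with formula value {expected}"
            )

    @property
    def category(self) -> THICategory:
        return classify_thi(self.thi)


@dataclass(frozen=True)
class DiurnalProgram:
    """24-hour set-point program for a climate-controlled room.

    ``hourly_targets`` holds 24 ``(ta, rh)`` pairs, one per clock hour.
    Between ``trough_reach`` and ``ramp_up_start`` the room sits at the
    daily minimum; the maximum is reached at ``plateau_start`` and held
    through ``plateau_end``.
    """

    day_min_ta: float
    day_max_ta: float
    day_min_rh: float
    day_max_rh: float
    ramp_up_start: int = 7
    plateau_start: int = 9
    plateau_end: int = 16
    trough_reach: int = 20
    hourly_targets: tuple = ()

    def hourly_thi(self) -> np.ndarray:
        """THI at each of the 24 hourly set-points."""
        ta = np.array([t for t, _ in self.hourly_targets])
        rh = np.array([r for _, r in self.hourly_targets])
        return compute_thi(ta, rh)


def _ramp(hour, start, end, lo, hi):
    frac = (hour - start) / (end - start)
    return lo + frac * (hi - lo)


def build_diurnal_program(
    day_min: tuple,
    day_max: tuple,
    *,
    ramp_up_start: int = 7,
    plateau_start: int = 9,
    plateau_end: int = 16,
    trough_reach: int = 20,
) -> DiurnalProgram:
    """Build the hourly (TA, RH) set-point program for one Challenge day.

    The program ramps linearly (evaluated on the hour) from the daily
    minimum at ``ramp_up_start`` to the maximum at ``plateau_start``,
    holds the maximum through ``plateau_end``, ramps back down to reach
    the minimum at ``trough_reach``, and holds the minimum overnight.

    Parameters
    ----------
    day_min, day_max : tuple of (ta, rh)
        Daily trough and plateau set-points.
    """
    min_ta, min_rh = float(day_min[0]), float(day_min[1])
    max_ta, max_rh = float(day_max[0]), float(day_max[1])
    if min_ta > max_ta or min_rh > max_rh:
        raise ValidationError(
            f"daily minimum ({min_ta}, {min_rh}) exceeds maximum ({max_ta}, {max_rh})"
        )
    hours = (ramp_up_start, plateau_start, plateau_end, trough_reach)
    if not all(0 <= h <= 23 for h in hours):
        raise ValidationError(f"schedule hours must lie in 0..23: {hours}")
    if not (ramp_up_start < plateau_start <= plateau_end < trough_reach):
        raise ValidationError(f"schedule hours must be strictly ordered: {hours}")

    targets = []
    for h in range(24):
        if h <= ramp_up_start or h >= trough_reach:
            targets.append((min_ta, min_rh))
        elif h < plateau_start:
            targets.append(
                (
                    _ramp(h, ramp_up_start, plateau_start, min_ta, max_ta),
                    _ramp(h, ramp_up_start, plateau_start, min_rh, max_rh),
                )
            )
        elif h <= plateau_end:
            targets.append((max_ta, max_rh))
        else:
            targets.append(
                (
                    _ramp(h, plateau_end, trough_reach, max_ta, min_ta),
                    _ramp(h, plateau_end, trough_reach, max_rh, min_rh),
                )
            )
    return DiurnalProgram(
        day_min_ta=min_ta,
        day_max_ta=max_ta,
        day_min_rh=min_rh,
        day_max_rh=max_rh,
        ramp_up_start=ramp_up_start,
        plateau_start=plateau_start,
        plateau_end=plateau_end,
        trough_reach=trough_reach,
        hourly_targets=tuple(targets),
    )


def thi_of_means(ta: Sequence[float], rh: Sequence[float]) -> float:
    """THI evaluated at the mean TA and mean RH (THI-of-means).

    Distinct from :func:`mean_of_thi` because THI is bilinear in TA and RH:
    with varying conditions the two aggregations differ, and reports should
    state which one they use.
    """
    return float(compute_thi(np.mean(np.asarray(ta, float)), np.mean(np.asarray(rh, float))))


def mean_of_thi(ta: Sequence[float], rh: Sequence[float]) -> float:
    """Mean of the instantaneous THI values (mean-of-THI)."""
    return float(np.mean(compute_thi(np.asarray(ta, float), np.asarray(rh, float))))


# -- climate CSV dialect: timestamp (ISO-8601), ta_c, rh_pct ----------------

def read_climate_csv(path) -> pd.DataFrame:
    """Read a climate CSV with columns timestamp, ta_c, rh_pct."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "ta_c", "rh_pct"} - set(df.columns)
    if missing:
        raise ValidationError(f"climate CSV {path} lacks columns {sorted(missing)}")
    return df


def annotate_climate(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with derived ``thi`` and ``category`` columns."""
    out = df.copy()
    thi = compute_thi(out["ta_c"].to_numpy(), out["rh_pct"].to_numpy())
    out["thi"] = np.atleast_1d(thi)
    out["category"] = [str(classify_thi(t)) for t in out["thi"]]
    return out


def write_climate_csv(df: pd.DataFrame, path) -> pd.DataFrame:
    """Write a climate CSV, appending derived thi and category columns."""
    out = annotate_climate(df)
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    return out
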