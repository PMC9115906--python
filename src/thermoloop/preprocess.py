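"""Ingestion and preprocessing of per-animal physiological observations.

Raw observations arrive as a tidy long table (one row per animal, timestamp
and measure).  This module applies the trial's cleaning rules, converts raw
measures to analysis units, applies the pair-offering feed rule, and
aggregates everything to per-animal daily (and hourly) means.

Cleaning rules implemented here:

* rumen-temperature (RT) readings at or below 35 deg C are dropped -- such
  values are artefacts of large drinking events or transmission faults, not
  core temperature;
* optionally, RT readings within a configurable window after a large
  water-consumption event are masked (off by default);
* bolus retransmissions (each transmission repeats the previous 11 points)
  are collapsed to one value per animal-timestamp, latest transmission
  winning on conflict.

Units: RT and surface temperatures in deg C, respiration rate in breaths
per minute (bpm), panting score on the 0-4.5 half-step feedlot scale, water
meter readings in cumulative litres, feed in kg (as-fed or dry matter as
labelled).
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "MEASURES",
    "OBS_COLUMNS",
    "rr_from_breath_timing",
    "sanitize_rt",
    "dedupe_bolus_transmissions",
    "pair_offer",
    "step_down_offer",
    "compute_wc",
    "compute_dmi",
    "assign_period",
    "aggregate",
    "aggregate_hourly",
    "read_observations_csv",
    "read_feed_csv",
    "read_lw_csv",
]

MEASURES = (
    "RT",
    "RR",
    "PS",
    "ST_head",
    "ST_shoulder",
    "ST_rump",
    "ST_leg",
    "WC_meter",
)

OBS_COLUMNS = (
    "animal_id",
    "treatment",
    "cohort",
    "pair_id",
    "timestamp",
    "measure",
    "value",
)

#: Trial calendar: Pre-Challenge days 1-4, Challenge 5-11, Recovery 12-18,
#: with days 4 and 12 flagged as transition days.
CHALLENGE_DAYS = range(5, 12)
TRANSITION_DAYS = (4, 12)

#: Mean-per-day columns produced by :func:`aggregate` for observer measures.
_MEAN_MEASURES = ("RT", "RR", "PS", "ST_head", "ST_shoulder", "ST_rump", "ST_leg")


def rr_from_breath_timing(seconds_for_10_breaths: float, n_breaths: int = 10) -> float:
    """Convert a timed breath count to respiration rate in bpm.

    Observers time how long the animal takes for 10 flank movements;
    the rate is ``60 * n_breaths / seconds``.
    """
    if not (seconds_for_10_breaths > 0) or not math.isfinite(seconds_for_10_breaths):
        raise ValidationError(
            f"breath timing must be a positive duration in seconds: got {seconds_for_10_breaths}"
        )
    return 60.0 * n_breaths / seconds_for_10_breaths


def sanitize_rt(
    obs: pd.DataFrame,
    *,
    rt_floor: float = 35.0,
    wc_mask: bool = False,
    wc_window_min: float = 60.0,
    wc_threshold_l: float = 8.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop implausible rumen-temperature readings.

    All RT values ``<= rt_floor`` (default 35 deg C) are removed.  When
    ``wc_mask`` is set, RT readings within ``wc_window_min`` minutes after a
    water-meter increment of at least ``wc_threshold_l`` litres for the same
    animal are additionally masked (drinking transiently chills the rumen).

    Returns the retained frame and a rejection log (list of dicts with
    animal_id, timestamp, value, reason), suitable for line-delimited JSON.
    """
    log: list[dict] = []
    out = obs
    is_rt = out["measure"] == "RT"
    too_cold = is_rt & (out["value"] <= rt_floor)
    for _, row in out.loc[too_cold].iterrows():
        log.append(
            {
                "animal_id": row["animal_id"],
                "timestamp": str(row["timestamp"]),
                "value": float(row["value"]),
                "reason": f"RT <= {rt_floor} C floor",
            }
        )
    out = out.loc[~too_cold]

    if wc_mask:
        window = pd.Timedelta(minutes=wc_window_min)
        drop_idx = []
        meters = out.loc[out["measure"] == "WC_meter"]
        for animal, grp in meters.groupby("animal_id", sort=False):
            grp = grp.sort_values("timestamp")
            events = grp.loc[grp["value"].diff() >= wc_threshold_l, "timestamp"]
            if events.empty:
                continue
            rt_rows = out.loc[(out["measure"] == "RT") & (out["animal_id"] == animal)]
            for t0 in events:
                hit = rt_rows.loc[
                    (rt_rows["timestamp"] > t0) & (rt_rows["timestamp"] <= t0 + window)
                ]
                for idx, row in hit.iterrows():
                    drop_idx.append(idx)
                    log.append(
                        {
                            "animal_id": animal,
                            "timestamp": str(row["timestamp"]),
                            "value": float(row["value"]),
                            "reason": f"RT within {wc_window_min} min of >= {wc_threshold_l} L drinking event",
                        }
                    )
        out = out.drop(index=set(drop_idx))
    return out.reset_index(drop=True), log


def dedupe_bolus_transmissions(
    records: pd.DataFrame, transmission_col: Optional[str] = "transmission"
) -> tuple[pd.DataFrame, list[dict]]:
    """Collapse repeated bolus transmissions to one value per timestamp.

    Each radio transmission repeats the previous 11 points, so most rows are
    exact duplicates.  Rows are unique per ``(animal_id, timestamp)`` on
    output; when duplicated timestamps carry *different* values, the latest
    transmission wins (retransmission is treated as a correction channel)
    and the conflict is logged.

    ``transmission_col`` orders transmissions; if absent, row order is used.
    """
    df = records.copy()
    if transmission_col and transmission_col in df.columns:
        df = df.sort_values([transmission_col], kind="stable")
    conflicts: list[dict] = []
    # one value per animal-timestamp within a measure stream; plain bolus
    # series (no measure column) key on animal-timestamp alone
    key = ["animal_id", "timestamp"]
    if "measure" in df.columns:
        key = ["animal_id", "measure", "timestamp"]
    dup_groups = df.groupby(key, sort=False)["value"]
    nuniq = dup_groups.transform("nunique")
    for (animal, ts), grp in df.loc[nuniq > 1].groupby(key, sort=False):
        conflicts.append(
            {
                "animal_id": animal,
                "timestamp": str(ts),
                "values": [float(v) for v in grp["value"]],
                "resolution": "latest transmission wins",
            }
        )
    out = df.drop_duplicates(subset=key, keep="last")
    drop_cols = [transmission_col] if transmission_col and transmission_col in out.columns else []
    return out.drop(columns=drop_cols).reset_index(drop=True), conflicts


def pair_offer(prev_day_intake_tc: float, uplift: float = 0.20) -> float:
    """Next-day feed offer to both members of a pair.

    Both animals of a weight-matched pair are offered, on the same day, the
    thermally-challenged member's previous-day intake plus an uplift
    (default 20%): an intake of 5 kg yields an offer of 6 kg.
    """
    if prev_day_intake_tc < 0 or not math.isfinite(prev_day_intake_tc):
        raise ValidationError(f"previous-day intake must be >= 0 kg: got {prev_day_intake_tc}")
    return prev_day_intake_tc * (1.0 + uplift)


def step_down_offer(frtn_prev_offer: float, tc_target: float, max_daily_drop: float) -> float:
    """Gradual step-down of the restricted arm's offer toward the pair target.

    When the challenged animal's intake collapses suddenly, the restricted
    partner's offer is reduced by at most ``max_daily_drop`` kg per day
    until it reaches the pair-offer target, avoiding an abrupt feed
    restriction.
    """
    if min(frtn_prev_offer, tc_target, max_daily_drop) < 0:
        raise ValidationError("offers and drops must be non-negative kg")
    return max(tc_target, frtn_prev_offer - max_daily_drop)


def compute_wc(
    meter: pd.DataFrame, baseline: Optional[dict] = None
) -> pd.DataFrame:
    """Daily water consumption from cumulative meter readings.

    A day's consumption is the last reading of the day minus the last
    reading of the previous day; the first day uses ``baseline[animal]``
    (or, failing that, the animal's first reading) as the day-start
    baseline.  Readings must be non-decreasing per animal.

    Parameters
    ----------
    meter : DataFrame
        Columns ``animal_id``, ``timestamp``, ``value`` (cumulative litres).

    Returns
    -------
    DataFrame with columns animal_id, date, wc_l.
    """
    rows = []
    for animal, grp in meter.groupby("animal_id", sort=False):
        grp = grp.sort_values("timestamp", kind="stable")
        vals = grp["value"].to_numpy(float)
        if np.any(np.diff(vals) < 0):
            i = int(np.argmax(np.diff(vals) < 0)) + 1
            bad = grp.iloc[i]
            raise ValidationError(
                f"water meter decreases for animal {animal} at {bad['timestamp']} "
                f"(reading {bad['value']})"
            )
        daily_last = grp.groupby(grp["timestamp"].dt.date)["value"].last()
        prev_close = float(baseline[animal]) if baseline and animal in baseline else float(vals[0])
        for date, close in daily_last.items():
            rows.append({"animal_id": animal, "date": date, "wc_l": float(close) - prev_close})
            prev_close = float(close)
    return pd.DataFrame(rows, columns=["animal_id", "date", "wc_l"])


def compute_dmi(
    feed: pd.DataFrame,
    *,
    chaff_dm: float = 1.08,
    chaff_policy: str = "assume_consumed",
) -> pd.DataFrame:
    """Derive dry-matter intake from the feed ledger.

    ``dmi = (offered_asfed - refusals_asfed) * dm_fraction`` for the grain
    ration, plus the fixed chaff allocation.  Refusal DM uses the diet DM
    fraction (refusals are not itemized by component).  ``chaff_policy``:

    * ``assume_consumed`` (default): the full chaff DM counts as intake;
    * ``prorate_refusals``: chaff intake is scaled by the fraction of the
      grain offer actually consumed.
    """
    if chaff_policy not in ("assume_consumed", "prorate_refusals"):
        raise ValidationError(f"unknown chaff policy {chaff_policy!r}")
    out = feed.copy()
    bad = out["refusals_asfed_kg"].gt(out["offered_asfed_kg"] + 1e-9) | out[
        "refusals_asfed_kg"
    ].lt(0)
    if bad.any():
        row = out.loc[bad].iloc[0]
        raise ValidationError(
            f"refusals must lie in [0, offered]: animal {row['animal_id']} day {row['day']}"
        )
    grain_dm = (out["offered_asfed_kg"] - out["refusals_asfed_kg"]) * out["dm_fraction"]
    if chaff_policy == "assume_consumed":
        chaff = chaff_dm
    else:
        offered = out["offered_asfed_kg"].to_numpy(float)
        consumed_frac = np.where(
            offered > 0, (offered - out["refusals_asfed_kg"].to_numpy(float)) / offered, 1.0
        )
        chaff = chaff_dm * consumed_frac
    out["dmi_kg"] = grain_dm + chaff
    return out


def assign_period(day: int) -> tuple[str, bool]:
    """Map a trial day (1-18) to its period and transition flag."""
    if day <= 4:
        return "PreChallenge", day == 4
    if day <= 11:
        return "Challenge", False
    return "Recovery", day == 12


def _trial_day(timestamps: pd.Series, trial_start) -> pd.Series:
    start = pd.Timestamp(trial_start).normalize()
    return (timestamps.dt.normalize() - start).dt.days + 1


def aggregate(
    obs: pd.DataFrame,
    feed: Optional[pd.DataFrame] = None,
    lw: Optional[pd.DataFrame] = None,
    *,
    trial_start=None,
    chaff_dm: float = 1.08,
    chaff_policy: str = "assume_consumed",
    wc_baseline: Optional[dict] = None,
) -> pd.DataFrame:
    """Aggregate sanitized observations to one row per animal per day.

    Each measure's daily value is the unweighted arithmetic mean of that
    day's retained records, with the contributing count stored alongside
    (``n_rt``, ``n_rr``, ...); a day with no retained records for a measure
    yields a missing value, never zero.  Water consumption comes from the
    meter deltas, DMI from the feed ledger, and live weight only on weigh
    days.

    ``trial_start`` anchors day 1; default is the earliest observation date.
    """
    if obs.empty:
        raise ValidationError("observations table is empty")
    obs = obs.copy()
    if trial_start is None:
        trial_start = obs["timestamp"].min().normalize()
    obs["day"] = _trial_day(obs["timestamp"], trial_start)

    ids = obs[["animal_id", "treatment", "cohort", "pair_id"]].drop_duplicates("animal_id")

    non_meter = obs.loc[obs["measure"] != "WC_meter"]
    piv = non_meter.pivot_table(
        index=["animal_id", "day"],
        columns="measure",
        values="value",
        aggfunc=["mean", "count"],
    )
    daily = pd.DataFrame(index=piv.index)
    for m in _MEAN_MEASURES:
        col = f"mean_{m.lower()}"
        if ("mean", m) in piv.columns:
            daily[col] = piv[("mean", m)]
            daily[f"n_{m.lower()}"] = piv[("count", m)].fillna(0).astype(int)
        else:
            daily[col] = np.nan
            daily[f"n_{m.lower()}"] = 0
    daily = daily.reset_index()

    meters = obs.loc[obs["measure"] == "WC_meter", ["animal_id", "timestamp", "value"]]
    if not meters.empty:
        wc = compute_wc(meters, baseline=wc_baseline)
        wc["day"] = _trial_day(pd.to_datetime(wc["date"]), trial_start)
        daily = daily.merge(wc[["animal_id", "day", "wc_l"]], on=["animal_id", "day"], how="left")
    else:
        daily["wc_l"] = np.nan

    if feed is not None and not feed.empty:
        fed = compute_dmi(feed, chaff_dm=chaff_dm, chaff_policy=chaff_policy)
        daily = daily.merge(
            fed[["animal_id", "day", "dmi_kg"]], on=["animal_id", "day"], how="left"
        )
    else:
        daily["dmi_kg"] = np.nan

    if lw is not None and not lw.empty:
        daily = daily.merge(
            lw.rename(columns={"lw_kg": "lw_kg"})[["animal_id", "day", "lw_kg"]],
            on=["animal_id", "day"],
            how="left",
        )
    else:
        daily["lw_kg"] = np.nan

    daily = daily.merge(ids, on="animal_id", how="left")
    periods = daily["day"].map(lambda d: assign_period(int(d)))
    daily["period"] = [p for p, _ in periods]
    daily["is_transition"] = [t for _, t in periods]
    front = ["animal_id", "treatment", "cohort", "pair_id", "day", "period", "is_transition"]
    daily = daily[front + [c for c in daily.columns if c not in front]]
    return daily.sort_values(["animal_id", "day"], kind="stable").reset_index(drop=True)


def aggregate_hourly(obs: pd.DataFrame, *, trial_start=None) -> pd.DataFrame:
    """Hourly-mean variant of :func:`aggregate`, keyed (animal, day, hour).

    Covers the observer measures and RT only; feed, water and live weight
    have no sub-daily resolution.
    """
    if obs.empty:
        raise ValidationError("observations table is empty")
    obs = obs.copy()
    if trial_start is None:
        trial_start = obs["timestamp"].min().normalize()
    obs["day"] = _trial_day(obs["timestamp"], trial_start)
    obs["hour"] = obs["timestamp"].dt.hour
    non_meter = obs.loc[obs["measure"] != "WC_meter"]
    piv = non_meter.pivot_table(
        index=["animal_id", "day", "hour"],
        columns="measure",
        values="value",
        aggfunc=["mean", "count"],
    )
    out = pd.DataFrame(index=piv.index)
    for m in _MEAN_MEASURES:
        if ("mean", m) in piv.columns:
            out[f"mean_{m.lower()}"] = piv[("mean", m)]
            out[f"n_{m.lower()}"] = piv[("count", m)].fillna(0).astype(int)
    return out.reset_index()


# -- CSV dialects ------------------------------------------------------------

def read_observations_csv(path) -> pd.DataFrame:
    """Tidy long observations: animal_id, treatment, cohort, pair_id, timestamp, measure, value."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"observations CSV {path} lacks columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"observations CSV {path} is empty")
    unknown = set(df["measure"].unique()) - set(MEASURES)
    if unknown:
        raise ValidationError(f"unknown measures in {path}: {sorted(unknown)}")
    return df


def read_feed_csv(path) -> pd.DataFrame:
    """Feed ledger: animal_id, day, offered_asfed_kg, refusals_asfed_kg, dm_fraction."""
    df = pd.read_csv(path)
    missing = {"animal_id", "day", "offered_asfed_kg", "refusals_asfed_kg", "dm_fraction"} - set(
        df.columns
    )
    if missing:
        raise ValidationError(f"feed CSV {path} lacks columns {sorted(missing)}")
    return df


def read_lw_csv(path) -> pd.DataFrame:
    """Live-weight table: animal_id, day, lw_kg."""
    df = pd.read_csv(path)
    missing = {"animal_id", "day", "lw_kg"} - set(df.columns)
    if missing:
        raise ValidationError(f"live-weight CSV {path} lacks columns {sorted(missing)}")
    return df
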