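"""Battery of bivariate linear relationships between daily means.

Fits the standard set of simple linear regressions relating daily-mean
rumen temperature (RT) to the climate drivers (daily max/min THI and TA)
and to the responding measures (DMI, live weight, respiration rate,
panting score, head surface temperature, water consumption), per treatment
group and pooled across groups.

Daily means here are *group-level* means (the mean over animals within a
treatment on each day), regressed across days -- days are treated as
independent observations even though they are serially correlated; every
fit carries an explicit caveat field recording that.  Significance labels:
p < 0.05 significant, 0.05 <= p <= 0.08 a tendency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, InsufficientDataError, ValidationError

__all__ = [
    "LinearFit",
    "fit_line",
    "transition_rate",
    "run_battery",
    "per_day_contrast",
    "DEFAULT_RESPONSE_PAIRS",
    "CLIMATE_PAIRS",
]

SERIAL_CAVEAT = "daily means treated as independent observations despite serial correlation"

#: Default response battery: x = daily-mean RT, y = responding measure.
DEFAULT_RESPONSE_PAIRS = (
    ("mean_rt", "dmi_kg"),
    ("mean_rt", "lw_kg"),
    ("mean_rt", "mean_rr"),
    ("mean_rt", "mean_ps"),
    ("mean_rt", "mean_st_head"),
    ("mean_rt", "wc_l"),
)

#: Climate battery: x = daily climate driver, y = daily-mean RT.
CLIMATE_PAIRS = (
    ("thi_max", "mean_rt"),
    ("thi_min", "mean_rt"),
    ("ta_max", "mean_rt"),
    ("ta_min", "mean_rt"),
)


@dataclass(frozen=True)
class LinearFit:
    """One ordinary-least-squares line with correlation and slope test."""

    x_name: str
    y_name: str
    group: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    stderr: float
    n: int
    x_range: tuple
    caveat: str = SERIAL_CAVEAT

    @property
    def r_squared(self) -> float:
        return self.pearson_r**2

    @property
    def ci95(self) -> tuple:
        """95% confidence interval for the slope (t-based, n - 2 df)."""
        half = stats.t.ppf(0.975, self.n - 2) * self.stderr
        return (self.slope - half, self.slope + half)

    @property
    def significance(self) -> str:
        if self.p_value < 0.05:
            return "significant"
        if self.p_value <= 0.08:
            return "tendency"
        return "ns"

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x

    def is_extrapolation(self, x: float) -> bool:
        lo, hi = self.x_range
        return x < lo or x > hi

    def to_dict(self) -> dict:
        out = asdict(self)
        out["r_squared"] = self.r_squared
        out["significance"] = self.significance
        out["ci95_lo"], out["ci95_hi"] = self.ci95
        return out


def fit_line(
    x: Sequence[float],
    y: Sequence[float],
    *,
    x_name: str = "x",
    y_name: str = "y",
    group: str = "pooled",
) -> LinearFit:
    """Ordinary least squares of y on x with Pearson r and slope t-test.

    Requires at least 3 paired finite observations and nonzero variance
    in x.  The p-value is the two-sided test of slope != 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(f"linear fit needs >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"regressor {x_name!r} is constant")
    res = stats.linregress(x, y)
    return LinearFit(
        x_name=x_name,
        y_name=y_name,
        group=group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(x),
        x_range=(float(x.min()), float(x.max())),
    )


def transition_rate(x0: float, y0: float, x1: float, y1: float) -> float:
    """Rate of change between two period means: ``(y1 - y0) / (x1 - x0)``.

    The two-point arithmetic used to express, e.g., the rise in respiration
    rate per unit air temperature between the pre-challenge and challenge
    period means.
    """
    if x1 == x0:
        raise DegenerateDataError("period means have identical x; rate undefined")
    return (y1 - y0) / (x1 - x0)


def _group_day_means(daily: pd.DataFrame) -> pd.DataFrame:
    value_cols = [
        c
        for c in daily.columns
        if c.startswith("mean_") or c in ("dmi_kg", "lw_kg", "wc_l")
    ]
    return (
        daily.groupby(["treatment", "day"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def run_battery(
    daily: pd.DataFrame,
    pairs: Optional[Sequence[tuple]] = None,
    climate_daily: Optional[pd.DataFrame] = None,
    groups: Sequence[str] = ("TC", "FRTN", "pooled"),
    *,
    exclude_day1_wc: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the full battery of linear fits on per-animal daily summaries.

    Parameters
    ----------
    daily : DataFrame
        Per-animal daily summaries (one row per animal-day) as produced by
        :func:`thermoloop.preprocess.aggregate`; collapsed internally to
        group-level day means.
    pairs : sequence of (x_col, y_col), optional
        Default: the response pairs (RT as x) plus, when ``climate_daily``
        is given, the climate pairs (RT as y).
    climate_daily : DataFrame, optional
        Columns ``treatment, day, thi_max, thi_min, ta_max, ta_min`` --
        merged onto the day means so climate drivers can serve as x.
    exclude_day1_wc : bool
        Drop day 1 from water-consumption fits (day-1 drinking is inflated
        by drinker training).

    Returns
    -------
    (DataFrame, skipped) : one row per (pair, group) fit, plus a log of
        combinations skipped for missing data.
    """
    gd = _group_day_means(daily)
    if climate_daily is not None:
        gd = gd.merge(climate_daily, on=["treatment", "day"], how="left")
    if pairs is None:
        pairs = list(DEFAULT_RESPONSE_PAIRS)
        if climate_daily is not None:
            pairs += list(CLIMATE_PAIRS)

    fits: list[dict] = []
    skipped: list[dict] = []
    for x_col, y_col in pairs:
        for group in groups:
            sub = gd if group == "pooled" else gd.loc[gd["treatment"] == group]
            if x_col not in sub.columns or y_col not in sub.columns:
                skipped.append({"x": x_col, "y": y_col, "group": group, "reason": "missing column"})
                continue
            data = sub[[x_col, y_col, "day"]].dropna()
            if exclude_day1_wc and "wc_l" in (x_col, y_col):
                data = data.loc[data["day"] != 1]
            if len(data) < 3:
                skipped.append(
                    {"x": x_col, "y": y_col, "group": group, "reason": f"only {len(data)} days"}
                )
                continue
            try:
                fit = fit_line(
                    data[x_col], data[y_col], x_name=x_col, y_name=y_col, group=group
                )
            except DegenerateDataError as err:
                skipped.append({"x": x_col, "y": y_col, "group": group, "reason": str(err)})
                continue
            fits.append(fit.to_dict())
    cols = [
        "x_name",
        "y_name",
        "group",
        "slope",
        "intercept",
        "pearson_r",
        "r_squared",
        "p_value",
        "significance",
        "stderr",
        "ci95_lo",
        "ci95_hi",
        "n",
        "x_range",
        "caveat",
    ]
    out = pd.DataFrame(fits, columns=cols) if fits else pd.DataFrame(columns=cols)
    return out, skipped


def per_day_contrast(
    daily: pd.DataFrame,
    measures: Optional[Sequence[str]] = None,
    *,
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Per-day between-group mean differences with Welch two-sample tests.

    For each day and measure, reports the TC and FRTN means, their
    difference (TC - FRTN), the standard error of the difference, and the
    two-sided Welch p-value.  With one animal per group, or zero variance
    in both groups, the difference is reported but the test suppressed
    (``test_flag`` records why).  ``adjust="holm"`` applies a Holm
    correction across days within each measure (off by default).
    """
    if adjust not in (None, "holm"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    if measures is None:
        measures = [
            c
            for c in daily.columns
            if c.startswith("mean_") or c in ("dmi_kg", "lw_kg", "wc_l")
        ]
    rows = []
    for day, day_df in daily.groupby("day", sort=True):
        tc = day_df.loc[day_df["treatment"] == "TC"]
        fr = day_df.loc[day_df["treatment"] == "FRTN"]
        if tc.empty or fr.empty:
            continue
        for m in measures:
            a = tc[m].dropna().to_numpy(float)
            b = fr[m].dropna().to_numpy(float)
            if len(a) == 0 or len(b) == 0:
                continue
            diff = a.mean() - b.mean()
            row = {"day": int(day), "measure": m, "mean_tc": a.mean(), "mean_frtn": b.mean(),
                   "diff": diff, "n_tc": len(a), "n_frtn": len(b)}
            if len(a) < 2 or len(b) < 2:
                row.update(sem=np.nan, p_value=np.nan, test_flag="single-animal group")
            elif a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                row.update(sem=0.0, p_value=1.0 if diff == 0 else np.nan,
                           test_flag="zero variance" if diff != 0 else "")
            else:
                sem = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
                t = stats.ttest_ind(a, b, equal_var=False)
                row.update(sem=sem, p_value=float(t.pvalue), test_flag="")
            rows.append(row)
    out = pd.DataFrame(rows)
    if adjust == "holm" and not out.empty:
        out["p_adjusted"] = np.nan
        for m, grp in out.groupby("measure"):
            mask = grp["p_value"].notna()
            p = grp.loc[mask, "p_value"].to_numpy()
            if p.size:
                order = np.argsort(p)
                adj = np.empty_like(p)
                running = 0.0
                for rank, idx in enumerate(order):
                    running = max(running, (p.size - rank) * p[idx])
                    adj[idx] = min(1.0, running)
                out.loc[grp.loc[mask].index, "p_adjusted"] = adj
    return out
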