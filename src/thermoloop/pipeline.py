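"""Config-driven end-to-end pipeline with a human-readable report.

Runs climate annotation -> preprocessing -> linear battery -> ellipse
characterization on either real CSV inputs or a simulated cohort, writing
a report bundle: daily-summary CSV, battery CSV, per-day contrast CSV, one
ellipse JSON per treatment group, a rejection log, a markdown report and a
manifest of completed stages.  A stage failure stops the run with a
nonzero status but preserves the outputs of completed stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import battery as battery_mod
from . import climate as climate_mod
from . import ellipse as ellipse_mod
from . import preprocess as prep
from . import simulate as sim
from .exceptions import PipelineStageError, ValidationError

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("thermoloop")

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Pipeline inputs and options.

    In simulate mode the cohort generator provides all inputs; in file
    mode the observation/feed/live-weight CSV paths must exist.
    """

    simulate: bool = True
    seed: int = 0
    out_dir: str = "thermoloop_out"
    observations_csv: Optional[str] = None
    feed_csv: Optional[str] = None
    lw_csv: Optional[str] = None
    climate_csv: Optional[str] = None  # optional; enables the climate battery
    trial_start: Optional[str] = None
    n_pairs: int = 18
    n_days: int = 18
    rt_floor: float = 35.0
    wc_mask: bool = False
    wc_window_min: float = 60.0
    wc_threshold_l: float = 8.0
    chaff_policy: str = "assume_consumed"
    exclude_day1_wc: bool = False
    ellipse_pairs: tuple = (("mean_rt", "dmi_kg"),)  # per-group loop fits

    def validate(self) -> None:
        if not self.simulate:
            for name in ("observations_csv", "feed_csv", "lw_csv"):
                path = getattr(self, name)
                if path is None:
                    raise ValidationError(f"file mode requires {name}")
                if not Path(path).exists():
                    raise ValidationError(f"{name} path does not exist: {path}")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "ellipse_pairs" in raw:
        raw["ellipse_pairs"] = tuple(tuple(p) for p in raw["ellipse_pairs"])
    return PipelineConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, date_format="%Y-%m-%dT%H:%M:%S")


def _period_table(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-period group means +/- SEM for every summarized measure."""
    value_cols = [
        c for c in daily.columns if c.startswith("mean_") or c in ("dmi_kg", "lw_kg", "wc_l")
    ]
    rows = []
    for (period, treatment), grp in daily.groupby(["period", "treatment"], sort=False):
        day_means = grp.groupby("day")[value_cols].mean()
        for col in value_cols:
            vals = day_means[col].dropna()
            if vals.empty:
                continue
            sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            rows.append(
                {
                    "period": period,
                    "treatment": treatment,
                    "measure": col,
                    "mean": vals.mean(),
                    "sem": sem,
                    "n_days": len(vals),
                }
            )
    order = {"PreChallenge": 0, "Challenge": 1, "Recovery": 2}
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["measure", "period", "treatment"], key=lambda s: s.map(order).fillna(s), kind="stable"
    ).reset_index(drop=True)


def _markdown_report(
    period_table: pd.DataFrame,
    battery_df: pd.DataFrame,
    contrasts: pd.DataFrame,
    ellipse_blocks: dict,
    n_rejected: int,
) -> str:
    lines = ["# Thermal challenge and recovery report", ""]
    lines += [f"Rejected records during sanitization: {n_rejected}", ""]
    lines += ["## Per-period group means (mean of daily means ± SEM over days)", ""]
    lines.append("| measure | period | group | mean | SEM | days |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in period_table.iterrows():
        sem = "" if pd.isna(r["sem"]) else f"{r['sem']:.3g}"
        lines.append(
            f"| {r['measure']} | {r['period']} | {r['treatment']} | {r['mean']:.4g} | {sem} | {r['n_days']} |"
        )
    lines += ["", "## Linear relationship battery", ""]
    lines.append("| y | x | group | slope | intercept | r | p | label | n |")
    lines.append("|---|---|---|---|---|---|---|---|---|")
    for _, r in battery_df.iterrows():
        lines.append(
            f"| {r['y_name']} | {r['x_name']} | {r['group']} | {r['slope']:.4g} "
            f"| {r['intercept']:.4g} | {r['pearson_r']:.3f} | {r['p_value']:.3g} "
            f"| {r['significance']} | {r['n']} |"
        )
    lines += ["", "## Elliptical RT-DMI relationships", ""]
    for group, block in sorted(ellipse_blocks.items()):
        lines.append(f"### Ellipse: {group}")
        lines.append("")
        if "error" in block:
            lines.append(f"fit failed: {block['error']}")
            lines.append("")
            continue
        lines.append(
            f"- center (RT, DMI): ({block['center'][0]:.3f} C, {block['center'][1]:.3f} kg/d)"
        )
        lines.append(
            f"- semi-axes: {block['semi_major']:.3f} / {block['semi_minor']:.3f}; "
            f"rotation {block['rotation_rad']:.3f} rad"
        )
        lines.append(
            f"- predicted DMI maximum {block['y_max_point'][1]:.2f} kg/d at RT {block['y_max_point'][0]:.2f} C"
        )
        lines.append(
            f"- predicted DMI minimum {block['y_min_point'][1]:.2f} kg/d at RT {block['y_min_point'][0]:.2f} C"
        )
        lines.append(
            f"- predicted RT range {block['x_min_point'][0]:.2f} to {block['x_max_point'][0]:.2f} C"
        )
        lines.append(f"- traversal: {block['direction']}")
        lines.append(
            f"- R2 (responding-variable) {block['r2_response']:.3f}; R2 (Sampson) {block['r2_sampson']:.3f}"
        )
        lines.append("")
    if not contrasts.empty:
        sig_days = contrasts.loc[contrasts["p_value"] < 0.05]
        lines.append(
            f"## Per-day group contrasts: {len(sig_days)} of {contrasts['p_value'].notna().sum()} "
            "Welch tests significant at p < 0.05"
        )
        lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"completed_stages": [], "outputs": [], "seed": config.seed}

    def done(stage: str, *files: str) -> None:
        manifest["completed_stages"].append(stage)
        manifest["outputs"].extend(files)
        log.info("stage %s complete", stage)

    try:
        if config.simulate:
            sim_cfg = sim.SimConfig(
                seed=config.seed, n_pairs=config.n_pairs, n_days=config.n_days
            )
            cohort = sim.simulate_cohort(sim_cfg)
            obs = cohort.observations
            feed, lw = cohort.feed, cohort.lw
            climate_daily = cohort.climate_daily
            trial_start = sim.TRIAL_START
            _write_csv(obs, out / "observations.csv")
            _write_csv(feed, out / "feed.csv")
            _write_csv(lw, out / "lw.csv")
            climate_mod.write_climate_csv(cohort.climate_tc, out / "climate_tc.csv")
            climate_mod.write_climate_csv(cohort.climate_frtn, out / "climate_frtn.csv")
            (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
            done(
                "simulate",
                "observations.csv", "feed.csv", "lw.csv",
                "climate_tc.csv", "climate_frtn.csv", "ground_truth.json",
            )
        else:
            obs = prep.read_observations_csv(config.observations_csv)
            feed = prep.read_feed_csv(config.feed_csv)
            lw = prep.read_lw_csv(config.lw_csv)
            climate_daily = None
            trial_start = config.trial_start
            done("load")
    except Exception as err:
        _finish(manifest, out, error=("simulate/load", str(err)))
        raise PipelineStageError("simulate/load", str(err)) from err

    try:
        obs, rejections = prep.sanitize_rt(
            obs,
            rt_floor=config.rt_floor,
            wc_mask=config.wc_mask,
            wc_window_min=config.wc_window_min,
            wc_threshold_l=config.wc_threshold_l,
        )
        obs, conflicts = prep.dedupe_bolus_transmissions(obs, transmission_col=None)
        daily = prep.aggregate(
            obs, feed, lw, trial_start=trial_start, chaff_policy=config.chaff_policy
        )
        _write_csv(daily, out / "daily_summary.csv")
        with open(out / "rejections.jsonl", "w") as fh:
            for rec in rejections + conflicts:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        done("preprocess", "daily_summary.csv", "rejections.jsonl")
    except Exception as err:
        _finish(manifest, out, error=("preprocess", str(err)))
        raise PipelineStageError("preprocess", str(err)) from err

    try:
        battery_df, skipped = battery_mod.run_battery(
            daily, climate_daily=climate_daily, exclude_day1_wc=config.exclude_day1_wc
        )
        _write_csv(battery_df, out / "battery.csv")
        for entry in skipped:
            log.info("battery skipped %s", entry)
        contrasts = battery_mod.per_day_contrast(daily)
        _write_csv(contrasts, out / "contrasts.csv")
        done("battery", "battery.csv", "contrasts.csv")
    except Exception as err:
        _finish(manifest, out, error=("battery", str(err)))
        raise PipelineStageError("battery", str(err)) from err

    try:
        ellipse_blocks: dict = {}
        gd = daily.groupby(["treatment", "day"], sort=True)[
            [c for c, _ in config.ellipse_pairs] + [c for _, c in config.ellipse_pairs]
        ].mean().reset_index()
        for x_col, y_col in config.ellipse_pairs:
            for group in sorted(gd["treatment"].unique()):
                pts = (
                    gd.loc[gd["treatment"] == group]
                    .sort_values("day")[[x_col, y_col]]
                    .dropna()
                    .to_numpy()
                )
                key = f"{group}"
                try:
                    payload = json.loads(
                        ellipse_mod.fit_to_json(pts, x_name=x_col, y_name=y_col)
                    )
                except Exception as err:  # keep the report going per group
                    payload = {"error": str(err), "x_name": x_col, "y_name": y_col}
                ellipse_blocks[key] = payload
                fname = f"ellipse_{group}.json"
                (out / fname).write_text(json.dumps(payload, indent=2, sort_keys=True))
                manifest["outputs"].append(fname)
        done("ellipse")
    except Exception as err:
        _finish(manifest, out, error=("ellipse", str(err)))
        raise PipelineStageError("ellipse", str(err)) from err

    try:
        report = _markdown_report(
            _period_table(daily), battery_df, contrasts, ellipse_blocks, len(rejections)
        )
        (out / "report.md").write_text(report)
        done("report", "report.md")
    except Exception as err:
        _finish(manifest, out, error=("report", str(err)))
        raise PipelineStageError("report", str(err)) from err

    _finish(manifest, out)
    return manifest


def _finish(manifest: dict, out: Path, error: Optional[tuple] = None) -> None:
    if error is not None:
        manifest["failed_stage"], manifest["error"] = error
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
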