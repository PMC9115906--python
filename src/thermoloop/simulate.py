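"""Synthetic paired-cohort generator for thermal-challenge trials.

Generates a virtual 18-day, two-arm trial: each weight-matched pair holds
one thermally challenged (TC) steer, exposed to diurnal heat-load cycling
during a 7-day Challenge window, and one feed-restricted thermoneutral
(FRTN) steer held at constant thermoneutral conditions but offered the
same ration as its TC partner (previous-day TC intake plus 20%).

The dynamics are the minimal mechanism that produces the qualitative
structure the downstream analysis assumes:

* THI forcing -- hourly set-points from the diurnal program, thermoneutral
  band THI ~68-71 outside Challenge and ~73-84 with diurnal cycling
  during Challenge; the FRTN rooms sit near THI 67.2 throughout;
* rumen temperature (RT) -- a fast first-order relaxation (time constant
  in hours) toward an equilibrium that rises with THI above a threshold
  and falls with reduced feed intake;
* dry-matter intake (DMI) -- a slow first-order relaxation (time constant
  in days) toward an appetite suppressed when daily RT exceeds a
  threshold.

The fast thermal lag and slow intake lag make the daily (RT, DMI)
trajectory close into a clockwise loop over challenge and recovery: RT
leads, DMI follows.  RR, panting score, surface temperatures and water
consumption are linear in the day's latent mean RT plus observation noise,
so the linear battery can be checked against known generating slopes.
All random draws flow from one seeded generator; the same config and seed
reproduce every output bit-identically.  Ground truth (animal-level
parameter draws, latent daily states, generating slopes) is returned
alongside the observation tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from . import climate as climate_mod
from .exceptions import ValidationError
from .preprocess import assign_period, pair_offer, step_down_offer

__all__ = [
    "DiurnalBand",
    "RTParams",
    "DMIParams",
    "ResponseParam",
    "LWParams",
    "SimConfig",
    "GroundTruth",
    "CohortData",
    "simulate_cohort",
    "sample_ellipse",
]

TRIAL_START = datetime(2014, 7, 27)  # day 1 of the climate-room phase
WEIGH_DAYS = (1, 2, 5, 7, 9, 10, 12, 14, 16, 18)
DM_FRACTION = 0.904  # finisher-diet dry-matter fraction
CHAFF_DM = 1.08  # kg DM/d, constant chaff allocation


@dataclass(frozen=True)
class DiurnalBand:
    """Daily (TA, RH) trough and plateau for one room program."""

    ta_min: float
    rh_min: float
    ta_max: float
    rh_max: float

    def program(self) -> climate_mod.DiurnalProgram:
        return climate_mod.build_diurnal_program(
            (self.ta_min, self.rh_min), (self.ta_max, self.rh_max)
        )


@dataclass(frozen=True)
class RTParams:
    """Rumen-temperature dynamics.

    Equilibrium RT = baseline + sensitivity * max(0, THI - threshold)
    + feed_gain * (previous-day intake - intake reference); hourly
    relaxation toward it with time constant ``tau_hours``.
    """

    baseline: float = 39.60  # deg C at thermoneutral, full feed
    thi_threshold: float = 74.0  # THI above which RT rises
    thi_sensitivity: float = 0.33  # deg C per THI unit above threshold
    tau_hours: float = 6.0
    feed_gain: float = 0.14  # deg C per kg DMI below/above reference
    bolus_noise_sd: float = 0.15  # deg C, per 10-min transmission
    baseline_sd: float = 0.10  # between-animal SD of baseline
    adapted_offset: float = -0.06  # deg C shift from Recovery onward (the
    # intake deficit contributes a further ~-0.19 via feed_gain)


@dataclass(frozen=True)
class DMIParams:
    """Appetite dynamics (total DMI, kg/steer/day, chaff included)."""

    baseline: float = 11.2
    rt_threshold: float = 39.8  # deg C above which appetite is suppressed
    suppression: float = 7.0  # kg DMI per deg C RT above threshold
    tau_days: float = 2.0
    baseline_sd: float = 0.5  # between-animal SD of baseline
    intake_noise_sd: float = 0.25  # kg, day-to-day intake noise
    adapted_fraction: float = 0.88  # Recovery appetite as fraction of baseline
    max_daily_drop: float = 2.5  # kg/d cap on FRTN offer step-down


@dataclass(frozen=True)
class ResponseParam:
    """One linear-in-RT response: value = value_at_ref + slope*(RT - ref)."""

    slope: float
    value_at_ref: float
    noise_sd: float


def _default_responses() -> dict:
    # slopes per deg C RT; reference RT is RTParams.baseline
    return {
        "RR": ResponseParam(slope=46.0, value_at_ref=75.0, noise_sd=6.0),
        "PS": ResponseParam(slope=0.63, value_at_ref=1.40, noise_sd=0.25),
        "ST_head": ResponseParam(slope=4.3, value_at_ref=24.5, noise_sd=1.0),
        "ST_shoulder": ResponseParam(slope=3.0, value_at_ref=27.0, noise_sd=1.0),
        "ST_rump": ResponseParam(slope=3.0, value_at_ref=26.0, noise_sd=1.0),
        "ST_leg": ResponseParam(slope=2.5, value_at_ref=24.0, noise_sd=1.0),
        "WC": ResponseParam(slope=10.5, value_at_ref=42.0, noise_sd=4.0),
    }


@dataclass(frozen=True)
class LWParams:
    """Live-weight integration: daily gain proportional to DMI surplus."""

    entry_mean: float = 521.0  # kg, room-entry live weight
    entry_sd: float = 23.0
    pair_scatter_sd: float = 8.0  # within-pair LW difference scale
    maintenance_dmi: float = 9.8  # kg DMI/d for zero gain
    gain_per_kg: float = 1.3  # kg LW per kg DMI above maintenance
    noise_sd: float = 1.0  # kg/d


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulated cohort.

    Defaults are the study conditions: 18 pairs over 18 days with the
    Challenge window on days 5-11.
    """

    n_pairs: int = 18
    n_days: int = 18
    challenge_start: int = 5
    challenge_end: int = 11
    thermoneutral_band: DiurnalBand = field(
        default_factory=lambda: DiurnalBand(21.1, 70.0, 23.1, 70.0)  # THI ~ 68-71
    )
    challenge_band: DiurnalBand = field(
        default_factory=lambda: DiurnalBand(26.0, 50.0, 34.5, 50.0)  # THI ~ 73-84
    )
    frtn_ta: float = 20.34
    frtn_rh: float = 71.51  # THI 66.9 at set-point
    room_ta_noise_sd: float = 0.25
    room_rh_noise_sd: float = 2.0
    rt: RTParams = field(default_factory=RTParams)
    dmi: DMIParams = field(default_factory=DMIParams)
    responses: dict = field(default_factory=_default_responses)
    lw: LWParams = field(default_factory=LWParams)
    adapted_state: bool = True  # lowered RT/appetite from Recovery onward
    stress_bump: bool = False  # transient FRTN hyperthermia, days 3-6
    stress_bump_c: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1 or self.n_days < 1:
            raise ValidationError("n_pairs and n_days must be positive")
        if not (1 <= self.challenge_start <= self.challenge_end <= self.n_days):
            raise ValidationError(
                f"challenge window {self.challenge_start}-{self.challenge_end} "
                f"must lie within days 1-{self.n_days}"
            )
        if self.rt.tau_hours <= 0 or self.dmi.tau_days <= 0:
            raise ValidationError("time constants must be positive")
        if self.dmi.tau_days <= self.rt.tau_hours / 24.0:
            raise ValidationError(
                "intake time constant (days) must exceed the RT time constant "
                "(hours)/24 for the loop to close"
            )
        sds = [
            self.rt.bolus_noise_sd,
            self.rt.baseline_sd,
            self.dmi.intake_noise_sd,
            self.dmi.baseline_sd,
            self.room_ta_noise_sd,
            self.room_rh_noise_sd,
            self.lw.noise_sd,
        ] + [r.noise_sd for r in self.responses.values()]
        if any(s < 0 for s in sds):
            raise ValidationError("noise SDs must be non-negative")

    def is_challenge_day(self, day: int) -> bool:
        return self.challenge_start <= day <= self.challenge_end

    def obs_hours(self, day: int) -> list:
        """Observer schedule: 2-hourly 0600-1800, around the clock in Challenge."""
        if self.is_challenge_day(day):
            return list(range(0, 24, 2))
        return list(range(6, 20, 2))


@dataclass
class GroundTruth:
    """Generating parameters and latent states written alongside the data."""

    seed: int
    animal_ids: list
    treatments: list
    base_rt: list  # per-animal RT baseline, deg C
    base_dmi: list  # per-animal appetite baseline, kg DMI/d (total)
    entry_lw: list
    response_params: dict  # measure -> {slope, value_at_ref, noise_sd}
    rt_ref: float
    rt_day_latent: list  # [day][animal] latent daily-mean RT
    dmi: list  # [day][animal] realized total DMI
    climate_daily: list  # per arm/day realized THI/TA extremes

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class CohortData:
    """Everything one simulated cohort produces."""

    config: SimConfig
    daily: pd.DataFrame  # per-animal daily summaries (fast path)
    climate_daily: pd.DataFrame  # treatment, day, thi/ta extremes
    feed: pd.DataFrame
    lw: pd.DataFrame
    ground_truth: GroundTruth
    observations: Optional[pd.DataFrame] = None  # tidy long records
    climate_tc: Optional[pd.DataFrame] = None  # hourly room climate
    climate_frtn: Optional[pd.DataFrame] = None


def _hourly_climate(config: SimConfig, rng: np.random.Generator):
    """Realized hourly (TA, RH, THI) per arm; room-level noise."""
    d, h = config.n_days, 24
    tn = config.thermoneutral_band.program()
    ch = config.challenge_band.program()
    ta_tc = np.empty((d, h))
    rh_tc = np.empty((d, h))
    for i in range(d):
        prog = ch if config.is_challenge_day(i + 1) else tn
        ta_tc[i] = [t for t, _ in prog.hourly_targets]
        rh_tc[i] = [r for _, r in prog.hourly_targets]
    ta_tc = ta_tc + rng.normal(0.0, config.room_ta_noise_sd, (d, h))
    rh_tc = np.clip(rh_tc + rng.normal(0.0, config.room_rh_noise_sd, (d, h)), 0.0, 100.0)
    ta_fr = config.frtn_ta + rng.normal(0.0, config.room_ta_noise_sd, (d, h))
    rh_fr = np.clip(
        config.frtn_rh + rng.normal(0.0, config.room_rh_noise_sd, (d, h)), 0.0, 100.0
    )
    thi_tc = climate_mod.compute_thi(ta_tc, rh_tc)
    thi_fr = climate_mod.compute_thi(ta_fr, rh_fr)
    return {"ta_tc": ta_tc, "rh_tc": rh_tc, "thi_tc": thi_tc,
            "ta_fr": ta_fr, "rh_fr": rh_fr, "thi_fr": thi_fr}


def _simulate_core(config: SimConfig) -> dict:
    """Run the full latent + observed simulation into numeric arrays.

    All draws come from one generator in a fixed order, so the output is a
    deterministic function of (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_pairs
    n_animals = 2 * p  # TC then FRTN, pair i <-> i and i+p
    d = config.n_days

    clim = _hourly_climate(config, rng)

    base_rt = config.rt.baseline + rng.normal(0.0, config.rt.baseline_sd, n_animals)
    base_dmi = config.dmi.baseline + rng.normal(0.0, config.dmi.baseline_sd, n_animals)
    base_dmi = np.clip(base_dmi, CHAFF_DM + 1.0, None)
    pair_lw = config.lw.entry_mean + rng.normal(0.0, config.lw.entry_sd, p)
    entry_lw = np.concatenate([pair_lw, pair_lw]) + rng.normal(
        0.0, config.lw.pair_scatter_sd, n_animals
    )

    base_grain = base_dmi - CHAFF_DM  # appetite for the grain ration, kg DM

    alpha = 1.0 - np.exp(-1.0 / config.rt.tau_hours)  # hourly relaxation gain
    beta = 1.0 - np.exp(-1.0 / config.dmi.tau_days)  # daily relaxation gain
    is_tc = np.arange(n_animals) < p

    rt_hourly = np.empty((d, 24, n_animals))
    rt_day = np.empty((d, n_animals))
    grain_intake = np.empty((d, n_animals))
    offered_grain = np.empty((d, n_animals))
    lw_daily = np.empty((d, n_animals))
    wc_daily = np.empty((d, n_animals))

    rt_state = base_rt.copy()
    appetite = base_grain.copy()  # TC appetite state (grain terms)
    intake_prev = base_grain.copy()
    # FRTN offers open at the pair-offer level implied by TC baseline intake
    offer_fr_prev = np.array([pair_offer(v) for v in base_grain[:p]])
    lw_state = entry_lw.copy()

    wc_par = config.responses["WC"]
    adapted = lambda day: (config.adapted_state and day >= config.challenge_end + 1)

    for i in range(d):
        day = i + 1
        rt_offset = config.rt.adapted_offset if adapted(day) else 0.0
        bump = (
            config.stress_bump_c
            if (config.stress_bump and 3 <= day <= 6)
            else 0.0
        )
        thi = np.where(is_tc[None, :], clim["thi_tc"][i][:, None], clim["thi_fr"][i][:, None])
        heat = config.rt.thi_sensitivity * np.clip(thi - config.rt.thi_threshold, 0.0, None)
        feed_term = config.rt.feed_gain * (
            (intake_prev + CHAFF_DM) - config.dmi.baseline
        )
        eq = base_rt[None, :] + rt_offset + heat + feed_term[None, :]
        eq[:, ~is_tc] += bump
        for h in range(24):
            rt_state = rt_state + alpha * (eq[h] - rt_state)
            rt_hourly[i, h] = rt_state
        rt_day[i] = rt_hourly[i].mean(axis=0)

        # TC appetite relaxes toward its heat-suppressed equilibrium
        adapt_frac = config.dmi.adapted_fraction if adapted(day) else 1.0
        suppression = config.dmi.suppression * np.clip(
            rt_day[i] - config.dmi.rt_threshold, 0.0, None
        )
        grain_eq = np.clip(base_grain * adapt_frac - suppression, 0.0, None)
        appetite = appetite + beta * (grain_eq - appetite)

        # pair offering: previous-day TC intake + 20%, same amount both arms
        off_tc = np.array([pair_offer(v) for v in intake_prev[:p]])
        target_fr = off_tc
        off_fr = np.array(
            [
                step_down_offer(prev, tgt, config.dmi.max_daily_drop)
                for prev, tgt in zip(offer_fr_prev, target_fr)
            ]
        )
        offer_fr_prev = off_fr
        offered = np.concatenate([off_tc, off_fr])
        offered_grain[i] = offered

        want = np.where(is_tc, appetite, base_grain * adapt_frac)
        noise = rng.normal(0.0, config.dmi.intake_noise_sd, n_animals)
        grain_intake[i] = np.clip(np.minimum(want, offered) + noise, 0.0, offered)
        intake_prev = grain_intake[i]

        total_dmi = grain_intake[i] + CHAFF_DM
        lw_state = lw_state + config.lw.gain_per_kg * (
            total_dmi - config.lw.maintenance_dmi
        ) + rng.normal(0.0, config.lw.noise_sd, n_animals)
        lw_daily[i] = lw_state

        wc_mean = wc_par.value_at_ref + wc_par.slope * (rt_day[i] - config.rt.baseline)
        wc_daily[i] = np.clip(wc_mean + rng.normal(0.0, wc_par.noise_sd, n_animals), 5.0, None)

    # observed bolus RT: 10-min interpolation of the hourly latent + noise
    j = np.arange(144)
    h_lo = j // 6
    frac = (j % 6) / 6.0
    h_hi = np.minimum(h_lo + 1, 23)
    bolus_latent = (
        (1.0 - frac)[None, :, None] * rt_hourly[:, h_lo, :]
        + frac[None, :, None] * rt_hourly[:, h_hi, :]
    )  # (day, 144, animal)
    bolus = bolus_latent + rng.normal(0.0, config.rt.bolus_noise_sd, bolus_latent.shape)

    # observer measures, linear in the day's latent mean RT
    obs_values = {}  # measure -> list over days of (n_obs, n_animals)
    for name in ("RR", "PS", "ST_head", "ST_shoulder", "ST_rump", "ST_leg"):
        par = config.responses[name]
        per_day = []
        for i in range(d):
            n_obs = len(config.obs_hours(i + 1))
            mean = par.value_at_ref + par.slope * (rt_day[i] - config.rt.baseline)
            vals = mean[None, :] + rng.normal(0.0, par.noise_sd, (n_obs, n_animals))
            if name == "PS":
                vals = np.clip(vals, 0.0, 4.5)
            per_day.append(vals)
        obs_values[name] = per_day

    return {
        "clim": clim,
        "base_rt": base_rt,
        "base_dmi": base_dmi,
        "entry_lw": entry_lw,
        "rt_hourly": rt_hourly,
        "rt_day": rt_day,
        "grain_intake": grain_intake,
        "offered_grain": offered_grain,
        "lw_daily": lw_daily,
        "wc_daily": wc_daily,
        "bolus": bolus,
        "obs_values": obs_values,
        "is_tc": is_tc,
    }


def _animal_ids(config: SimConfig) -> tuple[list, list, list, list]:
    p = config.n_pairs
    ids = [f"TC{i + 1:02d}" for i in range(p)] + [f"FR{i + 1:02d}" for i in range(p)]
    treatments = ["TC"] * p + ["FRTN"] * p
    pair_ids = [f"P{i + 1:02d}" for i in range(p)] * 2
    n_cohorts = min(3, p)
    cohorts = [(i * n_cohorts) // p + 1 for i in range(p)] * 2
    return ids, treatments, pair_ids, cohorts


def _daily_from_core(config: SimConfig, core: dict) -> pd.DataFrame:
    """Per-animal daily summaries straight from the simulation arrays.

    Numerically identical (to rounding) to emitting tidy records and
    aggregating them; that equality is covered by a test.
    """
    ids, treatments, pair_ids, cohorts = _animal_ids(config)
    d = config.n_days
    n_animals = 2 * config.n_pairs
    rows = []
    for a in range(n_animals):
        for i in range(d):
            day = i + 1
            period, trans = assign_period(day)
            row = {
                "animal_id": ids[a],
                "treatment": treatments[a],
                "cohort": cohorts[a],
                "pair_id": pair_ids[a],
                "day": day,
                "period": period,
                "is_transition": trans,
                "mean_rt": core["bolus"][i, :, a].mean(),
                "n_rt": 144,
                "wc_l": core["wc_daily"][i, a],
                "dmi_kg": core["grain_intake"][i, a] + CHAFF_DM,
                "lw_kg": core["lw_daily"][i, a] if day in WEIGH_DAYS else np.nan,
            }
            for name in ("RR", "PS", "ST_head", "ST_shoulder", "ST_rump", "ST_leg"):
                vals = core["obs_values"][name][i][:, a]
                row[f"mean_{name.lower()}"] = vals.mean()
                row[f"n_{name.lower()}"] = len(vals)
            rows.append(row)
    return pd.DataFrame(rows)


def _climate_daily_from_core(config: SimConfig, core: dict) -> pd.DataFrame:
    rows = []
    clim = core["clim"]
    for i in range(config.n_days):
        for arm, ta, rh, thi in (
            ("TC", clim["ta_tc"][i], clim["rh_tc"][i], clim["thi_tc"][i]),
            ("FRTN", clim["ta_fr"][i], clim["rh_fr"][i], clim["thi_fr"][i]),
        ):
            rows.append(
                {
                    "treatment": arm,
                    "day": i + 1,
                    "thi_max": thi.max(),
                    "thi_min": thi.min(),
                    "thi_mean": thi.mean(),
                    "ta_max": ta.max(),
                    "ta_min": ta.min(),
                    "rh_mean": rh.mean(),
                }
            )
    return pd.DataFrame(rows)


def _feed_lw_from_core(config: SimConfig, core: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    ids, _, _, _ = _animal_ids(config)
    d = config.n_days
    n_animals = 2 * config.n_pairs
    feed_rows = []
    lw_rows = []
    for a in range(n_animals):
        for i in range(d):
            day = i + 1
            offered = core["offered_grain"][i, a] / DM_FRACTION
            refused = (core["offered_grain"][i, a] - core["grain_intake"][i, a]) / DM_FRACTION
            feed_rows.append(
                {
                    "animal_id": ids[a],
                    "day": day,
                    "offered_asfed_kg": offered,
                    "refusals_asfed_kg": max(refused, 0.0),
                    "dm_fraction": DM_FRACTION,
                }
            )
            if day in WEIGH_DAYS:
                lw_rows.append(
                    {"animal_id": ids[a], "day": day, "lw_kg": core["lw_daily"][i, a]}
                )
    return pd.DataFrame(feed_rows), pd.DataFrame(lw_rows)


def _observations_from_core(config: SimConfig, core: dict) -> pd.DataFrame:
    """Emit the tidy long observation table on the trial schedule."""
    ids, treatments, pair_ids, cohorts = _animal_ids(config)
    d = config.n_days
    n_animals = 2 * config.n_pairs
    frames = []

    # bolus RT: every 10 minutes
    minutes = np.arange(144) * 10
    for i in range(d):
        day_start = TRIAL_START + timedelta(days=i)
        times = np.array([day_start + timedelta(minutes=int(m)) for m in minutes])
        vals = core["bolus"][i]  # (144, animals)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": np.repeat(ids, 144),
                    "timestamp": np.tile(times, n_animals),
                    "measure": "RT",
                    "value": vals.T.ravel(),
                }
            )
        )

    # observer measures and water meter
    meter_close = np.zeros(n_animals)
    for i in range(d):
        day = i + 1
        hours = config.obs_hours(day)
        day_start = TRIAL_START + timedelta(days=i)
        times = np.array([day_start + timedelta(hours=h) for h in hours])
        n_obs = len(hours)
        for name in ("RR", "PS", "ST_head", "ST_shoulder", "ST_rump", "ST_leg"):
            vals = core["obs_values"][name][i]  # (n_obs, animals)
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": np.repeat(ids, n_obs),
                        "timestamp": np.tile(times, n_animals),
                        "measure": name,
                        "value": vals.T.ravel(),
                    }
                )
            )
        # cumulative meter: first reading of the day is the previous close,
        # the last reading closes the day at previous close + daily intake
        frac = np.arange(n_obs) / (n_obs - 1) if n_obs > 1 else np.array([1.0])
        readings = meter_close[None, :] + frac[:, None] * core["wc_daily"][i][None, :]
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": np.repeat(ids, n_obs),
                    "timestamp": np.tile(times, n_animals),
                    "measure": "WC_meter",
                    "value": readings.T.ravel(),
                }
            )
        )
        meter_close = meter_close + core["wc_daily"][i]

    obs = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(
        {"animal_id": ids, "treatment": treatments, "cohort": cohorts, "pair_id": pair_ids}
    )
    obs = obs.merge(meta, on="animal_id", how="left")
    obs = obs[["animal_id", "treatment", "cohort", "pair_id", "timestamp", "measure", "value"]]
    return obs.sort_values(["animal_id", "timestamp", "measure"], kind="stable").reset_index(
        drop=True
    )


def _climate_frames(config: SimConfig, core: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    clim = core["clim"]
    d = config.n_days
    times = [
        TRIAL_START + timedelta(days=i, hours=h) for i in range(d) for h in range(24)
    ]
    tc = pd.DataFrame(
        {"timestamp": times, "ta_c": clim["ta_tc"].ravel(), "rh_pct": clim["rh_tc"].ravel()}
    )
    fr = pd.DataFrame(
        {"timestamp": times, "ta_c": clim["ta_fr"].ravel(), "rh_pct": clim["rh_fr"].ravel()}
    )
    return tc, fr


def simulate_cohort(config: Optional[SimConfig] = None, *, emit_records: bool = True) -> CohortData:
    """Simulate one paired cohort.

    Parameters
    ----------
    config : SimConfig
        Trial configuration; defaults are the study conditions.
    emit_records : bool
        Also build the tidy record-level tables (observations and hourly
        room climate).  The daily summaries, feed ledger, live weights and
        ground truth are always produced; skipping record emission is much
        faster for Monte-Carlo work and uses the identical random draws.

    Returns
    -------
    CohortData
    """
    if config is None:
        config = SimConfig()
    core = _simulate_core(config)
    ids, treatments, _, _ = _animal_ids(config)
    daily = _daily_from_core(config, core)
    climate_daily = _climate_daily_from_core(config, core)
    feed, lw = _feed_lw_from_core(config, core)
    gt = GroundTruth(
        seed=config.seed,
        animal_ids=ids,
        treatments=treatments,
        base_rt=[float(v) for v in core["base_rt"]],
        base_dmi=[float(v) for v in core["base_dmi"]],
        entry_lw=[float(v) for v in core["entry_lw"]],
        response_params={k: asdict(v) for k, v in config.responses.items()},
        rt_ref=config.rt.baseline,
        rt_day_latent=[[float(v) for v in row] for row in core["rt_day"]],
        dmi=[[float(v) for v in row + CHAFF_DM] for row in core["grain_intake"]],
        climate_daily=climate_daily.to_dict("records"),
    )
    data = CohortData(
        config=config,
        daily=daily,
        climate_daily=climate_daily,
        feed=feed,
        lw=lw,
        ground_truth=gt,
    )
    if emit_records:
        data.observations = _observations_from_core(config, core)
        data.climate_tc, data.climate_frtn = _climate_frames(config, core)
    return data


def sample_ellipse(
    geometry,
    n: int = 18,
    noise_sd: float = 0.0,
    rng=None,
    direction: str = "counterclockwise",
    theta0: float = 0.0,
):
    """Ordered points on a known ellipse, for recovery tests.

    Points sit at equal parametric angles; the ordering encodes the
    traversal direction.  Isotropic Gaussian noise of SD ``noise_sd`` is
    added to both coordinates.

    Parameters
    ----------
    geometry : EllipseGeometry or (x0, y0, semi_major, semi_minor, rotation)
    """
    if n < 6:
        raise ValidationError(f"need >= 6 sample points, got {n}")
    if hasattr(geometry, "center"):
        x0, y0 = geometry.center
        a, b, rot = geometry.semi_major, geometry.semi_minor, geometry.rotation
    else:
        x0, y0, a, b, rot = geometry
    sign = 1.0 if direction == "counterclockwise" else -1.0
    theta = theta0 + sign * 2.0 * np.pi * np.arange(n) / n
    ct, st = np.cos(rot), np.sin(rot)
    x = x0 + a * np.cos(theta) * ct - b * np.sin(theta) * st
    y = y0 + a * np.cos(theta) * st + b * np.sin(theta) * ct
    pts = np.column_stack([x, y])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        elif isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return pts
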