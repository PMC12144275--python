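"""Seeded synthetic ICU urine-output cohorts with known ground truth.

The generator emulates the charting behaviour of real ICU EHRs well enough
to exercise every stage of the pipeline while carrying exact ground truth:

* each patient has a piecewise-constant (per clock hour) true urine
  production trajectory — a log-normal baseline rate (median 85 ml/hr,
  the duration-weighted Foley rate typical of mixed ICU populations) with an
  optional oliguric episode of configurable onset, depth (ml/kg/hr) and
  duration, including anuria;
* charted volumes are *exact integrals* of the true rate over each
  collection interval, so with complete hourly charting the pipeline can
  recover the truth exactly;
* charting cadence per source follows shifted log-normal gaps whose modes
  mirror observed practice (Foley 60 min, voiding/condom 120, straight
  catheter 360, nephrostomy 120), or an exact hourly cadence for recovery
  tests;
* nephrostomy patients chart two single-kidney compartments at roughly half
  the bladder rate each;
* a first residual record per compartment, zero-volume double-charting rows
  (1-2.5 % of rows), and 30-day mortality drawn from a logistic model in the
  true peak KDIGO-UO stage;
* :func:`inject_artifacts` adds out-of-range volumes and weights,
  simultaneous duplicate pairs and exclusion-source labels with a manifest,
  so cleaning rules can be verified row by row.

Ground-truth stages are computed by a direct per-hour window scan, a
deliberately separate code path from the rolling-window implementation in
:mod:`uokit.staging`.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import yaml

from .staging import KdigoThresholds

__all__ = ["SimConfig", "SimResult", "simulate_cohort", "simulate_outcomes", "inject_artifacts"]

_BASE_DATE = pd.Timestamp("2020-01-01 00:00:00")

#: charting-gap mode per source, minutes
DEFAULT_CHARTING_MODES = {
    "Foley": 60,
    "Suprapubic": 60,
    "Ileoconduit": 60,
    "Void": 120,
    "Condom Cath": 120,
    "Straight Cath": 360,
    "R Nephrostomy": 120,
    "L Nephrostomy": 120,
}

#: probability a patient charts via each bladder-route source (nephrostomy
#: and ileal conduit handled separately)
DEFAULT_SOURCE_PROBS = {
    "Foley": 0.86,
    "Void": 0.07,
    "Straight Cath": 0.02,
    "Condom Cath": 0.01,
    "Suprapubic": 0.01,
    "Ileoconduit": 0.01,
    "Nephrostomy": 0.02,
}


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated cohort.  ``seed`` is mandatory."""

    n_patients: int
    seed: int
    stay_hours: int = 96
    charting: str = "realistic"  # or "hourly" (exact clock-aligned cadence)
    baseline_median_ml_hr: float = 85.0  # at the reference weight (weight_mean_kg)
    baseline_sigma: float = 0.45  # log-scale SD of the baseline per-kg rate
    baseline_min_ml_kg_hr: float = 0.6  # non-oliguric floor: only episodes cross KDIGO cuts
    p_oliguria: float = 0.5
    p_anuria_given_episode: float = 0.10
    episode_onset_max_hr: int = 36
    episode_duration_range_hr: tuple[int, int] = (6, 36)
    episode_depth_range: tuple[float, float] = (0.05, 0.45)  # ml/kg/hr
    zero_record_fraction: float = 0.015
    source_probs: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_SOURCE_PROBS))
    charting_modes: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CHARTING_MODES))
    weight_mean_kg: float = 81.0
    weight_sd_kg: float = 20.0
    age_mean_years: float = 65.0
    age_sd_years: float = 17.0
    p_female: float = 0.44
    baseline_mortality: float = 0.072
    stage_mortality_ors: dict = dataclasses.field(
        default_factory=lambda: {1: 1.75, 2: 3.3, 3: 7.5}
    )
    horizon_hours: int = 72
    thresholds: KdigoThresholds = dataclasses.field(default_factory=KdigoThresholds)

    def __post_init__(self) -> None:
        for name, p in (
            ("p_oliguria", self.p_oliguria),
            ("p_anuria_given_episode", self.p_anuria_given_episode),
            ("zero_record_fraction", self.zero_record_fraction),
            ("p_female", self.p_female),
            ("baseline_mortality", self.baseline_mortality),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.charting not in ("realistic", "hourly"):
            raise ValueError(f"charting must be 'realistic' or 'hourly', got {self.charting!r}")
        if self.stay_hours <= 0 or self.n_patients <= 0:
            raise ValueError("n_patients and stay_hours must be positive")
        lo, hi = self.episode_duration_range_hr
        if lo <= 0 or hi < lo:
            raise ValueError("episode_duration_range_hr must be positive and ordered")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "thresholds" in data:
            data["thresholds"] = KdigoThresholds(**data["thresholds"])
        for k in ("episode_duration_range_hr", "episode_depth_range"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)


@dataclasses.dataclass
class SimResult:
    admissions: pd.DataFrame
    uo_records: pd.DataFrame
    truth_hourly: pd.DataFrame   # admission_id, hour_start, true_ml, true_stage (cons), true_stage_mean
    truth_admissions: pd.DataFrame  # admission_id, true_peak_stage, at_admission, died_30d
    params: dict


def _direct_stage_scan(per_kg: np.ndarray, th: KdigoThresholds, interpretation: str) -> np.ndarray:
    """Ground-truth staging by explicit per-hour window slicing (all hours valid)."""
    n = len(per_kg)
    out = np.full(n, np.nan)
    stat = np.mean if interpretation == "mean" else np.max
    for t in range(n):
        if t + 1 < th.w1_hours:
            continue
        stage = 0
        if stat(per_kg[t + 1 - th.w1_hours: t + 1]) < th.t_stage12:
            stage = 1
        if t + 1 >= th.w2_hours and stat(per_kg[t + 1 - th.w2_hours: t + 1]) < th.t_stage12:
            stage = 2
        if t + 1 >= th.w3_hours and stat(per_kg[t + 1 - th.w3_hours: t + 1]) < th.t_stage3:
            stage = 3
        if t + 1 >= th.anuria_hours and np.max(per_kg[t + 1 - th.anuria_hours: t + 1]) == 0.0:
            stage = 3
        out[t] = stage
    return out


def _death_probability(stage: np.ndarray, p0: float, ors: dict) -> np.ndarray:
    logit0 = math.log(p0 / (1 - p0))
    lo = np.array([logit0 + math.log(ors.get(int(s), 1.0)) if s > 0 else logit0 for s in stage])
    return 1.0 / (1.0 + np.exp(-lo))


def _charting_gaps_minutes(rng, mode_min: int, total_min: int, cadence: str) -> np.ndarray:
    """Successive charting gaps covering at least ``total_min`` minutes."""
    if cadence == "hourly":
        return np.full(total_min // 60, 60, dtype=int)
    # shifted log-normal with the requested mode; sigma tuned for the
    # right-skewed shapes seen in real charting
    sigma = 0.6
    mu = math.log(mode_min) + sigma**2  # mode of lognormal = exp(mu - sigma^2)
    n_guess = max(8, int(total_min / mode_min * 2) + 8)
    gaps = np.exp(rng.normal(mu, sigma, size=n_guess))
    gaps = np.clip(np.round(gaps), 10, 18 * 60).astype(int)
    while gaps.sum() < total_min:
        extra = np.exp(rng.normal(mu, sigma, size=8))
        gaps = np.concatenate([gaps, np.clip(np.round(extra), 10, 18 * 60).astype(int)])
    cut = np.searchsorted(np.cumsum(gaps), total_min) + 1
    return gaps[:cut]


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate admissions, UO charting and ground truth for one cohort.

    Same seed, same config => identical output frames.  Charted volumes are
    exact integrals of the true hourly-piecewise-constant rate over each
    collection interval; ground truth carries the true hourly volumes and
    the true KDIGO-UO stage (both interpretations) per hour, plus each
    admission's true peak stage within the horizon and its simulated 30-day
    outcome.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    th = config.thresholds

    weight = np.clip(rng.normal(config.weight_mean_kg, config.weight_sd_kg, n), 40, 180).round(1)
    age = np.clip(rng.normal(config.age_mean_years, config.age_sd_years, n), 18, 95).round(0)
    female = rng.random(n) < config.p_female

    src_names = list(config.source_probs)
    src_p = np.array([config.source_probs[s] for s in src_names], float)
    src_p = src_p / src_p.sum()
    patient_source = rng.choice(src_names, size=n, p=src_p)

    has_episode = rng.random(n) < config.p_oliguria
    onset = rng.integers(0, config.episode_onset_max_hr + 1, n)
    dur_lo, dur_hi = config.episode_duration_range_hr
    duration = rng.integers(dur_lo, dur_hi + 1, n)
    is_anuric = has_episode & (rng.random(n) < config.p_anuria_given_episode)
    d_lo, d_hi = config.episode_depth_range
    depth = rng.uniform(d_lo, d_hi, n)
    depth[is_anuric] = 0.0

    # baseline production scales with body weight: draw a per-kg rate whose
    # median matches the configured total rate at the reference weight, floored
    # above the KDIGO cutoff so oliguria only arises from modelled episodes
    per_kg_median = config.baseline_median_ml_hr / config.weight_mean_kg
    baseline_rate = (
        np.maximum(
            np.exp(rng.normal(math.log(per_kg_median), config.baseline_sigma, n)),
            config.baseline_min_ml_kg_hr,
        )
        * weight
    )

    stay_min = config.stay_hours * 60
    adm_rows, uo_rows = [], []
    truth_hourly_frames = []
    truth_adm_rows = []

    for i in range(n):
        adm_id = f"adm{i:06d}"
        if config.charting == "hourly":
            icu_in = _BASE_DATE + pd.Timedelta(days=int(i % 360))
        else:
            icu_in = _BASE_DATE + pd.Timedelta(days=int(i % 360), minutes=int(rng.integers(0, 1440)))
        icu_out = icu_in + pd.Timedelta(hours=config.stay_hours)

        # true total-production trajectory, ml/hr per clock hour of the stay
        rate = np.full(config.stay_hours, baseline_rate[i])
        if has_episode[i]:
            a, b = int(onset[i]), min(int(onset[i] + duration[i]), config.stay_hours)
            rate[a:b] = depth[i] * weight[i]

        # compartments charted by this patient
        if patient_source[i] == "Nephrostomy":
            comps = [("R Nephrostomy", rate * 0.5), ("L Nephrostomy", rate * 0.5)]
        else:
            comps = [(patient_source[i], rate)]

        for label, comp_rate in comps:
            cum = np.concatenate([[0.0], np.cumsum(np.repeat(comp_rate / 60.0, 60))])
            gaps = _charting_gaps_minutes(
                rng, config.charting_modes.get(label, 60), stay_min, config.charting
            )
            times = np.cumsum(gaps)
            times = times[times <= stay_min]
            residual = float(np.round(rng.uniform(30, 400), 0))
            uo_rows.append((adm_id, icu_in, residual, label))
            prev = 0
            for t in times:
                vol = cum[int(t)] - cum[int(prev)]
                uo_rows.append((adm_id, icu_in + pd.Timedelta(minutes=int(t)), float(vol), label))
                prev = t

        per_kg = rate / weight[i]
        stage_cons = _direct_stage_scan(per_kg, th, "cons")
        stage_mean = _direct_stage_scan(per_kg, th, "mean")
        hours = icu_in.floor("h") + pd.to_timedelta(np.arange(config.stay_hours), unit="h")
        truth_hourly_frames.append(
            pd.DataFrame(
                {
                    "admission_id": adm_id,
                    "hour_start": hours,
                    "true_ml": rate,
                    "true_stage": pd.array(stage_cons, dtype="Int64"),
                    "true_stage_mean": pd.array(stage_mean, dtype="Int64"),
                }
            )
        )
        in_horizon = stage_cons[: config.horizon_hours]
        computable = ~np.isnan(in_horizon)
        peak = int(np.nanmax(in_horizon)) if computable.any() else None
        first_idx = int(np.argmax(computable)) if computable.any() else None
        at_adm = bool(in_horizon[first_idx] >= 1) if first_idx is not None else False
        truth_adm_rows.append((adm_id, peak, at_adm))
        adm_rows.append(
            (adm_id, f"pt{i:06d}", icu_in, icu_out, float(age[i]), float(weight[i]),
             "F" if female[i] else "M")
        )

    admissions = pd.DataFrame(
        adm_rows,
        columns=["admission_id", "patient_id", "icu_in", "icu_out", "age_years", "weight_kg", "gender"],
    )
    admissions["first_icu_admission"] = True
    uo = pd.DataFrame(uo_rows, columns=["admission_id", "chart_time", "volume_ml", "source_label"])
    uo["chart_time"] = pd.to_datetime(uo["chart_time"]).dt.floor("min")

    # zero-volume double-charting rows at existing timestamps
    n_zero = int(round(config.zero_record_fraction * len(uo)))
    if n_zero:
        picks = rng.choice(len(uo), size=n_zero, replace=False)
        zeros = uo.iloc[picks].copy()
        zeros["volume_ml"] = 0.0
        uo = pd.concat([uo, zeros], ignore_index=True)
    uo = uo.sort_values(["admission_id", "chart_time"], kind="stable").reset_index(drop=True)

    truth_adm = pd.DataFrame(truth_adm_rows, columns=["admission_id", "true_peak_stage", "at_admission"])
    peak_arr = truth_adm["true_peak_stage"].fillna(0).to_numpy(int)
    p_death = _death_probability(peak_arr, config.baseline_mortality, config.stage_mortality_ors)
    died = rng.random(n) < p_death
    death_days = rng.uniform(0.25, 29.75, n)
    death_time = pd.Series(pd.NaT, index=admissions.index, dtype="datetime64[ns]")
    death_time[died] = (
        admissions.loc[died, "icu_in"] + pd.to_timedelta(death_days[died], unit="D")
    ).dt.floor("min")
    admissions["death_time"] = death_time
    truth_adm["died_30d"] = died

    return SimResult(
        admissions=admissions,
        uo_records=uo,
        truth_hourly=pd.concat(truth_hourly_frames, ignore_index=True),
        truth_admissions=truth_adm,
        params={
            "baseline_mortality": config.baseline_mortality,
            "stage_mortality_ors": dict(config.stage_mortality_ors),
        },
    )


def simulate_outcomes(
    n_patients: int,
    seed: int,
    stage_probs: tuple[float, ...] = (0.52, 0.24, 0.19, 0.05),
    baseline_mortality: float = 0.072,
    stage_ors: dict | None = None,
) -> pd.DataFrame:
    """Cohort-level fast path: true peak stages and 30-day deaths only.

    Draws each patient's peak stage from ``stage_probs`` (defaults shaped
    like a large mixed-ICU population) and death from the same logistic
    mortality model the full generator uses.  Useful for large-n recovery
    checks of the odds-ratio machinery where charting is irrelevant.
    """
    if stage_ors is None:
        stage_ors = {1: 1.75, 2: 3.3, 3: 7.5}
    rng = np.random.default_rng(seed)
    probs = np.asarray(stage_probs, float)
    probs = probs / probs.sum()
    stage = rng.choice(len(probs), size=n_patients, p=probs)
    p = _death_probability(stage, baseline_mortality, stage_ors)
    died = rng.random(n_patients) < p
    return pd.DataFrame({"peak_stage": stage, "died_30d": died})


def inject_artifacts(
    uo: pd.DataFrame,
    admissions: pd.DataFrame,
    seed: int,
    n_bad_volumes: int = 0,
    n_bad_weights: int = 0,
    n_duplicates: int = 0,
    n_exclusion_admissions: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Corrupt clean simulated tables in precisely known ways.

    * ``n_bad_volumes`` extra rows with out-of-range volumes (> 5000 ml);
    * ``n_bad_weights`` admissions get an artifact weight (< 25 or > 300 kg);
    * ``n_duplicates`` existing rows are split into simultaneous pairs (the
      two volumes sum to the original, so merging restores totals exactly);
    * ``n_exclusion_admissions`` admissions receive one "GU Irrigation" row.

    Returns ``(uo', admissions', manifest)``; the manifest records exactly
    what was injected so cleaning can be audited row by row.
    """
    rng = np.random.default_rng(seed)
    uo = uo.copy()
    admissions = admissions.copy()
    manifest: dict = {
        "n_bad_volumes": n_bad_volumes,
        "n_bad_weights": n_bad_weights,
        "n_duplicates": n_duplicates,
        "n_exclusion_admissions": n_exclusion_admissions,
        "bad_weight_admissions": [],
        "exclusion_admissions": [],
    }

    adm_ids = admissions["admission_id"].to_numpy()

    if n_bad_volumes:
        picks = rng.choice(adm_ids, size=n_bad_volumes)
        spans = admissions.set_index("admission_id")
        rows = []
        for a in picks:
            t = spans.loc[a, "icu_in"] + pd.Timedelta(minutes=int(rng.integers(0, 600)))
            rows.append((a, t, round(float(rng.uniform(5001, 9000)), 0), "Foley"))
        uo = pd.concat(
            [uo, pd.DataFrame(rows, columns=["admission_id", "chart_time", "volume_ml", "source_label"])],
            ignore_index=True,
        )

    if n_bad_weights:
        picks = rng.choice(adm_ids, size=n_bad_weights, replace=False)
        bad_w = rng.choice([15.0, 350.0], size=n_bad_weights)
        sel = admissions["admission_id"].isin(picks)
        admissions.loc[sel, "weight_kg"] = admissions.loc[sel, "admission_id"].map(
            dict(zip(picks, bad_w))
        )
        manifest["bad_weight_admissions"] = sorted(picks.tolist())

    if n_duplicates:
        candidates = uo.index[uo["volume_ml"] > 0].to_numpy()
        picks = rng.choice(candidates, size=n_duplicates, replace=False)
        half = uo.loc[picks].copy()
        uo.loc[picks, "volume_ml"] = uo.loc[picks, "volume_ml"] / 2.0
        half["volume_ml"] = half["volume_ml"] - uo.loc[picks, "volume_ml"].to_numpy()
        uo = pd.concat([uo, half], ignore_index=True)

    if n_exclusion_admissions:
        pool = np.setdiff1d(adm_ids, np.array(manifest["bad_weight_admissions"], dtype=object))
        picks = rng.choice(pool, size=n_exclusion_admissions, replace=False)
        spans = admissions.set_index("admission_id")
        rows = [
            (a, spans.loc[a, "icu_in"] + pd.Timedelta(minutes=30), 100.0, "GU Irrigation")
            for a in picks
        ]
        uo = pd.concat(
            [uo, pd.DataFrame(rows, columns=["admission_id", "chart_time", "volume_ml", "source_label"])],
            ignore_index=True,
        )
        manifest["exclusion_admissions"] = sorted(picks.tolist())

    uo["chart_time"] = pd.to_datetime(uo["chart_time"]).dt.floor("min")
    uo = uo.sort_values(["admission_id", "chart_time"], kind="stable").reset_index(drop=True)
    return uo, admissions, manifest
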