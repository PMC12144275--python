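"""KDIGO urine-output staging on hourly-adjusted series.

The KDIGO guideline stages oliguric AKI from urine output per kg body weight
over trailing 6, 12 and 24-hour windows: stage 1 below 0.5 ml/kg/hr for
6-12 h, stage 2 below 0.5 for >= 12 h, stage 3 below 0.3 for >= 24 h or
anuria for >= 12 h.  Two customary readings of "UO below threshold over a
window" exist:

``mean``
    the *running average* over the window is below threshold (UO\\ :sup:`mean`);
``cons``
    *every consecutive hour* is below threshold, i.e. the window maximum is
    below threshold (UO\\ :sup:`cons`).

Since a window whose every hour is below threshold also has its mean below
threshold, the consecutive reading can never stage higher than the mean
reading at the same hour.

A stage is computed at hour t only from complete data: the trailing window
must consist entirely of valid, consecutive hourly-adjusted values.  The
first stage of an admission therefore appears no earlier than the sixth
hour.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "KdigoThresholds",
    "stage_series",
    "stage_both",
    "eligibility",
    "peak_stage",
    "scr_delta",
]


@dataclasses.dataclass(frozen=True)
class KdigoThresholds:
    """KDIGO-UO window lengths (hours) and per-kg rate thresholds (ml/kg/hr)."""

    w1_hours: int = 6
    w2_hours: int = 12
    w3_hours: int = 24
    anuria_hours: int = 12
    t_stage12: float = 0.5
    t_stage3: float = 0.3

    def __post_init__(self) -> None:
        if not (self.w1_hours < self.w2_hours < self.w3_hours):
            raise ValueError("window lengths must satisfy w1 < w2 < w3")
        if not (self.t_stage3 < self.t_stage12):
            raise ValueError("stage-3 threshold must be below the stage-1/2 threshold")


def _complete_grid(sub: pd.DataFrame) -> pd.DataFrame:
    hours = pd.date_range(sub["hour_start"].min(), sub["hour_start"].max(), freq="h")
    g = sub.set_index("hour_start").reindex(hours)
    g.index.name = "hour_start"
    return g


def _stage_one_admission(
    g: pd.DataFrame, thresholds: KdigoThresholds, interpretation: str
) -> pd.DataFrame:
    th = thresholds
    v = g["uo_ml_per_kg"].to_numpy(float)
    ok = g["valid"].astype("boolean").fillna(False).to_numpy(bool) & ~np.isnan(v)
    vv = pd.Series(np.where(ok, v, np.nan))
    oks = pd.Series(ok.astype(int))

    def window(w):
        computable = oks.rolling(w).sum().to_numpy() == w
        if interpretation == "mean":
            stat = vv.rolling(w).mean().to_numpy()
        else:
            stat = vv.rolling(w).max().to_numpy()
        return computable, stat

    c1, s1 = window(th.w1_hours)
    c2, s2 = window(th.w2_hours)
    c3, s3 = window(th.w3_hours)
    # anuria: every hour of the trailing window exactly zero (max == 0 works
    # for both interpretations and avoids mean round-off)
    ca = oks.rolling(th.anuria_hours).sum().to_numpy() == th.anuria_hours
    sa = vv.rolling(th.anuria_hours).max().to_numpy()

    with np.errstate(invalid="ignore"):
        stage3 = (c3 & (s3 < th.t_stage3)) | (ca & (sa == 0.0))
        stage2 = c2 & (s2 < th.t_stage12)
        stage1 = c1 & (s1 < th.t_stage12)

    stage = np.zeros(len(g), dtype=float)
    stage[stage1] = 1
    stage[stage2] = 2
    stage[stage3] = 3
    stage[~c1] = np.nan  # not computable without the 6-h window

    return pd.DataFrame(
        {
            "hour_start": g.index,
            "stage": pd.array(stage, dtype="Int64"),
            "computable_6": c1,
            "computable_12": c2,
            "computable_24": c3,
        }
    )


def stage_series(
    hourly: pd.DataFrame,
    thresholds: KdigoThresholds | None = None,
    interpretation: str = "cons",
) -> pd.DataFrame:
    """Hourly KDIGO-UO stages for one or more admissions.

    Parameters
    ----------
    hourly : frame with admission_id, hour_start, uo_ml_per_kg, valid
        (from :func:`uokit.hourly.per_kg`).
    thresholds : KDIGO windows and thresholds; guideline defaults.
    interpretation : ``"mean"`` (running average) or ``"cons"``
        (window maximum, every-hour-below-threshold).

    Returns
    -------
    One row per admission per grid hour between the admission's first and
    last charted hour: admission_id, hour_start, stage (nullable integer;
    NA where the 6-h window is not computable), computable_6/12/24.
    """
    if interpretation not in ("mean", "cons"):
        raise ValueError(f"unknown interpretation {interpretation!r}")
    if thresholds is None:
        thresholds = KdigoThresholds()
    frames = []
    for adm, sub in hourly.groupby("admission_id", sort=True):
        g = _complete_grid(sub)
        out = _stage_one_admission(g, thresholds, interpretation)
        out.insert(0, "admission_id", adm)
        frames.append(out)
    if not frames:
        return pd.DataFrame(
            columns=["admission_id", "hour_start", "stage", "computable_6", "computable_12", "computable_24"]
        )
    return pd.concat(frames, ignore_index=True)


def stage_both(hourly: pd.DataFrame, thresholds: KdigoThresholds | None = None) -> pd.DataFrame:
    """Both interpretations side by side: columns stage_mean and stage_cons."""
    m = stage_series(hourly, thresholds, "mean").rename(columns={"stage": "stage_mean"})
    c = stage_series(hourly, thresholds, "cons").rename(columns={"stage": "stage_cons"})
    return m.merge(
        c[["admission_id", "hour_start", "stage_cons"]], on=["admission_id", "hour_start"]
    )


def eligibility(
    admission: pd.Series,
    hourly: pd.DataFrame,
    min_consecutive_hours: int = 6,
    require_first_admission: bool = True,
) -> tuple[bool, list[str]]:
    """Can KDIGO-UO staging be attempted for this admission?

    Requires a known, plausible admission weight, at least
    ``min_consecutive_hours`` consecutive valid hourly-adjusted values, and
    (for the AKI analysis) that this is the patient's first ICU admission.
    Returns (eligible, reasons) where reasons lists every failed requirement.
    """
    reasons: list[str] = []
    w = admission.get("weight_kg")
    if w is None or (isinstance(w, float) and np.isnan(w)):
        reasons.append("missing_weight")
    if len(hourly) == 0:
        reasons.append("no_hourly_uo")
    else:
        g = _complete_grid(hourly)
        ok = g["valid"].astype("boolean").fillna(False).to_numpy(bool)
        run = pd.Series(ok.astype(int))
        best = int(run.groupby((run == 0).cumsum()).cumsum().max())
        if best < min_consecutive_hours:
            reasons.append(f"no_{min_consecutive_hours}_consecutive_valid_hours")
    if require_first_admission and not bool(admission.get("first_icu_admission", True)):
        reasons.append("not_first_icu_admission")
    return (len(reasons) == 0), reasons


def peak_stage(
    staging: pd.DataFrame,
    anchor: pd.Timestamp,
    horizon_hours: int = 72,
) -> dict:
    """Maximal stage over the first ``horizon_hours`` after ``anchor``.

    ``anchor`` is the time of the admission's first UO record.  Returns
    ``{"peak": int | None, "at_admission": bool}``; ``at_admission`` flags a
    stage >= 1 at the earliest computable hour (diagnosis already present
    when staging first becomes possible).  ``peak`` is None when no hour in
    the horizon is computable.
    """
    horizon = pd.Timestamp(anchor) + pd.Timedelta(hours=horizon_hours)
    sub = staging.loc[(staging["hour_start"] < horizon) & staging["stage"].notna()]
    if len(sub) == 0:
        return {"peak": None, "at_admission": False}
    first = sub.loc[sub["hour_start"].idxmin(), "stage"]
    return {"peak": int(sub["stage"].max()), "at_admission": bool(first >= 1)}


def scr_delta(scr: pd.DataFrame, window_days: float = 7.0) -> pd.DataFrame:
    """Change in serum creatinine from its recent minimum.

    For each measurement the baseline is the lowest value in the preceding
    ``window_days`` (the measurement itself included, so a fresh minimum has
    zero absolute change).  Points with no *prior* measurement in the window
    get a missing baseline.

    Parameters
    ----------
    scr : frame with columns ``time`` and ``value`` (mg/dL), any order.

    Returns
    -------
    Input sorted by time with baseline, absolute_change (mg/dL) and
    relative_change (ratio) columns appended.
    """
    out = scr.sort_values("time", kind="stable").reset_index(drop=True).copy()
    t = out["time"].to_numpy()
    v = out["value"].to_numpy(float)
    win = pd.Timedelta(days=window_days).to_numpy()
    baseline = np.full(len(out), np.nan)
    for i in range(len(out)):
        in_win = (t > t[i] - win) & (t <= t[i])
        in_win[i + 1:] = False
        if in_win[:i].any():  # needs at least one prior point
            baseline[i] = v[in_win].min()
    out["baseline"] = baseline
    out["absolute_change"] = v - baseline
    with np.errstate(divide="ignore", invalid="ignore"):
        out["relative_change"] = v / baseline
    return out
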