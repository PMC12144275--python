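"""Collection intervals and urine-output rates.

Charted UO volumes have no recorded collection duration; the duration is
reconstructed as the time since the previous record *in the same anatomical
compartment*.  The first record per (admission, compartment) accumulated
before monitoring began (residual volume) and contributes no rate — it only
anchors the first interval.  Each subsequent record r with predecessor p
yields the half-open interval (p.time, r.time] carrying r's volume at rate
volume / duration.  Implausibly long gaps (default > 24 h) are dropped as
outliers rather than converted into a near-zero rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["merge_simultaneous", "build_intervals", "duration_summary"]

INTERVAL_COLUMNS = [
    "admission_id",
    "compartment",
    "start_time",
    "end_time",
    "volume_ml",
    "duration_hr",
    "rate_ml_hr",
]


def merge_simultaneous(records: pd.DataFrame) -> pd.DataFrame:
    """Merge records sharing (admission, compartment, chart_time).

    Simultaneous rows in one compartment are double-charting of a single
    collection event; their volumes are summed into one record.  Rows in
    different compartments at the same time are genuinely concurrent and are
    left untouched.  Output is sorted by (admission, compartment, time).
    """
    keys = ["admission_id", "compartment", "chart_time"]
    agg = {"volume_ml": "sum"}
    if "source_label" in records.columns:
        agg["source_label"] = "first"
    merged = records.groupby(keys, as_index=False, sort=True).agg(agg)
    return merged.sort_values(keys, kind="stable").reset_index(drop=True)


def build_intervals(
    records: pd.DataFrame,
    max_duration_hr: float = 24.0,
    admissions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Convert per-compartment records to rate intervals.

    Parameters
    ----------
    records : canonical UO frame with a ``compartment`` column, simultaneous
        entries already merged.
    max_duration_hr : drop intervals longer than this (collection gaps this
        long are charting lapses, not collections).
    admissions : optional; when given, records timestamped outside
        [icu_in, icu_out] are dropped first.

    Returns
    -------
    (intervals, report)
        ``intervals`` has one row per interval: admission_id, compartment,
        start_time, end_time, volume_ml, duration_hr, rate_ml_hr (plus
        source_label when present).  ``report`` counts residual anchors,
        duration outliers and out-of-stay records.
    """
    rec = records
    n_outside = 0
    if admissions is not None:
        spans = admissions.set_index("admission_id")[["icu_in", "icu_out"]]
        icu_in = rec["admission_id"].map(spans["icu_in"])
        icu_out = rec["admission_id"].map(spans["icu_out"])
        inside = (rec["chart_time"] >= icu_in) & (rec["chart_time"] <= icu_out)
        n_outside = int((~inside).sum())
        rec = rec.loc[inside]

    keys = ["admission_id", "compartment"]
    rec = rec.sort_values(keys + ["chart_time"], kind="stable")
    grp = rec.groupby(keys, sort=False)
    prev_time = grp["chart_time"].shift(1)
    is_residual = prev_time.isna()

    duration_hr = (rec["chart_time"] - prev_time) / pd.Timedelta(hours=1)
    if not is_residual.all() and (duration_hr.dropna() <= 0).any():
        raise RuntimeError("non-positive interval duration; merge_simultaneous not applied?")

    too_long = duration_hr > max_duration_hr
    keep = ~is_residual & ~too_long

    intervals = pd.DataFrame(
        {
            "admission_id": rec.loc[keep, "admission_id"].to_numpy(),
            "compartment": rec.loc[keep, "compartment"].to_numpy(),
            "start_time": prev_time.loc[keep].to_numpy(),
            "end_time": rec.loc[keep, "chart_time"].to_numpy(),
            "volume_ml": rec.loc[keep, "volume_ml"].to_numpy(),
            "duration_hr": duration_hr.loc[keep].to_numpy(),
        }
    )
    intervals["rate_ml_hr"] = intervals["volume_ml"] / intervals["duration_hr"]
    if "source_label" in rec.columns:
        intervals["source_label"] = rec.loc[keep, "source_label"].to_numpy()

    report = {
        "records_in": int(len(records)),
        "outside_icu_stay": n_outside,
        "residual_dropped": int(is_residual.sum()),
        "residual_volume_ml": float(rec.loc[is_residual, "volume_ml"].sum()),
        "duration_outliers": int(too_long.sum()),
        "outlier_volume_ml": float(rec.loc[too_long.fillna(False), "volume_ml"].sum()),
        "intervals_out": int(len(intervals)),
    }
    return intervals.reset_index(drop=True), report


def duration_summary(intervals: pd.DataFrame, by: str = "compartment") -> pd.DataFrame:
    """Per-group collection-duration statistics and duration-weighted mean rate.

    The weighted mean rate weights each interval's rate by its collection
    duration, which reduces algebraically to total volume over total
    duration.  The mode is computed on durations rounded to whole minutes.

    Parameters
    ----------
    by : "compartment" or "source_label"
    """
    if by not in intervals.columns:
        raise KeyError(f"grouping column {by!r} not present on intervals")
    rows = []
    for group, sub in intervals.groupby(by, sort=True):
        if len(sub) == 0:
            rows.append({by: group, "n": 0})
            continue
        minutes = (sub["duration_hr"] * 60).round().astype(int)
        rows.append(
            {
                by: group,
                "n": int(len(sub)),
                "mean_duration_min": float(minutes.mean()),
                "sd_duration_min": float(minutes.std(ddof=1)) if len(sub) > 1 else np.nan,
                "median_duration_min": float(minutes.median()),
                "mode_duration_min": float(minutes.mode().iloc[0]),
                "weighted_mean_rate_ml_hr": float(
                    sub["volume_ml"].sum() / sub["duration_hr"].sum()
                ),
            }
        )
    return pd.DataFrame(rows)
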