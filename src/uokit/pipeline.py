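"""End-to-end orchestration: charting tables in, staged cohort out.

Mirrors the study workflow: source-map exclusions -> artifact cleaning ->
simultaneous-entry merge -> per-compartment rate intervals (residuals
dropped, duration outliers removed) -> hourly-adjusted UO with coverage
validity -> per-kg normalization -> KDIGO-UO staging under both
interpretations -> per-admission peak stage over the first days -> analysis
cohort.  The returned manifest records the row counts at every step, so
included + each exclusion reason always reconstructs the input.
"""

from __future__ import annotations

import pandas as pd

from . import charting, cohort as cohort_mod, hourly as hourly_mod, rates, staging as staging_mod

__all__ = ["run_pipeline", "peak_stages"]


def peak_stages(
    staged: pd.DataFrame, anchors: pd.Series, horizon_hours: int = 72
) -> pd.DataFrame:
    """Per-admission peak stage and at-admission flag from an hourly staging frame.

    ``staged`` needs admission_id, hour_start and a ``stage`` column;
    ``anchors`` maps admission_id to the time of its first UO record.
    Admissions with no computable hour inside the horizon get a missing peak.
    """
    df = staged.copy()
    df["anchor"] = df["admission_id"].map(anchors)
    df = df.loc[
        df["stage"].notna()
        & (df["hour_start"] < df["anchor"] + pd.to_timedelta(horizon_hours, unit="h"))
    ]
    if len(df) == 0:
        return pd.DataFrame(columns=["admission_id", "peak", "at_admission"])
    df = df.sort_values(["admission_id", "hour_start"], kind="stable")
    grp = df.groupby("admission_id", sort=True)
    out = grp.agg(peak=("stage", "max"), first_stage=("stage", "first")).reset_index()
    out["at_admission"] = out["first_stage"] >= 1
    return out[["admission_id", "peak", "at_admission"]]


def run_pipeline(
    uo_records: pd.DataFrame,
    admissions: pd.DataFrame,
    source_map: charting.SourceMap | None = None,
    max_duration_hr: float = 24.0,
    coverage_threshold: float = 0.5,
    thresholds: staging_mod.KdigoThresholds | None = None,
    horizon_hours: int = 72,
    interpretation: str = "cons",
    unknown_labels: str = "fail",
    restrict_to_stay: bool = True,
) -> dict:
    """Run the full standardization + staging + cohort workflow.

    Parameters mirror the study's knobs: the source map, the maximum
    plausible collection duration, the most-of-the-hour coverage threshold,
    the KDIGO windows/thresholds, the peak-stage horizon and the KDIGO-UO
    interpretation used for the analysis cohort (``"cons"`` by default,
    ``"mean"`` for the running-average reading).

    Returns a dict of artifacts: kept records, intervals, hourly frame,
    staging frame (both interpretations), per-admission peaks, eligibility,
    cohort, and a manifest of row counts per step.
    """
    kept, excluded_admissions = charting.apply_source_map(uo_records, source_map, unknown_labels)
    adm = admissions.loc[~admissions["admission_id"].isin(excluded_admissions)].reset_index(drop=True)

    kept, adm, clean_report = charting.clean_records(kept, adm)
    merged = rates.merge_simultaneous(kept)
    intervals, interval_report = rates.build_intervals(
        merged, max_duration_hr, admissions=adm if restrict_to_stay else None
    )

    hourly = hourly_mod.compute_hourly(intervals, coverage_threshold=coverage_threshold)
    weights = adm.set_index("admission_id")["weight_kg"]
    hourly = hourly_mod.per_kg(hourly, weights)

    staged = staging_mod.stage_both(hourly, thresholds)
    stage_col = "stage_cons" if interpretation == "cons" else "stage_mean"

    anchors = merged.groupby("admission_id")["chart_time"].min()
    peaks = peak_stages(
        staged.rename(columns={stage_col: "stage"}), anchors, horizon_hours
    )

    # eligibility: weight known and >= 6 consecutive valid hours (computable_6
    # is true exactly when the trailing 6 hours are all valid)
    has_window = staged.groupby("admission_id")["computable_6"].any()
    adm_idx = adm.set_index("admission_id")
    elig = pd.DataFrame(
        {
            "admission_id": adm["admission_id"],
            "has_weight": adm["weight_kg"].notna().to_numpy(),
            "has_6h_window": adm["admission_id"]
            .map(has_window)
            .astype("boolean")
            .fillna(False)
            .to_numpy(bool),
            "first_icu_admission": adm["first_icu_admission"].astype(bool).to_numpy(),
        }
    )
    elig["eligible"] = elig["has_weight"] & elig["has_6h_window"] & elig["first_icu_admission"]

    staging_results = peaks.loc[
        peaks["admission_id"].isin(set(elig.loc[elig["eligible"], "admission_id"]))
    ]
    cohort, cohort_report = cohort_mod.build_cohort(adm, staging_results)

    manifest = {
        "records_in": int(len(uo_records)),
        "admissions_in": int(len(admissions)),
        "excluded_admissions_by_source": int(len(excluded_admissions)),
        **{f"clean_{k}": v for k, v in clean_report.items()},
        **{f"intervals_{k}": v for k, v in interval_report.items()},
        "hourly_rows": int(len(hourly)),
        "valid_hours": int(hourly["valid"].sum()) if len(hourly) else 0,
        "eligible_admissions": int(elig["eligible"].sum()),
        **{f"cohort_{k}": v for k, v in cohort_report.items()},
    }
    return {
        "records": merged,
        "excluded_admissions": excluded_admissions,
        "admissions": adm,
        "intervals": intervals,
        "hourly": hourly,
        "staging": staged,
        "peaks": peaks,
        "eligibility": elig,
        "cohort": cohort,
        "manifest": manifest,
    }
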