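"""Cohort-level analysis: stratified summaries, odds ratios and 30-day survival.

Admissions are stratified by their peak KDIGO-UO stage over the first days
in the ICU.  Mortality contrasts use unadjusted odds ratios from 2x2 tables
(Woolf log-OR confidence intervals) and adjusted *marginal* odds ratios from
a logistic model with stage-by-covariate interactions, marginalized by
g-computation: predict everyone at stage s, average the probabilities, and
express the contrast to stage 0 as an odds ratio.  Survival uses
Kaplan-Meier curves censored at 30 days with pairwise log-rank tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "build_cohort",
    "two_by_two_tables",
    "unadjusted_or",
    "adjusted_or_marginal",
    "km_logrank",
    "stratified_summary",
]

FOLLOWUP_DAYS = 30.0


@dataclasses.dataclass(frozen=True)
class TwoByTwo:
    """Admission counts and 30-day deaths in an exposed arm vs a reference arm."""

    n_exposed: int
    d_exposed: int
    n_ref: int
    d_ref: int

    def __post_init__(self) -> None:
        if min(self.n_exposed, self.d_exposed, self.n_ref, self.d_ref) < 0:
            raise ValueError("counts must be non-negative")
        if self.d_exposed > self.n_exposed or self.d_ref > self.n_ref:
            raise ValueError("deaths cannot exceed admissions")


def build_cohort(
    admissions: pd.DataFrame,
    staging_results: pd.DataFrame,
    followup_days: float = FOLLOWUP_DAYS,
) -> tuple[pd.DataFrame, dict]:
    """One analysis row per eligible first ICU admission.

    Parameters
    ----------
    admissions : canonical admissions frame.
    staging_results : per-admission frame with columns admission_id, peak
        (nullable int) and at_admission, e.g. aggregated from
        :func:`uokit.staging.peak_stage`.

    Returns
    -------
    (cohort, report): cohort columns are admission_id, peak_stage,
    at_admission, age_years, weight_kg, gender, died_30d, followup_days.
    Admissions with an undefined peak are excluded and counted in the
    report, as are repeat ICU admissions.
    """
    merged = admissions.merge(staging_results, on="admission_id", how="inner")
    n_in = len(merged)
    not_first = ~merged["first_icu_admission"].astype(bool)
    no_peak = merged["peak"].isna()
    keep = ~not_first & ~no_peak
    sub = merged.loc[keep].copy()

    dt_days = (sub["death_time"] - sub["icu_in"]) / pd.Timedelta(days=1)
    died = dt_days.notna() & (dt_days <= followup_days)
    followup = np.where(died, dt_days, followup_days)
    # survivors whose ICU record ends before the horizon are still followed to
    # 30 days here; hospital-mortality-only sources should censor at discharge
    cohort = pd.DataFrame(
        {
            "admission_id": sub["admission_id"],
            "peak_stage": sub["peak"].astype(int),
            "at_admission": sub["at_admission"].astype(bool),
            "age_years": sub["age_years"].astype(float),
            "weight_kg": sub["weight_kg"].astype(float),
            "gender": sub["gender"],
            "died_30d": died.to_numpy(),
            "followup_days": np.minimum(followup, followup_days),
        }
    ).reset_index(drop=True)
    report = {
        "admissions_in": int(n_in),
        "excluded_not_first_admission": int(not_first.sum()),
        "excluded_undefined_peak": int((no_peak & ~not_first).sum()),
        "cohort_rows": int(len(cohort)),
    }
    return cohort, report


def two_by_two_tables(cohort: pd.DataFrame, ref_stage: int = 0) -> dict[int, TwoByTwo]:
    """Per-stage 2x2 mortality tables against the no-AKI reference arm."""
    grp = cohort.groupby("peak_stage")["died_30d"].agg(["size", "sum"])
    if ref_stage not in grp.index:
        raise ValueError(f"reference stage {ref_stage} absent from cohort")
    n_ref, d_ref = int(grp.loc[ref_stage, "size"]), int(grp.loc[ref_stage, "sum"])
    return {
        int(s): TwoByTwo(int(row["size"]), int(row["sum"]), n_ref, d_ref)
        for s, row in grp.iterrows()
        if s != ref_stage
    }


def unadjusted_or(t: TwoByTwo, alpha: float = 0.05) -> dict:
    """Odds ratio with a Woolf (log-OR normal) confidence interval.

    OR = [d_e/(n_e-d_e)] / [d_r/(n_r-d_r)].  No continuity correction: any
    zero cell makes the OR or its CI undefined (returned as NaN).
    """
    a, b = t.d_exposed, t.n_exposed - t.d_exposed
    c, d = t.d_ref, t.n_ref - t.d_ref
    if b == 0 or c == 0:
        return {"or": np.nan, "ci_low": np.nan, "ci_high": np.nan}
    or_ = (a / b) / (c / d)
    if min(a, b, c, d) == 0:
        return {"or": or_, "ci_low": np.nan, "ci_high": np.nan}
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "or": or_,
        "ci_low": float(np.exp(np.log(or_) - z * se)),
        "ci_high": float(np.exp(np.log(or_) + z * se)),
    }


def _fit_logit(df: pd.DataFrame):
    import statsmodels.formula.api as smf

    formula = (
        "died ~ C(peak_stage) * (age_years + weight_kg + C(gender) + at_admission)"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.logit(formula, data=df)
        res = model.fit(disp=0, maxiter=200, method="newton")
    return res


def _marginal_ors(res, df: pd.DataFrame, stages: list[int], ref_stage: int) -> dict[int, float]:
    base = df.copy()
    base["peak_stage"] = ref_stage
    p_ref = float(res.predict(base).mean())
    odds_ref = p_ref / (1 - p_ref)
    out = {}
    for s in stages:
        cf = df.copy()
        cf["peak_stage"] = s
        p = float(res.predict(cf).mean())
        out[s] = (p / (1 - p)) / odds_ref
    return out


def adjusted_or_marginal(
    cohort: pd.DataFrame,
    ref_stage: int = 0,
    n_boot: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Adjusted marginal odds ratios per stage, by g-computation.

    Fits one logistic model of 30-day death on stage (categorical), age,
    weight, gender and diagnosis-at-admission, with stage-by-covariate
    interactions.  For each stage s the marginal OR contrasts the odds of the
    cohort-average predicted probability with everyone set to stage s versus
    everyone set to the reference stage.  Confidence intervals come from a
    nonparametric bootstrap over admissions (percentile method).

    Rows with missing covariates are dropped (and counted in the returned
    frame's ``attrs["n_dropped"]``).  A stage for which the model cannot be
    fit in a resample is simply absent from that resample's draw.
    """
    cols = ["peak_stage", "age_years", "weight_kg", "gender", "at_admission", "died_30d"]
    df = cohort[cols].dropna().copy()
    n_dropped = len(cohort) - len(df)
    df["died"] = df["died_30d"].astype(int)
    stages = sorted(int(s) for s in df["peak_stage"].unique() if int(s) != ref_stage)

    res = _fit_logit(df)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic model did not converge on the full cohort")
    point = _marginal_ors(res, df, stages, ref_stage)

    rng = np.random.default_rng(seed)
    draws: dict[int, list[float]] = {s: [] for s in stages}
    for _ in range(n_boot):
        boot = df.sample(n=len(df), replace=True, random_state=int(rng.integers(2**31)))
        if boot["peak_stage"].nunique() < len(stages) + 1:
            continue
        try:
            r = _fit_logit(boot)
        except Exception:
            continue
        for s, v in _marginal_ors(r, boot, stages, ref_stage).items():
            draws[s].append(v)

    rows = []
    for s in stages:
        d = np.asarray(draws[s])
        lo, hi = (
            (np.nan, np.nan)
            if len(d) < 10
            else tuple(np.quantile(d, [alpha / 2, 1 - alpha / 2]))
        )
        rows.append(
            {"stage": s, "or": point[s], "ci_low": lo, "ci_high": hi, "n_boot_ok": len(d)}
        )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped
    return out


def km_logrank(cohort: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per peak stage plus pairwise log-rank tests.

    Returns ``{"curves": {stage: survival DataFrame}, "pairwise": DataFrame
    with stage_a, stage_b, test_statistic, p_value, "fitters": ...}``.
    Stages with zero subjects are omitted with a warning.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    curves: dict[int, pd.DataFrame] = {}
    fitters: dict[int, object] = {}
    groups = {int(s): sub for s, sub in cohort.groupby("peak_stage") if len(sub)}
    for s, sub in groups.items():
        kmf = KaplanMeierFitter(label=f"stage {s}")
        kmf.fit(sub["followup_days"], event_observed=sub["died_30d"].astype(int))
        fitters[s] = kmf
        curves[s] = kmf.survival_function_

    rows = []
    keys = sorted(groups)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            ga, gb = groups[a], groups[b]
            r = logrank_test(
                ga["followup_days"], gb["followup_days"],
                event_observed_A=ga["died_30d"].astype(int),
                event_observed_B=gb["died_30d"].astype(int),
            )
            rows.append(
                {"stage_a": a, "stage_b": b, "test_statistic": r.test_statistic, "p_value": r.p_value}
            )
    return {"curves": curves, "fitters": fitters, "pairwise": pd.DataFrame(rows)}


def plot_km(km: dict, path) -> None:
    """Write a 30-day survival plot (one curve per stage) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in sorted(km["fitters"]):
        km["fitters"][s].plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("days since ICU admission")
    ax.set_ylabel("30-day survival")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stratified_summary(
    cohort: pd.DataFrame,
    columns: dict[str, str],
    by: str = "peak_stage",
) -> pd.DataFrame:
    """Per-stage descriptive table with between-group tests.

    ``columns`` maps column name -> kind: ``"normal"`` (mean (SD), ANOVA),
    ``"skewed"`` (median (Q1, Q3), Kruskal-Wallis) or ``"categorical"``
    (n (%), chi-square; Fisher exact for 2x2 tables with an expected cell
    below 5).
    """
    groups = [sub for _, sub in cohort.groupby(by, sort=True)]
    labels = sorted(cohort[by].unique())
    rows = [{"characteristic": "n", **{str(l): len(g) for l, g in zip(labels, groups)}, "p_value": np.nan}]
    for col, kind in columns.items():
        row: dict = {"characteristic": col}
        if kind in ("normal", "skewed"):
            vals = [g[col].dropna().to_numpy(float) for g in groups]
            for l, v in zip(labels, vals):
                if kind == "normal":
                    row[str(l)] = f"{np.mean(v):.2f} ({np.std(v, ddof=1):.2f})" if len(v) > 1 else "-"
                else:
                    q1, med, q3 = np.percentile(v, [25, 50, 75]) if len(v) else (np.nan,) * 3
                    row[str(l)] = f"{med:.2f} ({q1:.2f}, {q3:.2f})" if len(v) else "-"
            usable = [v for v in vals if len(v) > 1]
            if len(usable) >= 2:
                if kind == "normal":
                    stat, p = stats.f_oneway(*usable)
                    p = 1.0 if np.isnan(p) else p  # identical groups: zero between-group variance
                else:
                    try:
                        stat, p = stats.kruskal(*usable)
                    except ValueError:  # all values identical
                        p = 1.0
                row["p_value"] = float(p)
        elif kind == "categorical":
            tab = pd.crosstab(cohort[col], cohort[by])
            for l in labels:
                counts = tab[l] if l in tab.columns else None
                if counts is None:
                    row[str(l)] = "-"
                else:
                    total = counts.sum()
                    row[str(l)] = "; ".join(
                        f"{idx}: {c} ({100 * c / total:.0f}%)" for idx, c in counts.items()
                    )
            if tab.shape[0] >= 2 and tab.shape[1] >= 2:
                chi2, p, _, expected = stats.chi2_contingency(tab)
                if tab.shape == (2, 2) and (expected < 5).any():
                    _, p = stats.fisher_exact(tab)
                row["p_value"] = float(p)
        else:
            raise ValueError(f"unknown column kind {kind!r} for {col!r}")
        rows.append(row)
    return pd.DataFrame(rows)
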