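"""Cohort construction, odds ratios, survival and stratified summaries."""

import numpy as np
import pandas as pd
import pytest

from uokit import (
    TwoByTwo,
    adjusted_or_marginal,
    build_cohort,
    km_logrank,
    stratified_summary,
    two_by_two_tables,
    unadjusted_or,
)

from conftest import make_admissions


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestBuildCohort:
    def staging_results(self, ids, peak=1, at_adm=False):
        return pd.DataFrame(
            {"admission_id": ids, "peak": peak, "at_admission": at_adm}
        )

    def test_only_first_admission_kept(self):
        adm = make_admissions(
            [
                ("a1", "p1", "2020-01-01", "2020-01-05", 60, 80, "F", None, True),
                ("a2", "p1", "2020-02-01", "2020-02-05", 60, 80, "F", None, False),
            ]
        )
        cohort, report = build_cohort(adm, self.staging_results(["a1", "a2"]))
        assert cohort["admission_id"].tolist() == ["a1"]
        assert report["excluded_not_first_admission"] == 1

    def test_death_day_boundaries(self):
        adm = make_admissions(
            [
                ("a1", "p1", "2020-01-01", "2020-01-05", 60, 80, "F", "2020-02-01", True),  # day 31
                ("a2", "p2", "2020-01-01", "2020-01-05", 60, 80, "M", "2020-01-11", True),  # day 10
            ]
        )
        cohort, _ = build_cohort(adm, self.staging_results(["a1", "a2"]))
        row1 = cohort.set_index("admission_id").loc["a1"]
        row2 = cohort.set_index("admission_id").loc["a2"]
        assert not row1["died_30d"] and row1["followup_days"] == 30.0
        assert row2["died_30d"] and row2["followup_days"] == pytest.approx(10.0)

    def test_undefined_peak_excluded_and_counted(self):
        adm = make_admissions([("a1", "p1", "2020-01-01", "2020-01-05", 60, 80, "F", None, True)])
        sr = pd.DataFrame({"admission_id": ["a1"], "peak": [pd.NA], "at_admission": [False]})
        cohort, report = build_cohort(adm, sr)
        assert len(cohort) == 0 and report["excluded_undefined_peak"] == 1


class TestUnadjustedOr:
    # printed per-stage admission/death counts from the two source cohorts
    @pytest.mark.parametrize(
        "n_e,d_e,n_r,d_r,expected",
        [
            (11262, 1336, 23972, 1715, 1.75),
            (8991, 1826, 23972, 1715, 3.31),
            (2119, 775, 23972, 1715, 7.48),
            (2456, 384, 10235, 605, 2.95),
            (1589, 428, 10235, 605, 5.87),
            (643, 312, 10235, 605, 15.0),
        ],
    )
    def test_reproduces_published_cohort_ors(self, n_e, d_e, n_r, d_r, expected):
        out = unadjusted_or(TwoByTwo(n_e, d_e, n_r, d_r))
        assert round(out["or"], 2) == pytest.approx(expected, abs=0.005) or round(
            out["or"], 1
        ) == expected

    def test_equal_proportions_give_or_one(self):
        out = unadjusted_or(TwoByTwo(1000, 100, 500, 50))
        assert out["or"] == pytest.approx(1.0)
        assert out["ci_low"] < 1.0 < out["ci_high"]

    def test_scaling_both_arms_leaves_or_unchanged(self):
        a = unadjusted_or(TwoByTwo(200, 30, 400, 20))
        b = unadjusted_or(TwoByTwo(600, 90, 1200, 60))
        assert a["or"] == pytest.approx(b["or"])

    def test_zero_cell_reported_as_undefined(self):
        out = unadjusted_or(TwoByTwo(10, 0, 10, 5))
        assert np.isnan(out["ci_low"])

    def test_ci_is_woolf_log_normal(self):
        t = TwoByTwo(100, 20, 100, 10)
        out = unadjusted_or(t)
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        assert out["ci_high"] == pytest.approx(out["or"] * np.exp(1.959963985 * se))

    def test_two_by_two_tables_from_cohort(self):
        cohort = pd.DataFrame(
            {
                "peak_stage": [0] * 10 + [1] * 6 + [2] * 4,
                "died_30d": [True] * 2 + [False] * 8 + [True] * 3 + [False] * 3 + [True] * 2 + [False] * 2,
            }
        )
        tabs = two_by_two_tables(cohort)
        assert tabs[1] == TwoByTwo(6, 3, 10, 2)
        assert tabs[2] == TwoByTwo(4, 2, 10, 2)


def simulate_adjusted_cohort(n, rng, stage_effects=(0.6, 1.2, 2.0), confounding=True):
    """Known logistic model with optional confounding of stage by weight."""
    weight = rng.normal(80, 15, n)
    age = rng.normal(65, 12, n)
    female = rng.random(n) < 0.45
    if confounding:
        p_stage = np.stack(
            [np.full(n, 3.0), 1 + (weight - 80) / 20, np.full(n, 0.8), np.full(n, 0.4)]
        ).T
        p_stage = np.clip(p_stage, 0.05, None)
        p_stage = p_stage / p_stage.sum(1, keepdims=True)
        stage = np.array([rng.choice(4, p=p) for p in p_stage])
    else:
        stage = rng.choice(4, size=n, p=[0.5, 0.25, 0.18, 0.07])
    eta = (
        -2.8
        + np.where(stage > 0, np.array((0,) + tuple(stage_effects))[stage], 0.0)
        + 0.01 * (age - 65)
        + 0.005 * (weight - 80)
    )
    died = rng.random(n) < _expit(eta)
    return pd.DataFrame(
        {
            "peak_stage": stage,
            "age_years": age,
            "weight_kg": weight,
            "gender": np.where(female, "F", "M"),
            "at_admission": rng.random(n) < 0.15,
            "died_30d": died,
        }
    ), eta, stage


class TestAdjustedOr:
    def test_no_confounding_matches_unadjusted(self, rng):
        cohort, _, _ = simulate_adjusted_cohort(8000, rng, confounding=False)
        adj = adjusted_or_marginal(cohort, n_boot=0).set_index("stage")["or"]
        tabs = two_by_two_tables(cohort)
        for s, t in tabs.items():
            unadj = unadjusted_or(t)["or"]
            assert adj[s] == pytest.approx(unadj, rel=0.25)

    def test_null_stage_effect_gives_or_one(self, rng):
        cohort, _, _ = simulate_adjusted_cohort(20000, rng, stage_effects=(0.0, 0.0, 0.0), confounding=False)
        adj = adjusted_or_marginal(cohort, n_boot=0)
        # 3-sigma band on the log-OR for the smallest stage arm (~1,400
        # subjects at ~5% mortality): |log OR| < 0.4
        assert np.all(np.abs(np.log(adj["or"])) < 0.4)

    def test_recovers_generator_marginal_ors_under_confounding(self, rng):
        cohort, _, stage = simulate_adjusted_cohort(20000, rng, confounding=True)
        # generator's own g-computation: true probabilities with stage forced
        age, weight = cohort["age_years"].to_numpy(), cohort["weight_kg"].to_numpy()
        def true_marginal(s):
            eff = {0: 0.0, 1: 0.6, 2: 1.2, 3: 2.0}[s]
            p = _expit(-2.8 + eff + 0.01 * (age - 65) + 0.005 * (weight - 80))
            m = p.mean()
            return m / (1 - m)
        adj = adjusted_or_marginal(cohort, n_boot=0).set_index("stage")["or"]
        for s in (1, 2, 3):
            want = true_marginal(s) / true_marginal(0)
            assert adj[s] == pytest.approx(want, rel=0.15)

    def test_bootstrap_ci_brackets_point(self, rng):
        cohort, _, _ = simulate_adjusted_cohort(2500, rng, confounding=False)
        adj = adjusted_or_marginal(cohort, n_boot=40, seed=7)
        assert (adj["ci_low"] <= adj["or"]).all()
        assert (adj["ci_high"] >= adj["or"]).all()


class TestKmLogrank:
    def cohort(self, rows):
        return pd.DataFrame(rows, columns=["peak_stage", "followup_days", "died_30d"])

    def test_no_deaths_flat_curves_zero_statistic(self):
        c = self.cohort([(0, 30.0, False)] * 5 + [(1, 30.0, False)] * 5)
        out = km_logrank(c)
        for s, curve in out["curves"].items():
            assert (curve.to_numpy() == 1.0).all()
        assert out["pairwise"]["test_statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_zero_statistic(self):
        rows = [(0, 5.0, True), (0, 12.0, False), (0, 20.0, True), (0, 30.0, False)]
        rows += [(1, t, e) for _, t, e in rows]
        out = km_logrank(self.cohort(rows))
        assert out["pairwise"]["test_statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_km_with_no_censoring_is_empirical_survival(self):
        times = [2.0, 4.0, 7.0, 9.0, 15.0]
        c = self.cohort([(0, t, True) for t in times])
        curve = km_logrank(c)["curves"][0]["stage 0"]
        for i, t in enumerate(times):
            assert curve.loc[t] == pytest.approx(1 - (i + 1) / 5)

    def test_eight_subject_hand_worked_example(self):
        """O_A=3, E_A=2.26190, Var=1.21712 -> chi-square 0.44760 (hand-worked)."""
        rows = [(0, 1.0, True), (0, 4.0, True), (0, 6.0, False), (0, 9.0, True)]
        rows += [(1, 2.0, True), (1, 5.0, False), (1, 7.0, True), (1, 10.0, False)]
        out = km_logrank(self.cohort(rows))
        assert out["pairwise"]["test_statistic"].iloc[0] == pytest.approx(0.447601, abs=1e-4)
        # product-limit steps for group 0: 3/4, then 2/3, then 1/2 of the remainder
        curve = out["curves"][0]["stage 0"]
        assert curve.loc[1.0] == pytest.approx(0.75)
        assert curve.loc[4.0] == pytest.approx(0.5)
        assert curve.loc[9.0] == pytest.approx(0.0)


class TestStratifiedSummary:
    def cohort(self, rng, n=900, shift=0.0):
        stage = rng.choice(3, size=n)
        return pd.DataFrame(
            {
                "peak_stage": stage,
                "age_years": rng.normal(65 + shift * stage, 10, n),
                "los_days": rng.lognormal(1.0, 0.6, n),
                "gender": rng.choice(["F", "M"], size=n),
            }
        )

    def test_counts_partition_cohort(self, rng):
        c = self.cohort(rng)
        out = stratified_summary(c, {"age_years": "normal"})
        n_row = out.loc[out["characteristic"] == "n"]
        assert sum(int(n_row[str(s)].iloc[0]) for s in (0, 1, 2)) == len(c)

    def test_identical_groups_give_p_one_region(self, rng):
        c = self.cohort(rng)
        c["flat"] = 5.0
        out = stratified_summary(c, {"flat": "normal"}).set_index("characteristic")
        assert out.loc["flat", "p_value"] == pytest.approx(1.0)

    def test_group_means_match_generator_within_se(self, rng):
        c = self.cohort(rng, n=3000, shift=3.0)
        out = stratified_summary(c, {"age_years": "normal"}).set_index("characteristic")
        for s in (0, 1, 2):
            mean = float(out.loc["age_years", str(s)].split(" ")[0])
            n_s = (c["peak_stage"] == s).sum()
            assert mean == pytest.approx(65 + 3.0 * s, abs=3 * 10 / np.sqrt(n_s))
        assert out.loc["age_years", "p_value"] < 0.001

    def test_categorical_chi_square(self, rng):
        c = self.cohort(rng)
        out = stratified_summary(c, {"gender": "categorical", "los_days": "skewed"})
        assert out["p_value"].iloc[1:].notna().all()
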