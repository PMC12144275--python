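import numpy as np
import pandas as pd
import pytest

from uokit import SimConfig, simulate_cohort


def make_records(rows):
    """rows: (admission_id, iso time, volume, label[, compartment])"""
    df = pd.DataFrame(rows, columns=["admission_id", "chart_time", "volume_ml", "source_label", "compartment"][: len(rows[0])])
    df["chart_time"] = pd.to_datetime(df["chart_time"])
    df["volume_ml"] = df["volume_ml"].astype(float)
    return df


def make_admissions(rows):
    """rows: (admission_id, patient_id, icu_in, icu_out, age, weight, gender[, death_time[, first]])"""
    cols = ["admission_id", "patient_id", "icu_in", "icu_out", "age_years", "weight_kg", "gender", "death_time", "first_icu_admission"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    for c in ("icu_in", "icu_out", "death_time"):
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
        else:
            df[c] = pd.NaT
    if "first_icu_admission" not in df.columns:
        df["first_icu_admission"] = True
    df["weight_kg"] = df["weight_kg"].astype(float)
    return df


@pytest.fixture(scope="session")
def small_hourly_sim():
    """60 admissions with exact clock-aligned hourly charting, no artifacts."""
    return simulate_cohort(SimConfig(n_patients=60, seed=20240601, charting="hourly"))


@pytest.fixture(scope="session")
def small_realistic_sim():
    """80 admissions with realistic per-source charting cadence."""
    return simulate_cohort(SimConfig(n_patients=80, seed=20240602))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
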