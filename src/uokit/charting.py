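"""Reading, mapping and cleaning raw urine-output charting tables.

ICU urine output (UO) is charted as discrete events: a timestamp, a volume in
ml, and a collection-source label (Foley catheter, spontaneous void,
nephrostomy, ...).  This module turns delimiter-separated event tables from
different EHR dialects into a single canonical frame, attaches the anatomical
*compartment* each source drains (urine is additive across compartments but
sequential within one), and applies record- and admission-level cleaning
rules: volumes outside [0, 5000] ml are artifacts, admission weights outside
[25, 300] kg are artifacts, and a handful of source labels (urethral stents,
GU irrigation, urinary leak) disqualify the whole admission because the
charted volumes cannot be trusted.

Canonical UO frame columns::

    admission_id   object
    chart_time     datetime64[ns]  (floored to whole minutes)
    volume_ml      float64
    source_label   object

Canonical admissions frame columns::

    admission_id, patient_id, icu_in, icu_out, age_years, weight_kg,
    gender, death_time, first_icu_admission
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BLADDER",
    "L_NEPHROSTOMY",
    "R_NEPHROSTOMY",
    "ILEOCONDUIT",
    "COMPARTMENTS",
    "INCLUDE",
    "EXCLUDE_ADMISSION",
    "SourceMap",
    "SchemaError",
    "UnknownSourceLabelError",
    "default_source_map",
    "read_uo_table",
    "read_admissions_table",
    "expand_range_group",
    "apply_source_map",
    "clean_records",
]

BLADDER = "BLADDER"
L_NEPHROSTOMY = "L_NEPHROSTOMY"
R_NEPHROSTOMY = "R_NEPHROSTOMY"
ILEOCONDUIT = "ILEOCONDUIT"
COMPARTMENTS = (BLADDER, L_NEPHROSTOMY, R_NEPHROSTOMY, ILEOCONDUIT)

INCLUDE = "INCLUDE"
EXCLUDE_ADMISSION = "EXCLUDE_ADMISSION"

VOLUME_MIN_ML = 0.0
VOLUME_MAX_ML = 5000.0
WEIGHT_MIN_KG = 25.0
WEIGHT_MAX_KG = 300.0


class SchemaError(ValueError):
    """An input table is missing a required column."""


class UnknownSourceLabelError(KeyError):
    """A source label does not resolve in the active SourceMap."""


@dataclasses.dataclass(frozen=True)
class SourceMap:
    """Maps each charting source label to a compartment and an action.

    ``entries`` maps label -> (compartment, action).  Action ``INCLUDE``
    keeps the record under its compartment; ``EXCLUDE_ADMISSION`` disqualifies
    every admission charting that label even once (post-renal obstruction or
    irrigation makes its volumes uninterpretable).
    """

    entries: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for label, (compartment, action) in self.entries.items():
            if action == INCLUDE and compartment not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {compartment!r} for label {label!r}")
            if action not in (INCLUDE, EXCLUDE_ADMISSION):
                raise ValueError(f"unknown action {action!r} for label {label!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def compartment(self, label: str) -> str:
        return self.entries[label][0]

    def action(self, label: str) -> str:
        return self.entries[label][1]

    @classmethod
    def from_entries(cls, entries: Iterable[Mapping[str, str]]) -> "SourceMap":
        """Build from a list of ``{label, compartment, action}`` dicts (YAML/JSON form)."""
        out: dict[str, tuple[str, str]] = {}
        for e in entries:
            label = e["label"]
            if label in out:
                raise ValueError(f"duplicate source-map entry for label {label!r}")
            out[label] = (e.get("compartment", ""), e["action"])
        return cls(out)

    @classmethod
    def from_yaml(cls, path) -> "SourceMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_entries(data)

    def to_yaml(self, path) -> None:
        data = [
            {"label": label, "compartment": comp, "action": action}
            for label, (comp, action) in self.entries.items()
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_source_map() -> SourceMap:
    """The twelve-label default map.

    Bladder drainage routes (indwelling, intermittent, external and
    suprapubic catheters, spontaneous voiding) all empty the same reservoir;
    each nephrostomy drains a single kidney; an ileal conduit replaces the
    bladder after cystectomy.  Stents, irrigation and leaks invalidate the
    admission's UO record.
    """
    entries = {
        "Foley": (BLADDER, INCLUDE),
        "Void": (BLADDER, INCLUDE),
        "Condom Cath": (BLADDER, INCLUDE),
        "Straight Cath": (BLADDER, INCLUDE),
        "Suprapubic": (BLADDER, INCLUDE),
        "R Nephrostomy": (R_NEPHROSTOMY, INCLUDE),
        "L Nephrostomy": (L_NEPHROSTOMY, INCLUDE),
        "Ileoconduit": (ILEOCONDUIT, INCLUDE),
        "Urethral Stent": ("", EXCLUDE_ADMISSION),
        "GU Irrigation": ("", EXCLUDE_ADMISSION),
        "Urinary Leak": ("", EXCLUDE_ADMISSION),
    }
    return SourceMap(entries)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_UO_DIALECT_COLUMNS = {
    "generic": {
        "admission_id": "admission_id",
        "chart_time": "chart_time",
        "volume_ml": "volume_ml",
        "source_label": "source_label",
    },
    "mimic": {
        "admission_id": "stay_id",
        "chart_time": "charttime",
        "volume_ml": "value",
        "source_label": "label",
    },
    "aumc": {
        "admission_id": "admissionid",
        "chart_time": "measuredat",
        "volume_ml": "value",
        "source_label": "item",
    },
}

#: epoch used to turn AmsterdamUMCdb millisecond offsets into timestamps
AUMC_EPOCH = pd.Timestamp("2000-01-01 00:00:00")


def _require_columns(df: pd.DataFrame, needed: Iterable[str], what: str) -> None:
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def read_uo_table(path, dialect: str = "generic") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a UO events table into the canonical frame.

    Parameters
    ----------
    path : str or path-like
        CSV file.  Column schema depends on ``dialect``:
        ``generic`` -> admission_id, chart_time (ISO-8601), volume_ml,
        source_label; ``mimic`` -> stay_id, charttime, value, label;
        ``aumc`` -> admissionid, measuredat (milliseconds from a fixed
        origin), value, item.
    dialect : {"generic", "mimic", "aumc"}

    Returns
    -------
    (records, rejects)
        ``records`` is the canonical UO frame, input row order preserved,
        timestamps floored to whole minutes.  ``rejects`` holds unparseable
        rows with ``line`` (1-based data line number) and ``reason`` columns.
    """
    if dialect not in _UO_DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _UO_DIALECT_COLUMNS[dialect]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, colmap.values(), f"UO ({dialect})")

    volume = pd.to_numeric(raw[colmap["volume_ml"]], errors="coerce")
    if dialect == "aumc":
        offset_ms = pd.to_numeric(raw[colmap["chart_time"]], errors="coerce")
        chart_time = AUMC_EPOCH + pd.to_timedelta(offset_ms, unit="ms")
    else:
        chart_time = pd.to_datetime(raw[colmap["chart_time"]], errors="coerce", format="mixed")
    chart_time = chart_time.dt.floor("min")

    bad_volume = volume.isna()
    bad_time = chart_time.isna() & ~bad_volume
    bad = bad_volume | chart_time.isna()

    reasons = np.where(bad_volume, "unparseable_volume", np.where(bad_time, "unparseable_timestamp", ""))
    rejects = raw.loc[bad].copy()
    rejects["line"] = rejects.index + 2  # header is line 1
    rejects["reason"] = reasons[bad.to_numpy()]
    rejects = rejects.reset_index(drop=True)

    records = pd.DataFrame(
        {
            "admission_id": raw[colmap["admission_id"]],
            "chart_time": chart_time,
            "volume_ml": volume.astype(float),
            "source_label": raw[colmap["source_label"]],
        }
    ).loc[~bad]
    return records.reset_index(drop=True), rejects


def write_uo_table(records: pd.DataFrame, path, dialect: str = "generic") -> None:
    """Write a canonical UO frame back out in the given dialect."""
    if dialect not in _UO_DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _UO_DIALECT_COLUMNS[dialect]
    out = pd.DataFrame()
    out[colmap["admission_id"]] = records["admission_id"]
    if dialect == "aumc":
        out[colmap["chart_time"]] = (
            (records["chart_time"] - AUMC_EPOCH) // pd.Timedelta(milliseconds=1)
        )
    else:
        out[colmap["chart_time"]] = records["chart_time"].dt.strftime("%Y-%m-%d %H:%M:%S")
    out[colmap["volume_ml"]] = records["volume_ml"]
    out[colmap["source_label"]] = records["source_label"]
    out.to_csv(path, index=False)


_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)\s*$")
_TAIL_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*\+\s*$")


def expand_range_group(value, tail_pad: float = 5.0) -> float:
    """Expand a range-group string to a point value.

    AmsterdamUMCdb stores age and weight as 10-unit range groups
    ("70-79"); these expand to the group midpoint.  Open-ended tail groups
    ("80+") take the tail value plus ``tail_pad`` units.  Plain numbers pass
    through unchanged, missing values return NaN.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "none"):
        return float("nan")
    m = _RANGE_RE.match(s)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo + hi) / 2.0
    m = _TAIL_RE.match(s)
    if m:
        return float(m.group(1)) + tail_pad
    return float(s)


def read_admissions_table(path, dialect: str = "generic") -> pd.DataFrame:
    """Read an admissions table into the canonical frame.

    The generic schema has columns admission_id, patient_id, icu_in, icu_out,
    age_years, weight_kg, gender, death_time and (optionally)
    first_icu_admission.  The ``aumc`` dialect uses millisecond offsets for
    the time columns and may carry age/weight as range-group strings, which
    are expanded to midpoints (tail groups: tail value + 5).  When
    first_icu_admission is absent it is derived: a patient's earliest
    admission by icu_in is the first.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = ["admission_id", "patient_id", "icu_in", "icu_out", "age_years", "weight_kg", "gender"]
    if dialect == "aumc":
        alias = {
            "admissionid": "admission_id",
            "patientid": "patient_id",
            "admittedat": "icu_in",
            "dischargedat": "icu_out",
            "agegroup": "age_years",
            "weightgroup": "weight_kg",
            "dateofdeath": "death_time",
        }
        raw = raw.rename(columns=alias)
    _require_columns(raw, needed, f"admissions ({dialect})")

    def _times(col):
        if col not in raw.columns:
            return pd.Series(pd.NaT, index=raw.index)
        if dialect == "aumc":
            ms = pd.to_numeric(raw[col], errors="coerce")
            return (AUMC_EPOCH + pd.to_timedelta(ms, unit="ms")).dt.floor("min")
        return pd.to_datetime(raw[col].replace("", pd.NaT), errors="coerce", format="mixed").dt.floor("min")

    adm = pd.DataFrame(
        {
            "admission_id": raw["admission_id"],
            "patient_id": raw["patient_id"],
            "icu_in": _times("icu_in"),
            "icu_out": _times("icu_out"),
            "age_years": raw["age_years"].map(expand_range_group),
            "weight_kg": raw["weight_kg"].map(expand_range_group),
            "gender": raw["gender"],
            "death_time": _times("death_time"),
        }
    )
    if "first_icu_admission" in raw.columns:
        adm["first_icu_admission"] = raw["first_icu_admission"].str.lower().isin(("true", "1", "yes"))
    else:
        first = adm.sort_values("icu_in").drop_duplicates("patient_id", keep="first")["admission_id"]
        adm["first_icu_admission"] = adm["admission_id"].isin(set(first))
    return adm


# ---------------------------------------------------------------------------
# source-map application and cleaning
# ---------------------------------------------------------------------------


def apply_source_map(
    records: pd.DataFrame,
    source_map: SourceMap | None = None,
    unknown: str = "fail",
) -> tuple[pd.DataFrame, set]:
    """Attach compartments and apply admission-level source exclusions.

    Any admission charting at least one label whose action is
    ``EXCLUDE_ADMISSION`` is removed entirely.  ``unknown`` controls labels
    absent from the map: ``"fail"`` raises, ``"exclude-admission"`` treats
    them like exclusion labels, ``"drop-record"`` silently drops the rows.

    Returns ``(kept, excluded_admissions)`` where ``kept`` carries a new
    ``compartment`` column; volumes and timestamps are untouched.
    """
    if source_map is None:
        source_map = default_source_map()
    if unknown not in ("fail", "exclude-admission", "drop-record"):
        raise ValueError(f"unknown policy {unknown!r}")
    if len(records) and not source_map.entries:
        raise ValueError("source map has no entries but records are nonempty")

    labels = records["source_label"]
    known = labels.isin(source_map.entries)
    if not known.all():
        unresolved = sorted(labels[~known].unique())
        if unknown == "fail":
            raise UnknownSourceLabelError(f"unresolvable source labels: {unresolved}")

    actions = labels.map({k: v[1] for k, v in source_map.entries.items()})
    excl_mask = (actions == EXCLUDE_ADMISSION) | (~known & (unknown == "exclude-admission"))
    excluded_admissions = set(records.loc[excl_mask, "admission_id"].unique())

    keep = known & (actions == INCLUDE) & ~records["admission_id"].isin(excluded_admissions)
    kept = records.loc[keep].copy()
    kept["compartment"] = kept["source_label"].map({k: v[0] for k, v in source_map.entries.items()})
    return kept.reset_index(drop=True), excluded_admissions


def clean_records(
    records: pd.DataFrame, admissions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Remove artifact volumes and artifact-weight admissions.

    Volumes below 0 or above 5000 ml are charting artifacts and are dropped
    record-wise (zero is a legal volume — true anuria is charted as 0 ml).
    Admission weights outside [25, 300] kg are artifacts; those admissions
    are dropped together with all their UO records.  Missing weights are
    retained here (eligibility handles them later).

    Returns ``(records', admissions', report)`` where ``report`` counts every
    exclusion reason; kept + excluded always partitions the input.
    """
    vol_bad = (records["volume_ml"] < VOLUME_MIN_ML) | (records["volume_ml"] > VOLUME_MAX_ML)

    w = admissions["weight_kg"]
    w_bad = w.notna() & ((w < WEIGHT_MIN_KG) | (w > WEIGHT_MAX_KG))
    bad_adm = set(admissions.loc[w_bad, "admission_id"])

    rec_from_bad_adm = records["admission_id"].isin(bad_adm) & ~vol_bad
    keep_rec = ~vol_bad & ~rec_from_bad_adm

    report = {
        "records_in": int(len(records)),
        "records_kept": int(keep_rec.sum()),
        "volume_out_of_range": int(vol_bad.sum()),
        "records_from_artifact_weight_admissions": int(rec_from_bad_adm.sum()),
        "admissions_in": int(len(admissions)),
        "admissions_kept": int(len(admissions) - len(bad_adm)),
        "weight_out_of_range": int(len(bad_adm)),
    }
    return (
        records.loc[keep_rec].reset_index(drop=True),
        admissions.loc[~w_bad].reset_index(drop=True),
        report,
    )
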