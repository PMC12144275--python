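"""From raw charting rows to hourly-adjusted urine output.

Builds a tiny charting table by hand — a Foley catheter emptied at irregular
times plus a nephrostomy — and walks it through the standardization chain:
source-to-compartment mapping, simultaneous-entry merge, collection-interval
reconstruction (the first volume per compartment is residual and only
anchors timing), and projection onto clock-aligned hours.
"""

import pandas as pd

from uokit import apply_source_map, build_intervals, compute_hourly, merge_simultaneous, per_kg

records = pd.DataFrame(
    {
        "admission_id": "icu-001",
        "chart_time": pd.to_datetime(
            [
                "2024-03-01 08:10",  # residual volume: accumulated before monitoring
                "2024-03-01 09:40",
                "2024-03-01 09:40",  # double-charted entry, merged by summation
                "2024-03-01 11:10",
                "2024-03-01 08:10",  # right nephrostomy, its own compartment
                "2024-03-01 10:10",
            ]
        ),
        "volume_ml": [220.0, 90.0, 30.0, 45.0, 80.0, 70.0],
        "source_label": ["Foley"] * 4 + ["R Nephrostomy"] * 2,
    }
)

kept, excluded = apply_source_map(records)
merged = merge_simultaneous(kept)
intervals, report = build_intervals(merged)
print("rate intervals (per compartment, residuals dropped):")
print(intervals[["compartment", "start_time", "end_time", "volume_ml", "rate_ml_hr"]].to_string(index=False))

hourly = per_kg(compute_hourly(intervals), 80.0)
print("\nhourly-adjusted UO (80 kg patient):")
print(hourly[["hour_start", "uo_ml", "coverage", "valid", "uo_ml_per_kg"]].round(3).to_string(index=False))

print(
    "\nEach hour's volume sums rate x overlap across compartments; 'coverage' is the"
    "\nfraction of the hour with a known rate, and an hour is valid only when that"
    "\nfraction exceeds one half - no volume is extrapolated into uncovered minutes."
)
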