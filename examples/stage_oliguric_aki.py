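"""Staging an oliguric episode under the two KDIGO-UO readings.

A patient produces normally, then slips into 18 hours of oliguria at
0.25 ml/kg/hr.  The running-average reading (UO-mean) and the
every-consecutive-hour reading (UO-cons) are staged side by side; the
consecutive reading can never stage higher, which is why it is the more
specific choice for e-alerts.
"""

import numpy as np
import pandas as pd

from uokit import stage_both

T0 = pd.Timestamp("2024-03-01 00:00")
per_kg = np.array([1.1] * 10 + [0.25] * 18 + [1.0] * 8)

hourly = pd.DataFrame(
    {
        "admission_id": "icu-002",
        "hour_start": T0 + pd.to_timedelta(np.arange(len(per_kg)), unit="h"),
        "uo_ml": per_kg * 75,
        "uo_ml_per_kg": per_kg,
        "valid": True,
    }
)

staged = stage_both(hourly)
staged["hour"] = np.arange(len(staged))
print(staged[["hour", "stage_mean", "stage_cons"]].to_string(index=False))

peak_mean = staged["stage_mean"].max()
peak_cons = staged["stage_cons"].max()
print(
    f"\npeak stage: mean-reading {peak_mean}, consecutive-reading {peak_cons}."
    "\nStages appear only once a full valid window exists (first at hour 5);"
    "\nstage 2 requires the 12-h window, stage 3 the 24-h window or 12 h of anuria."
)
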