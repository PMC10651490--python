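"""Cuff-log aggregation: values of the day and of the week.

Builds a two-week home blood-pressure log (three morning readings per
day), aggregates each day into a value of the day and each week into a
value of the week (defined only when >= 3 days were recorded).
"""

import numpy as np
import pandas as pd

import ifshear as ifs

rng = np.random.default_rng(4)
rows = []
for day, n_ok in [("2024-03-04", 3), ("2024-03-05", 3), ("2024-03-06", 3),
                  ("2024-03-07", 3), ("2024-03-11", 3), ("2024-03-12", 3)]:
    for slot in range(1, 4):
        rows.append({
            "date": day, "slot": slot,
            "sbp": round(142 + rng.normal(0, 4)), "dbp": round(88 + rng.normal(0, 3)),
            "hr": round(64 + rng.normal(0, 3)),
        })

weekly = ifs.weekly_values(pd.DataFrame(rows))
print(weekly.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print(f"\nMAP for 142/88 mm Hg  : {ifs.compute_map(142, 88):.1f} mm Hg")
print("A week with fewer than three recorded days yields defined=False and")
print("is excluded from trend statistics rather than silently averaged.")
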