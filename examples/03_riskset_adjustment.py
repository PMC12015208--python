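"""The daily pregnancy risk-set adjustment W_i on a toy cohort.

W_i is the average probability of birth among ongoing pregnancies at
risk of the outcome in a ZCTA on day i: sum_g Z_ig * W_g / Z_i.  It
absorbs within-month drift in the baseline birth probability (e.g.
from conception seasonality) that would otherwise confound the
case-crossover contrast.
"""

import numpy as np
import pandas as pd

from heatbirth import adjustment_series, birth_week_hazard

rng = np.random.default_rng(2)
n = 400
births = pd.DataFrame(
    {
        "zcta_id": "Z1",
        "birth_date": pd.Timestamp("2010-01-01")
        + pd.to_timedelta(rng.integers(0, 540, n), unit="D"),
        "ga_weeks": rng.choice([34, 36, 37, 38, 39, 40, 41],
                               p=[0.02, 0.04, 0.10, 0.16, 0.33, 0.25, 0.10],
                               size=n),
    }
)

hazard = birth_week_hazard(births)
print("week-specific birth hazard W_g (births at g / births reaching g):")
print(hazard[hazard["ga_weeks"] >= 36].to_string(index=False))

wi = adjustment_series(births, "Z1", pd.date_range("2010-07-01", "2010-07-07"),
                       outcome="ETB", week_hazard=hazard)
print("\ndaily ETB risk-set adjustment, first week of July:")
print(wi[["date", "z_total", "w_i"]].to_string(index=False))
# z_total counts all ongoing pregnancies that day; w_i averages the
# week-37/38 hazard over them and is 0 when no pregnancy is in the
# early-term risk window.
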