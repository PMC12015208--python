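"""Time-stratified case-crossover strata for a few births.

The event day is the birth day; referents are all other same-weekday
days in the same calendar month, so each stratum has 4 or 5 days and
every within-stratum exposure contrast is free of confounding by
anything constant within the month.
"""

import numpy as np
import pandas as pd

from heatbirth import ZctaTempSeries, assemble_strata, exposure_table, referent_days

print("referents for a birth on Thu 2010-07-15:",
      [str(d.date()) for d in referent_days("2010-07-15")])

rng = np.random.default_rng(1)
dates = pd.date_range("2010-01-01", periods=365)
series = ZctaTempSeries("Z1", dates, rng.normal(24, 4, len(dates)))
exposures = exposure_table({"Z1": series})

births = pd.DataFrame(
    {
        "birth_id": [1, 2, 3],
        "state": "S1",
        "zcta_id": "Z1",
        # one PTB in July, one out-of-season (April), one early-term birth
        "birth_date": pd.to_datetime(["2010-07-15", "2010-04-10", "2010-08-02"]),
        "ga_weeks": [30, 30, 37],
    }
)

strata, exclusions = assemble_strata(births, exposures, None, outcome="PTB")
print("\nexclusions by reason:", exclusions)
print("\nstratum for birth 1 (is_case marks the event day):")
print(strata[["birth_id", "date", "is_case", "run_length", "aat"]].to_string(index=False))
# Only the warm-season preterm birth forms a stratum; the April case is
# out of the May-September window and the 37-week birth is early term.
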