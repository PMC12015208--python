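"""Heat-wave metrics on a single ZCTA temperature series.

Builds two years of daily temperatures for one ZCTA, computes the
relative hot-day threshold (97.5th percentile of the full series) and
the 4-day-window metrics for a handful of July days.
"""

import numpy as np
import pandas as pd

from heatbirth import ZctaTempSeries, exposure_for_date, hot_day_threshold

rng = np.random.default_rng(0)
dates = pd.date_range("2015-01-01", "2016-12-31")
doy = dates.dayofyear.to_numpy()
tmean = 17 + 9 * np.cos(2 * np.pi * (doy - 197) / 365.25) + rng.normal(0, 2.5, len(dates))

series = ZctaTempSeries("Z-DEMO", dates, tmean)
thr = hot_day_threshold(series)
print(f"hot-day threshold (97.5th pct of {len(series)} days): {thr:.2f} C")

for day in pd.date_range("2015-07-18", "2015-07-24"):
    e = exposure_for_date(series, day)
    print(
        f"{day.date()}  run_length={e.run_length}  AAT={e.aat:.2f} C  "
        f"hw>=2:{e.hw_ge2}  hw>=3:{e.hw_ge3}  hw=4:{e.hw_eq4}"
    )

# run_length counts consecutive window days strictly above the threshold;
# AAT is the window-mean exceedance in deg C, floored at zero — the
# continuous definition capturing both intensity and duration.
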