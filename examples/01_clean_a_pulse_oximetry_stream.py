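"""Clean a raw pulse-oximetry stream: slope-based artefact rejection,
minute averaging and capped LOCF gap filling.

A finger oximeter occasionally emits step artefacts when the probe shifts;
a change faster than 4 %/s is physiologically impossible and is discarded.
Retained samples are averaged per minute, and gaps up to 60 min are filled
by carrying the last observed minute forward.
"""

import numpy as np

from vitalwatch import SampleSeries, filter_spo2_artifacts, locf_fill, to_minute_grid
from vitalwatch.series import ARTIFACT_REJECTED, LOCF_FILLED

t0 = np.datetime64("2022-03-01T12:00:00", "s")

# 3 minutes of 10-s samples around 95 %, one probe artefact, then a 5-min gap
seconds = list(range(0, 180, 10))
values = [95.0] * 18
values[7] = 40.0  # probe-shift artefact: 55 % drop in 10 s
series = SampleSeries("SPO2", [t0 + np.timedelta64(s, "s") for s in seconds], values)

clean = filter_spo2_artifacts(series, slope_limit=4.0)
n_rejected = int((clean.quality == ARTIFACT_REJECTED).sum())
print(f"rejected {n_rejected} of {len(clean)} samples as slope artefacts")

grid = to_minute_grid(clean, (t0, t0 + np.timedelta64(8 * 60, "s")))
print("minute means      :", np.round(grid.values, 2))

filled = locf_fill(grid, max_gap=60)
print("after LOCF filling:", np.round(filled.values, 2))
print("filled minutes    :", np.flatnonzero(filled.quality == LOCF_FILLED).tolist())

# The artefact never reaches the minute average: its minute is the mean of
# the five retained samples, and the empty trailing minutes take the last
# observed value (flagged as imputed, with their source minute recorded).
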