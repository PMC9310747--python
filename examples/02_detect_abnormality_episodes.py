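"""Detect duration x severity abnormality episodes on a minute grid.

An episode needs both severity (a strict threshold crossing) and
persistence (a tier-specific minimum duration), and abnormal stretches
less than 5 minutes apart count as a single episode.
"""

import numpy as np

from vitalwatch import DEFAULT_TIERS, MinuteGrid, detect_channel_episodes

t0 = np.datetime64("2022-03-01T12:00:00", "s")

# 30 minutes of SpO2: two desaturation dips below 85 % separated by 4 min
values = np.full(30, 95.0)
values[5:9] = 83.0    # 4 min below 85
values[13:16] = 82.0  # 3 min below 85, 4 min after the first dip ends
grid = MinuteGrid("SPO2", t0, values)

tier85 = next(t for t in DEFAULT_TIERS if t.label == "SPO2<85>=5min")
episodes = detect_channel_episodes(grid, tier85, merge_gap=5)
for e in episodes:
    print(f"{tier85.label}: minutes {e.start}-{e.end}, "
          f"{e.duration:g} abnormal min from {e.n_merged} merged runs")

# The two dips merge (gap < 5 min) into one episode of 7 condition-true
# minutes, which passes the >=5-min persistence requirement even though
# neither dip alone would.

tier80 = next(t for t in DEFAULT_TIERS if t.label == "SPO2<80>=1min")
print(f"{tier80.label}: {len(detect_channel_episodes(grid, tier80, 5))} episodes "
      "(the dips never cross the severer 80 % threshold)")
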