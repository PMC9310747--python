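import math

import numpy as np
import pytest

from vitalwatch import AnalysisConfig, MinuteGrid, SampleSeries

T0 = np.datetime64("2022-03-01T12:00:00", "s")


def ts(seconds: float) -> np.datetime64:
    return T0 + np.timedelta64(int(seconds), "s")


def make_series(channel, seconds, values):
    return SampleSeries(channel, [ts(s) for s in seconds], values)


def make_grid(channel, values, start=T0):
    return MinuteGrid(channel, start, np.asarray(values, dtype=float))


@pytest.fixture
def config():
    return AnalysisConfig()


def brute_force_episodes(values, direction, threshold, gap, min_persistence):
    """Independent enumerator of duration x severity episodes.

    Scans minute by minute for maximal condition-true runs, merges adjacent
    runs by fixpoint iteration of the "< gap minutes apart" rule, then keeps
    the intervals whose condition-true time meets the persistence floor.
    Deliberately written as plain loops, unrelated to the vectorised
    implementation it checks.
    """
    n = len(values)
    cond = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            cond.append(False)
        elif direction == "below":
            cond.append(v < threshold)
        else:
            cond.append(v > threshold)
    runs = []
    i = 0
    while i < n:
        if cond[i]:
            j = i
            while j + 1 < n and cond[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 1):
            (s1, e1), (s2, e2) = runs[k], runs[k + 1]
            if s2 - e1 - 1 < gap:
                runs[k : k + 2] = [(s1, e2)]
                changed = True
                break
    episodes = []
    for s, e in runs:
        true_minutes = sum(cond[s : e + 1])
        if true_minutes >= min_persistence:
            episodes.append((s, e, true_minutes))
    return episodes
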