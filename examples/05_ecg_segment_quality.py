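"""Judge ECG segment quality by QRS template correlation.

Heart rate comes from 10-s single-lead ECG excerpts, one per monitored
minute.  Each detected beat is correlated against the segment's own
average beat; a segment whose worst beat correlates poorly is artefact
and contributes no heart-rate sample.
"""

import numpy as np

from vitalwatch import EcgSegment, assess_ecg_segment, make_ecg_segment

rng = np.random.default_rng(1)

clean = make_ecg_segment(72.0, noise_sd=0.02, rng=rng)
res = assess_ecg_segment(clean, correlation_threshold=0.8)
print(f"clean segment   : {res.quality}, HR = {res.hr:.1f} beats/min, "
      f"worst beat correlation {res.beat_correlations.min():.3f}")

corrupted = clean.samples.copy()
corrupted[4000:] = rng.uniform(-1, 1, size=6000)  # electrode motion
res = assess_ecg_segment(EcgSegment(0, corrupted), correlation_threshold=0.8)
print(f"corrupted segment: {res.quality} ({res.reason})")

flat = assess_ecg_segment(EcgSegment(0, np.zeros(10_000)), 0.8)
print(f"flat segment     : {flat.quality} ({flat.reason})")

# Only the clean segment yields a heart rate; the corrupted and flat
# minutes are simply missing in the per-minute series and may later be
# bridged by LOCF (up to 60 min).
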