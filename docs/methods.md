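# Methods

This note records the models, conventions and numerical choices behind
`vitalwatch`, in the order the pipeline applies them.

## Monitoring model and data contract

Four channels are analysed. Heart rate (HR, beats/min) and respiratory rate
(RR, breaths/min) arrive as per-minute values, HR optionally derived from
10-s single-lead ECG segments digitized at 1000 samples/s (one segment per
monitored minute). Peripheral oxygen saturation (SpO₂, %) arrives at raw
sub-minute cadence. Systolic blood pressure (SBP, mmHg) is intermittent and
oscillometric, scheduled every 30 min during the day (07:00–21:59) and every
60 min at night (22:00–06:59), anchored to clock marks. Monitoring runs from
ward arrival until discharge or 96 h, whichever is first; the pipeline
truncates longer records at 96 h.

Plausibility ranges are fixed configuration, not inferred: HR 10–300, RR
0–80, SpO₂ 40–100, SBP 30–300. Values outside the range are flagged
artefact on ingest. This range gate is the package's minimal reading of
"remove noise and artefacts first" and can be disabled
(`plausibility_gate=False`).

## ECG segment quality

A derivative-energy QRS detector (25-ms pre-smoothing, squared first
difference integrated over 120 ms, peaks ≥ 25 % of the maximum energy,
200-ms refractory period, refinement to the largest deflection within
±60 ms) locates beats. Beats are windowed ±120 ms, averaged into a
template, and each beat is Pearson-correlated with that template. The
segment is accepted iff the **minimum** per-beat correlation reaches the
threshold (default 0.8). Accepted segments contribute
`HR = 60·(n−1)/span_s`. Segments with fewer than two full-window beats are
rejected with reason "insufficient beats".

Open choices resolved here: the detector itself, the correlation summary
(minimum, the conservative reading of "at low correlation … removed") and
the 0.8 threshold are this package's choices — the upstream description
fixes none of them — and all are configurable. The quality logic, not the
detector, is the load-bearing part; the detector is deliberately plain.

## SpO₂ artefact filter

A sample whose change from the previous **retained** sample exceeds 4 %/s
is rejected. Using the retained baseline stops one spike from cascading
into rejections of the normal samples after it. After three consecutive
rejections the next sample is accepted unconditionally: a level sustained
that long is a state change, not a transient, and an unbounded baseline
would otherwise discard the remainder of the stream after an accepted
outlier (e.g. a spike that entered at a moment with no slope baseline).
The filter is idempotent, a property the suite checks on contaminated
streams.

## Minute averaging and LOCF

Minute bins are left-closed right-open, anchored at monitoring start. A
minute's value is the arithmetic mean of its non-rejected samples; a minute
with none is missing. During episode computation, a missing minute takes
the most recent observed minute's value if that observation is at most
60 min old (configurable); filled minutes are flagged and carry the index
of their source minute. Leading missing minutes are never filled, and the
cap counts from the observed source, so a 61-min gap ends with one missing
minute. LOCF applies to all four channels by default (`locf_channels`);
whether the original analysis filled only SBP (where the 30/60-min cadence
makes it essential — "assigned for 30 min during the day, 60 at night" *is*
LOCF) or all channels is not stated, so the scope is configurable.

## Episode definition

For continuous channels, a **run** is a maximal stretch of minutes on which
the tier condition holds; inequalities are strict in both directions
(`<` / `>`, following the tier table; the alternative "≥ 110" phrasing that
appears in summary text is not used). Missing minutes never satisfy a
condition and therefore terminate runs. Runs strictly less than 5 min apart
merge; the separating minutes do not count as abnormal time. A merged run
qualifies as an **episode** iff its condition-true minutes reach the tier's
minimum persistence.

Merge-before-qualify is the default because the alternative order makes the
merge rule incapable of ever creating a qualifying episode, reducing it to
a counting convention; whether the original analysis merged before or after
the persistence test is not stated, so `persistence_mode` also offers
`span` (gaps count toward persistence) and `premerge` (runs must qualify
individually) for sensitivity analysis.

SBP tiers count **consecutive measurements**: each maximal stretch of at
least `min_consecutive` (default 2, the "two times in a row" reading; the
text is ambiguous between ≥ 2 and > 2, and 2 is the tier table's wording)
successive measurements beyond threshold is one episode, so three in a row
are one episode, not two. Missing scheduled measurements do not break
consecutiveness — the schedule is intermittent by design, so
consecutiveness is defined on successive retained measurements, not on
minutes. Episode duration is the span between the first and last qualifying
measurement.

Cumulative duration at a threshold is the plain count of condition-true
minutes — no persistence, no merging — and is additive over any partition
of the window, which the day/night identity tests exploit.

The detector is held, on 1000 random grids, to exact agreement with an
independent brute-force enumerator written as plain loops.

## Groups, exposure windows, normalization

Groups: first SAE inside the monitoring period (SAE-during), after it but
within 30 days of monitoring start (SAE-after), otherwise no-SAE. An SAE
before monitoring start is an error. Only data preceding the first SAE are
analysed: a SAE-during patient's window is the up-to-24-h interval ending
at the SAE; the other groups contribute the whole monitoring period.

Counts and durations are scaled by `1440 / window_minutes`. The factor is
below 1 for stays longer than 24 h — scaling works both ways, matching the
"divide by the monitoring time and multiply to give the 24-h average" rule.
A patient with a normalized episode count below one is not counted as
having the abnormality. The denominator is elapsed window length by
default; `coverage_based_normalization` divides by minutes actually covered
by data instead. No minimum-monitoring floor is applied by default
(`min_monitoring_minutes=0`).

Day/night strata are 07:00–21:59 and 22:00–06:59; every minute belongs to
exactly one stratum. Stratified tables renormalize to the stratum length
(episodes per 15-h day / per 9-h night; `daynight_normalization="per24h"`
switches to a 24-h scale). Episodes are assigned to the stratum of their
onset; durations are split minute-by-minute. Patients with zero observed
minutes on a tier's channel inside the window are excluded from that tier's
table, and the exclusion count is reported alongside it.

## Statistics

Frequencies: Pearson chi-square on the 2 × 3 table without continuity
correction (the correction is a 2 × 2 device); df = k − 1; an expected
zero cell raises rather than returning a meaningless statistic. Durations:
Kruskal–Wallis H with tie correction and the chi-square approximation;
all-identical samples return H = 0, p = 1. Medians and IQRs use linear
interpolation between order statistics (quantile type 7), the dominant
convention. No multiple-comparison correction is applied, matching the
exploratory design. The chi-square path is verified against a from-first-
principles Σ(O−E)²/E implementation to 1e-9 relative error, and the
worked-example tables built from the published counts reproduce the
published p-values.

## Synthetic cohort generator

Each channel is `baseline + between-patient offset + circadian + AR(1)
noise`. The circadian term is a single 24-h cosine with acrophase 16:00
(afternoon peak, nocturnal trough) — the simplest structure exhibiting
day/night contrast. Noise is lag-1 autoregressive on the sampling grid
(φ = 0.95–0.97 per minute, SpO₂'s φ rescaled to its cadence) because white
noise would badly understate run lengths and hence episode counts.
Between-patient offsets are Gaussian plus sparse phenotype mixtures
(sustained tachy-/bradycardia, tachypnea, hypertension: 2–6 % of patients
with 9–40-unit shifts) standing in for discrete postoperative phenomena —
atrial fibrillation, opioid effect, fever, uncontrolled hypertension — that
Gaussian wander cannot produce. SpO₂ additionally carries transient
desaturation events (Poisson in time with gamma-distributed patient rates,
exponential depth and duration, trapezoidal profile shallow enough never to
violate the 4 %/s rule) and is clipped at the 100 % ceiling.

Cohort structure follows the study's printed summaries: SAE prevalence
0.37, fraction of first SAEs during monitoring 0.38, monitoring 79 h,
first-SAE times log-normal with μ = ln(111 h), σ = 0.987 — the values
fitted to the printed median (4 d 15 h) and IQR (2 d 3 h – 8 d 1 h) —
truncated at 30 days and to the relevant side of monitoring end. Signal
parameters (baselines 75 / 16 / 95 / 125, amplitudes, noise scales,
missingness rates, desaturation rates) were calibrated once against the
printed cohort summaries — tier prevalences for the common tiers,
cumulative-duration medians (e.g. SpO₂ < 92 % ≈ 150 min/24 h), and
per-channel data volumes (≈ 73 h HR/RR, ≈ 43 h SpO₂, ≈ 63 BP measurements
per patient) — and then frozen. Artefact injection is constructed to be
removable: HR/RR spikes are implausible values the range gate catches, SpO₂
spikes are step drops of `5·Δt + 5` % (slope ≥ 5 %/s at any cadence),
skipped where the signal lacks headroom and on the first sample.

All randomness flows from one seed; each patient derives per-purpose
substreams (SAE, each channel, gaps, artefacts, desaturations, window) from
`SeedSequence(seed, spawn_key=(patient,))`, so toggling one process leaves
every other draw untouched — the property the planted-episode and
artefact-robustness tests rely on.

What the generator does **not** emulate: measurement-level device bias,
activity artefacts correlated across channels, intervention effects
(oxygen, fluids) that truncate real abnormalities, and the very rare
extreme tiers (HR < 30, SBP < 70, SBP > 220 — in the real cohort these
0–4 % prevalences plausibly include residual sensor artefact). Passing
tests therefore certify the pipeline's arithmetic and the tests' statistical
behaviour, not clinical realism of any single trace.

## Scenario presets and problem sizes

Four shipped presets: `paper-like` (full realism: 491 patients, 79 h,
10-s SpO₂, gaps, artefacts, a modest ramped pre-SAE shift of HR +14 /
SBP −14 over 12 h), `tachycardia-effect` and `hypotension-effect` (clean
24-h cohorts with step/ramp pre-SAE shifts of ±45 units over 6 h), and
`null`. The null preset makes the labelling exactly exchangeable: fixed
24-h monitoring, the during-group's SAE pinned to monitoring end, no
pre-SAE effect — so every patient has the identical 24-h exposure window
and rejection rates estimate test size. With SAE times drawn *inside* the
window instead, the 24-h normalization itself (factor 1440/T) inflates the
during-group's normalized counts and the comparison is no longer null —
a genuine asymmetry of the normalization design, not of the tests, and the
reason the calibration scenario pins the SAE time. Effect scenarios use
24-h monitoring and 60-s SpO₂ so that Monte-Carlo suites (1000 null
replicates of n = 200; 200 effect replicates of n = 491) complete in
minutes; under random labelling the rejection rate is invariant to window
length, and the effect scenarios' power is if anything understated by the
shorter window. Both step and ramp effect shapes are provided because no
pre-SAE trajectory is specified anywhere; the shape is a scenario choice.

## Known limitations

- The RR channel is taken as supplied; derivation of respiratory rate from
  ECG amplitude modulation is out of scope.
- The slope filter's three-rejection reset trades a bounded amount of
  false acceptance during sustained garbage for immunity to baseline
  poisoning; streams whose artefacts hold a constant false level for
  longer than three samples will partially pass.
- Day/night episode assignment uses the onset minute; an episode
  straddling 22:00 counts wholly toward its onset stratum (durations,
  by contrast, are split exactly).
- The published headline duration medians (272 / 259 / 261 min) are not
  recomputable without the raw cohort; the pipeline reproduces the
  published frequency-table p-values exactly and matches the duration
  medians only in order of magnitude through the calibrated generator.
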