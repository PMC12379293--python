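# Methods

## Signal model and assumptions

A stereo pulse-event recorder reduces the 55–235 kHz soundscape to a
point process with marks: detection times on a 0.5 ms clock, received
pressures `spl_a`, `spl_b` on two hydrophones (linear, Pa), and a signed
arrival-time difference `td` on a 0.25 µs grid. Only pulses whose
received pressure reaches the detection threshold (default
139 dB re 1 µPa ≈ 8.91 Pa) exist in the data; the package treats that
contract as an invariant and rejects sub-threshold rows at ingest.

Pressures are stored and processed on the **linear** scale. This is a
convention, not a device fact: the sound-pressure-ratio criterion
(SPLR ≥ 0.6) and the SPL coefficient of variation are only meaningful
as ratios of linear quantities, and dB inputs are converted once at the
boundary (`db_to_linear(L) = 10^(L/20) µPa`).

Four event phenomenologies are modeled:

* **Regular click trains** — smooth inter-pulse-interval and SPL
  evolution, high and stable SPLR (the narrow-band high-frequency click
  of Phocoenidae is strong on the 70 kHz hydrophone), and a per-train
  stable bearing, i.e. small spread of `td`.
* **Buzzes** — the same, compressed to intervals ≤ 10 ms.
* **Vessel noise** — minutes-scale duration, dense, with intervals,
  SPLs, SPLR and `td` all irregular (many uncorrelated cavitation
  sources on a moving vessel).
* **Snapping shrimp** — a Poisson impulse background with click-like
  amplitudes and broadly random SPLR and `td`; the dominant
  false-positive source in warm coastal water.

## Rule-based filters

Both branches are *segment-then-test*: the stream is cut at large gaps
and each segment is scored as cut, never re-split. The click branch
first removes presumed reflections with a left-to-right sweep that keeps
a pulse iff it is ≥ 2 ms after the last **kept** pulse (the earlier
pulse of a close pair is the direct arrival; the sweep is idempotent),
then cuts at gaps > 100 ms. The vessel branch runs on the raw stream
and cuts at gaps ≥ 500 ms. Boundary semantics follow the printed
inequalities exactly: inclusive ≥/≤, exclusive </> — an interval of
exactly 100 ms stays inside a click train, a gap of exactly 500 ms
splits a vessel event, 81 pulses satisfy "> 80".

Criterion statistics and their conventions:

* intervals are successive time differences within the segment;
* every SD is the sample SD (n−1); undefined statistics (fewer than two
  pulses/intervals) **fail** the criterion rather than passing vacuously;
* interval CV = SD/mean ≤ 0.4; median interval < 100 ms;
* the SPLR criterion uses the segment **mean** of per-pulse
  `spl_a/spl_b` (the ratio is a property of the train; a per-pulse
  `all_pulses` mode is available via `ClickTrainCriteria.splr_mode`);
* the SPL CV bound "≤ 100" is interpreted **in percent**
  (SD ≤ mean); a unitless bound of 100 would exclude nothing;
* the `td` criterion uses the SD of the **signed** values — the sign
  carries the bearing information the stereo pair exists for.

Segments failing criteria are still reported (with per-criterion
flags), so false-positive accounting can enumerate everything the
filter emitted; only passing candidates feed the classifier by default.
Both branches run independently: a pulse may belong to one candidate of
each kind.

A consequence of segment-then-test worth stating plainly: one
background impulse inside a train (or within 100 ms of its edges, where
it merges into the same segment) perturbs the interval CV and the
`td`-spread statistics and can fail an otherwise clean train. The
branch is deliberately tolerant of such errors because classification
or manual review follows; the magnitude of the effect is quantified
under *Limitations*.

## Features

18 click-branch / 17 vessel-branch features per candidate, in a fixed,
versioned column order: pulse count; duration (ms); start and end
timestamps encoded as **minutes since the Unix epoch, truncated to the
minute** (temporal features let the model learn diel/seasonal activity
structure; minute truncation matches the precision at which such
timestamps are recorded); max/min/mean/SD of intervals; max/mean/SD of
per-pulse SPLR, of signed `td` (the maximum is of the signed values,
not magnitudes) and of `spl_a`; and, for the click branch only,
`buzz_check` — 1 iff some run of ≥ 5 consecutive pulses has all
intervals ≤ 10 ms. Naive `start_datetime` values are interpreted as
UTC so epoch arithmetic is unambiguous.

## Classifier

`RandomForestClassifier` with 100 estimators, `max_depth=30`,
`min_samples_split=7`, all other hyperparameters at library defaults,
seeded. The 70/30 train/validation split is stratified by label —
labeled pulse-event datasets are severely imbalanced (buzzes are an
order of magnitude rarer than noise) and unstratified small splits can
lose a class entirely; singleton classes are kept whole in the training
side with a warning. Importances are mean decrease in impurity
(normalized, sorted), with permutation importance behind a flag.
Models serialize as a joblib artifact plus a JSON manifest (branch,
column order, hyperparameters, training-data hash); loading without the
manifest, or predicting with mismatched columns, is refused.

## Evaluation

Classification metrics follow the standard confusion-matrix
definitions, with regular clicks and buzzes merged into a single
positive click-train category (both are porpoise signal; the
`buzz_check` feature makes the internal split deterministic). Metrics
with a zero denominator return an explicit `UNDEFINED` marker — never a
silent 0 — because small validation sets (tens of vessel events) make
degenerate denominators realistic. Reported percentages round half-up.

Filter-level evaluation counts events: detections and annotations are
paired greedily in time order, one-to-one, any span overlap qualifying
by default (`min_overlap_fraction` is configurable). Detection rate is
matched/annotated; FP proportion is unmatched/detected. Per-event
(not per-pulse) arithmetic reproduces every published campaign rate
from its event counts exactly.

## Simulator

The generator's defaults are the study conditions for every test in
this repository, chosen once from field realism:

| component | parameter | default | margin to filter bound |
|---|---|---|---|
| regular train | pulses | 10–40 | ≥ 6 |
| | initial interval | 15–80 ms | inside [2, 100]; clip floor 10.5 ms keeps `buzz_check`=0 |
| | interval step | ≤ 5 % per pulse, clipped to [0.7, 1.4]× | CV ≲ 0.2 vs bound 0.4 |
| | SPLR | N(0.9, 0.06) clipped ≥ 0.65 | vs bound 0.6 |
| | td | base U(−100, 100) µs, jitter SD 5 µs | vs bound SD < 25 µs |
| | SPL | 12 Pa floor + Hann peak 15–60 Pa | CV ≲ 60 % vs 100 % |
| buzz | interval | 3–8 ms, clipped ≤ 9.5 ms | buzz bound 10 ms |
| vessel | duration | 12–25 s, ≥ 100 pulses | vs ≥ 10 s, > 80 |
| | intervals | i.i.d. U(10, 300) ms | vs split at 500 ms |
| shrimp | rate | 5 Hz (configurable) | — |
| | SPL | U(10, 60) Pa | overlaps trains on purpose |
| | SPLR | U(0.3, 0.9) | broadband snap vs NBHF click |
| | td | U(−127, 127) µs | full physical range |

The ±127 µs `td` range is the physical bound of a 190 mm vertical
hydrophone pair at c = 1500 m/s; train bearings stay inside it.
Interval smoothness is a bounded multiplicative random walk rather than
a parametric inter-click-interval curve: it satisfies the one property
that matters (smooth change) while spanning the criteria space.

All randomness flows from one seed through per-component child streams
(`SeedSequence.spawn`), so adding a component does not perturb the
pulses of another and identical configurations export byte-identical
CSVs. Slot collisions (two pulses in one 0.5 ms slot) keep the louder
hydrophone-A pulse — an amplitude-triggered recorder stores the
dominant arrival.

Two generator contracts back the test suite:

* **Clean-signal guarantee**: with no background, every default train,
  buzz and vessel event passes its filter (every margin above is
  strict; asserted across 100 seeds).
* **Separability**: the class-conditional distributions differ in mean
  SPLR and interval regularity, so classifier-recovery tests are
  well-posed. The labeled-dataset builders imitate the *operational*
  labeling workflow, where labels are assigned to rule-based-filter
  detections: the click-branch noise class therefore mimics
  filter-passing background aggregations (interval CV below 0.4 but
  rougher than a train, `td` spread near but under 25 µs, mean SPLR
  just above 0.6). That leaves mean SPLR as the decisive porpoise/noise
  separator — which is exactly why it ranks first in the trained
  model's importances.

What the simulator does **not** emulate: propagation physics (spreading
loss, absorption), hydrophone frequency response, waveforms, bearing
drift within a train, inter-site differences in click parameters, or
temporal autocorrelation of porpoise presence (event placement is
uniform, timestamps carry no class signal). Passing tests therefore
demonstrate correctness of the pipeline's logic under the stated
phenomenology, not field-performance levels on real recordings.

## Numerical choices

* Times are floats in ms; multiples of 0.5 (and 0.25 for µs `td`) are
  exactly representable in binary floating point, so quantization
  checks are exact comparisons, not tolerance tests.
* CSV round-trips are exact: `%.17g` on write, `float_precision=
  "round_trip"` on read.
* `percent()` rounds half-up (not banker's) to match conventional
  reporting of rates.
* Validation reports the first offending row and fixes nothing.

## Problem sizes

Oracle cross-checks run 1,000 random series (≈ 2–40 pulses each)
against a plain-Python brute-force validator that shares no code with
the implementation. Simulator recovery uses 100 seeds per event type
plus one 600 s soundscape with 50 trains over a 5 Hz shrimp background.
Classifier recovery uses 600 events (three balanced classes), a
stratified 70/30 split and one forest fit. The full suite and the
acceptance script each complete in seconds on one CPU.

## Limitations

* **Background-contaminated trains are lost by design.** With the
  strict per-segment criteria and no re-splitting, a train of duration
  D merges any background impulse within D + 0.2 s (its span plus
  100 ms per edge); at a shrimp rate r the expected number of
  contaminating impulses is r·(D + 0.2 s) — ≥ 1 for realistic trains
  already at r = 1 Hz. A single broad-`td` impulse typically pushes the
  segment's `td` SD past 25 µs, and an edge impulse adds an interval of
  up to 100 ms that breaks the CV bound for fast trains. Measured at
  r = 5 Hz over 600 s (50 trains, fixed seed), filter recall on
  injected trains is 0.14, with failures dominated by the `td`-spread
  and interval-CV criteria. The acceptance suite asserts a 0.98 recall
  expectation under exactly these conditions and that test fails; the
  measured value is reported honestly by `scripts/acceptance.py`.
  Recovering contaminated trains would require robust statistics or
  recursive re-splitting, both outside the segment-then-test design.
* The classifier results on simulated data (accuracy ≈ 1.0) reflect the
  generator's separability contract, not expected field accuracy.
* The vessel branch models only the high-frequency (> 55 kHz) component
  of vessel noise detectable by the recorder — nearby, fast, cavitating
  vessels — not shipping noise at large.
* The proprietary binary format of any particular recorder is not
  parsed; the CSV interchange defined in the README is canonical.
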