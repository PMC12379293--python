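# pulsetrain

Detection and classification of narrow-ridged finless porpoise
(*Neophocaena asiaeorientalis*) echolocation click trains and
high-frequency vessel noise in data from stereo ultrasonic
**pulse-event recorders**.

Pulse-event recorders (such as the A-tag) are long-term passive acoustic
monitors that store no waveform. Whenever the received pressure exceeds
an amplitude threshold (139 dB re 1 µPa by default) they log one row per
ultrasonic pulse: detection time at 0.5 ms resolution, the received
sound pressure on two hydrophones with different peak sensitivities
(A ≈ 70 kHz, B ≈ 130 kHz), and the arrival-time difference between them
at 0.25 µs resolution. Conventional click detectors do not apply to
such event streams, and in coastal waters the streams are dominated by
broadband snapping-shrimp impulses of click-like amplitude. `pulsetrain`
implements a hybrid detector for this setting:

1. **Rule-based filters** segment the pulse stream into candidate
   events. The *click-train branch* removes presumed reflections
   (inter-pulse interval < 2 ms), splits at gaps > 100 ms, and accepts a
   segment only if all nine criteria hold: ≥ 6 pulses; interval
   coefficient of variation CV = SD/mean ≤ 0.4; mean sound-pressure
   ratio SPLR = SPL_A/SPL_B ≥ 0.6 (the narrow-band high-frequency
   porpoise click signature); duration ≥ 12 ms; SD of the stereo
   arrival-time difference < 25 µs (one animal ⇒ one stable bearing);
   SPL CV ≤ 100 %; median interval < 100 ms. The *vessel branch* splits
   the raw stream at gaps ≥ 500 ms and requires > 80 consecutive pulses
   spanning ≥ 10 s.
2. **Feature extraction** summarizes each candidate with 18 (click) or
   17 (vessel) values: pulse count, duration, minute-truncated start/end
   timestamps, and max/min/mean/SD statistics of intervals, SPLR,
   arrival-time difference and hydrophone-A SPL, plus `buzz_check` — 1
   iff the event contains ≥ 5 consecutive pulses at intervals ≤ 10 ms
   (the terminal-buzz feeding signature).
3. **Random forests** (100 trees, depth 30, minimum split 7; stratified
   seeded 70/30 split) classify click-branch candidates into
   regular clicks / buzzes / noise and vessel-branch candidates into
   vessel / non-vessel.
4. **Evaluation**: accuracy, precision, recall, F1 = 2·P·R/(P+R) and
   FPR = FP/(TN+FP), with regular clicks and buzzes merged into one
   positive click-train category; plus filter-level detection rate
   (recovered fraction of annotated events) and FP proportion
   (unmatched fraction of detections) via greedy one-to-one span
   matching.
5. A **seeded soundscape simulator** generates click trains with
   smoothly varying intervals and SPL, buzzes, vessel noise and
   snapping-shrimp background — with exact ground truth — so the whole
   pipeline is testable without field recordings.

## Worked example

```python
from pulsetrain import *

config = SimConfig(duration_s=300.0, seed=11, n_click_trains=8, n_buzzes=2,
                   n_vessels=1, shrimp_spec=ShrimpSpec(rate_hz=0.5))
series, truth = simulate_soundscape(config)
print("pulses:", len(series), "ground-truth events:", len(truth))

clicks = passed_events(detect_click_trains(series))
vessels = passed_events(detect_vessel_events(series))
click_truth = [a for a in truth if a.label in ("regular_click", "buzz")]
print("click filter:", filter_evaluation(clicks, click_truth).as_percent())

dataset = make_labeled_click_dataset(n_events=600, seed=11)
tr, va = split_train_validation(dataset, seed=11)
model = train(tr, RFHyperparams(seed=11))
print("held-out accuracy:", (predict(model, va.features) == va.labels).mean())
print("top importances:", [(n, round(v, 3)) for n, v in importances(model)[:3]])
```

prints

```
pulses: 518 ground-truth events: 11
click filter: {'detection_rate': 80.0, 'fp_proportion': 0.0}
held-out accuracy: 1.0
top importances: [('av_splr', 0.198), ('sd_td_us', 0.143), ('av_pi_ms', 0.125)]
```

The simulated five-minute recording contains 8 regular trains, 2 buzzes
and 1 vessel passage over a light 0.5 Hz shrimp background. The filter
recovers 8 of the 10 porpoise events with no false positives — the two
misses are trains spoiled by a background impulse landing inside the
segment, which inflates a criterion statistic past its bound; this
behavior of strict per-segment criteria under impulsive background is
expected and is quantified in `docs/methods.md`. On a labeled simulated
dataset the classifier separates the three click-branch classes
perfectly, and the mean sound-pressure ratio (`av_splr`) is the most
important feature, as it is the one physical quantity that
distinguishes narrow-band high-frequency porpoise clicks from broadband
noise.

The same workflow is available from a shell:

```sh
pulsetrain simulate --duration 300 --seed 11 --out pulses.csv --annotations truth.csv
pulsetrain detect --pulses pulses.csv --out-prefix cand
pulsetrain evaluate --detections cand_click.csv --annotations truth.csv --branch click
```

## File formats

* Pulse CSV: `t_ms,spl_a_pa,spl_b_pa,td_us` (+ optional JSON sidecar
  with `start_datetime`, `threshold_db`, site metadata). SPLs are
  linear pressures relative to 1 Pa; `td_us > 0` means the pulse
  reached hydrophone A first.
* Annotation CSV: `t_start_ms,t_end_ms,label` with labels from
  `regular_click, buzz, click_train, vessel, noise`.
* Candidate CSV: spans, pulse count, `passed`, one column per
  criterion flag. Feature CSV: `event_id,kind` + the fixed feature
  order above.
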