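# Methods

## Signal model

Each insole reduces its plantar pressure field to six binary channels: a
pressure-sensing unit (PSU) outputs 1 while the local pressure *reaches or
exceeds* its mechanical threshold (comparison is inclusive, `>=`). Default
thresholds are 50 kPa at the heel (S1), 20 kPa at the two forefoot units
(S4, S5), and 27.5 kPa — the mid-range of the 20–35 kPa production variants
— at the three metatarsal units (S2, S3, S6). Both insoles sample at 32 Hz;
time is sample-indexed, sample `n` covering `[n·Δt, (n+1)·Δt)` with
`Δt = 1/32 s`. No wall-clock timestamps exist in the core model, and left
and right streams must already share rate and origin (no resampling shim; a
mismatch is an error).

The per-foot combined signal is the sample-wise OR of the six channels:
1 = foot loaded (single support), 0 = airborne (swing). Foot-strike and
foot-off are its 0→1 and 1→0 transitions; an event's time is the first
sample of the new state. Double support is the AND of the two combined
signals.

## Segmentation conventions

Maximal constant runs become phase episodes with half-open intervals: a run
over samples `a..b` maps to `[a·Δt, (b+1)·Δt)`, so duration = run length ×
Δt — this is also the largest value the running accumulator attains inside
the episode, making "peak duration" and episode duration the same number.
Episodes touching a recording boundary are flagged `truncated`: their
durations underestimate the true phase duration.

Truncation handling follows from the direction of each comparison:

* calibration excludes truncated episodes (an underestimate biases a mean);
* short-swing classification excludes truncated swings (a `<=` comparison
  on an underestimate would false-alarm);
* long-double-support flagging *keeps* truncated episodes: a `>=` threshold
  crossed by an underestimated duration is still crossed, and a causal
  online detector necessarily fires on a trailing truncated episode once
  its accumulator crosses. Excluding them offline would break the exact
  offline/online equivalence that the streaming model guarantees.

## Detection

Calibration pools both feet for the swing baseline and uses the bilateral
double-support episodes for the double-support baseline; at least 8
non-truncated episodes per phase (and per foot for swings) are required.
The swing index uses the reciprocal of the *mean* swing duration (not the
mean of reciprocals).

Decision rules, with calibration means `T̄_DS`, `T̄_SW`:

* double-support episode flags iff `duration >= k_DS · T̄_DS`;
* swing is short iff `duration <= T̄_SW / k_SW`; the `m_SW`-th consecutive
  short swing of the same foot flags (default `m_SW = 2`; the other foot's
  activity never resets a counter, only a non-short swing of the same foot
  does);
* FoG at a sample iff either index covers it (the per-sample flags are
  taken from the pre-merge events so this identity is exact).

Raw events — one per flagged double-support episode, one per maximal run of
`>= m_SW` consecutive short swings — are merged when separated by less than
`merge_gap = 0.5 s` (below one gait cycle), keeping the first constituent's
kind and the earliest onset. Onsets: the long-DS onset is
`episode start + ceil(k_DS·T̄_DS/Δt)·Δt` (the accumulator-crossing sample);
the short-swing onset is the foot-strike ending the `m_SW`-th short swing.

The online detector is a per-sample state machine over (left, right) bits
and reproduces the offline raw events exactly on any finite stream; this
dual route (vectorized episode-wise vs causal sample-wise) is property
tested on randomized streams.

## Streaming and cueing

Transport batches 8 consecutive samples per packet; a packet is delivered
at its last sample's capture time plus a configurable transmission delay
(default 0 — radio latency is out of scope). A sample's availability delay
therefore spans `[delay, (packet_size−1)/Fs + delay]`, and the packet
period `packet_size/Fs` (0.25 s at defaults) bounds the decision-time
spread. A trailing partial packet is flushed so finite recordings replay
completely. An event's decision time is the later of its algorithmic onset
and the delivery of the triggering sample; packetization shifts decision
times, never decisions. The cueing controller activates on the first
delivered onset and returns to idle only after 30 s of continuous normal
gait; any FoG during the countdown clears the timer. Wear-life arithmetic
uses a 30.44-day month.

## Threshold training

Every non-truncated double-support episode and every maximal same-label run
of consecutive same-foot swings becomes a labeled instance on the
dimensionless ratio axis (`duration/T̄_DS`; `T̄_SW/min swing in run`).
Labeling is kind-aware: double-support instances are fog only when they
overlap a long-double-support truth interval, swing runs only when they
overlap a same-foot shuffling interval — the two indices respond to
different FoG manifestations and are trained independently. (Plain
any-overlap labeling would mark the ~0.2 s double supports inside shuffling
episodes as fog and collapse the double-support fuzzy zone into the
normal-gait range.)

The fuzzy zone is bounded by the largest normal and smallest fog ratio
(stored sorted). Candidates run over the zone in steps of 0.1 (the
precision of the reference values 4.7/4.5); classification at training uses
the same inclusive `>=` as detection. The maximizer of
sensitivity + specificity is returned; on ties, the midpoint of the longest
maximal-scoring contiguous grid interval, rounding to the lower grid point
on an exact half. Sensitivity is non-increasing and specificity
non-decreasing along the grid by construction, and this is asserted during
training.

## Evaluation

Event matching expands truth intervals by a tolerance (default 0.5 s,
absorbing annotation jitter between video and sensor clocks) and matches
predictions greedily one-to-one in time order. Sensitivity, specificity and
accuracy are event-framed: TP/FN are matched/missed truth episodes, FP
unmatched predictions, TN normal-labeled instances left unflagged.

The correct/over/under accounting mirrors the clinical reminder audit: the
correct-detection percentage counts *predictions verified against truth*
(several reminders during one long freeze are each verified — matching is
many-to-one here), while under-detection counts distinct truth episodes
missed. Correct + over = 100 by construction.

## Synthetic generator

The generator emulates the temporal structure the detector consumes, not
ground-reaction-force biomechanics:

* normal gait: alternating steps with swing ~ N(0.45 s, CV 8 %) clipped to
  [0.30, 0.65] s and double support ~ N(0.15 s, CV 8 %) clipped to
  [0.06, 0.32] s; 10 % of double supports are widened ×1.5 to stand in for
  turns (the detector consumes only temporal structure, so turns are not
  modeled spatially);
* stance pressures are stylized heel-then-forefoot loading (heel 120 kPa
  over the first 55 % of stance, forefoot 80 kPa from 35 % to toe-off —
  amplitudes are synthetic conveniences chosen to clear the thresholds with
  margin); binary streams are produced by the same binarization contract as
  hardware;
* akinesia: both feet fully loaded; tremble: both heels loaded while one
  forefoot oscillates about its threshold at 4–8 Hz (ground contact never
  clears, so it presents as long double support — labeled LDDS); shuffle:
  one foot (chosen uniformly) takes swings of U[0.05, 0.12] s between 0.2 s
  flat-footed stances while the other stays loaded (labeled SSW for that
  foot);
* episode durations follow LogNormal(μ, σ = 0.8) truncated by *rejection*
  (no atoms at the bounds) to [0.4, 31.8] s, with μ solved deterministically
  (Brent) so the truncated mean equals 2.4 s, the clinical cohort mean;
* episode starts follow a Poisson process at 2/min, rejecting arrivals in
  the first 30 s (reserved clean calibration window), within 2 s of the
  previous episode, or overrunning the last 2 s of the recording — the two
  margins keep injected episodes non-truncated and non-merging;
* all randomness flows from one seed; equal configurations are
  bit-identical.

Truth intervals record the *realized* episodes. Freezes are injected at
gait-phase seams: normally the airborne foot's swing is extended to land
exactly at the planned start; when the walker reaches the seam with both
feet loaded, the long-double-support interval starts at the moment both
feet actually became loaded (slightly before the planned start) and the
truth reflects that. Shuffle episodes shorter than ~0.55 s physically fit
fewer than two short swings and are undetectable by construction; they stay
in the truth and count as misses.

What passing tests on this generator do and do not show: the synthetic
cohorts are separable by construction (injected long double supports are at
least 0.4 s against a ~0.15 s baseline; shuffle swings at most 0.12 s
against a ~0.45 s baseline), so they validate the machinery — calibration,
training, the exact offline/streaming equivalence, latency bookkeeping —
under the stated study conditions, not the clinical difficulty of the
original cohort. The clinically reported thresholds (4.7/4.5) come from
undeposited patient data and are shipped as reference defaults; thresholds
trained on the synthetic cohorts land lower (k_DS ≈ 2.5) because the
synthetic normal/fog gap sits closer to the baseline.

## Problem sizes and numerics

The cohort protocol uses 20 recordings × 180 s (seeds 1–20: train on 1–10,
test on 11–20), ~5 episodes per recording — comfortably enough events for
stable event-level rates while keeping a full run in seconds. Numerical
conventions: inclusive comparisons carry a 1e-9 guard; accumulator
crossings use `ceil(x/Δt − 1e-9)`; the location solve brackets
`[log(low) − 6σ, log(high) + 6σ]` with xtol 1e-9 and verifies the truncated
mean to 1e-3 s; the truncated-mean closed form
`e^{μ+σ²/2}·(Φ(β−σ)−Φ(α−σ))/(Φ(β)−Φ(α))` is cross-checked against
quadrature in the tests.

## Known limitations

* Square-edged synthetic pressures: no load ramps, sensor bounce, drift, or
  dropout; the binarization boundary case is exercised by constructed
  traces instead.
* The paper-style mean response time mixes algorithmic and radio latency;
  only the packet-period component is modeled (transmission delay defaults
  to 0), so measured decision latencies here are not comparable to
  field-reported response times.
* Swing-run training instances use the shortest swing of the run, so a
  trained `k_SW` near the fuzzy-zone midpoint can leave individual swings
  in the upper shuffle range (0.10–0.12 s) unclassified as short,
  fragmenting one freeze into several detector events; the verified-reminder
  accounting treats such fragments as correct detections, as a human audit
  would.
* Medication-state drift is not modeled; it can only be emulated by
  re-running the generator with altered means.
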