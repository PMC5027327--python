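# Methods

This note documents the models, parameters, and numerical choices behind
`neurotree`, and what the synthetic study conditions do and do not establish
about real recordings.

## Synthetic EEG sessions

A session emulates a blindfolded object-handling protocol: three solid shapes
(ball, cube, parallelogram) handled in labelled epochs separated by rest
("interval") epochs, recorded on a 32-channel 10-20 cap.

**Signal model.** Every channel carries band-limited Gaussian background
activity: white noise filtered to 0.3–100 Hz (4th-order Butterworth, applied
forward-backward so the noise itself has no phase distortion) and scaled to a
baseline RMS of 20 μV — a typical scalp-EEG magnitude well inside the
physiological 0–200 μV envelope. During an object epoch, channels over the
lobes active for that object additionally carry an alpha-band (8–13 Hz)
band-limited Gaussian burst with RMS `burst_gain × 20 μV`; the default
`burst_gain = 4` makes the burst dominate in-band background power by roughly
an order of magnitude after filtering, i.e. a strong, cleanly separable
effect. If the summed signal exceeds the 200 μV cap anywhere, the whole
recording is rescaled by one common factor — clipping would distort the
relative band power that the downstream features measure.

**Study conditions.** The raw sampling rate is 512 Hz (configurable; only the
post-averaging instance rate matters downstream). Each object epoch lasts
2.5 s: at 512 Hz with 32-sample buffers this produces exactly 40 feature
instances per object epoch, so the minority classes enter balancing at 40 —
the cardinality the rest of the bookkeeping (160 balanced, 16 grouped
instances) is built on.

**Subject profiles.** Each object class activates a distinct lobe signature:

| class | sighted | blind |
| --- | --- | --- |
| ball | occipital | frontal |
| cube | parietal | parietal |
| parallelogram | frontal | frontal + parietal |
| interval | — | — |

Distinctness matters: because each lobe is *necessary* to separate some pair
of classes, its presence in the induced tree is diagnostic of signal rather
than of redundancy-resolution order. The sighted union
(occipital + frontal + parietal) and blind union (frontal + parietal) encode
the modeled physiology: sighted subjects recruit visual imagery (occipital)
for the most "visual" shape, blind subjects substitute executive and tactile
processing.

**What the simulator does not model:** volume conduction between channels,
1/f ("pink") spectral slope, eye-blink and muscle artifacts, non-stationary
burst envelopes, inter-subject amplitude variability. Passing tests therefore
show that the *pipeline* recovers lobe-level structure planted under its own
assumptions — a mechanism check, not evidence about any real population.

## Preprocessing chain

Per channel: 4th-order Butterworth band-pass 3.5–30 Hz (keeping theta, alpha,
beta), elementwise squaring (`x*x`, removing signs), then the mean over
non-overlapping 32-sample buffers, each buffer becoming one instance. The
filter order is configurable (4 is a common BCI default; the band edges are
the pipeline's fixed analysis band). Filtering is causal (forward-only) by
default, matching real-time semantics; zero-phase filtering is available as
an option. An instance's class is the majority epoch label within its buffer,
with ties broken toward "interval" so ambiguous buffers are never credited to
an object. `Time` is a 1-based instance index. Trailing partial buffers are
dropped rather than padded — padding would inject synthetic amplitudes.

## Table preparation

Order: channel subset (optional) → balance → normalize → group.

- **Balancing**: uniform seeded undersampling of every class to the
  minority-class count. The balanced table is emitted in class blocks
  (classes by first appearance, within-class time order preserved). The
  blocked layout is deliberate: rest epochs recur between objects, so
  time-interleaved output would fragment the rest class into short runs and
  the grouping stage — which never lets a window cross a class boundary, so
  that no grouped instance mixes classes — could not produce the expected
  four groups per class.
- **Normalization**: per-column min-max to [0, 1]; constant columns map
  to 0. Normalizing before grouping (rather than after) preserves which
  instance holds the column peak while changing only the scale of
  thresholds. A side benefit exploited by the inducer: all attributes end up
  on a common scale, making threshold margins comparable across electrodes.
- **Peak grouping**: windows of 10 consecutive same-class instances
  (≈ 0.6 s of signal at the default rates; one instance per second at a
  320 Hz raw rate) collapse to per-channel maxima; the grouped `Time` is the
  window's maximum; trailing partial windows are dropped. Peak pooling makes
  each instance a burst-envelope summary and is the step that suppresses the
  overfitting large instance-level trees exhibit.
- **Channel subsets**: a 12-electrode reduced montage is supported; the
  default list in `prep.DEFAULT_CHANNEL_SUBSET_12` is an explicit stand-in
  configuration, not a canonical set.

## Tree induction

Binary threshold splits on numeric attributes, chosen by gain ratio; split
candidates are midpoints between consecutive distinct sorted values;
candidates are admissible when both sides keep at least the minimum leaf
count (a fraction of the training set, converted by ceiling, so 1% of 16 is
still 1) and information gain is strictly positive. Growth stops at purity,
at fewer than twice the minimum leaf count, or when no admissible split
exists.

**Tie-breaking.** On peak-grouped 16-instance tables, exact gain-ratio ties
are the norm: every split that separates whole classes cleanly scores exactly
1.0, and with 32 electrodes a chance-perfect ordering on an uninformative
channel regularly ties with a genuinely discriminative one. Selection is
therefore lexicographic: highest gain ratio, then **widest value gap at the
threshold** (margins are comparable because all attributes are min-max
scaled), then lowest attribute index, then lowest threshold. The margin
criterion is what keeps attribution meaningful — a channel separating classes
by a wide normalized gap is preferred over one separating them by luck —
while the final index/threshold keys keep induction fully deterministic given
table order. Without the margin rule, tie resolution would follow montage
column order, and a lobe's appearance in the tree would partly be an artifact
of where its electrodes sit in the CSV header.

**Pruning.** Pessimistic subtree replacement: a subtree collapses to a leaf
when the leaf's upper-confidence-bound error estimate (normal approximation
with continuity correction, confidence factor 0.25, with the customary
small-error interpolation for leaves with fewer than one observed error) does
not exceed the sum over its leaves plus a 0.1-instance slack. Subtree raising
and the MDL correction on numeric-split gain are deliberately omitted — they
complicate the inducer without affecting the lobe-recovery mechanism — so
induced trees can differ from a full J48 implementation in borderline splits.

**Attributes.** By default only electrode columns are split candidates.
`Time` is carried as metadata and can be opted in explicitly; under blocked
balancing each class occupies one contiguous index range, so the instance
index is a perfect class proxy that would shadow every electrode and empty
the attribution of meaning.

Missing values are unsupported (the pipeline never produces them). The
paper-of-record for evaluation here is resubstitution (training-set)
accuracy: the goal is pattern discovery on the analyzed session, not
generalization, so no cross-validation machinery is included.

## Rule extraction and attribution

One rule per leaf, conditions in root-to-leaf order; the rule set is mutually
exclusive and jointly exhaustive over the attribute space. Trees render as
indented if/else text and as DOT digraphs (thresholds to 3 decimals).

A lobe counts as showing "significant activity" for a subject iff at least
one of its electrodes appears as a split attribute anywhere in the final tree
— any-node presence, not root-only; split depth is reported but not used.
The electrode→lobe map covers the full 32-channel montage by prefix rules
(Fp/F/FC/FT → frontal, T/TP → temporal, C → central, CP/P → parietal,
O → occipital), extending the classical four-lobe electrode listing with the
central and centro-parietal sites that real trees select.

## Problem sizes and determinism

Default sessions are 15 s × 32 channels at 512 Hz (≈ 0.25 M samples), chosen
so a full subject — generation through attribution — runs in well under a
second and the 20-vs-20 subject mechanism experiment in seconds. All
stochastic stages (noise, bursts, balancing) are driven by explicit integer
seeds; identical configurations are bit-reproducible, and the multi-subject
experiment manifest records every seed and parameter next to its output
files.

## Known limitations

- The simulator's burst-vs-baseline contrast is strong by design; the
  pipeline's behaviour under marginal effect sizes is exercised only by the
  `burst_gain` monotonicity property, not by the acceptance-level checks.
- Pruning estimates are heuristic (as in the original pessimistic scheme);
  no statistical guarantee attaches to pruned-tree error.
- With 16-instance tables, chance-perfect splits on uninformative electrodes
  tie with informative ones at gain ratio 1.0; the margin tie-break makes
  the informative electrode win under the default effect size but cannot
  help when the effect is within noise.
- Lobe attribution is presence-based and does not quantify effect strength;
  it inherits every caveat of interpreting tree structure causally.
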