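# Methods

## Problem and model

The package classifies 30 s intracranial-EEG epochs into two states:
*interictal* (far from any seizure) and *preictal* (the L minutes before a
lead-seizure onset). The working assumption is that of the seizure-prediction
literature: some spectral change precedes (some) seizures, its onset time is
unknown and patient-specific, and a classifier trained at the *right* L sees
a coherent preictal class, while a too-long L dilutes the class with
unchanged background. The pipeline therefore treats L, the electrode count
k, and the sampling rate fs as the experimental variables, not as fixed
preprocessing choices.

## Interval algebra

Seizure annotations are half-open intervals `[onset, termination)` in
seconds from recording start. Grouping into series uses a linear scan:
consecutive events belong to one series iff the next onset is less than the
merge gap after the previous event's onset. The gap reference point
(onset-to-onset vs termination-to-onset) is not fixed by the definitions we
follow; onset-to-onset is the default because ictal durations are one to two
minutes against gaps of an hour, making the difference negligible, and the
alternative is available as `gap_reference="termination"`.

The merge gap is 60 min for L ≤ 30 and L + 30 min for L ∈ {60, 120}, so a
lead seizure's preictal and postictal windows always fit between series.
Labeling priority where definitions overlap is ictal > postictal > preictal;
a preictal window clipped (by the recording start or a preceding series)
below half of L flags its lead seizure, and flagged preictal intervals are
excluded from epoch extraction rather than silently dropped. A time point is
interictal iff it lies farther than 3 h from *every* lead onset, in both
directions; everything else not otherwise labeled is `unused` and never
sampled. The labeling is validated as an exact partition of
`[0, duration)`.

Open point, resolved: the 3 h interictal margin is measured from lead onsets
only (not from every seizure), and postictal time beyond 30 min that is
still within 3 h of a lead onset stays `unused`.

## Featurization

* Resampling: polyphase anti-aliased decimation (scipy `resample_poly`)
  directly from the native rate to each target rate, never chained.
* Band-pass: 4th-order Butterworth applied forward–backward (zero phase),
  0.5–50 Hz at 128 Hz and 0.5–90 Hz at 256/512 Hz. At 60 Hz — a quarter
  octave above the 50 Hz edge — this design leaves about 2% of the power;
  one octave beyond the edge the attenuation exceeds 20 dB by a wide margin.
  Line noise is handled not by the filter but by the 55–64 Hz bin mask below.
* Epoching: interictal epochs use a fixed 30 s step (no overlap; interictal
  time is abundant). Preictal epochs use the largest step (searched on a
  0.5 s grid with a 1 s floor) whose total count reaches the interictal
  count from above; if even the floor step cannot reach it, the floor is
  used and the shortfall is reported. Epochs never cross interval
  boundaries.
* STFT: per channel, 1 s Hamming window, 0.5 s hop, no epoch padding —
  giving floor((30fs − fs)/(fs/2)) + 1 = 59 frames at every supported rate
  and exactly 1 Hz bin spacing. The per-channel epoch mean is removed first
  so DC does not leak into bin 0. Retained bins: 0–64 Hz (65 bins) at
  128 Hz; 0–90 Hz minus 55–64 Hz inclusive (81 bins) at 256/512 Hz.
* Scaling: magnitudes are compressed as log(1 + |S|) (an unstated choice in
  the protocol, standard for spectrogram-CNN inputs), then standardized per
  channel using statistics computed on the training split only — the split
  is made before standardization precisely so that no test statistics leak
  into the normalization.

## Dataset assembly

Balancing precedes splitting: the majority class is randomly under-sampled
without replacement to the minority count (exact 1:1). The 6:2:2 split is
stratified by class — the protocol says only "randomly split", but the
balanced design clearly intends 1:1 within each subset, and stratification
costs nothing. All randomness flows from one named seed per run through
`numpy.random.SeedSequence`; derived seeds are logged in every result row.

Two split modes exist:

* `epoch` (default, protocol-faithful): epochs assigned uniformly at random.
* `block`: contiguous time blocks per class, circularly rotated by the seed.

The distinction matters whenever preictal epochs overlap. With a short L and
few lead seizures the equalization step produces heavily overlapping
preictal epochs (e.g. a 2 s step at L = 5 with one lead: adjacent epochs
share 93% of their samples), and an epoch-level random split then places
near-duplicates of each test epoch in the training set. Measured on the
synthetic cohort with *zero* planted effect, an epoch-split run reaches test
accuracy 1.0 purely by segment memorization; the block split stays at
0.54–0.57. The synthetic end-to-end study therefore uses block mode
throughout, and the epoch mode remains the default for runs that mirror the
original protocol (documented optimism).

## Classifier

Architecture is declared as data (`ArchitectureSpec`) and consumed both by
the model builder and by a closed-form parameter count:

    conv: out·(in·kh·kw) + out        batch norm: 2·out (γ, β)
    fc1: flatten·256 + 256            fc2: 256 + 1

with valid (unpadded) convolutions and pools, flatten after the third pool.
This configuration is pinned by four printed percentages it must reproduce
(parameter ratios 60.9/63.1/67.4% across montage sizes and 86.2% across
rates); the tests verify the closed form against enumeration of instantiated
weight arrays for every (n, F) combination used.

Training: RMSProp with smoothing constant 0.99 and ε = 10⁻⁸ (the defaults of
the framework the protocol was originally implemented in), learning rate
5·10⁻⁴, momentum 0.9, coupled weight decay 10⁻⁶; binary cross-entropy on
logits (numerically stable softplus form); He-normal initialization;
mini-batches of 32; early stopping monitors validation loss with patience 10
(max 100 epochs) by default and restores the best weights. An improvement
must exceed 10⁻⁶ to reset the patience counter. Batch-norm biases make conv
biases redundant; they are kept anyway because the parameter accounting
includes them. Dropout (p = 0.5) acts only on FC1. Evaluation thresholds the
sigmoid at 0.5 with preictal as the positive class; ratios with empty
denominators (e.g. precision with no positive predictions) are reported as
explicit nulls, never as 0.

Everything is deterministic given the seed: identical data and configuration
reproduce bit-identical training histories.

## Synthetic generator

The generator emulates the features of presurgical recordings the pipeline
depends on — not the biophysics. Per channel: 1/f-weighted Gaussian noise
(Kellet IIR approximation, scaled to 50 µV SD) plus a 10 Hz alpha rhythm
(10 µV × U(0.5, 1.5), random phase). Defaults: 24 channels at a 1600 Hz
native rate. Seizures come in clusters (intra-cluster onset gaps < 60 min,
so a cluster collapses to one lead seizure under the 1 h rule; inter-cluster
gaps > 5 h), with one of three ictal morphologies rendered at full amplitude
on affected channels and 20% elsewhere: 70–90 Hz low-voltage fast activity
with background suppression, ~5 Hz trains of high-amplitude Ricker-like
polyspikes, or large sawtooth-sharpened 3–12 Hz waves.

The preictal transition multiplies 30–50 Hz band power by (1 + effect size)
on the m top-ranked channels during [lead − τ·60 s, lead), rising with a
30 s cosine ramp to avoid an artificial edge. The gamma band was chosen
because preictal gamma changes are the recurring finding in this literature,
and it makes the rate sweep meaningful: the 0.5–50 Hz band at 128 Hz clips
part of the signature. The ranked-channel list places affected channels
first (in random order), exactly the input format the real-data path expects
from clinicians.

What the generator does **not** model: artifacts, electrode drift,
nonstationary background, sleep–wake cycles, inter-patient heterogeneity of
the transition, or any dipole/forward physics. Passing the end-to-end tests
therefore shows the pipeline recovers a known spectral transition under
controlled conditions — it says nothing about clinical performance.

## Study sizes

The synthetic end-to-end study uses 3 patients × 8 channels (4 affected),
5.5 h recordings with one 3-seizure cluster at ~4 h, effect size 2, τ = 5
min, featurized at 256 Hz with 120 epochs per class, trained with max 40
epochs and patience 5, three training seeds. The 5.5 h duration is the
shortest that leaves interictal time under the 3 h margin with a margin of
safety; the per-class cap and the training-loop bounds keep a full study run
in minutes on one CPU while leaving the learning outcome unambiguous
(matched-L accuracy 1.0 vs mismatched-L ~0.5 and a null control inside the
99% binomial band around 0.5).

## Known limitations

* The EDF writer covers the classic 16-bit layout with 1 s records and
  integer rates only — sufficient for round-tripping synthetic cohorts, not
  a general EDF+ implementation.
* Epoch-level splits overstate generalization when epochs overlap (see
  above); leave-one-seizure-out evaluation and alarm-time metrics
  (sensitivity / false-prediction rate per hour) are out of scope.
* `best_L` selection uses patient-averaged accuracy only.
* The CPU network is practical for the matrix sizes used here (tens of
  milliseconds per training batch), not a general deep-learning substrate.
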