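# Methods

This note documents the models, conventions and parameter choices behind
`holterpaf`, in the order data flows through the pipeline, and states what
the synthetic cohorts can and cannot demonstrate.

## Input model

A Holter exam is a 3-channel sampled voltage signal (millivolts; channels
modified V5, modified V1, lead III) at a nominal 128 Hz, clock-anchored:
sample *k* occurs at `start_time + k/fs`.  Beat annotations label sample
positions NORMAL, SVE (supraventricular ectopy), VE (ventricular ectopy) or
OTHER.  Records are read and written in the WFDB/MIT convention (text
header, 16-bit little-endian signal file, MIT byte-pair annotation file);
the writer chooses per-channel gain to span most of the 16-bit range, so
round-trip error is below one quantization step (~max|x|/30000 mV).  The
annotation dialect is a fixed declared convention: N/L/R → NORMAL,
S/A/a/J → SVE, V → VE, everything else → OTHER.  Cohort metadata travels as
a CSV manifest (`patient_id, paf_label, index_date, exam_date, record_path,
annotation_path`, ISO-8601 dates); pAF rows must carry an index date (the
date AF was first documented), controls leave it blank.

## Preprocessing

* **Ectopy excision.** Around every VE beat, the window [beat − 3.5 s,
  beat + 3.5 s] is removed; the same window also removes T-wave turbulence
  following the ectopic beat and covers couplets.  Under *setting 2* the
  same excision is applied to SVE beats, leaving pure sinus rhythm; under
  *setting 1* SVE-containing segments are retained and flagged.
  Overlapping windows merge; interval arithmetic is exact and tested
  against a per-sample brute-force oracle.
* **Segmentation.** Each kept interval is tiled from its start with
  non-overlapping 7-s windows (896 samples per channel at 128 Hz); short
  remainders are discarded.  Non-overlap keeps segment counts
  interpretable; no stride/phase tuning is attempted.
* **Noise gate.** The learned-plus-manual noise triage a clinical workflow
  would use is replaced by a deterministic rule-based gate: a segment is
  dropped if any channel is flatline (variance < 1e-6 mV²), saturated
  (> 5 % of samples at ≥ 5 mV) or out of physiological range (> 10 mV).
  Thresholds are exposed as arguments and decisions operate on raw
  amplitudes, before normalization.
* **Normalization and STFT.** Per-channel Z-normalization (zero-variance
  channels map to zeros); then a short-time Fourier transform with a Hann
  window of 50 samples, hop 25 (half-window), no padding, log(1 + |X|)
  scaling.  The resulting spectrogram is 3 × 26 × 34 (channels × frequency
  bins × frames).  Only the window size is canonical; Hann/hop/log1p are
  standard signal-processing defaults, all configurable.
* **Diurnal tag.** A segment is NIGHT iff its *start* time lies in
  [22:00, 07:00), half-open at both ends so boundary segments are counted
  once; windows straddling a boundary follow their start time.
* **Labels.** Every segment inherits its patient's pAF label — the
  weak-supervision assumption that makes segment-wise pretraining possible:
  most sinus segments of a pAF patient are presumed to carry some substrate
  signature, and mislabeled (signal-free) segments act as label noise.

## Stage 1 — residual CNN segment encoder

2-D convolutions run over (frequency × time) with the three leads as input
channels.  Each residual block is [conv → batch-norm → ReLU] × 2 with an
identity shortcut (1×1 strided projection when shape changes); blocks after
the first downsample by stride 2.  Global average pooling feeds a linear
layer to the latent dimension (ReLU; this is the exposed embedding) and a
final linear layer yields one logit.  Defaults: 3 blocks of widths
(16, 32, 64), 3×3 kernels, latent 32, Adam at learning rate 1e-4, batch
size 1024, early stopping on validation loss (patience 5) with a
patient-wise validation split so no patient straddles train/validation.
Inverse-prevalence loss weighting is available but off by default.

The network and its training loop are implemented directly in NumPy
(im2col-style convolution, explicit backward passes, Adam); gradients are
verified against central differences in the test suite, and training is
bit-deterministic given the seed.  Desk-scale runs in the tests and the
acceptance script use a reduced instance of the same architecture —
widths (8, 16, 32), latent 16, learning rate 1e-3, batch 128, ≤ 10 epochs,
and at most 1,200 training segments per fold — so a full 5-fold experiment
on a 60-patient cohort completes in a few minutes on one CPU.  These are
scale choices, not architectural changes; the wide defaults remain
available through configuration.

## Stage 2 — temporal aggregation + gradient boosting

Variable-length latent sequences become a fixed vector by dividing the
recording span into B equal clock-time bins (default B = 24, one per hour
of a 24-h exam): per bin the mean latent, mean segment probability,
segment count and an empty-bin flag; globally the probability mean, max
and SD, the fraction of SVE-containing segments (structurally zero in
setting 2) and the total count.  Length is B·(d+3)+5.  Empty bins
contribute zeros with the flag set; a patient with zero segments yields an
all-empty vector that is still a valid prediction input.  Segment
probabilities are included alongside latents because the classification
head is trained information; both-or-latents-only is configurable at the
feature level.  The classifier is LightGBM (binary objective,
deterministic single-thread mode) with small-cohort defaults
(200 trees, learning rate 0.05, 15 leaves, `min_child_samples` 3,
`min_data_in_bin` 1 so that splits remain possible at a few dozen
patients); an
optional seeded random search over a small grid with inner stratified CV
stands in for heavier hyper-parameter tuners, which are deliberately out
of scope.

## Baseline

SVE burden = fraction of retained setting-1 segments containing at least
one SVE beat, used directly as the pAF score.  Computed after VE excision
and gating so model and baseline share a denominator.  Patients with zero
segments are excluded with a logged warning.

## Evaluation protocol

Stratified patient-level k-fold CV (default k = 5), seeded and
deterministic.  Within each fold the encoder sees only training-fold
segments, every patient is then embedded, the GBM trains on training-fold
patients, and test-fold patients receive scores; leakage is asserted
programmatically.  AUROC is the normalized Mann–Whitney U (ties one half).
The operating cutoff maximizes sensitivity + specificity over observed
scores; ties break toward higher sensitivity, then the lower threshold;
prediction is positive iff score ≥ cutoff.  Undefined ratios (zero
denominators) are reported as absent, never as zero.
F<sub>β</sub> = (1+β²)·PPV·sens / (β²·PPV + sens) with β = 1, 2, and 0 by
convention when both inputs vanish.

CIs: model metrics get mean ± t(k−1, 0.975)·SD/√k across folds; the
baseline gets a 1,000-replicate percentile bootstrap over patients, with
replicates redrawn until both classes are present (bounded retries) and a
refusal if the metric is undefined on most replicates.  Headline AUROC is
reported both as the fold mean and pooled over all cross-validated
predictions.

Diurnal analysis re-runs the entire two-stage pipeline on period-filtered
segments (filter applied before both training stages, same folds).
Elapsed-time analysis converts exam − index to months of 30.44 days and
reports the detection rate at the chosen cutoff among pAF patients with
elapsed time above and below each T ∈ {3, 6, 12, 36}; a patient with
elapsed exactly T falls in the "< T" stratum.  The CNN-only ablation is
the pooled AUROC of test-fold *segment* probabilities.

## Synthetic cohorts

Each beat is the sum of parameterized pulses: Gaussian lobes for P
(default 100 ms, per-channel amplitudes ~0.07–0.14 mV) and T, a
raised-cosine lobe for the QRS (90 ms), projected onto the three channels;
SVE beats are premature (coupling ≈ 0.65 RR, then a compensatory pause)
with an absent P; VE beats are wide (×1.9), tall (×1.4) with inverted T
and no P.  Beat-to-beat intervals follow a diurnal heart-rate profile
(75 bpm day / 55 bpm night plateaus, cosine-blended over one hour around
the fixed 22:00 and 07:00 boundaries) with multiplicative log-normal
jitter (σ = 0.05); ectopy arrives as thinned Poisson processes at
configured hourly rates; white Gaussian noise (0.05 mV) is added; beats
closer than 0.25 s to their predecessor are skipped and counted.
Between-patient variation: a Gaussian heart-rate offset (SD 3 bpm) and a
±10 % amplitude scale.  At night the P wave is mildly prolonged (+5 %) in
both classes, consistent with circadian P-wave behaviour.

The pAF "substrate" is two effects applied only to pAF patients: a
fractional P-duration prolongation with half-weighted amplitude increase
(`p_wave_effect`; the CNN's channel) and an elevated SVE rate (the
baseline's channel).  Effect sizes are configuration, not claims about
real cohorts.  pAF index dates are drawn log-uniformly over 0.5–60 months
before the exam, spanning every elapsed-time stratum.  The whole cohort is
a pure function of the config including its seed — file-level
byte-identical on regeneration.

**Study conditions used by the tests and acceptance script.**  The null
cohort is 60 patients (30 % pAF) × 20-min recordings with
`p_wave_effect = 0` and equal SVE rates (4/h), VE 2/h; the signal cohort is
identical except `p_wave_effect = 0.2` (a ~20-ms P-duration prolongation —
subtle at segment level, where discrimination stays clearly below the
patient level, so the aggregation advantage is visible) and SVE 7/h in pAF
patients.  Desk-scale runs use B = 6 temporal bins over the 20-min span
(~3.3-min bins; the hourly default targets 24-h exams) and train the
encoder for up to 10 epochs on ≤ 1,200 subsampled training-fold segments.  With rates fixed per class, a patient's burden is approximately
Gaussian with mean p = 1 − exp(−rate·7 s) and binomial variance p(1−p)/n,
so the baseline's expected AUROC has the closed form Φ(Δ/√(σ₀²+σ₁²)) —
about 0.70 under these conditions — which the measured burden AUROC is
checked against.  Twenty-minute recordings stand in for 24-h exams: one
hourly bin per recording span keeps the feature layout identical while the
per-patient segment count (~170) is large enough for burden statistics to
be approximately Gaussian.

**What passing does not show.**  The simulator's morphology differences
are stylized and time-homogeneous (no AF-adjacent bursts, no fibrillatory
waves — recordings are AF-free by design, as in the screening setting); it
has no motion/electrode artifacts beyond white noise, no missing channels,
and annotation labels are perfect ground truth rather than Holter-software
output.  Passing the null and signal checks demonstrates absence of
leakage and correct end-to-end signal propagation, not clinical
performance; real-cohort accuracy cannot be inferred from these tests.

## Numerical conventions and degenerate inputs

Zero-variance channels normalize to zeros rather than NaN.  Batch-norm
uses ε = 1e-5 and momentum 0.1 with running statistics for inference.
Bootstrap and fold CIs refuse rather than fabricate when inputs are
degenerate (single class, < 2 folds, mostly-undefined replicates).  All
randomness — simulation, fold assignment, subsampling, initialization,
batch order, bootstrap — flows from explicit integer seeds; LightGBM runs
in deterministic single-thread mode.  Per-fold seeds are derived as
`(seed·31 + fold) mod 2³¹−1`.

## Known limitations

* The NumPy CNN is single-threaded BLAS-bound; it is sized for
  desk-scale cohorts, not for millions of segments.
* Aggregation assumes the recording span is meaningful for binning; for
  very short recordings most bins are empty and the global block carries
  the signal.
* The elapsed-time analysis uses calendar arithmetic with 30.44-day
  months; clinical month boundaries may differ.
* Probabilities are not calibrated; scores are rankings, and the reported
  cutoff is an in-sample Youden optimum on pooled CV predictions.
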