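# Methods

## Problem and scope

`arnet2` detects atrial fibrillation and atrial flutter (jointly the
positive class, "AF_l") from long-term beat-to-beat (RR) interval series,
estimates each recording's AF burden (AFB, the fraction of monitored time
spent in AF_l), stratifies patients by severity, and issues a patient-level
diagnosis.  The package covers the full chain: waveform conditioning and
QRS detection (when raw ECG is available), beat-based signal-quality
gating, 60-beat windowing with an exclusion cascade, the two-stage neural
classifier, clinical metrics, and a synthetic cohort simulator so that
every stage is testable without clinical data.

## Preprocessing

ECG input is resampled to 200 Hz by polyphase rational resampling (built-in
anti-alias filtering) and filtered with a zero-phase second-order IIR
bandpass with passband [0.67, 100] Hz, applied forward-backward.  At
fs = 200 Hz the upper edge coincides with the Nyquist frequency, where a
bandpass edge cannot be realized; the filter is therefore constructed as a
second-order zero-phase high-pass at 0.67 Hz — the content above 100 Hz is
already excluded by the sampling itself, so the realized magnitude response
matches the intended passband.

Two algorithmically independent QRS detectors are bundled:

* **primary** — a Pan-Tompkins-style energy detector (5-15 Hz bandpass,
  five-point derivative, squaring, 150 ms moving-window integration,
  adaptive two-pass thresholding with a 250 ms refractory period);
* **secondary** — a matched filter using a generic ~80 ms Mexican-hat QRS
  template, squared and peak-picked with the same adaptive rule.

Both threshold candidate peaks at 30% of the top-decile peak height and
reject everything when no peak clearly dominates the envelope's global
median (so flat lines and pure noise yield zero beats rather than
artifacts).  Detected fiducials are refined to the local energy maximum.

Per-window signal quality is the beat-agreement index bSQI computed between
the two detectors with a 50 ms agreement window.  The index uses the
Jaccard form

    bSQI = N_matched / (N_ref + N_test − N_matched)

with deterministic one-to-one greedy nearest-neighbour matching (candidate
pairs ordered by |Δt|, ties toward the earlier beat).  The Jaccard form was
chosen because it is symmetric, bounded in [0, 1], and penalizes both
missed and spurious beats; it equals 1 exactly when the matching is a
perfect bijection.  Two empty sequences score 0 (flagged low quality, not
an error).  bSQI is computed on the filtered signal.

## Windowing and exclusion cascade

Beat sequences are cut into consecutive, non-overlapping 60-beat windows
(59 RR intervals each); the trailing remainder is dropped because the
classifier consumes a fixed-length input.  A window's binary label is the
plurality vote of its 60 beat labels with AF and AFL positive and all other
rhythms — including atrial tachycardia (AT) — negative; an exact 30/30 tie
resolves positive, favouring sensitivity in a screening context.  A
window's "missing" duration is the sum of RR intervals terminating at beats
whose annotation is UNKNOWN.

The exclusion cascade runs in a fixed order with the default thresholds:

1. flag windows with **more than 10 s** of missing beat labels;
2. discard the recording if **more than 25%** of its windows are flagged;
3. flag remaining windows with **bSQI below 0.8**;
4. discard the recording if the total excluded fraction **exceeds 75%**.

All four printed inequalities are read strictly (exactly 10 s / 25% / 0.8 /
75% survive), every threshold is configurable, and discarding is a recorded
status, never an exception.  The order matters and is asserted by tests: a
recording failing both patient-level rules is reported as
`TOO_MANY_MISSING`, not `TOO_NOISY`.

## The two-stage classifier

**Stage 1** is a pre-activation residual CNN over one 59-RR window
(channels-last, input 59×1).  Five residual blocks of two same-padded 1-D
convolutions (filter length 10) each; the filter count doubles and the
temporal length halves every second block, giving [64, 64, 128, 128, 256]
filters and lengths 59 → 30 → 15.  Each block applies BN → ReLU before each
convolution; the shortcut is the identity, or a 1×1 convolution projection
when the channel count changes, and downsampling is a width-2 max-pool
(ceil semantics) on the merged output.  Dropout 0.2 sits between blocks.
After a closing BN → ReLU the feature map is flattened into three dense
layers (512 → 256 → 128, ReLU, dropout 0.5 each) and a final size-1 dense
output.  The 128-dimensional activations entering that final layer are the
window *embedding*.

**Stage 2** is a pool of four structurally identical GRU heads (64 units,
then dense 64 → ReLU → dense 1), one per severity stratum.  A head consumes
the temporal concatenation of a window's embedding with its h = 6
predecessors; missing history at a recording's start is zero-padded.
During training each recording is assigned a stratum from its TRUE window
labels (total AF_l time and AFB through the severity taxonomy below) and
every window trains exactly one head.  At inference, stage-1 probabilities
are binarized at the stage-1 threshold, the resulting estimated AFB and
total AF_l time select ONE head for the whole recording, and that head
scores every window.  Head selection per recording (rather than per
window) follows the description of inference as conditioning on "the
patient's AFB"; this was a genuinely open design point and is the
convention implemented and tested here.

**Training.**  Both stages minimize weighted binary cross-entropy (the
positive class up-weighted by N_neg/N_pos of the respective training set
unless overridden) with Adam at learning rate 1e-2 under global-norm
gradient clipping (default 1.0), early stopping on the
validation loss (minimum delta 0.001, patience 5 epochs), restoring the
checkpoint with the best validation AUROC (parameters *and* batch-norm
running statistics).  Splits are always by patient, never by window.
Classification thresholds (stage 1, and per head in stage 2) are the
observed probability maximizing F1 on the training outputs, ties resolved
toward the lowest threshold; a head whose stratum is single-class falls
back to 0.5.  A head with an empty stratum keeps its initialization with a
logged warning.

The network library itself (`arnet2.nn`) is a small NumPy implementation
with hand-derived backpropagation — 1-D convolution via im2col, batch
normalization, max-pooling with ceil semantics, dropout, dense layers, an
unrolled GRU and Adam — exercised by central finite-difference gradient
checks in the test suite.  Computation is float32; the gradient checks run
in float64.  All randomness (initialization, shuffling, dropout) flows
from explicit seeded generators, so a fixed seed reproduces training
bit-exactly on the same platform.

Training at this learning rate is visibly non-monotone on small cohorts
(validation loss can spike between epochs).  Two mechanisms keep the
aggressive default usable at desk scale: global-norm gradient clipping
bounds the occasional huge mini-batch update that would otherwise throw
the optimizer into a regime it does not recover from, and the best-AUROC
checkpoint restore — not the final epoch — defines the model.

## Clinical metrics

For included windows with durations t_i (ms) and binary labels:

    AFB  = Σ t_i·I_i / Σ t_i
    E_AF(%) = 100 · Σ t_i·(ŷ_i − y_i) / Σ t_i

The identity E_AF = 100·(AFB(ŷ) − AFB(y)) holds exactly and is asserted to
1e-12.  An empty window set yields a *missing* burden, never 0.  Severity:

| level   | rule                                   |
|---------|----------------------------------------|
| Non-AF_l| total AF_l time < 30 s                 |
| mild    | ≥ 30 s and AFB < 4%                    |
| moderate| 4% ≤ AFB ≤ 80%                         |
| severe  | AFB > 80%                              |

Boundary conventions are strict readings of the printed inequalities
(exactly 30 s → mild; exactly 4% → moderate; exactly 80% → moderate) and
configurable.  The patient-level diagnosis is positive iff AFB ≥ 4%.

Window statistics (Se, Sp, PPV, NPV, F1, AUROC by trapezoidal ROC, AUCPR
by step-wise precision-recall integration) are pooled across recordings
within a stratum; |E_AF| is summarized as median (Q1-Q3) across recordings
with linear-interpolation quartiles.  An undefined PPV is reported missing
and F1 as 0; rank metrics are missing for single-class labels.  AUROC and
AUCPR are delegated to scikit-learn, whose estimators are exactly these
constructions; an independent O(n²) pairwise-concordance oracle verifies
the AUROC in the tests.

## Synthetic cohorts

RR dynamics are an AR(1) process per rhythm — the simplest process with
independently controllable mean, variance and lag-1 autocorrelation, which
are the three properties an interval-based classifier exploits.  Default
profiles (mean RR ms, sd ms, lag-1 autocorrelation):

| rhythm | mean | sd  | ρ₁   | character                         |
|--------|------|-----|------|-----------------------------------|
| NSR    | 850  | 40  | 0.80 | slow, regular, autocorrelated     |
| AF     | 700  | 150 | 0.05 | irregular, nearly memoryless      |
| AFL    | 430  | 10  | 0.90 | fast and *more* regular than NSR  |
| AT     | 450  | 30  | 0.70 | fast, fairly regular, negative    |

RR values are truncated to [250, 2500] ms.  Episodes are planted as
uniform random non-overlapping intervals, greedily until the target burden
is met, each at least the minimum episode duration (60 s by default), with
the final episode trimmed to the remainder; the realized burden therefore
lands within half a minimum episode of the target.  The generator's
reported "true" AFB is computed from its own labels with the same
windowing arithmetic the pipeline uses, so truth and pipeline agree
exactly.  The 30-s episode rule label (positive iff some contiguous AF_l
span lasts ≥ 30 s) is stored alongside.

The default cohort is 40 patients of ~2 h each: 40% non-AF_l and 20% each
mild (target burden 2%), moderate (45%) and severe (90%), so all four
severity heads receive data.  Half of the patients additionally carry AT
episodes (~5% of record time) in the negative class; this is deliberate —
with only slow-regular NSR as the negative class, heart *rate* alone would
separate the classes and the flutter-hardness property would be
untestable.  With AT present, the classifier must use irregularity, which
is the mechanism the real task rewards and the reason flutter is missed.

Toy ECG synthesis places an ~80 ms Mexican-hat pulse at each beat time
plus white Gaussian noise at a given SNR; it supports detector and bSQI
testing only.  What the simulator does *not* model: P/F-wave morphology,
ectopic beats, non-stationary noise, detector-induced RR errors, rhythm
transitions inside a window boundary mid-episode.  Passing the end-to-end
checks therefore demonstrates that the pipeline machinery is correct and
that the architecture can exploit interval statistics — not clinical-grade
performance on real Holter data.

## Problem sizes and numerical choices

The end-to-end checks train the full default architecture on the default
40-patient cohort (~6,000 windows; 24 train / 8 validation / 8 test
patients) for up to 8 epochs — a deliberately desk-scale study.  The
flutter-hardness check re-scores a 16-patient AFL-episode cohort with the
same trained weights, mirroring an error analysis of a fixed model rather
than retraining.  Detector checks use 10 minutes of synthetic ECG at
20 dB SNR.  Batch-norm epsilon is 1e-5, momentum 0.9; Adam uses the
standard (0.9, 0.999) moments; dropout masks are inverted-scaled.  Windows
are 0-based; window spans are half-open [start, start + t_i).

## Known limitations

* The simulator's AR(1) rhythms are far easier to separate than clinical
  tachograms; absolute metric values here should not be read as clinical
  performance.
* Flutter windows are (by design and in line with the underlying clinical
  finding) largely missed; the package demonstrates the limitation rather
  than solving it.
* Only one ECG lead is processed; no multi-lead fusion.
* The WFDB support covers single-segment format-16 records and the MIT
  annotation subset needed for rhythm labels, not the full WFDB ecosystem.
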