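# Methods

## The detection model

The pipeline treats IED detection as two separable problems: *waveform
recognition* on single channels, and *event determination* across montages.

Stage 1 classifies every 1 s single-channel window (256 samples at 256 Hz)
into IED / artifact / background. Training on three classes rather than the
usual IED vs non-IED split lets the classifier learn artifact morphology
explicitly instead of relying on amplitude-based artifact rejection, which
both removes genuine spikes and passes spike-like artifacts. Windows are
standardized per segment (zero mean, unit SD, SD floored at 1e-6) before
entering the network, making the classifier amplitude-scale invariant —
absolute microvolt levels vary across subjects, sites and montages, so the
discriminative signal must be morphological. The consequence is that
amplitude itself cannot be used as a feature; the synthetic experiments show
morphology suffices.

Stage 2 converts the per-instant 2 × 19 probability array into event calls.
The two-montage rule mirrors how readers verify a discharge across montages:
a genuine IED with a focal field appears on at least one earlobe-referential
channel and, because its field has a spatial gradient, on at least two
bipolar derivations — and those appearances must involve the same scalp
electrode. Threshold comparisons are inclusive (≥) so that τ = 1 remains
meaningful for saturated probabilities; τ = 0 is degenerate by the same
convention (every instant positive). "Spatially correlated" is
operationalized as non-empty electrode intersection between active channels
(the weakest faithful reading); a stricter variant requiring one earlobe
electrode inside ≥ 2 active bipolar pairs is available as
`spatial_rule="strict"`. A single threshold is shared by both montages;
per-montage thresholds would be a straightforward extension.

Event extent is the union of the contributing 1 s windows, and events with
gaps < 1 s are merged transitively — the same convention applied to the
reference labels, so detections and labels are commensurable under the
≥ 50 % overlap match.

## Network architectures

The TCN stacks residual blocks of two causal dilated convolutions
(kernel 7; dilations 1, 2, 4, 8, 16; 12 filters; dropout 0.1), giving a
receptive field of 1 + Σ 2·(k−1)·d = 373 samples, comfortably covering the
256-sample window — receptive-field coverage is the binding design
constraint. Causality (output at *t* sees only inputs ≤ *t*) is preserved by
left zero-padding and is verified by test. Classification uses global
average pooling over the feature sequence followed by a dense softmax head;
GAP keeps parameters few and spreads gradients over all time steps, which
proved necessary for stable training in this stack (a last-time-step readout
trained poorly). The MLP baseline (256 → 128 → 64 → 3, dropout 0.1)
deliberately discards temporal structure.

Both models run on a small NumPy layer library written for this package:
float32 arithmetic, manual backpropagation (the convolution input-gradient
is computed as a correlation with the time-flipped kernel, one GEMM), Adam,
and a one-cycle learning-rate schedule (cosine warmup over the first 25 % of
steps from max_lr/25, cosine annealing to max_lr/1e4). Defaults: 20 epochs,
max learning rate 1e-2, batch 64. Convolution gradients are verified against
finite differences in the test suite. The training seed fully determines
initialization, dropout and batch order, so runs are bit-reproducible.

## Preprocessing

Recordings are resampled to 256 Hz (polyphase, anti-aliased) and filtered
channel-wise: 4th-order Butterworth 0.5 Hz high-pass, 4th-order 45 Hz
low-pass, 2nd-order Butterworth band-stop 49–51 Hz (mains). Filter order is
a package choice (standard clinical practice); all corners and the order are
configurable. Filtering is zero-phase (forward–backward) by default because
spike morphology and latency matter downstream; a causal mode exists for
streaming-style use. The filter chain's parameters are hashed into a
fingerprint stored in model checkpoints, and inference refuses recordings
preprocessed under a different chain.

## Montages

Earlobe referencing: left hemisphere → A1, right → A2, midline → (A1+A2)/2
(the dominant clinical convention; linked-ears referencing for all channels
is a config option). The longitudinal bipolar montage is the standard 18
"double banana" derivations; where a fixed 2 × 19 probability frame is
required, the 19th bipolar slot is padded with probability 0 — padding can
never create a detection. Common average subtracts the mean of the 19 scalp
electrodes. Channel order is part of the system contract because frames are
index-aligned. Reference electrodes are excluded from channel provenance so
the spatial rule operates on scalp sites only.

## Segmentation and training data

Annotations ≥ 1 s are cut into consecutive 1 s windows with 0.5 s overlap:
floor((L−1)/0.5)+1 windows, no tail window beyond the annotation. Shorter
annotations (single IED waveforms) yield one window centered on the
annotation midpoint, shifted inward at recording edges rather than
zero-padded, keeping real signal statistics. Class balance is achieved by
oversampling minority classes to the majority count — every expert
annotation is retained. Cross-validation folds are stratified on
(label, montage) with each fold's stratum share within 2 percentage points
of the global share.

The end-to-end training protocol cuts segments from simulated *annotated
recordings* through the actual preprocessing and montage pipeline, optionally
augmented with directly generated segments for amplitude diversity. This
matters: classifiers trained only on raw synthetic windows see neither the
filter chain's spectral shaping nor the montage-derived noise structure and
then misfire when scanning preprocessed recordings, so the direct segment
generator also synthesizes each window inside 3 s of context, applies the
standard filter cascade and crops the center, with bipolar-tagged segments
using difference-of-noise backgrounds.

## The synthetic generator

What it emulates: 1/f ("pink") background noise on every electrode
(10 µV SD), a 10 Hz alpha rhythm with a slow amplitude envelope on posterior
electrodes (30 µV), spike-wave IEDs (negative biphasic spike ≈ 70 ms, a
difference of Gaussians, followed by a ≈ 300 ms half-sine slow wave; peak
120 µV with ±30 % jitter) injected at the electrode level through a focal
spatial field (gain 1 at the focus, 0.5 at graph-distance 1, 0.25 at
distance 2 on the 10–20 adjacency), and three artifact classes — EMG
(30–90 Hz bursts, temporal electrodes), ECG (~1.1 Hz QRS-like trains) and
movement (< 2 Hz high-amplitude excursions). A1/A2 carry attenuated
background only. Injecting fields at the electrode level (pre-montage) makes
earlobe and bipolar appearances physically consistent, including the
≥ 2-bipolar-channel footprint the TMDM requires; foci are drawn from
electrodes participating in ≥ 2 bipolar derivations (all scalp sites except
Fz and Pz), so every event is recoverable by the rule in principle.

Event timing: one Bernoulli draw per 1 s epoch at the configured rate
(default 2/min), midpoints aligned to epoch centers with ± 0.1 s jitter, and
arrivals thinned to a ≥ 3 s inter-event gap (interictal discharges are
sparse; the type contract requires only ≥ 1 s). Epoch alignment makes exact
epoch-level agreement achievable in the oracle validation — detections span
whole 1 s windows, so an event placed inside one epoch is detected inside
that same epoch — and is immaterial to the sliding-window detector, which
scans every 0.5 s regardless.

What it does **not** emulate: volume conduction and realistic field
topographies, non-stationary background (sleep stages, drowsiness), benign
epileptiform variants, electrode pops, generalized or multifocal discharge
morphology variability, and recording artifacts correlated across channels.
Passing the synthetic end-to-end checks therefore demonstrates that the
pipeline's machinery is correct and self-consistent — not that clinical
performance transfers; the synthetic task is much cleaner than clinical EEG,
where reported false-positive rates are orders of magnitude higher.

## Evaluation conventions

Matching uses overlap / min(durations) ≥ 0.5 with greedy one-to-one pairing
in decreasing-overlap order (alternative denominators are configurable).
PR curves pool TP/FP/FN across recordings (micro-average); per-recording
tables are reported separately. AUPRC is the trapezoidal area of precision
over sensitivity with threshold ties collapsed to their best precision (the
operating frontier) and extension to sensitivity 0 at the highest-precision
point. Precision at zero detections is defined as 1. The operating point for
a sensitivity target picks the **largest** threshold whose pooled
sensitivity reaches the target. Cohen's κ is computed from binary per-epoch
indicators via scikit-learn, with documented conventions for degenerate
marginals: identical arrays → 1 (flagged when constant), p_e = 1 with
different arrays, or p_o = p_e = 0 → 0 with a degeneracy flag. Bootstrap CIs
(default 1000 iterations, percentile 2.5/97.5) resample whole recordings,
the independent units; replicates with undefined metrics are redrawn and
counted.

## Problem sizes and numerical choices

The shipped experiments run on one CPU: training uses a 30-minute simulated
recording's pipeline segments plus 600 direct segments (~20 epochs, about
two minutes), and held-out detection uses 10-minute recordings (~1200
frames, 37 scanned channels). Threshold grids default to 0.05…0.95 in steps
of 0.05. EDF round trips are exact to 16-bit quantization of the
per-channel physical range. Flat channels are written with a widened 1 µV
physical span to keep the EDF scaling non-degenerate. Filters fall back to
a single data record when the sampling rate is non-integral.

## Known limitations

* The NumPy network stack is CPU-bound; large-scale hyperparameter sweeps
  or hour-scale recordings are out of its intended envelope.
* Only the TCN and MLP cores are implemented; the other seven architecture
  names are registry placeholders for plugins.
* The earlobe montage hard-requires A1/A2; recordings without them can only
  be scanned with the common-average variant.
* The spatial-correlation rule is one reading of a principle with several
  faithful operationalizations; both shipped variants are documented, and
  neither claims to match any particular clinical implementation.
* Synthetic realism is phenomenological, not biophysical (see above).
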