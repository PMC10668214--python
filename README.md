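# iedscan

Two-stage automatic detection of interictal epileptiform discharges (IEDs)
in scalp EEG.

IEDs — transient spikes and sharp waves occurring between seizures — are the
key EEG finding supporting a diagnosis of epilepsy, but annotating them by
visual inspection is slow, error-prone and limited by the supply of trained
readers. `iedscan` implements a complete detection pipeline for
10–20-system scalp recordings, plus the synthetic EEG generator and the
event-level evaluation protocol needed to develop and test it without
clinical data.

## The method

**Stage 1 — single-channel classification.** A classifier maps every 1 s
single-channel window *x* ∈ ℝ²⁵⁶ (256 Hz) to a probability triple over
{IED, artifact, background}. The shipped core is a temporal convolutional
network (TCN): causal dilated 1-D convolutions in residual blocks, dilations
1, 2, 4, 8, 16, receptive field 373 samples ≥ 256, global-average-pooled
into a softmax head. An MLP baseline is included, and further architectures
can be registered. The fitted classifier slides over the recording with a
0.5 s stride in **two montages at once** — earlobe-referential (shape and
amplitude preserved) and longitudinal bipolar ("double banana"; suppresses
common-mode artifacts, highlights local gradients) — producing a
2 × 19 array *P(t)* of IED probabilities per time instant *t*.

**Stage 2 — two-montage decision mechanism (TMDM).** An IED event is
declared at instant *t* when, for threshold τ:

1. at least 1 earlobe value and at least 2 bipolar values of *P(t)* are ≥ τ, and
2. the activations are spatially consistent: an active earlobe channel's
   electrode belongs to an active bipolar channel's electrode pair.

Runs of positive instants become events spanning the union of their 1 s
windows; events closer than 1 s are merged. A single-montage comparator
(SMDM: max earlobe probability ≥ τ) and a common-average variant are
included.

**Evaluation.** A detection is a true positive when its overlap with an
expert event label reaches ≥ 50 % of the shorter interval (greedy one-to-one
matching). Pooled precision–recall curves over a threshold grid give the
AUPRC; the operating point at sensitivity 0.8 yields false positives per
minute and F1; epoch-wise Cohen's κ measures chance-corrected agreement per
1 s epoch. Bootstrap CIs resample whole recordings.

## Worked example

`examples/detect_and_evaluate.py` simulates a 10-min annotated recording,
trains the TCN on its pipeline-derived segments, scans a held-out 5-min
recording and scores it:

```
event-level AUPRC        : 1.000
operating threshold      : 0.95 (sensitivity target 0.8)
sensitivity / precision  : 0.857 / 1.000
false positives per min  : 0.000
F1 score                 : 0.923
epoch-wise Cohen's kappa : 0.921

6 detections vs 7 reference events.
```

An AUPRC of 1.0 means some threshold separates all injected spike-wave
events from the background perfectly; the operating-point rule then picks
the *largest* threshold still meeting the 0.8 sensitivity target (here 0.95,
which trades one missed event for zero false alarms). FP/min is the review
burden a clinician would face at that operating point.
`examples/decision_rule_demo.py` shows the TMDM logic on hand-built frames,
`examples/simulate_recording.py` the generator, and
`examples/train_and_crossvalidate.py` the stratified five-fold (here
three-fold) classifier evaluation.

A thin CLI binds the same stages end to end:

```bash
iedscan simulate --seed 1 --out out/sim
iedscan train    --config cfg.yaml --out out/train
iedscan detect   --config cfg.yaml --out out/detect
iedscan evaluate --config cfg.yaml --out out/eval --plot
```

## Layout

```
src/iedscan/
  io.py            EDF + CSV annotation/event formats, interval types
  preprocess.py    resampling to 256 Hz, Butterworth 0.5–45 Hz + 50 Hz notch
  montage.py       earlobe / longitudinal-bipolar / common-average views
  segmentation.py  1 s training segments, class balancing, stratified folds
  models/          TCN + MLP classifiers, training, cross-validation
  inference.py     stage 1: sliding-window scan → probability frames
  decision.py      stage 2: TMDM / SMDM / common-average, event formation
  evaluation.py    overlap matching, PR/AUPRC, FP-rate, F1, kappa, bootstrap
  synthetic.py     reproducible synthetic EEG with exact ground truth
  cli.py           `iedscan` command-line surface
docs/methods.md    model assumptions, parameters, design notes
```
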