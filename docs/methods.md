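# Methods

This note documents the models, parameters and design decisions behind
`swallowseg`, and what the synthetic experiments do and do not demonstrate.

## Problem setting

The task is sound-event detection in cervical-auscultation audio: given a
mono recording of a feeding session, emit the start and end times of every
swallow. Swallows are short (a few hundred milliseconds) broadband "fluid
flushing" transients; recordings also contain background noise and
distractor sounds (voices, hums, contact clicks). Supervision is a list of
half-open intervals [start, end) per recording, annotated per participant.

## Front end

All audio is resampled to 16 kHz (polyphase, anti-aliased) and peak-
normalized per recording to [-1, 1]. Analysis frames are 0.96 s with 50 %
overlap (hop 0.48 s); the final partial frame is zero-padded so swallows at
the end of a recording remain detectable. Per frame:

* **Log-mel patch**: magnitude STFT with 25 ms Hann window and 10 ms hop
  (512-point FFT), mapped onto 64 triangular mel bands spanning 125–7500 Hz
  (HTK mel scale), then `log(E + 0.001)`. The frame tail is zero-padded so
  exactly 96 STFT steps result; silence maps to the constant `log(0.001)`.
  These parameters follow the published front-end convention of the
  pretrained audio network the pipeline targets; they are constants in
  `config.py`.
* **Zero-crossing rate**: sign changes between consecutive samples divided
  by (L−1), zeros counted as positive. A cheap proxy for dominant frequency,
  appended to the embedding rather than the spectrogram input.

Note one geometry subtlety: an STFT step whose 25 ms window starts after
sample 14960 reads into the tail padding, so the final two steps of every
patch partially measure the padding discontinuity rather than audio. The
patch keeps all 96 steps (shape contract), but the fallback embedding pools
statistics only over the 94 fully-supported steps.

## Embedding backends

The head consumes a fixed 1024-dim embedding per frame plus the ZCR scalar.
Backends are pluggable behind one contract (deterministic; fixed dim; named,
so model artifacts can refuse a mismatched backend).

* `yamnet` adapts the published pretrained audio-classification network
  (penultimate-layer embeddings, computed from the raw 0.96 s waveform).
  It requires `tensorflow-hub` and a model download, and is never exercised
  by the test suite.
* `mel-stats` is the default, dependency-free backend. The log-mel patch is
  normalized per band — subtract the band's temporal mean (the cepstral-
  mean-subtraction analog; removes static background level and color), then
  divide by the band's temporal std (removes the band's fluctuation scale,
  which varies with background spectrum). From this "shape" patch it pools
  per-band 10th/90th percentiles (robust to the spiky extremes the log
  offset produces in near-silent bands) and per-band means over the six
  subframe-aligned time segments; the raw per-band std is kept as 64 dims
  of scale information. The resulting 64 + 128 + 384 = 576 statistics are
  projected to 1024 dims by a random linear map drawn once from a fixed
  seed (`config.MELSTATS_PROJECTION_SEED`), so artifacts are reproducible
  across machines.

Two of these choices deserve their rationale spelled out. First, purely
time-pooled statistics (mean/std/min/max per band) are blind to *where*
within the frame energy occurs — two frames with the same content in a
different temporal order are indistinguishable — yet the head must predict
*which* 0.16 s subframes contain a swallow. The subframe-aligned segment
means restore exactly the temporal resolution the head's output grid needs.
Second, the per-band normalization makes the embedding invariant to a
constant additive shift of the patch and largely invariant to background
color/level changes; this is what lets a head trained on one background
profile transfer to a shifted one. The trade-off is that absolute loudness
is compressed into the 64 scale dims; on strongly level-coded tasks a
backend with absolute energy features could do better.

## Subframe labels

Each frame is subdivided into six 0.16 s subframes; subframe i of a frame
starting at t covers [t + 0.16 i, t + 0.16 (i+1)). A subframe is labelled 1
when the union of annotated swallow intervals covers at least half of it
(0.08 s). The 50 % rule is symmetric, suppresses sliver labels, and bounds
the boundary quantization error at 0.08 s per edge. Labels are computed in
absolute recording time, so overlapping frames always agree on shared slots
— the property the overlap-add decoder relies on.

## Prediction head and training

The head is a fully-connected network: input 1025 (embedding + ZCR), hidden
layers of 1024, 1024 and 512 ReLU units, and a 6-unit sigmoid output (one
confidence per subframe). It is implemented directly on numpy.

Training minimizes mean squared error against the binary subframe labels
with Adam (default learning rate 1e-3), mini-batches of 32, and an L2
penalty (default 1e-4) on the first two hidden layers' weights only. Before
every epoch the training examples are re-balanced — frames containing at
least one swallow subframe versus all-zero frames, equalized by random
undersampling of the majority group — and shuffled; both draws derive from
the run seed, so training is bit-reproducible. Inputs are z-scored with
training-set statistics stored in the artifact. The epoch with the lowest
validation loss is kept; early stopping aborts after 10 non-improving
epochs (configurable; the 100-epoch cap always applies). "Balanced" is
interpreted at the frame level because the labelling unit the sampler sees
is the frame; subframe-level balancing would break the example/feature
correspondence.

Datasets are split by participant (80/20 by default), never by example, so
no participant contributes to both sides; the trainer asserts disjointness.
Model artifacts (`.npz` weights + `.json` sidecar with architecture,
backend name/dim, seeds and training history) refuse to run under a
backend that does not match the sidecar.

Weight initialization is fan-in-scaled (He) from the run seed. Output
logits are clipped to ±30 before the sigmoid so predictions stay strictly
inside (0, 1) in floating point.

## Overlap-add decoding

Each frame adds its six confidences onto a global 0.16 s slot timeline;
with 50 % overlap, interior slots receive two contributions and recording
edges one. The timeline is thresholded on the coverage-normalized mean
(default tau = 0.5, ties to 1) rather than the raw sum, so a single
threshold is meaningful at edges and interior alike, and duplicating a
frame's contribution changes nothing. Maximal runs of above-threshold slots
become events with boundaries quantized to 0.16 s. Two post-processing
parameters — minimum event duration and gap merging — exist but default to
0: the emulated protocol reports raw, unprocessed segments.

Used as an oracle (feeding the binary labels in as confidences), the
label→decode round trip recovers every event boundary to within one slot,
which bounds the decoder's intrinsic quantization error.

## Evaluation

Event level: a ground-truth swallow is a true positive when the union of
predicted swallow time covers at least 30 % of its duration (inclusive);
fragmented predictions may jointly reach the threshold. A predicted event
is a true positive if it intersects any detected truth event; remaining
predictions are false positives. Subframe level: binary masks on the
0.16 s grid are tallied slot-wise into tp/fp/fn/tn, from which PPV, NPV,
specificity, sensitivity and F1 are computed per class plus overall
accuracy; a metric with a zero denominator is reported as NaN, never as 0.

## Synthetic data

Real CA audio cannot be shared, so the generator produces labelled
surrogates with controllable acoustics. Per participant (defaults in
parentheses): a one-minute (60 s) 16 kHz recording with a colored-noise
background (pink, reference RMS 0.05 full scale) and 5–20 swallow events of
0.3–0.9 s separated by at least 0.5 s. Each swallow is a train of 2–3
band-limited (300–3000 Hz) noise bursts with exponential-decay envelopes
(time constants 0.08–0.15 s), onsets spread across the interval so the
event is audible throughout its annotated extent, scaled so the mean
in-band power inside the event sits `snr_db` (10 dB) above the background.
Distractors — amplitude-modulated tonal hums (200–500 Hz, 1–3 s) and single
loud clicks (5–20 ms, 10x background RMS) — appear at ~4/min, never overlap
swallows, and are absent from the annotations. Colored-noise synthesis is
floored at 20 Hz, emulating the AC coupling of any real recording chain;
without it, steep (1/f²) spectra are dominated by physically meaningless
infrasonic drift. Everything derives from one seed; cohorts are written as
16-bit WAV + events CSV + a JSON manifest recording per-participant seeds.

Cohorts can generate their test participants with a shifted background
profile — brown (1/f²) noise at +3 dB instead of pink — to emulate the
domain mismatch of training on one recording setup and testing on another.

What the generator does *not* emulate: real swallow acoustics (it claims
separability, not clinical realism), breath sounds, speech, overlapping
distractors, microphone contact variation within a recording, or annotation
noise. Passing the synthetic experiments therefore demonstrates that the
pipeline's machinery — features, labelling, training, decoding, scoring —
is correct and robust to background changes at 10 dB SNR; it does not
certify clinical performance.

## Experiment scale and measured behaviour

The standard synthetic experiment (also run by `scripts/acceptance.py`)
uses 10 train-role participants (split 8/2 by participant into
train/validation) and 4 test participants, one minute each — about 1 200
training frames, of which roughly a quarter contain a swallow subframe.
Training typically converges within 10–20 epochs under early stopping
(seconds to tens of seconds on one CPU core). At these sizes the pipeline
reaches event-level sensitivity 1.0 and precision ≥ 0.90 on both matched
and background-shifted test cohorts across the seeds exercised in the test
suite; the remaining false positives are isolated single-slot detections,
typically on clicks. The worked confusion-matrix example (tp=192, fn=46,
fp=54, tn=837) reproduces the reference metric table to its printed
precision: accuracy 0.91, sensitivities 0.81/0.94, F1 0.79/0.94, NPV 0.95.

## Known limitations

* The `mel-stats` backend is a deterministic surrogate, not a learned
  representation; with the optional `yamnet` backend the same pipeline runs
  unchanged, but no results with it are asserted by the tests.
* Sub-frame resolution is bounded by the 0.16 s grid and the 0.08 s
  labelling threshold; boundaries are accurate to one slot at best.
* MSE training of sigmoid outputs saturates confidences; the decoder
  threshold is robust to this, but calibrated probabilities should not be
  read off the head's outputs.
* Single-channel, single-event-class design: no speech/cough classes, no
  overlapping event handling beyond interval union.
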