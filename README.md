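# swallowseg

Automatic segmentation of swallowing sounds in cervical-auscultation (CA)
audio recordings.

CA — recording the sounds of the swallow with a microphone at the neck — is
a cheap, repeatable complement to the videofluoroscopic swallow study, but
using it at scale requires finding the swallows in a noisy clinical
recording automatically, without expert manual segmentation. `swallowseg`
implements a transfer-learning pipeline for that task: a pretrained-style
audio embedding of short analysis frames feeds a small fully-connected
network that predicts, at sub-frame resolution, where swallows occur, and an
overlap-add decoder turns those predictions into time-stamped swallow
events.

## Pipeline

1. **Front end.** The recording is resampled to 16 kHz, amplitude-normalized
   to [-1, 1], and cut into frames of 0.96 s with 50 % overlap (hop 0.48 s).
   Each frame is summarised as a 96-step x 64-band log-mel spectrogram patch
   (25 ms window, 10 ms hop, 125-7500 Hz, log(E + 0.001)) plus its
   zero-crossing rate (ZCR).
2. **Embedding.** A pluggable backend maps each frame to a deterministic
   1024-dim vector; the ZCR scalar is concatenated, giving 1025 features per
   frame. Two backends ship: `yamnet` (adapter for the published pretrained
   audio-classification network; optional, needs `tensorflow-hub` and a
   download) and `mel-stats` (deterministic, dependency-free log-mel summary
   statistics behind a fixed random projection; the default, used by all
   tests).
3. **Head.** A fully-connected network (1024 -> 1024 -> 512 hidden units,
   ReLU; sigmoid output) predicts six confidences per frame, one per 0.16 s
   subframe. Training: MSE loss against binary subframe labels, Adam,
   mini-batches of 32, L2 on the first two hidden layers, class balancing by
   random undersampling re-drawn before every epoch, at most 100 epochs,
   participant-disjoint 80/20 train/validation split, best-validation epoch
   kept.
4. **Decoder.** Overlapping frames' subframe confidences are overlap-added
   onto a common 0.16 s timeline, coverage-normalized, thresholded at
   tau = 0.5, and maximal runs become predicted events — boundaries
   quantized to 0.16 s.
5. **Evaluation.** A ground-truth swallow counts as detected when at least
   30 % of its duration is covered by predicted swallow time; subframe-level
   confusion matrices yield PPV/NPV, specificity, sensitivity and F1 per
   class.

No clinical audio ships with the package. A synthetic-data module generates
labelled one-minute CA-like recordings (pink-noise background, band-limited
swallow bursts at a controlled SNR, tonal-hum and click distractors) so the
entire pipeline is testable offline, including a train/test background
mismatch that mirrors training and testing on differently recorded cohorts.

## Worked example

```sh
swallowseg simulate --train 4 --test 2 --seed 7 --out data/ --matched-test
swallowseg train    --data data/ --out head.npz --seed 7
swallowseg segment  --model head.npz --wav data/test01.wav --out pred.csv
swallowseg evaluate --truth data/test01.csv --pred pred.csv --out report.json
```

which logs

```
wrote 6 recordings to data/
trained 11 epochs (best 0, val MSE 0.0294); artifact at head.npz
wrote 22 predicted events to pred.csv
wrote evaluation report to report.json
```

`pred.csv` holds the predicted swallow intervals, boundaries on the 0.16 s
grid:

```
start_s,end_s,label
1.600,1.760,swallow
1.920,2.240,swallow
6.400,6.720,swallow
...
```

and `report.json` contains the event-level scores for that recording — 18
true swallows of which 17 were detected (one missed), one spurious
detection:

```json
{"tp": 17, "fn": 1, "fp": 1, "sensitivity": 0.944, "precision": 0.955}
```

A counts-only mode computes the metric table directly from a confusion
matrix, without audio:

```sh
swallowseg evaluate --counts 192,46,54,837 --out table.json
```

giving overall accuracy 0.91, swallow sensitivity 0.81 / F1 0.79 / NPV 0.95,
and non-swallow sensitivity 0.94 / F1 0.94.

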