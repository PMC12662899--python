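"""Shared front-end and pipeline constants.

The analysis grid is fixed by the pretrained-audio-embedding convention this
pipeline targets: 0.96 s frames with 50 % overlap, each summarised as a
96-step x 64-band log-mel patch, and each frame predicted at the resolution
of six 0.16 s subframes.
"""

#: Internal processing sample rate (Hz); all audio is resampled to this.
SAMPLE_RATE = 16_000

#: Analysis frame length (s) and its size in samples at SAMPLE_RATE.
FRAME_S = 0.96
FRAME_SAMPLES = 15_360

#: Frame hop (s) for 50 % overlap, and its size in samples.
HOP_S = 0.48
HOP_SAMPLES = 7_680

#: Subframe grid: six 0.16 s slots per frame; the decoder's time resolution.
SUBFRAME_S = 0.16
N_SUBFRAMES = 6

# STFT front-end for the log-mel patch: 25 ms Hann window, 10 ms hop,
# zero-padded to 512-point FFT; 96 steps per frame (tail zero-padded).
STFT_WINDOW_S = 0.025
STFT_HOP_S = 0.010
N_FFT = 512
N_PATCH_STEPS = 96

#: Mel filterbank: 64 triangular bands spanning 125-7500 Hz (HTK mel scale).
N_MELS = 64
MEL_FMIN = 125.0
MEL_FMAX = 7_500.0

#: Additive offset inside the log: log(mel energy + LOG_OFFSET).
LOG_OFFSET = 1e-3

#: Embedding width exposed by every backend (matches the pretrained network).
EMBEDDING_DIM = 1024

#: Fixed seed of the mel-stats fallback's random projection. Changing it
#: invalidates every trained artifact, so it is a constant, not a parameter.
MELSTATS_PROJECTION_SEED = 76_132

#: Minimum overlap (fraction of the subframe) for a subframe to be labelled 1.
LABEL_MIN_OVERLAP_S = 0.08

#: Default decoder threshold on the coverage-normalized confidence timeline.
DECODER_TAU = 0.5

#: Event-level matching: a true swallow counts as detected if at least this
#: fraction of its duration is covered by predicted swallow time.
EVENT_MIN_OVERLAP_FRAC = 0.30
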