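"""WAV reading, resampling, normalization and annotation CSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile

from swallowseg.audio_io import (
    AudioSignal,
    EventInterval,
    EventList,
    normalize_amplitude,
    read_events_csv,
    read_wav,
    resample,
    write_events_csv,
    write_wav,
)


class TestReadWav:
    def test_mono_length_and_rate(self, tmp_path, rng):
        path = tmp_path / "mono.wav"
        pcm = (rng.uniform(-0.5, 0.5, 88200) * 32767).astype(np.int16)
        wavfile.write(path, 44100, pcm)
        sig = read_wav(path)
        assert len(sig) == 88200
        assert sig.rate == 44100

    def test_stereo_averaged_to_mono(self, tmp_path):
        path = tmp_path / "stereo.wav"
        half = np.full((1000, 2), int(0.5 * 32767), dtype=np.int16)
        wavfile.write(path, 16000, half)
        sig = read_wav(path)
        assert sig.samples.ndim == 1
        assert np.allclose(sig.samples, half[0, 0] / 32768.0)

    def test_full_scale_int16_maps_near_one(self, tmp_path):
        path = tmp_path / "full.wav"
        wavfile.write(path, 16000, np.full(100, 32767, dtype=np.int16))
        sig = read_wav(path)
        assert np.allclose(sig.samples, 32767 / 32768.0)
        assert np.all(np.abs(sig.samples) <= 1.0)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.wav"):
            read_wav(tmp_path / "nope.wav")

    def test_write_read_round_trip(self, tmp_path, rng):
        sig = AudioSignal(rng.uniform(-0.9, 0.9, 4000), 16000)
        write_wav(tmp_path / "rt.wav", sig)
        back = read_wav(tmp_path / "rt.wav")
        assert back.rate == 16000
        # 16-bit quantization plus the 32767/32768 full-scale convention gap
        assert np.allclose(back.samples, sig.samples, atol=1e-4)


class TestResample:
    def test_same_rate_identity(self, rng):
        sig = AudioSignal(rng.standard_normal(1000), 16000)
        assert resample(sig, 16000) is sig

    def test_44100_to_16000_length(self, rng):
        sig = AudioSignal(rng.standard_normal(44100), 44100)
        out = resample(sig, 16000)
        assert out.rate == 16000
        assert len(out) == 16000

    def test_sine_peak_preserved(self):
        t = np.arange(44100) / 44100
        sig = AudioSignal(np.sin(2 * np.pi * 1000 * t), 44100)
        out = resample(sig, 16000)
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out), 1 / 16000)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 1000.0) <= freqs[1]  # within one FFT bin

    def test_nonpositive_rate_rejected(self, rng):
        sig = AudioSignal(rng.standard_normal(100), 16000)
        with pytest.raises(ValueError):
            resample(sig, 0)

    @given(n=st.integers(min_value=100, max_value=5000))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_length_idempotent(self, n):
        sig = AudioSignal(np.sin(np.linspace(0, 50, n)), 44100)
        once = resample(sig, 16000)
        twice = resample(once, 16000)
        assert len(twice) == len(once)


class TestNormalize:
    def test_all_zero_unchanged(self):
        sig = AudioSignal(np.zeros(10), 16000)
        assert np.array_equal(normalize_amplitude(sig).samples, np.zeros(10))

    def test_peak_two_halved(self):
        sig = AudioSignal(np.array([0.5, -2.0, 1.0]), 16000)
        out = normalize_amplitude(sig)
        assert np.max(np.abs(out.samples)) == 1.0

    def test_ramp_oracle(self):
        out = normalize_amplitude(AudioSignal(np.array([-0.2, 0.1, 0.4]), 16000))
        assert np.allclose(out.samples, [-0.5, 0.25, 1.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    @settings(derandomize=True, deadline=None)
    def test_idempotent(self, values):
        sig = AudioSignal(np.asarray(values), 16000)
        once = normalize_amplitude(sig)
        twice = normalize_amplitude(once)
        assert np.array_equal(once.samples, twice.samples)


class TestEventsCsv:
    def test_parse_two_rows(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("start_s,end_s,label\n0.50,1.10,swallow\n3.00,3.40,swallow\n")
        events = read_events_csv(path)
        assert len(events) == 2
        assert events[0] == EventInterval(0.5, 1.1, "swallow")

    def test_header_only_empty(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("start_s,end_s,label\n")
        assert len(read_events_csv(path)) == 0

    def test_unsorted_rows_sorted_in_memory(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("start_s,end_s,label\n3.0,3.4,swallow\n0.5,1.1,swallow\n")
        events = read_events_csv(path)
        assert [e.start_s for e in events] == [0.5, 3.0]

    @pytest.mark.parametrize(
        "row,msg",
        [
            ("1.0,0.5,swallow", ":2"),          # end <= start, line number named
            ("-1.0,0.5,swallow", ":2"),         # negative time
            ("abc,0.5,swallow", ":2"),          # non-numeric
            ("1.0,2.0", "3 columns"),           # malformed
        ],
    )
    def test_malformed_rows_name_line(self, tmp_path, row, msg):
        path = tmp_path / "bad.csv"
        path.write_text(f"start_s,end_s,label\n{row}\n")
        with pytest.raises(ValueError, match=msg):
            read_events_csv(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("begin,end,tag\n0.1,0.2,swallow\n")
        with pytest.raises(ValueError, match="header"):
            read_events_csv(path)

    @given(
        st.lists(
            st.tuples(st.integers(0, 50_000), st.integers(1, 5_000)),
            min_size=0,
            max_size=20,
        )
    )
    @settings(derandomize=True, deadline=None)
    def test_write_read_round_trip(self, tmp_path_factory, raw):
        # times on the millisecond grid: round trip must be exact
        events = EventList.from_pairs([(a / 1000, (a + d) / 1000) for a, d in raw])
        path = tmp_path_factory.mktemp("csv") / "rt.csv"
        write_events_csv(events, path)
        back = read_events_csv(path)
        assert len(back) == len(events)
        for e1, e2 in zip(back, events):
            assert abs(e1.start_s - e2.start_s) < 5e-4
            assert abs(e1.end_s - e2.end_s) < 5e-4
            assert e1.label == e2.label


class TestEventTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            EventInterval(1.0, 1.0)
        with pytest.raises(ValueError):
            EventInterval(-0.1, 1.0)

    def test_event_list_sorts_and_checks_disjoint(self):
        ev = EventList.from_pairs([(2.0, 3.0), (0.0, 1.0)])
        assert ev[0].start_s == 0.0
        assert ev.is_disjoint()
        overlapping = EventList.from_pairs([(0.0, 2.0), (1.0, 3.0)])
        with pytest.raises(ValueError):
            overlapping.require_disjoint()
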