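"""Containers, file round-trips and signal primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cardiomotor import core_io
from cardiomotor.core_io import (
    EventList,
    Recording,
    bandpass_notch,
    downsample,
    epoch,
    read_events,
    read_recording,
    rereference_mastoids,
    write_events,
    write_recording,
)
from cardiomotor.exceptions import (
    EmptyEpochsError,
    FormatError,
    ParameterError,
)


def _small_recording(rate=1000.0, seconds=2, n_ch=4, seed=0):
    rng = np.random.default_rng(seed)
    n = int(rate * seconds)
    labels = ["C4", "M1", "M2", "ECG"]
    roles = ["eeg", "eeg", "eeg", "ecg"]
    return Recording(rng.standard_normal((n_ch, n)) * 10, rate, labels, roles)


class TestRoundTrips:
    def test_bundle_roundtrip_is_lossless(self, tmp_path):
        rec = _small_recording()
        write_recording(rec, tmp_path / "b", format="bundle")
        back = read_recording(tmp_path / "b")
        np.testing.assert_allclose(back.data, rec.data, rtol=1e-6)
        assert back.labels == rec.labels
        assert back.roles == rec.roles
        assert back.rate == rec.rate

    def test_edf_roundtrip_within_quantization(self, tmp_path):
        rec = _small_recording()
        write_recording(rec, tmp_path / "r.edf", format="edf")
        back = read_recording(tmp_path / "r.edf")
        assert back.rate == rec.rate
        assert back.labels == rec.labels
        assert back.roles == rec.roles  # inferred from channel names
        # 16-bit quantization bounds the error per channel
        for i in range(rec.n_channels):
            step = np.ptp(rec.data[i]) / 2 ** 16
            assert np.max(np.abs(back.data[i] - rec.data[i])) < 2 * step

    def test_truncated_edf_raises_io_error(self, tmp_path):
        rec = _small_recording()
        write_recording(rec, tmp_path / "r.edf", format="edf")
        blob = (tmp_path / "r.edf").read_bytes()
        (tmp_path / "bad.edf").write_bytes(blob[:300])
        with pytest.raises(FormatError, match="bad.edf"):
            read_recording(tmp_path / "bad.edf")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FormatError, match="nope"):
            read_recording(tmp_path / "nope")

    def test_epochs_container_roundtrip(self, tmp_path):
        from cardiomotor.core_io import EpochArray, load_epochs, save_epochs
        rng = np.random.default_rng(3)
        ep = EpochArray(rng.normal(size=(3, 2, 50)), 500.0, -0.02, "tms",
                        ["C4", "EMG"], ["eeg", "emg"],
                        [{"phase": "systole"}, {}, {}],
                        excluded=np.zeros(50, dtype=bool))
        path = tmp_path / "ep.npz"
        save_epochs(ep, path)
        back = load_epochs(path)
        np.testing.assert_array_equal(back.data, ep.data)
        assert back.trial_meta == ep.trial_meta
        assert back.rate == ep.rate and back.tmin == ep.tmin

    def test_events_tsv_roundtrip(self, tmp_path):
        ev = EventList(np.array([0.5, 1.25]), ["tms", "sham"],
                       [{"phase": "systole"}, {}])
        write_events(ev, tmp_path / "ev.tsv")
        back = read_events(tmp_path / "ev.tsv")
        np.testing.assert_allclose(back.times, ev.times)
        assert back.labels == ev.labels
        assert back.meta[0]["phase"] == "systole"


class TestEpoching:
    def test_constant_signal_zero_after_baseline(self):
        rec = _small_recording()
        rec.data[:] = 7.5
        ev = EventList(np.array([1.0]), ["tms"])
        ep = epoch(rec, ev, "tms", -0.2, 0.2, baseline=(-0.1, -0.05))
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_event_near_edge_dropped_and_counted(self):
        rec = _small_recording()
        ev = EventList(np.array([0.1, 1.0]), ["tms", "tms"])
        ep = epoch(rec, ev, "tms", -0.5, 0.2)
        assert ep.n_trials == 1
        assert ep.n_dropped == 1
        assert ep.n_trials + ep.n_dropped == 2

    def test_trial_count_matches_events(self):
        rec = _small_recording()
        times = np.linspace(0.5, 1.5, 10)
        ev = EventList(times, ["tms"] * 10)
        ep = epoch(rec, ev, "tms", -0.1, 0.1)
        assert ep.n_trials == 10

    def test_no_usable_events_raises(self):
        rec = _small_recording()
        ev = EventList(np.array([0.01]), ["tms"])
        with pytest.raises(EmptyEpochsError):
            epoch(rec, ev, "tms", -1.5, 0.5)


class TestFiltering:
    rate = 5000.0

    def _tone(self, f, seconds=4.0, amp=1.0):
        t = np.arange(int(self.rate * seconds)) / self.rate
        return amp * np.sin(2 * np.pi * f * t)

    def test_dc_removed(self):
        rec = Recording(np.full((1, 20000), 10.0), self.rate, ["C4"], ["eeg"])
        out = bandpass_notch(rec)
        assert np.abs(out.data).mean() < 0.1

    def test_notch_attenuates_50hz_by_40db(self):
        x = self._tone(50.0)
        rec = Recording(x[None, :], self.rate, ["C4"], ["eeg"])
        out = bandpass_notch(rec)
        # amplitude of the 50 Hz component (quadrature projection away
        # from the filter edge transients)
        mid = slice(5000, 15000)
        t = np.arange(x.size)[mid] / self.rate
        seg = out.data[0, mid]
        c = 2 * np.mean(seg * np.cos(2 * np.pi * 50 * t))
        s = 2 * np.mean(seg * np.sin(2 * np.pi * 50 * t))
        assert np.hypot(c, s) < 1.0 * 10 ** (-40 / 20)

    def test_passband_tone_preserved(self):
        x = self._tone(10.0)
        rec = Recording(x[None, :], self.rate, ["C4"], ["eeg"])
        out = bandpass_notch(rec)
        mid = slice(5000, 15000)
        amp = np.ptp(out.data[0, mid]) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        rec = _small_recording(rate=100.0)
        with pytest.raises(ParameterError):
            bandpass_notch(rec, band=(0.5, 60.0), notch_stop=None)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=hst.floats(-3, 3), b=hst.floats(-3, 3))
    def test_filter_linearity(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)

        def f(sig):
            rec = Recording(sig[None, :], 1000.0, ["C4"], ["eeg"])
            return bandpass_notch(rec).data[0]

        np.testing.assert_allclose(
            f(a * x + b * y), a * f(x) + b * f(y), atol=1e-8)


class TestRereference:
    def test_mastoids_equal_to_channel_gives_zeros(self):
        rec = _small_recording()
        rec.data[1] = rec.data[0]  # M1
        rec.data[2] = rec.data[0]  # M2
        out = rereference_mastoids(rec)
        np.testing.assert_allclose(out.data[0], 0.0, atol=1e-12)

    def test_zero_mastoids_leave_data_unchanged(self):
        rec = _small_recording()
        rec.data[1] = 0.0
        rec.data[2] = 0.0
        out = rereference_mastoids(rec)
        np.testing.assert_allclose(out.data[0], rec.data[0])

    def test_asymmetric_mastoids_subtract_mean(self):
        rec = _small_recording()
        expect = rec.data[0] - 0.5 * (rec.data[1] + rec.data[2])
        out = rereference_mastoids(rec)
        np.testing.assert_allclose(out.data[0], expect)
        # ECG untouched
        np.testing.assert_allclose(out.data[3], rec.data[3])

    def test_missing_mastoid_raises(self):
        rec = _small_recording()
        rec.labels[1] = "TP9"
        from cardiomotor.exceptions import ChannelError
        with pytest.raises(ChannelError):
            rereference_mastoids(rec)


class TestDownsample:
    def test_tone_preserved_across_decimation(self):
        rate = 5000.0
        t = np.arange(int(rate * 4)) / rate
        x = np.sin(2 * np.pi * 5.0 * t)
        rec = Recording(x[None, :], rate, ["C4"], ["eeg"])
        out = downsample(rec, 500.0)
        assert out.rate == 500.0
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.rate)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(5.0, abs=0.1)
        amp = np.ptp(out.data[0, 200:-200]) / 2
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_constant_stays_constant(self):
        rec = Recording(np.full((1, 5000), 3.0), 5000.0, ["C4"], ["eeg"])
        out = downsample(rec, 500.0)
        np.testing.assert_allclose(out.data[0, 10:-10], 3.0, rtol=1e-6)

    def test_above_target_nyquist_content_suppressed(self):
        rate = 5000.0
        t = np.arange(int(rate * 4)) / rate
        x = np.sin(2 * np.pi * 400.0 * t)
        rec = Recording(x[None, :], rate, ["C4"], ["eeg"])
        out = downsample(rec, 500.0)
        resid = np.sqrt(np.mean(out.data[0, 200:-200] ** 2))
        assert resid < 0.01  # < 1 % of the input amplitude
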