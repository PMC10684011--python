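"""ECG processing: artifact interpolation, R-peaks, T-end, phase windows."""

import numpy as np
import pytest

from cardiomotor import cardiac
from cardiomotor.cardiac import (
    build_cardiac_map,
    classify_events,
    detect_r_peaks,
    detect_t_end,
    ibi_sham_correct,
    ibi_table,
    ibi_triplets,
    interpolate_stim_artifact_ecg,
)
from cardiomotor.core_io import EventList
from cardiomotor.exceptions import DetectionError
from cardiomotor.synthgen import SynthConfig, gen_ecg

from conftest import effects_on_config, null_config


class TestStimArtifactInterpolation:
    rate = 1000.0

    def test_linear_ramp_reproduced(self):
        x = np.linspace(0.0, 10.0, 2000)
        out = interpolate_stim_artifact_ecg(x, self.rate, [1.0])
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_spike_removed(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000) * 0.1
        spike = slice(int(2.001 * self.rate), int(2.006 * self.rate))
        x[spike] += 50.0
        out = interpolate_stim_artifact_ecg(x, self.rate, [2.0])
        win = slice(int(1.998 * self.rate), int(2.011 * self.rate))
        assert np.sqrt(np.mean(out[win] ** 2)) < \
            0.1 * np.sqrt(np.mean(x[win] ** 2))

    def test_no_events_identity(self):
        x = np.random.default_rng(1).standard_normal(1000)
        out = interpolate_stim_artifact_ecg(x, self.rate, [])
        assert np.array_equal(out, x)

    def test_outside_window_bit_identical(self):
        x = np.random.default_rng(2).standard_normal(3000)
        out = interpolate_stim_artifact_ecg(x, self.rate, [1.5])
        i0 = int(np.floor((1.5 - 0.002) * self.rate))
        i1 = int(np.ceil((1.5 + 0.010) * self.rate)) + 1
        assert np.array_equal(out[:i0], x[:i0])
        assert np.array_equal(out[i1:], x[i1:])

    def test_overlapping_windows_merged(self):
        x = np.zeros(2000)
        out = interpolate_stim_artifact_ecg(x, self.rate, [1.0, 1.005])
        np.testing.assert_allclose(out, 0.0)


class TestRPeaks:
    def test_detection_matches_truth(self):
        cfg = SynthConfig(seed=41, rate=500.0, rr_sd_ms=0.0,
                          duration_s=60.0)
        ecg, r_true, _ = gen_ecg(cfg)
        r = detect_r_peaks(ecg, cfg.rate)
        assert r.size == r_true.size
        err = np.abs(r[:, None] - r_true[None, :]).min(axis=1)
        assert np.all(err < 0.005)

    def test_polarity_flip_equivariance(self):
        cfg = SynthConfig(seed=42, rate=500.0, duration_s=40.0)
        ecg, _, _ = gen_ecg(cfg)
        r1 = detect_r_peaks(ecg, cfg.rate)
        r2 = detect_r_peaks(-ecg, cfg.rate)
        np.testing.assert_allclose(r1, r2, atol=2 / cfg.rate)

    def test_white_noise_raises_detection_error(self):
        x = np.random.default_rng(0).standard_normal(10000)
        with pytest.raises(DetectionError):
            detect_r_peaks(x, 1000.0)

    def test_refractory_enforced(self):
        cfg = SynthConfig(seed=43, rate=500.0, duration_s=40.0)
        ecg, _, _ = gen_ecg(cfg)
        r = detect_r_peaks(ecg, cfg.rate)
        assert np.all(np.diff(r) >= 0.25)


class TestTEnd:
    def _gaussian_beat(self, rate=1000.0, sigma=0.040, center=0.300):
        """One R-peak at 0.5 s with a Gaussian T-wave."""
        n = int(3.0 * rate)
        t = np.arange(n) / rate
        x = 800.0 * np.exp(-0.5 * ((t - 0.5) / 0.008) ** 2)
        x += 200.0 * np.exp(-0.5 * ((t - 0.5 - center) / sigma) ** 2)
        return x, np.array([0.5, 1.6]), sigma, 0.5 + center

    def test_gaussian_twave_end_in_tail(self):
        x, r, sigma, c = self._gaussian_beat()
        te = detect_t_end(x, r, 1000.0)
        assert np.isfinite(te[0])
        assert c + 1.5 * sigma <= te[0] <= c + 3.0 * sigma

    def test_matches_exhaustive_argmax_oracle(self):
        x, r, sigma, c = self._gaussian_beat()
        rate = 1000.0
        te = detect_t_end(x, r, rate)
        # independent brute force: T-peak, reference point, trapezoid area
        s0, s1 = int((r[0] + 0.08) * rate), int((r[0] + 0.45) * rate)
        seg = x[s0:s1]
        x_m = s0 + int(np.argmax(seg - np.median(seg)))
        x_r = min(int((r[0] + 0.57) * rate), int((r[1] - 0.01) * rate))
        best, best_area = None, -np.inf
        for xi in range(x_m + 1, x_r):
            area = 0.5 * (x[x_m] - x[xi]) * (2 * x_r - xi - x_m)
            if area > best_area:
                best_area, best = area, xi
        assert abs(te[0] - best / rate) < 0.015

    def test_monotone_tail_knee_matches_oracle(self):
        rate = 1000.0
        n = int(3.0 * rate)
        t = np.arange(n) / rate
        x = 800.0 * np.exp(-0.5 * ((t - 0.5) / 0.008) ** 2)
        # linear descent from a T-peak to baseline, then flat: the knee
        peak, knee = 0.78, 0.95
        ramp = (t >= peak) & (t < knee)
        x[ramp] += 150.0 * (knee - t[ramp]) / (knee - peak)
        x[(t >= 0.70) & (t < peak)] += 150.0 * \
            (t[(t >= 0.70) & (t < peak)] - 0.70) / (peak - 0.70)
        te = detect_t_end(x, np.array([0.5, 1.7]), rate)
        assert te[0] == pytest.approx(knee, abs=0.010)

    def test_flat_ecg_after_qrs_unusable(self):
        rate = 1000.0
        t = np.arange(int(3.0 * rate)) / rate
        x = 800.0 * np.exp(-0.5 * ((t - 0.5) / 0.008) ** 2)
        te = detect_t_end(x, np.array([0.5, 1.6]), rate)
        assert np.isnan(te[0])

    @pytest.mark.parametrize("rr", [700.0, 900.0, 1100.0])
    def test_median_error_under_15ms_across_rates(self, rr):
        # systole shortens at faster heart rates (and the generator requires
        # rr > 2 L): scale the systole length with the cycle
        cfg = SynthConfig(seed=44, rate=500.0, rr_mean_ms=rr,
                          systole_len_ms=min(350.0, 0.42 * rr),
                          duration_s=60.0)
        ecg, r_true, te_true = gen_ecg(cfg)
        r = detect_r_peaks(ecg, cfg.rate)
        te = detect_t_end(ecg, r, cfg.rate)
        errs = []
        for i in np.flatnonzero(np.isfinite(te)):
            j = np.argmin(np.abs(r_true - r[i]))
            errs.append(abs(te[i] - te_true[j]) * 1000)
        assert np.median(errs) < 15.0


class TestCardiacMap:
    def test_windows_forced_by_definition(self):
        cmap = build_cardiac_map(np.array([0.0, 0.9]),
                                 np.array([0.351, np.nan]))
        assert cmap.usable[0]
        assert not cmap.usable[1]  # last beat: no next R
        assert cmap.systole_len[0] == pytest.approx(0.351)
        assert cmap.diastole_start()[0] == pytest.approx(0.549)

    def test_overlapping_windows_unusable(self):
        cmap = build_cardiac_map(np.array([0.0, 0.6]),
                                 np.array([0.351, np.nan]))
        assert not cmap.usable[0]

    def test_systole_equals_diastole_length_exactly(self, session_effects):
        cmap = session_effects["cmap"]
        use = cmap.usable
        dia_len = (cmap.r_time[:-1] + cmap.rr[:-1]) - \
            cmap.diastole_start()[:-1]
        np.testing.assert_allclose(dia_len[use[:-1]],
                                   cmap.systole_len[:-1][use[:-1]])

    def test_mean_systole_matches_generator(self, session_effects):
        cmap = session_effects["cmap"]
        truth = session_effects["truth"]
        est = np.mean(cmap.systole_len[cmap.usable]) * 1000
        true = np.mean((truth.t_ends - truth.r_times)) * 1000
        assert abs(est - true) < 15.0


class TestClassification:
    def _map(self):
        return build_cardiac_map(np.array([0.0, 0.9, 1.8]),
                                 np.array([0.351, 1.251, np.nan]))

    def test_event_in_systole(self):
        ev = EventList(np.array([0.1]), ["tms"])
        out = classify_events(ev, self._map())
        assert out.meta[0]["phase"] == "systole"
        assert out.meta[0]["distance_ms"] == pytest.approx(100.0)

    def test_event_in_gap_is_neither(self):
        ev = EventList(np.array([0.4]), ["tms"])
        out = classify_events(ev, self._map())
        assert out.meta[0]["phase"] == "neither"

    def test_event_in_diastole(self):
        ev = EventList(np.array([0.6]), ["tms"])
        out = classify_events(ev, self._map())
        assert out.meta[0]["phase"] == "diastole"

    def test_event_outside_map_flagged(self):
        ev = EventList(np.array([2.5]), ["tms"])
        out = classify_events(ev, self._map())
        assert out.meta[0]["phase"] == "neither"
        assert out.meta[0].get("outside_map")

    def test_invariant_to_other_labels(self):
        ev = EventList(np.array([0.1]), ["tms"])
        ev2 = EventList(np.array([0.1, 0.2, 0.7]),
                        ["tms", "mock", "rest_probe"])
        out1 = classify_events(ev, self._map())
        out2 = classify_events(ev2, self._map())
        tms_meta = [m for m, l in zip(out2.meta, out2.labels) if l == "tms"]
        assert tms_meta[0]["phase"] == out1.meta[0]["phase"]

    def test_uniform_events_equal_phase_probability(self):
        # equal-length windows equate the probability of landing in either
        cfg = null_config(seed=45, rate=500.0, n_tms=0, n_sham=0,
                          duration_s=120.0)
        from cardiomotor.synthgen import gen_ecg
        ecg, r, te = gen_ecg(cfg)
        cmap = build_cardiac_map(r, te)
        rng = np.random.default_rng(9)
        times = rng.uniform(r[0], r[-1], size=10000)
        out = classify_events(EventList(times, ["mock"] * times.size), cmap)
        n_sys = sum(m["phase"] == "systole" for m in out.meta)
        n_dia = sum(m["phase"] == "diastole" for m in out.meta)
        from scipy.stats import binomtest
        p = binomtest(n_sys, n_sys + n_dia, 0.5).pvalue
        assert p > 0.01


class TestIbi:
    def test_constant_rr_flat_triplets(self):
        r = np.arange(0.0, 20.0, 0.9)
        trips, dropped = ibi_triplets(np.array([5.0, 10.0]), r,
                                      ["systole", "diastole"])
        for tr in trips:
            assert tr.ibi_pre == pytest.approx(900.0)
            assert tr.ibi_tms == pytest.approx(900.0)
            assert tr.ibi_post == pytest.approx(900.0)

    def test_edge_events_dropped(self):
        r = np.array([0.0, 1.0, 2.0, 3.0])
        trips, dropped = ibi_triplets(np.array([0.5, 1.5, 2.5]), r,
                                      ["systole"] * 3)
        assert len(trips) == 1
        assert dropped == 2

    def test_injected_deceleration_recovered(self, session_effects):
        s = session_effects
        cl = s["classified"].select("tms")
        phases = [m["phase"] for m in cl.meta]
        trips, _ = ibi_triplets(cl.times, s["r"], phases)
        tab = ibi_table(trips)
        decel = tab[("tms", "systole")] - tab[("pre", "systole")]
        # injected +40 ms against rr_sd 50 ms sampling noise
        n_sys = sum(1 for p in phases if p == "systole")
        se = 50.0 * np.sqrt(2.0 / max(n_sys, 1))
        assert abs(decel - 40.0) < 3 * se

    def test_sham_self_subtraction_zero(self):
        r = np.arange(0.0, 20.0, 0.9)
        trips, _ = ibi_triplets(np.array([5.0, 10.3]), r,
                                ["systole", "diastole"])
        corr = ibi_sham_correct(trips, trips)
        for tr in corr:
            assert tr.ibi_tms == pytest.approx(0.0, abs=1e-9)
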