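"""Signal conditioning, event detection, peaks, features, fragments."""

import numpy as np
import pandas as pd
import pytest

from cytosim import dsp
from cytosim import signal_sim as ss
from cytosim.signal_sim import NoiseModel, TransitEvent, simulate_event
from cytosim.virtual_lab import PopulationSpec, generate_population, simulate_cells


class TestDetrendAndFilter:
    def test_removes_pure_linear_drift(self):
        n = 5000
        drift = np.linspace(0.0, 2.0, n)[:, None] * np.ones((1, 6))
        out = dsp.detrend_and_filter(drift, baseline_window=301)
        assert np.max(np.abs(out)) < 0.01 * 2.0

    def test_preserves_event_amplitude_under_drift(self, clean_bead_event):
        ev = clean_bead_event.channels
        n = ev.shape[0]
        pad = np.zeros((400, 6))
        stream_clean = np.vstack([pad, ev, pad])
        # slow wander: ~20 % of the peak amplitude across the whole stream
        drift = np.linspace(0.0, 0.01, stream_clean.shape[0])[:, None]
        stream_drift = stream_clean + drift * np.r_[np.ones(3), np.zeros(3)]
        window = 2 * n + 1
        a = dsp.detrend_and_filter(stream_clean, baseline_window=window)
        b = dsp.detrend_and_filter(stream_drift, baseline_window=window)
        pa = dsp.extract_peaks(a[380 : 420 + n], frequencies=(0.5e6, 1e6, 2e6))
        pb = dsp.extract_peaks(b[380 : 420 + n], frequencies=(0.5e6, 1e6, 2e6))
        assert pa.valid and pb.valid
        ratio = abs(pb.amplitudes[0, 1]) / abs(pa.amplitudes[0, 1])
        assert abs(ratio - 1.0) < 0.02

    def test_zero_in_zero_out(self):
        out = dsp.detrend_and_filter(np.zeros((1000, 6)), baseline_window=101)
        assert np.allclose(out, 0.0)

    def test_rejects_short_window(self):
        with pytest.raises(ValueError):
            dsp.detrend_and_filter(np.zeros((100, 6)), baseline_window=2)


class TestDetectEvents:
    def test_pure_noise_yields_no_events(self):
        rng = np.random.default_rng(0)
        stream = rng.normal(0.0, 1e-3, size=(1_000_000, 1))
        assert dsp.detect_events(stream, k=5.0) == []

    def test_recovers_injected_events(self, rng):
        n = 200_000
        noise_sd = 1e-3
        stream = rng.normal(0.0, noise_sd, size=(n, 1))
        pulse = np.sin(np.linspace(0, np.pi, 60)) * 20 * noise_sd
        starts = np.arange(50, 50_000, 1000)[:50] * 4
        for s in starts:
            stream[s : s + 60, 0] += pulse
        spans = dsp.detect_events(stream, k=5.0)
        assert len(spans) == 50
        for (a, b), s in zip(spans, starts):
            assert a <= s and b >= s + 60

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            dsp.detect_events(np.empty((0, 6)))

    def test_low_k_rejected(self):
        with pytest.raises(ValueError):
            dsp.detect_events(np.zeros((100, 1)), k=2.0)


class TestExtractPeaks:
    def test_clean_t1_bead_signs(self, clean_bead_event):
        peaks = dsp.extract_peaks(clean_bead_event)
        assert peaks.valid
        assert peaks.trajectory == "T1"
        signs = np.sign(peaks.amplitudes[0])
        assert list(signs) == [1.0, -1.0, 1.0, -1.0]

    def test_canonical_second_peak_trajectory_invariant(self, clean_bead_event):
        mirrored = -clean_bead_event.channels[::-1]
        peaks_t1 = dsp.extract_peaks(clean_bead_event)
        peaks_t2 = dsp.extract_peaks(mirrored, frequencies=clean_bead_event.frequencies)
        assert peaks_t2.trajectory == "T2"
        assert abs(peaks_t2.amplitudes[0, 1]) == pytest.approx(
            abs(peaks_t1.amplitudes[0, 1]), rel=1e-12
        )

    def test_noise_fragment_rejected(self, rng):
        frag = rng.normal(0.0, 1.0, size=(150, 6))
        peaks = dsp.extract_peaks(frag, frequencies=(0.5e6, 1e6, 2e6))
        assert not peaks.valid
        assert peaks.reason


class TestSizeCalibration:
    def test_noiseless_beads_fit(self, calibration):
        assert np.all(calibration.r_squared > 0.9999)
        assert np.all(np.abs(calibration.intercept) < 0.07)  # ~1% of 7 um

    def test_cube_root_identity_mapping(self):
        # amplitudes {1, 8, 27} with slope 1, intercept 0 -> diameters {1,2,3}
        cal = dsp.SizeCalibration(
            slope=np.ones((3, 4)), intercept=np.zeros((3, 4)),
            r_squared=np.ones((3, 4)), frequencies=(0.5e6, 1e6, 2e6),
        )
        for amp, d in [(1.0, 1.0), (8.0, 2.0), (27.0, 3.0)]:
            assert cal.diameter(amp) == pytest.approx(d)

    def test_two_sizes_rejected(self, electrode, pbs, bead):
        peak_sets = []
        for d in (7.0, 7.0, 10.0):
            sig = simulate_event(TransitEvent(particle=bead.with_diameter(d)),
                                 electrode, pbs)
            peak_sets.append(dsp.extract_peaks(sig))
        with pytest.raises(ValueError, match="3 distinct"):
            dsp.fit_size_calibration(peak_sets, [7.0, 7.0, 10.0])


class TestComputeFeatures:
    def test_equal_amplitudes_give_unit_opacity(self, calibration):
        amps = np.full((3, 4), 2.0) * np.array([1, -1, 1, -1])
        peaks = dsp.PeakSet(indices=np.tile(np.arange(4), (3, 1)),
                            amplitudes=amps, phases=np.full((3, 4), 0.5),
                            trajectory="T1", frequencies=(0.5e6, 1e6, 2e6))
        feats = dsp.compute_features(peaks, calibration)
        assert feats.opacity_1_05 == pytest.approx(1.0)
        assert feats.opacity_2_05 == pytest.approx(1.0)
        assert feats.opacity_2_1 == pytest.approx(1.0)
        assert feats.op_theta_2_05 == pytest.approx(1.0)

    def test_bead_opacity_cv_below_2pct(self, electrode, pbs, bead, calibration):
        noise = NoiseModel(amplitude_noise_sd=1e-3, phase_noise_sd=0.02)
        root = np.random.default_rng(5)
        means = []
        for d in (7.0, 10.0, 15.0, 20.0):
            vals = []
            for _ in range(60):
                rng = np.random.default_rng(root.integers(0, 2**63))
                sig = simulate_event(TransitEvent(particle=bead.with_diameter(d)),
                                     electrode, pbs, noise, rng=rng)
                peaks = dsp.extract_peaks(sig)
                if peaks.valid:
                    vals.append(dsp.compute_features(peaks, calibration).opacity_2_05)
            means.append(np.mean(vals))
        cv = np.std(means) / np.mean(means)
        assert cv < 0.02

    def test_wbc_tumor_orderings(self, electrode, pbs, calibration):
        stats = {}
        for name in ("WBC", "MCF-7"):
            cells, _ = generate_population(PopulationSpec(preset=name, count=150),
                                           seed=11)
            feats = []
            for ev in simulate_cells(cells, config=electrode, seed=12):
                peaks = dsp.extract_peaks(ev)
                if peaks.valid:
                    feats.append(dsp.compute_features(peaks, calibration))
            stats[name] = (
                np.mean([f.estimated_diameter_um for f in feats]),
                np.mean([f.opacity_2_05 for f in feats]),
            )
        assert stats["MCF-7"][0] > stats["WBC"][0]
        assert stats["MCF-7"][1] < stats["WBC"][1]

    def test_zero_low_frequency_amplitude_rejected(self, calibration):
        amps = np.zeros((3, 4))
        peaks = dsp.PeakSet(indices=np.tile(np.arange(4), (3, 1)),
                            amplitudes=amps, phases=amps.copy(),
                            trajectory="T1", frequencies=(0.5e6, 1e6, 2e6))
        with pytest.raises(ValueError):
            dsp.compute_features(peaks, calibration)


class TestMinimumDetectableSize:
    def test_cube_root_noise_scaling(self):
        cal = dsp.SizeCalibration(slope=np.ones((3, 4)), intercept=np.zeros((3, 4)),
                                  r_squared=np.ones((3, 4)),
                                  frequencies=(0.5e6, 1e6, 2e6))
        d1 = dsp.minimum_detectable_size(1e-3, cal)
        d2 = dsp.minimum_detectable_size(2e-3, cal)
        assert d2 == pytest.approx(d1 * 2.0 ** (1.0 / 3.0))

    def test_monotone_in_noise(self, calibration):
        d1 = dsp.minimum_detectable_size(1e-3, calibration)
        d2 = dsp.minimum_detectable_size(5e-3, calibration)
        assert np.all(d2 >= d1)

    def test_second_peak_is_most_sensitive(self, calibration):
        # the strongest lobe reads the smallest minimum size; cross-checked
        # by direct inversion at each peak's own fitted calibration line
        d = dsp.minimum_detectable_size(1e-3, calibration)
        for fi in range(3):
            assert np.argmin(d[fi]) == 1
            amp = (3.0 * 1e-3)  # snr_threshold * noise_sd
            oracle = calibration.slope[fi] * amp ** (1 / 3) + calibration.intercept[fi]
            assert d[fi] == pytest.approx(np.maximum(oracle, 0.0))

    def test_rejects_bad_noise(self, calibration):
        with pytest.raises(ValueError):
            dsp.minimum_detectable_size(0.0, calibration)


class TestResampleFragment:
    def test_long_fragment_resampled(self, rng):
        frag = rng.normal(size=(400, 6))
        out = dsp.resample_fragment(frag)
        assert out.values.shape == (100, 6)

    def test_identity_up_to_normalisation(self, rng):
        frag = rng.normal(size=(100, 6))
        out = dsp.resample_fragment(frag, normalization="per_channel")
        assert np.allclose(out.values * out.scales, frag, atol=1e-6)

    def test_constant_and_zero_channels(self):
        frag = np.zeros((100, 6))
        frag[:, 0] = 3.0
        out = dsp.resample_fragment(frag, normalization="per_channel")
        assert np.allclose(out.values[:, 0], 1.0)
        assert np.allclose(out.values[:, 1:], 0.0)
        assert np.all(np.isfinite(out.values))

    def test_grouped_normalisation_preserves_opacity(self, clean_bead_event):
        out = dsp.resample_fragment(clean_bead_event, normalization="grouped")
        # amplitude channels share one scale -> their ratio is preserved
        orig = clean_bead_event.channels
        r_orig = np.max(np.abs(orig[:, 2])) / np.max(np.abs(orig[:, 0]))
        r_norm = np.max(np.abs(out.values[:, 2])) / np.max(np.abs(out.values[:, 0]))
        assert r_norm == pytest.approx(r_orig, rel=1e-3)

    def test_short_fragment_rejected(self):
        with pytest.raises(ValueError):
            dsp.resample_fragment(np.zeros((10, 6)))


class TestCorrelationMatrix:
    def _frame(self, rng, n=10_000):
        return pd.DataFrame(
            {c: rng.normal(size=n) for c in dsp.FEATURE_COLUMNS}
        )

    def test_diagonal_and_symmetry(self, rng):
        corr, flagged = dsp.feature_correlation_matrix(self._frame(rng, 500))
        m = corr.to_numpy()
        assert np.allclose(np.diag(m), 1.0)
        assert np.max(np.abs(m - m.T)) < 1e-12
        assert flagged == []

    def test_duplicated_feature_correlates_fully(self, rng):
        frame = self._frame(rng, 500)
        frame["opacity_2_05"] = frame["opacity_1_05"]
        corr, _ = dsp.feature_correlation_matrix(frame)
        assert corr.loc["opacity_1_05", "opacity_2_05"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        corr, _ = dsp.feature_correlation_matrix(self._frame(rng, 10_000))
        off = corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_constant_column_flagged(self, rng):
        frame = self._frame(rng, 100)
        frame["op_theta_2_05"] = 1.0
        corr, flagged = dsp.feature_correlation_matrix(frame)
        assert flagged == ["op_theta_2_05"]
        assert corr.loc["op_theta_2_05", "estimated_diameter_um"] != corr.loc[
            "op_theta_2_05", "op_theta_2_05"
        ] or np.isnan(corr.loc["op_theta_2_05", "estimated_diameter_um"])

    def test_too_few_events(self, rng):
        with pytest.raises(ValueError):
            dsp.feature_correlation_matrix(self._frame(rng, 2))


class TestEndToEnd:
    def test_noiseless_diameter_recovery(self, electrode, pbs, bead, calibration):
        for d in (6.0, 9.0, 13.0, 18.0):
            sig = simulate_event(TransitEvent(particle=bead.with_diameter(d)),
                                 electrode, pbs)
            feats = dsp.compute_features(dsp.extract_peaks(sig), calibration)
            assert abs(feats.estimated_diameter_um - d) / d < 0.005

    def test_trajectory_invariant_features(self, electrode, pbs, mcf7, calibration):
        f = {}
        for traj in ("T1", "T2"):
            sig = simulate_event(TransitEvent(particle=mcf7, trajectory=traj),
                                 electrode, pbs)
            f[traj] = dsp.compute_features(dsp.extract_peaks(sig), calibration)
        assert f["T1"].estimated_diameter_um == pytest.approx(
            f["T2"].estimated_diameter_um, rel=1e-12
        )
        assert f["T1"].opacity_2_05 == pytest.approx(f["T2"].opacity_2_05, rel=1e-12)
        assert f["T1"].op_theta_2_05 == pytest.approx(f["T2"].op_theta_2_05, rel=1e-12)

    def test_process_event_stream_accounting(self, electrode, pbs, calibration):
        cells, _ = generate_population(PopulationSpec(preset="MCF-7", count=40), seed=3)
        events = simulate_cells(cells, config=electrode, seed=4)
        result = dsp.process_event_stream(
            events, calibration, 1e-3, rng=np.random.default_rng(5)
        )
        assert result.n_detected == 40
        assert len(result.processed) + sum(result.rejected_reasons.values()) == 40
        for pe in result.processed:
            assert pe.fragment.label == "TUMOR"
            assert pe.event_index is not None
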