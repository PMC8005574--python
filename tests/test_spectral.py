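import numpy as np
import pytest
from scipy import signal as sps

from medstate.spectral import (
    BAND_COLUMNS,
    DEFAULT_BANDS,
    FeatureConfig,
    PowerSpectrum,
    average_vertex_spectra,
    band_power,
    build_feature_table,
    extract_snippet_features,
    lowpass_filter,
    normalize_snippet,
    reject_noisy_epochs,
    segment_snippets,
    welch_psd,
)
from medstate import synthetic

FS = 1000.0


def _epoch_band_power_oracle(signal, fs, n_epoch, lo, hi):
    """Direct per-epoch mean periodogram power, written independently."""
    scores = []
    for i in range(len(signal) // n_epoch):
        seg = signal[i * n_epoch:(i + 1) * n_epoch]
        spec = np.abs(np.fft.rfft(seg)) ** 2 / (fs * len(seg))
        spec[1:-1] *= 2
        f = np.fft.rfftfreq(len(seg), 1 / fs)
        scores.append(spec[(f >= lo) & (f <= hi)].mean())
    return np.array(scores)


class TestRejectNoisyEpochs:
    def test_identical_epochs_none_rejected(self, rng):
        epoch = rng.standard_normal(5000)
        signal = np.tile(epoch, 6)
        mask = reject_noisy_epochs(signal, FS)
        assert mask.keep.all()

    def test_burst_epoch_rejected(self, rng):
        signal = rng.standard_normal(50000)
        t = np.arange(5000) / FS
        signal[15000:20000] += 10 * np.sin(2 * np.pi * 200 * t)  # epoch 3
        mask = reject_noisy_epochs(signal, FS)
        assert not mask.keep[3]
        assert mask.keep.sum() == 9
        oracle = _epoch_band_power_oracle(signal, FS, 5000, 50.0, 330.0)
        np.testing.assert_allclose(mask.rejection_scores, oracle, rtol=1e-8)

    def test_single_epoch_kept(self, rng):
        mask = reject_noisy_epochs(rng.standard_normal(5000), FS)
        assert mask.keep.tolist() == [True]

    def test_too_short_signal_errors(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            reject_noisy_epochs(rng.standard_normal(4000), FS)

    def test_band_clipped_to_nyquist_with_warning(self, rng):
        with pytest.warns(UserWarning, match="Nyquist"):
            reject_noisy_epochs(rng.standard_normal(3000), fs=500.0)


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        out = lowpass_filter(np.ones(20000), FS)
        # after the startup transient, away from resampler edge effects
        assert abs(out[10000] - 1.0) < 1e-6

    def test_half_power_at_48hz(self):
        t = np.arange(0, 60, 1 / FS)
        out = lowpass_filter(np.sin(2 * np.pi * 48.0 * t), FS)
        steady = out[30000:]
        gain = np.sqrt(2) * steady.std()  # amplitude of steady-state sinusoid
        assert abs(gain - 1 / np.sqrt(2)) < 0.01 / np.sqrt(2)

    def test_stopband_matches_closed_form(self):
        # |H(f)| of an order-18 Butterworth: 1/sqrt(1+(f/48)^36)
        t = np.arange(0, 120, 1 / FS)
        out = lowpass_filter(np.sin(2 * np.pi * 100.0 * t), FS)
        steady = out[60000:]
        gain_db = 20 * np.log10(np.sqrt(2) * steady.std())
        expected_db = -10 * np.log10(1 + (100 / 48) ** 36)
        assert abs(expected_db - (-20 * 18 * np.log10(100 / 48))) < 0.1
        assert abs(gain_db - expected_db) < 3.0

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(1000), fs=96.0)

    def test_output_length_preserved(self, rng):
        x = rng.standard_normal(12345)
        assert len(lowpass_filter(x, FS)) == len(x)


class TestSegmentSnippets:
    def test_exactly_one_snippet(self, rng):
        assert len(segment_snippets(rng.standard_normal(5000), FS)) == 1

    def test_180s_gives_71_snippets(self, rng):
        # oracle: floor((180 - 5) / 2.5) + 1
        expected = int(np.floor((180 - 5) / 2.5)) + 1
        assert expected == 71
        snippets = segment_snippets(rng.standard_normal(180000), FS)
        assert len(snippets) == 71
        assert all(len(s) == 5000 for s in snippets)

    def test_short_signal_warns_and_returns_empty(self, rng):
        with pytest.warns(UserWarning, match="snippet"):
            assert segment_snippets(rng.standard_normal(4000), FS) == []

    def test_snippet_starts_at_half_overlap_steps(self):
        x = np.arange(20000, dtype=float)
        snippets = segment_snippets(x, FS)
        starts = [s[0] for s in snippets]
        assert starts == [0.0, 2500.0, 5000.0, 7500.0, 10000.0, 12500.0, 15000.0]


class TestNormalizeSnippet:
    def test_affine_invariance(self, rng):
        x = rng.standard_normal(5000)
        np.testing.assert_allclose(normalize_snippet(3.7 * x - 11.0),
                                   normalize_snippet(x), atol=1e-10)

    def test_idempotent_on_standardized_input(self, rng):
        x = normalize_snippet(rng.standard_normal(5000))
        np.testing.assert_allclose(normalize_snippet(x), x, atol=1e-10)

    def test_variance_four_mapped_to_one(self, rng):
        x = 2.0 * rng.standard_normal(5000)
        out = normalize_snippet(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.var() - 1.0) < 1e-8

    def test_constant_snippet_errors(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_snippet(np.full(100, 2.0))


class TestWelchPsd:
    def test_grid_spacing_half_hz(self, rng):
        spectrum = welch_psd(rng.standard_normal(5000), FS)
        assert spectrum.grid_hz == pytest.approx(0.5)

    def test_white_noise_parseval(self, rng):
        integrals = []
        for _ in range(20):
            x = normalize_snippet(rng.standard_normal(5000))
            s = welch_psd(x, FS)
            integrals.append(np.trapezoid(s.power, s.frequencies_hz))
        assert np.mean(integrals) == pytest.approx(1.0, rel=0.10)

    def test_sinusoid_peak_location(self):
        t = np.arange(5000) / FS
        x = normalize_snippet(np.sin(2 * np.pi * 10.0 * t))
        s = welch_psd(x, FS)
        assert s.frequencies_hz[np.argmax(s.power)] == pytest.approx(10.0)
        # oracle: direct DFT of Hamming-windowed 1 s segments, zero-padded to 2 s
        win = sps.get_window("hamming", 1000)
        segs = [x[i:i + 1000] for i in range(0, 4001, 500)]
        mags = np.mean([np.abs(np.fft.rfft(seg * win, 2000)) ** 2 for seg in segs],
                       axis=0)
        assert np.fft.rfftfreq(2000, 1 / FS)[np.argmax(mags)] == pytest.approx(10.0)

    def test_too_short_snippet_errors(self, rng):
        with pytest.raises(ValueError, match="window"):
            welch_psd(rng.standard_normal(900), FS)


class TestAverageVertexSpectra:
    def grid(self):
        return np.arange(0, 500.5, 0.5)

    def test_single_spectrum_identity(self, rng):
        s = PowerSpectrum(self.grid(), rng.random(1001))
        out = average_vertex_spectra([s])
        np.testing.assert_array_equal(out.power, s.power)

    def test_two_constant_spectra(self):
        a = PowerSpectrum(self.grid(), np.zeros(1001))
        b = PowerSpectrum(self.grid(), np.full(1001, 2.0))
        np.testing.assert_array_equal(average_vertex_spectra([a, b]).power,
                                      np.ones(1001))

    def test_matches_brute_force_mean(self, rng):
        spectra = [PowerSpectrum(self.grid(), rng.random(1001)) for _ in range(5)]
        out = average_vertex_spectra(spectra)
        brute = sum(s.power for s in spectra) / 5
        np.testing.assert_allclose(out.power, brute, atol=1e-12)

    def test_mismatched_grids_error(self, rng):
        a = PowerSpectrum(self.grid(), rng.random(1001))
        b = PowerSpectrum(np.arange(0, 250.5, 0.5), rng.random(501))
        with pytest.raises(ValueError, match="grid"):
            average_vertex_spectra([a, b])


class TestBandPower:
    def grid(self):
        return np.arange(0, 500.5, 0.5)

    def test_flat_psd(self):
        s = PowerSpectrum(self.grid(), np.ones(1001))
        np.testing.assert_allclose(band_power(s), np.ones(4))

    def test_indicator_psd_selects_third_band(self):
        f = self.grid()
        power = ((f >= 20) & (f < 30)).astype(float)
        np.testing.assert_allclose(band_power(PowerSpectrum(f, power)),
                                   [0.0, 0.0, 1.0, 0.0])

    def test_matches_brute_force_bin_mean(self, rng):
        f = self.grid()
        power = rng.random(1001)
        s = PowerSpectrum(f, power)
        for i, (lo, hi) in enumerate(DEFAULT_BANDS):
            brute = np.mean([p for fv, p in zip(f, power) if lo <= fv < hi])
            assert band_power(s)[i] == pytest.approx(brute, abs=1e-12)

    def test_band_outside_grid_errors(self):
        s = PowerSpectrum(np.arange(0, 10.5, 0.5), np.ones(21))
        with pytest.raises(ValueError, match="band"):
            band_power(s, bands=((7.0, 13.0),))

    def test_shared_edge_counted_once(self):
        f = self.grid()
        s = PowerSpectrum(f, np.ones(1001))
        sel1 = (f >= 7) & (f < 13)
        sel2 = (f >= 13) & (f < 20)
        assert not np.any(sel1 & sel2)
        assert np.sum(sel1) + np.sum(sel2) == np.sum((f >= 7) & (f < 20))


class TestBuildFeatureTable:
    def _recordings(self, spec, duration_s=60.0, seed=0):
        return {
            (c, h): synthetic.generate_source_signal(spec, c, h, duration_s, FS, seed)
            for c in synthetic.CONDITIONS for h in synthetic.HEMISPHERES
        }

    def test_sample_count_matches_epoch_mask_oracle(self):
        spec = synthetic.SubjectSpec("S01")
        recs = self._recordings(spec)
        table = build_feature_table(recs)
        # oracle: count snippets fully inside kept epochs, per signal
        expected = 0
        for rec in recs.values():
            mask = reject_noisy_epochs(rec.samples, FS)
            keep = np.ones(len(rec.samples), dtype=bool)
            for start, k in zip(mask.epoch_starts, mask.keep):
                if not k:
                    keep[start:start + 5000] = False
            expected += sum(
                np.all(keep[s:s + 5000])
                for s in range(0, len(rec.samples) - 4999, 2500))
        assert len(table) == expected

    def test_labels_contain_both_conditions(self, null_table):
        assert set(null_table["condition"]) == {"OFF", "ON"}

    def test_contaminated_preset_retains_fewer_samples(self):
        # moderate burst rate: the relative threshold adapts, so heavy
        # contamination would inflate the rejection sd and mask itself
        clean = build_feature_table(
            self._recordings(synthetic.SubjectSpec("S01"), duration_s=120.0))
        noisy = build_feature_table(self._recordings(
            synthetic.contaminated_preset("S01", burst_rate=2.0),
            duration_s=120.0))
        assert len(noisy) < len(clean)

    def test_missing_condition_errors(self):
        spec = synthetic.SubjectSpec("S01")
        recs = self._recordings(spec)
        off_only = {k: v for k, v in recs.items() if k[0] == "OFF"}
        with pytest.raises(ValueError, match="OFF and ON"):
            build_feature_table(off_only)

    def test_determinism(self):
        spec = synthetic.SubjectSpec("S01")
        t1 = build_feature_table(self._recordings(spec))
        t2 = build_feature_table(self._recordings(spec))
        assert t1.equals(t2)

    def test_scale_invariance(self):
        spec = synthetic.SubjectSpec("S01")
        recs = self._recordings(spec)
        scaled = {
            k: synthetic.SourceRecording(v.subject_id, v.condition, v.hemisphere,
                                         v.samples * 250.0, v.sampling_rate_hz)
            for k, v in recs.items()
        }
        t1 = build_feature_table(recs)
        t2 = build_feature_table(scaled)
        np.testing.assert_allclose(t1[list(BAND_COLUMNS)].to_numpy(),
                                   t2[list(BAND_COLUMNS)].to_numpy(), rtol=1e-8)


def test_added_band_power_increases_third_feature():
    # monotone response: a 20-30 Hz ON shift raises bp_20_30 relative to OFF
    spec = synthetic.SubjectSpec("S01", effect_log_power_shift=(0, 0, 1.0, 0))
    recs = {
        (c, h): synthetic.generate_source_signal(spec, c, h, 60.0, FS, seed=0)
        for c in synthetic.CONDITIONS for h in synthetic.HEMISPHERES
    }
    table = build_feature_table(recs)
    means = table.groupby("condition")[list(BAND_COLUMNS)].mean()
    assert means.loc["ON", "bp_20_30"] > means.loc["OFF", "bp_20_30"]
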