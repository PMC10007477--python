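"""HRV indices: time domain, spectrum, band powers, RSA, sliding windows."""

import math

import numpy as np
import pytest

from ei_hrv import (
    RrGenSpec,
    SpectralConfig,
    band_powers,
    generate_rr_series,
    hrv_index_set,
    power_spectrum,
    rr_from_peaks,
    rsa,
    sliding_hrv,
    time_domain_indices,
)
from ei_hrv.hrv import INDEX_NAMES, HrvComputationError, _band_integral


def series_from_intervals(intervals_ms):
    iv = np.asarray(intervals_ms, dtype=float)
    return rr_from_peaks(np.concatenate([[0.0], np.cumsum(iv) / 1000.0]))


def brute_force_time_domain(iv):
    """Independent loop-based recomputation of the time-domain indices."""
    n = len(iv)
    mean = sum(iv) / n
    sdnn = math.sqrt(sum((x - mean) ** 2 for x in iv) / (n - 1))
    diffs = [iv[i + 1] - iv[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d**2 for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(abs(d) > 50 for d in diffs) / len(diffs)
    return {"BPM": 60000.0 / mean, "SDNN": sdnn, "RMSSD": rmssd, "pNN50": pnn50}


class TestTimeDomain:
    def test_constant_intervals(self):
        td = time_domain_indices(np.array([800.0] * 4))
        assert td == {"BPM": 75.0, "SDNN": 0.0, "RMSSD": 0.0, "pNN50": 0.0}

    def test_hand_computed_example(self):
        td = time_domain_indices(np.array([700.0, 750.0, 800.0, 850.0]))
        assert td["BPM"] == pytest.approx(77.4194, abs=1e-4)
        assert td["SDNN"] == pytest.approx(64.5497, abs=1e-4)
        assert td["RMSSD"] == pytest.approx(50.0)
        assert td["pNN50"] == 0.0  # differences equal 50, not "more than 50"

    def test_pnn50_strict_threshold(self):
        td = time_domain_indices(np.array([800.0, 860.0, 800.0]))
        assert td["pNN50"] == 100.0

    def test_matches_brute_force(self, rng):
        iv = rng.normal(800, 50, size=100)
        td = time_domain_indices(iv)
        oracle = brute_force_time_domain(list(iv))
        for key in td:
            assert td[key] == pytest.approx(oracle[key], rel=1e-9)

    def test_too_few_intervals(self):
        with pytest.raises(HrvComputationError):
            time_domain_indices(np.array([800.0, 810.0]))

    def test_rejected_intervals_break_pairs(self):
        from ei_hrv import RrSeries

        iv = np.array([800.0, 860.0, 2500.0, 800.0, 860.0])
        times = np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        quality = np.array([True, True, False, True, True])
        rr = RrSeries(beat_times=times, intervals=iv, quality=quality)
        td = time_domain_indices(rr)
        # pairs: (800,860) and (800,860); the pair spanning the artifact is gone
        assert td["RMSSD"] == pytest.approx(60.0)
        assert td["pNN50"] == 100.0


class TestPowerSpectrum:
    def test_constant_tachogram_has_no_power(self, uniform_rr):
        freqs, psd = power_spectrum(uniform_rr)
        assert _band_integral(freqs, psd, 0.0033, 0.4) < 1e-6

    def test_peak_at_modulation_frequency(self, modulated_rr):
        cfg = SpectralConfig()
        freqs, psd = power_spectrum(modulated_rr, cfg)
        peak = freqs[np.argmax(psd)]
        bin_width = 1.0 / cfg.segment_length
        assert abs(peak - 0.25) <= bin_width

    def test_lf_tone_concentrates_in_lf(self):
        rr = generate_rr_series(
            RrGenSpec(mean_rr=800, modulations=((50.0, 0.1, 0.0),), duration=360)
        )
        cfg = SpectralConfig()
        fd = band_powers(*power_spectrum(rr, cfg), cfg)
        assert fd["LF"] / (fd["VLF"] + fd["LF"] + fd["HF"]) >= 0.95

    def test_power_integrates_to_variance(self, modulated_rr):
        from ei_hrv.hrv import resample_tachogram

        cfg = SpectralConfig()
        freqs, psd = power_spectrum(modulated_rr, cfg)
        _, x = resample_tachogram(modulated_rr, cfg.resample_rate)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(np.var(x), rel=0.10)

    def test_short_epoch_rejected(self):
        rr = series_from_intervals([800.0] * 50)  # 40 s
        with pytest.raises(HrvComputationError, match="shorter"):
            power_spectrum(rr)


class TestBandPowers:
    def test_ln_identity(self, modulated_rr):
        cfg = SpectralConfig()
        fd = band_powers(*power_spectrum(modulated_rr, cfg), cfg)
        for band in ("VLF", "LF", "HF"):
            assert fd[f"ln{band}"] == pytest.approx(math.log(fd[band]), rel=1e-12)

    def test_relative_powers_sum_to_one(self, modulated_rr):
        cfg = SpectralConfig()
        fd = band_powers(*power_spectrum(modulated_rr, cfg), cfg)
        assert fd["VLFp"] + fd["LFp"] + fd["HFp"] == pytest.approx(1.0, abs=1e-9)
        assert fd["LF_HF"] == pytest.approx(fd["LF"] / fd["HF"], rel=1e-12)
        assert fd["VLF_HF"] == pytest.approx(fd["VLF"] / fd["HF"], rel=1e-12)
        assert fd["tHz"] == fd["tPow"]

    def test_coherence_ratio_on_constructed_spectrum(self):
        # 90 % of total power inside +-peak_halfwidth of 0.2 Hz: CohRatio = 9
        cfg = SpectralConfig()
        freqs = np.arange(0.0, 0.5001, 0.0005)
        lo, hi = cfg.total_band
        background = 0.1 / (hi - lo)
        # triangular tone at 0.2 Hz inside +-peak_halfwidth; together with the
        # background under it the window carries 0.9 of the total power:
        # solve (A + b*w) = 0.9 * (0.1 + A) for the triangle area A
        b_times_w = background * 2 * cfg.peak_halfwidth
        tri_area = (0.9 * 0.1 - b_times_w) / (1 - 0.9)
        height = tri_area / cfg.peak_halfwidth
        tri = np.clip(1 - np.abs(freqs - 0.2) / cfg.peak_halfwidth, 0, None) * height
        psd = np.where((freqs >= lo) & (freqs <= hi), background + tri, 0.0)
        fd = band_powers(freqs, psd, cfg)
        assert fd["dHz"] == pytest.approx(0.2, abs=0.001)
        assert fd["CohRatio"] == pytest.approx(9.0, abs=0.5)

    def test_white_spectrum_relative_powers_match_band_widths(self):
        cfg = SpectralConfig()
        freqs = np.linspace(0.0, 0.5, 5001)
        psd = np.ones_like(freqs)
        fd = band_powers(freqs, psd, cfg)
        widths = np.array([0.0367, 0.11, 0.25])
        expected = widths / widths.sum()
        np.testing.assert_allclose(
            [fd["VLFp"], fd["LFp"], fd["HFp"]], expected, rtol=1e-3
        )

    def test_band_integrals_are_additive(self, modulated_rr):
        freqs, psd = power_spectrum(modulated_rr)
        whole = _band_integral(freqs, psd, 0.04, 0.40)
        parts = _band_integral(freqs, psd, 0.04, 0.15) + _band_integral(freqs, psd, 0.15, 0.40)
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_zero_band_power_raises_not_minus_inf(self):
        cfg = SpectralConfig()
        freqs = np.linspace(0.0, 0.5, 1001)
        psd = np.where(freqs > 0.1, 1.0, 0.0)  # VLF band empty
        with pytest.raises(HrvComputationError, match="ln"):
            band_powers(freqs, psd, cfg)

    def test_printed_bands_variant(self):
        cfg = SpectralConfig.printed_bands()
        assert cfg.lf_band == (0.004, 0.15)
        assert cfg.hf_band == (0.015, 0.40)
        with pytest.raises(ValueError):
            SpectralConfig(lf_band=(0.004, 0.15), hf_band=(0.015, 0.40))


class TestRsa:
    def test_constant_tachogram_returns_zero(self, uniform_rr):
        assert rsa(uniform_rr) == 0.0

    def test_respiratory_tone_peak_to_trough(self, modulated_rr):
        assert rsa(modulated_rr) == pytest.approx(100.0, abs=5.0)

    def test_out_of_band_tone_rejected_by_filter(self):
        rr = generate_rr_series(
            RrGenSpec(mean_rr=800, modulations=((50.0, 0.05, 0.0),), duration=360)
        )
        assert rsa(rr) < 5.0

    def test_short_epoch_rejected(self):
        rr = series_from_intervals([800.0] * 40)
        with pytest.raises(HrvComputationError, match="60"):
            rsa(rr)


class TestSlidingHrv:
    def test_window_count(self, modulated_rr):
        ts = sliding_hrv(modulated_rr, window=180, step=10, span=(0.0, 360.0))
        assert ts.n_windows == 19
        assert set(ts.frame.columns) == set(INDEX_NAMES)

    def test_single_window_epoch(self):
        rr = rr_from_peaks(np.arange(0, 180.4, 0.8))
        ts = sliding_hrv(rr, window=180, step=10, span=(0.0, 180.0))
        assert ts.n_windows == 1

    def test_window_longer_than_epoch(self, uniform_rr):
        with pytest.raises(HrvComputationError, match="exceeds"):
            sliding_hrv(uniform_rr, window=500, step=10)

    def test_stationary_input_has_lower_sdnn_variance(self, rng):
        iv_stat = rng.normal(800, 20, size=900)
        iv_step = np.concatenate([rng.normal(800, 5, 450), rng.normal(800, 50, 450)])
        ts_stat = sliding_hrv(series_from_intervals(iv_stat), window=180, step=30)
        ts_step = sliding_hrv(series_from_intervals(iv_step), window=180, step=30)
        var_stat = np.nanvar(ts_stat.frame["SDNN"])
        var_step = np.nanvar(ts_step.frame["SDNN"])
        assert var_stat < var_step


class TestCrossModuleIdentities:
    def test_rmssd_squared_equals_mssd(self, rng):
        from ei_hrv import instability

        iv = rng.normal(800, 40, size=100)
        td = time_domain_indices(iv)
        assert td["RMSSD"] ** 2 == pytest.approx(instability(iv), rel=1e-12)

    def test_scaling_laws(self, rng):
        iv = rng.normal(800, 30, size=500)
        c = 2.5
        scaled = 800 + c * (iv - 800)
        td, td_c = time_domain_indices(iv), time_domain_indices(scaled)
        assert td_c["SDNN"] == pytest.approx(c * td["SDNN"], rel=1e-9)
        assert td_c["RMSSD"] == pytest.approx(c * td["RMSSD"], rel=1e-9)
        cfg = SpectralConfig()
        fd = band_powers(*power_spectrum(series_from_intervals(iv), cfg), cfg)
        fd_c = band_powers(*power_spectrum(series_from_intervals(scaled), cfg), cfg)
        assert fd_c["tPow"] == pytest.approx(c**2 * fd["tPow"], rel=0.05)

    def test_full_index_set_is_complete(self, modulated_rr):
        ix = hrv_index_set(modulated_rr)
        values = ix.as_dict()
        assert set(values) == set(INDEX_NAMES)
        assert all(np.isfinite(v) for v in values.values())
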