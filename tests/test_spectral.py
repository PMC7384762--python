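"""Sliding windows, power spectra, normalization, ACE, linear fits."""

import numpy as np
import pytest

from qusradiomics.config import PipelineConfig
from qusradiomics.datamodel import RFFrame, ROIMask
from qusradiomics.spectral import (
    EmptyGridError,
    NormalizedSpectrum,
    SpectralError,
    band_from_reference,
    build_spectral_maps,
    compensate_attenuation,
    estimate_ace,
    fit_linear_spectrum,
    normalize_spectrum,
    tile_roi,
    window_power_spectrum,
)
from tests.conftest import make_tumour_frame, rect_roi


def _frame_from(samples, fs=40e6, c=1540.0, lateral_pitch=60e-3 / 256):
    return RFFrame(
        samples=samples,
        fs=fs,
        c=c,
        f_center=6.3e6,
        band=(3.0e6, 8.5e6),
        lateral_pitch=lateral_pitch,
    )


class TestTileRoi:
    def test_92_percent_overlap_step(self):
        # 2 mm window at 92 % overlap -> 0.16 mm step per axis
        rng = np.random.default_rng(0)
        fr = _frame_from(rng.normal(size=(1200, 64)))
        roi = ROIMask(np.ones(fr.samples.shape, dtype=bool))
        grid = tile_roi(roi, fr, win_mm=2.0, overlap=0.92)
        step_ax_mm = np.diff(grid.ax_origins)[0] * fr.axial_pitch * 1e3
        assert step_ax_mm == pytest.approx(0.16, abs=fr.axial_pitch * 1e3)
        # lateral pitch 0.234 mm cannot subdivide 0.16 mm; one line is the floor
        assert np.diff(grid.lat_origins)[0] == 1

    def test_roi_smaller_than_window_gives_empty_grid(self):
        rng = np.random.default_rng(0)
        fr = _frame_from(rng.normal(size=(600, 32)))
        mask = np.zeros(fr.samples.shape, dtype=bool)
        mask[10:40, 2:4] = True  # far below 2 mm per side
        grid = tile_roi(ROIMask(mask), fr, 2.0, 0.92)
        assert grid.n_windows == 0

    def test_window_count_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        fr = _frame_from(rng.normal(size=(900, 64)))
        mask = np.zeros(fr.samples.shape, dtype=bool)
        n_ax_roi = int(0.010 / fr.axial_pitch)
        n_lat_roi = int(0.010 / fr.lateral_pitch)
        mask[50 : 50 + n_ax_roi, 5 : 5 + n_lat_roi] = True
        grid = tile_roi(ROIMask(mask), fr, 2.0, 0.92)
        n_ax, n_lat = grid.win_samples
        count = 0
        for a in grid.ax_origins:
            for l in grid.lat_origins:
                count += mask[a : a + n_ax, l : l + n_lat].all()
        assert grid.n_windows == count > 0

    def test_partial_windows_are_discarded(self):
        rng = np.random.default_rng(1)
        fr = _frame_from(rng.normal(size=(900, 64)))
        mask = np.zeros(fr.samples.shape, dtype=bool)
        mask[100:400, 10:40] = True
        mask[150:180, 20:25] = False  # hole
        grid = tile_roi(ROIMask(mask), fr, 2.0, 0.8)
        n_ax, n_lat = grid.win_samples
        for a, l in grid.origins():
            assert mask[a : a + n_ax, l : l + n_lat].all()


class TestWindowSpectrum:
    def test_sinusoid_peak_at_its_frequency(self):
        fs = 40e6
        n = 512
        t = np.arange(n) / fs
        line = np.sin(2 * np.pi * 5e6 * t)
        fr = _frame_from(np.tile(line[:, None], (1, 8)))
        freqs, s_db = window_power_spectrum(fr, (0, 0), (n, 8))
        assert abs(freqs[np.argmax(s_db)] - 5e6) <= freqs[1] - freqs[0]

    def test_amplitude_doubling_adds_6dB(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(size=(256, 8))
        fr1 = _frame_from(samples)
        fr2 = _frame_from(2 * samples)
        _, s1 = window_power_spectrum(fr1, (0, 0), (256, 8))
        _, s2 = window_power_spectrum(fr2, (0, 0), (256, 8))
        np.testing.assert_allclose(s2 - s1, 20 * np.log10(2), atol=1e-9)

    def test_white_noise_variance_shrinks_with_lines(self):
        # periodogram averaging: spectral variance scales ~1/n_lines
        def band_std(n_lines, seed):
            rng = np.random.default_rng(seed)
            fr = _frame_from(rng.normal(size=(256, n_lines)))
            freqs, s_db = window_power_spectrum(fr, (0, 0), (256, n_lines))
            sel = (freqs > 2e6) & (freqs < 18e6)
            return np.std(10 ** (s_db[sel] / 10))

        few = np.median([band_std(4, s) for s in range(20)])
        many = np.median([band_std(32, s) for s in range(20)])
        assert many < few / 2  # expect ~1/sqrt(8) ratio

    def test_all_zero_segment_is_error(self):
        fr = _frame_from(np.r_[np.zeros((64, 8)), np.ones((64, 8))])
        with pytest.raises(SpectralError):
            window_power_spectrum(fr, (0, 0), (64, 8))


class TestNormalize:
    def test_self_normalization_is_zero(self):
        freqs = np.linspace(3e6, 8e6, 32)
        s = np.sin(freqs / 1e6)
        out = normalize_spectrum((freqs, s), s, depth_cm=1.0)
        np.testing.assert_array_equal(out.s_db, np.zeros_like(s))

    def test_double_power_is_3dB(self):
        freqs = np.linspace(3e6, 8e6, 32)
        base = np.zeros(32)
        out = normalize_spectrum((freqs, base + 10 * np.log10(2)), base, depth_cm=1.0)
        np.testing.assert_allclose(out.s_db, 10 * np.log10(2))

    def test_grid_mismatch_is_error(self):
        freqs = np.linspace(3e6, 8e6, 32)
        with pytest.raises(SpectralError):
            normalize_spectrum((freqs, np.zeros(32)), np.zeros(31), depth_cm=1.0)


class TestACE:
    def _make_spectra(self, beta, alpha_ref, depths=(1.0, 1.5, 2.0, 2.5)):
        freqs = np.linspace(3e6, 8.5e6, 24)
        f_mhz = freqs / 1e6
        return [
            NormalizedSpectrum(freqs, -2.0 * beta * f_mhz * d + 1.7, depth_cm=d)
            for d in depths
        ]

    def test_matching_attenuation_returns_alpha_ref(self):
        spectra = self._make_spectra(beta=0.0, alpha_ref=0.5)
        assert estimate_ace(spectra, alpha_ref=0.5).ace == pytest.approx(0.5)

    def test_known_difference_recovered_exactly(self):
        # noise-free spectra decaying at 2*beta*f*z -> ace = alpha_ref + beta
        spectra = self._make_spectra(beta=0.4, alpha_ref=0.5)
        assert estimate_ace(spectra, alpha_ref=0.5).ace == pytest.approx(0.9, abs=1e-10)

    def test_depth_order_invariance(self):
        spectra = self._make_spectra(beta=0.3, alpha_ref=0.5)
        a1 = estimate_ace(spectra, 0.5).ace
        a2 = estimate_ace(spectra[::-1], 0.5).ace
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_insufficient_span_is_error(self):
        spectra = self._make_spectra(0.3, 0.5, depths=(1.0, 1.1, 1.2))
        with pytest.raises(SpectralError):
            estimate_ace(spectra, 0.5)


class TestCompensation:
    def test_identity_when_ace_equals_alpha_ref(self):
        freqs = np.linspace(3e6, 8e6, 16)
        spec = NormalizedSpectrum(freqs, np.sin(freqs / 1e6), depth_cm=2.0)
        out = compensate_attenuation(spec, ace=0.5, alpha_ref=0.5)
        np.testing.assert_array_equal(out.s_db, spec.s_db)

    def test_compensate_then_decompensate_is_identity(self):
        rng = np.random.default_rng(0)
        freqs = np.linspace(3e6, 8e6, 16)
        spec = NormalizedSpectrum(freqs, rng.normal(size=16), depth_cm=3.0)
        comp = compensate_attenuation(spec, ace=1.1, alpha_ref=0.5)
        # de-compensation: swap the roles of ace and alpha_ref
        back = compensate_attenuation(comp, ace=0.5, alpha_ref=1.1)
        np.testing.assert_allclose(back.s_db, spec.s_db, atol=1e-12)


class TestLinearFit:
    def test_flat_spectrum(self):
        freqs = np.linspace(3e6, 8.5e6, 24)
        fit = fit_linear_spectrum(NormalizedSpectrum(freqs, np.zeros(24), 1.0), (3e6, 8.5e6))
        assert (fit.MBF, fit.SS, fit.SI) == (0.0, 0.0, 0.0)

    def test_exact_line_closed_form(self):
        # s = 2 f - 3 over 3.0-8.5 MHz: SS = 2, SI = -3, MBF = 2*5.75 - 3 = 8.5
        freqs = np.linspace(3e6, 8.5e6, 24)
        s = 2.0 * freqs / 1e6 - 3.0
        fit = fit_linear_spectrum(NormalizedSpectrum(freqs, s, 1.0), (3e6, 8.5e6))
        assert fit.SS == pytest.approx(2.0, abs=1e-9)
        assert fit.SI == pytest.approx(-3.0, abs=1e-9)
        assert fit.MBF == pytest.approx(8.5, abs=1e-9)

    def test_midband_midpoint_identity_random_spectra(self):
        rng = np.random.default_rng(4)
        freqs = np.linspace(3e6, 8.5e6, 40)
        for _ in range(25):
            s = rng.normal(size=40)
            fit = fit_linear_spectrum(NormalizedSpectrum(freqs, s, 1.0), (3e6, 8.5e6))
            f_c = 0.5 * (fit.band_used[0] + fit.band_used[1])
            assert fit.MBF == pytest.approx(fit.SS * f_c + fit.SI, abs=1e-9)

    def test_linearity_in_added_line(self):
        # adding a*f + b shifts SS by a and SI by b exactly
        rng = np.random.default_rng(5)
        freqs = np.linspace(3e6, 8.5e6, 40)
        s = rng.normal(size=40)
        base = fit_linear_spectrum(NormalizedSpectrum(freqs, s, 1.0), (3e6, 8.5e6))
        a, b = 1.3, -2.1
        shifted = fit_linear_spectrum(
            NormalizedSpectrum(freqs, s + a * freqs / 1e6 + b, 1.0), (3e6, 8.5e6)
        )
        assert shifted.SS == pytest.approx(base.SS + a, abs=1e-9)
        assert shifted.SI == pytest.approx(base.SI + b, abs=1e-9)

    def test_degenerate_band_is_error(self):
        freqs = np.linspace(3e6, 8.5e6, 24)
        with pytest.raises(SpectralError):
            fit_linear_spectrum(NormalizedSpectrum(freqs, np.zeros(24), 1.0), (9e6, 10e6))


class TestBandFromReference:
    def test_gaussian_reference_recovers_specified_edges(self):
        # Gaussian (in dB: parabola) with -6 dB points at 3.0 and 8.5 MHz
        freqs = np.linspace(0.5e6, 12e6, 600)
        fc, lo, hi = 5.75e6, 3.0e6, 8.5e6
        s_db = -6.0 * ((freqs - fc) / (hi - fc)) ** 2
        band = band_from_reference(freqs, s_db)
        assert band[0] == pytest.approx(lo, abs=2 * (freqs[1] - freqs[0]))
        assert band[1] == pytest.approx(hi, abs=2 * (freqs[1] - freqs[0]))

    def test_flat_spectrum_returns_full_grid(self):
        freqs = np.linspace(1e6, 10e6, 64)
        band = band_from_reference(freqs, np.zeros(64))
        assert band == (freqs[0], freqs[-1])

    def test_scale_invariance(self):
        freqs = np.linspace(0.5e6, 12e6, 300)
        s_db = -6.0 * ((freqs - 5.75e6) / 2.75e6) ** 2
        b1 = band_from_reference(freqs, s_db)
        b2 = band_from_reference(freqs, s_db + 33.3)
        assert b1 == pytest.approx(b2, rel=1e-9)


class TestBuildSpectralMaps:
    def test_empty_grid_raises(self, phantom, fast_cfg):
        frame, _ = make_tumour_frame(seed=3)
        mask = np.zeros(frame.samples.shape, dtype=bool)
        mask[10:30, 2:5] = True
        with pytest.raises(EmptyGridError):
            build_spectral_maps(frame, ROIMask(mask), phantom, fast_cfg)

    def test_homogeneous_medium_maps_are_speckle_limited(self, phantom, fast_cfg):
        frame, truth = make_tumour_frame(seed=7, alpha=0.5)
        maps, ace, rs = build_spectral_maps(frame, rect_roi(frame), phantom, fast_cfg)
        mbf = maps["MBF"].values
        vals = mbf[np.isfinite(mbf)]
        # homogeneous medium: spatial std of MBF stays within a few dB
        assert np.std(vals) < 3.0
        assert maps["MBF"].grid.n_windows == np.isfinite(mbf).sum()

    def test_concentration_contrast_has_correct_sign(self, phantom, fast_cfg):
        # doubling scatterer concentration raises MBF by ~3 dB
        lo_frame, _ = make_tumour_frame(seed=9, alpha=0.5, density=16.0)
        hi_frame, _ = make_tumour_frame(seed=9, alpha=0.5, density=32.0)
        lo_maps, _, _ = build_spectral_maps(lo_frame, rect_roi(lo_frame), phantom, fast_cfg)
        hi_maps, _, _ = build_spectral_maps(hi_frame, rect_roi(hi_frame), phantom, fast_cfg)
        assert hi_maps["MBF"].mean() > lo_maps["MBF"].mean()
        assert hi_maps["MBF"].mean() - lo_maps["MBF"].mean() == pytest.approx(3.0, abs=1.5)
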