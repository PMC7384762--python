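"""Backscatter-coefficient estimation and scatterer-property maps.

The backscatter coefficient (BSC) of each window follows the
reference-phantom method: the sample/reference power ratio (the
attenuation-compensated normalized spectrum) scales the phantom's known
BSC. The spherical Gaussian form-factor model

    BSC(f) = C0 * k^4 * a^6 * conc * exp(-0.827 k^2 a^2),  k = 2 pi f / c

(k in 1/cm, a the effective scatterer radius in cm, conc = n zbar^2 the
acoustic concentration in 1/cm^3, C0 = 1/36 the model's amplitude
convention) is fitted in linearized form — regress ln(BSC / f^4) on k^2 —
yielding the average scatterer diameter ASD = 2 a (reported in microns)
and average acoustic concentration AAC = 10 log10(conc) (dB/cm^3).

Mean spacing among scatterers (SAS, mm) comes from the periodicity of
spectral ripples in a Burg autoregressive power spectrum of the gated
raw RF: a quasi-regular arrangement of scatterers at spacing d imprints
ripples every c/(2 d) Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.regression.linear_model import burg as _burg

from qusradiomics.config import PipelineConfig
from qusradiomics.datamodel import PhantomReference, RFFrame, ROIMask
from qusradiomics.spectral import (
    EmptyGridError,
    NormalizedSpectrum,
    ParametricMap,
    RoiSpectra,
    SpectralError,
    compute_roi_spectra,
)

#: spherical Gaussian form-factor decay constant
GAUSSIAN_FF_CONST = 0.827
#: model amplitude convention (documented, cancels in deltas)
BSC_AMPLITUDE_C0 = 1.0 / 36.0


class BSCFitError(ValueError):
    """Non-physical BSC fit (no size information in the band)."""


@dataclass
class BSCCurve:
    """Backscatter coefficient vs frequency, sr^-1 cm^-1."""

    freqs: np.ndarray  # Hz
    bsc: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.bsc = np.asarray(self.bsc, dtype=float)
        if self.freqs.shape != self.bsc.shape:
            raise ValueError("freqs/bsc shape mismatch")


@dataclass
class BSCFit:
    """Spherical-Gaussian fit of a BSC curve."""

    ASD: float  # effective scatterer diameter, microns
    AAC: float  # 10 log10 acoustic concentration, dB/cm^3
    rss: float  # residual sum of squares of the linearized fit


@dataclass
class SASValue:
    """Mean spacing among scatterers with a coherence score in [0, 1]."""

    SAS: float  # mm
    coherence: float


def bsc_model(freqs_hz: np.ndarray, a_eff_um: float, conc: float, c: float = 1540.0) -> np.ndarray:
    """Model BSC curve for an effective radius (um) and concentration (1/cm^3)."""
    a_cm = a_eff_um * 1e-4
    k = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float) / (c * 100.0)  # 1/cm
    return BSC_AMPLITUDE_C0 * k**4 * a_cm**6 * conc * np.exp(-GAUSSIAN_FF_CONST * (k * a_cm) ** 2)


def estimate_bsc(spec: NormalizedSpectrum, phantom: PhantomReference) -> BSCCurve:
    """Reference-phantom BSC: known reference BSC scaled by the
    (attenuation-compensated) sample/reference power ratio."""
    ref = phantom.bsc_at(spec.freqs)
    if np.any(ref <= 0):
        raise ValueError("reference BSC must be positive over the band")
    return BSCCurve(freqs=spec.freqs, bsc=ref * 10.0 ** (spec.s_db / 10.0))


def _linearized_xy(freqs_hz: np.ndarray, bsc: np.ndarray, c: float) -> tuple[np.ndarray, np.ndarray]:
    k = 2.0 * np.pi * freqs_hz / (c * 100.0)
    y = np.log(bsc) - 4.0 * np.log(k)
    return k**2, y


def fit_gaussian_form_factor(
    bsc: BSCCurve, band_hz: tuple[float, float] | None = None, c: float = 1540.0
) -> BSCFit:
    """Invert the spherical Gaussian model for ASD and AAC.

    Linearized least squares: regress ln(BSC/k^4) on k^2; the slope gives
    the effective radius (a non-negative slope means the band carries no
    size information and raises :class:`BSCFitError`), the intercept the
    concentration once the model's a^6 amplitude factor is divided out.
    """
    if band_hz is not None:
        mask = (bsc.freqs >= band_hz[0]) & (bsc.freqs <= band_hz[1])
    else:
        mask = np.ones(bsc.freqs.shape, dtype=bool)
    mask &= np.isfinite(bsc.bsc) & (bsc.bsc > 0) & (bsc.freqs > 0)
    if mask.sum() < 4:
        raise BSCFitError("need >= 4 positive BSC bins in band")
    x, y = _linearized_xy(bsc.freqs[mask], bsc.bsc[mask], c)
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise BSCFitError("non-negative linearized slope: no scatterer-size information")
    a_cm = float(np.sqrt(-slope / GAUSSIAN_FF_CONST))
    conc = float(np.exp(intercept) / (BSC_AMPLITUDE_C0 * a_cm**6))
    resid = y - (slope * x + intercept)
    return BSCFit(ASD=2.0 * a_cm * 1e4, AAC=10.0 * np.log10(conc), rss=float(resid @ resid))


# ---------------------------------------------------------------------------
# SAS
# ---------------------------------------------------------------------------


def _burg_psd_db(x: np.ndarray, order: int, freqs_hz: np.ndarray, fs: float) -> np.ndarray:
    """Burg AR power spectrum (dB) of one gated line on a frequency grid."""
    rho, sigma2 = _burg(x - x.mean(), order=order)
    w = 2.0 * np.pi * freqs_hz / fs
    _, h = signal.freqz([1.0], np.concatenate([[1.0], -rho]), worN=w)
    return 10.0 * np.log10(sigma2 * np.abs(h) ** 2 + 1e-300)


def estimate_sas(
    frame: RFFrame,
    origin: tuple[int, int],
    win_samples: tuple[int, int],
    c: float = 1540.0,
    ar_order: int = 64,
    band_hz: tuple[float, float] | None = None,
    sas_range_mm: tuple[float, float] = (0.15, 0.8),
) -> SASValue:
    """Mean scatterer spacing from Burg-AR spectral ripple periodicity.

    Per scan line, the Burg AR power spectrum of the gated raw RF is
    computed; dB spectra are averaged across lines, detrended with a
    cubic baseline over the analysis band, and the dominant ripple
    period Delta-f is located as the autocorrelation peak within the lag
    range implied by ``sas_range_mm``. SAS = c / (2 Delta-f); coherence
    is the normalized autocorrelation at the peak (0 when no clear
    periodicity exists — the global maximum is still reported).
    """
    a0, l0 = origin
    n_ax, n_lat = win_samples
    if n_ax < 4 * ar_order:
        raise ValueError(f"window length {n_ax} < 4 x AR order {ar_order}")
    seg = frame.samples[a0 : a0 + n_ax, l0 : l0 + n_lat]
    band_hz = band_hz or sas_band(frame)
    freqs = _sas_freq_grid(band_hz, c, sas_range_mm)
    acc = np.zeros(freqs.size)
    for j in range(n_lat):
        acc += _burg_psd_db(seg[:, j], ar_order, freqs, frame.fs)
    return _detect_ripple_spacing(acc / n_lat, freqs, c, sas_range_mm)


def sas_band(frame: RFFrame) -> tuple[float, float]:
    """Analysis band for SAS: the nominal -6 dB band widened to the
    pulse's ~-20 dB span. The raw (un-normalized) RF keeps usable ripple
    structure well past -6 dB, and short spacings need the extra
    bandwidth to show more than one ripple period."""
    f_lo, f_hi = frame.band
    fc = 0.5 * (f_lo + f_hi)
    half = 0.5 * (f_hi - f_lo) * np.sqrt(20.0 / 6.0)
    return (max(0.05 * frame.fs / 2, fc - half), min(0.9 * frame.fs / 2, fc + half))


def _sas_freq_grid(
    band_hz: tuple[float, float], c: float, sas_range_mm: tuple[float, float]
) -> np.ndarray:
    # dense grid across the band, fine enough for the shortest ripple
    df_min = c / (2.0 * sas_range_mm[1] * 1e-3)  # Hz, longest spacing
    n_grid = max(256, int(8 * (band_hz[1] - band_hz[0]) / df_min))
    return np.linspace(band_hz[0], band_hz[1], n_grid)


def _detect_ripple_spacing(
    mean_db: np.ndarray,
    freqs: np.ndarray,
    c: float,
    sas_range_mm: tuple[float, float],
) -> SASValue:
    """Locate the dominant spectral-ripple period and convert to spacing."""
    n_grid = freqs.size
    # remove the broad pulse envelope, keep the ripples
    xnorm = np.linspace(-1.0, 1.0, n_grid)
    baseline = np.polyval(np.polyfit(xnorm, mean_db, 3), xnorm)
    ripple = mean_db - baseline
    ripple = ripple - ripple.mean()
    ac = np.correlate(ripple, ripple, mode="full")[n_grid - 1 :]
    ac = ac / (n_grid - np.arange(n_grid))  # unbiased: divide by overlap count
    if ac[0] <= 0:
        return SASValue(SAS=float(sas_range_mm[1]), coherence=0.0)
    ac = ac / ac[0]
    dgrid = freqs[1] - freqs[0]
    lag_lo = c / (2.0 * sas_range_mm[1] * 1e-3) / dgrid
    lag_hi = c / (2.0 * sas_range_mm[0] * 1e-3) / dgrid
    i_lo = max(1, int(np.floor(lag_lo)))
    i_hi = min(ac.size - 2, int(np.ceil(lag_hi)))
    if i_hi <= i_lo:
        return SASValue(SAS=float(sas_range_mm[1]), coherence=0.0)
    window = ac[i_lo : i_hi + 1]
    peaks, _ = signal.find_peaks(window)
    if peaks.size:
        # prefer the fundamental: earliest peak comparable to the tallest
        # (harmonics of the ripple period also produce autocorrelation peaks)
        h_max = window[peaks].max()
        rel = int(peaks[window[peaks] >= 0.6 * h_max][0])
    else:
        rel = int(np.argmax(window))
    peak = i_lo + rel
    # sub-bin refinement by parabolic interpolation
    y0, y1, y2 = ac[peak - 1], ac[peak], ac[peak + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    shift = float(np.clip(shift, -0.5, 0.5))
    delta_f = (peak + shift) * dgrid
    sas_mm = c / (2.0 * delta_f) * 1e3
    coherence = float(np.clip(y1, 0.0, 1.0))
    return SASValue(SAS=float(sas_mm), coherence=coherence)


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------


def _sas_map(frame: RFFrame, grid, config: PipelineConfig) -> np.ndarray:
    """SAS per window, sharing Burg PSDs between overlapping windows.

    The AR gate is the window extended axially (centered) to at least
    4 x AR order samples so the model is identifiable; per-(gate, line)
    dB spectra are computed once and averaged per window.
    """
    ar_order = config.ar_order
    n_gate = max(grid.win_samples[0], 4 * ar_order)
    band = sas_band(frame)
    freqs = _sas_freq_grid(band, config.sound_speed, config.sas_range_mm)
    n_ax, n_lat = grid.shape
    sas = np.full((n_ax, n_lat), np.nan)
    n_lat_win = grid.win_samples[1]
    psd_rows: dict[int, np.ndarray] = {}  # a_start -> (n_lines, n_grid) cumsum
    for i, a0 in enumerate(grid.ax_origins):
        if not grid.valid[i].any():
            continue
        a_start = max(0, min(int(a0) - (n_gate - grid.win_samples[0]) // 2, frame.n_samples - n_gate))
        if a_start not in psd_rows:
            seg = frame.samples[a_start : a_start + n_gate]
            psd = np.stack(
                [_burg_psd_db(seg[:, j], ar_order, freqs, frame.fs) for j in range(frame.n_lines)]
            )
            psd_rows[a_start] = np.concatenate(
                [np.zeros((1, freqs.size)), np.cumsum(psd, axis=0)]
            )
        cum = psd_rows[a_start]
        for j, l0 in enumerate(grid.lat_origins):
            if not grid.valid[i, j]:
                continue
            mean_db = (cum[int(l0) + n_lat_win] - cum[int(l0)]) / n_lat_win
            sas[i, j] = _detect_ripple_spacing(
                mean_db, freqs, config.sound_speed, config.sas_range_mm
            ).SAS
    return sas


def build_backscatter_maps(
    frame: RFFrame,
    roi: ROIMask,
    phantom: PhantomReference,
    config: PipelineConfig | None = None,
    roi_spectra: RoiSpectra | None = None,
    include_sas: bool = True,
) -> tuple[dict[str, ParametricMap], dict[str, float]]:
    """ASD, AAC and SAS parametric maps on the ROI window grid.

    Windows whose linearized BSC fit has a non-negative slope carry no
    size information; they are flagged (NaN in the maps, hence excluded
    from map means) and their fraction reported. ``include_sas=False``
    skips the (comparatively expensive) SAS map; its entries stay NaN.
    """
    config = config or PipelineConfig()
    rs = roi_spectra or compute_roi_spectra(frame, roi, phantom, config)
    grid = rs.grid
    if grid.n_windows == 0:
        raise EmptyGridError("ROI admits no analysis window")
    n_ax, n_lat = grid.shape
    c = config.sound_speed

    ref_bsc = phantom.bsc_at(rs.freqs)
    x, _ = _linearized_xy(rs.freqs, np.ones_like(rs.freqs), c)  # x = k^2
    logk4 = 4.0 * np.log(2.0 * np.pi * rs.freqs / (c * 100.0))
    design = np.column_stack([x, np.ones_like(x)])
    pinv = np.linalg.pinv(design)

    asd = np.full((n_ax, n_lat), np.nan)
    aac = np.full((n_ax, n_lat), np.nan)
    sas = np.full((n_ax, n_lat), np.nan)
    n_flagged = 0

    flat = rs.s_db.reshape(n_ax * n_lat, -1)
    ok = np.all(np.isfinite(flat), axis=1)
    bsc_flat = ref_bsc[None, :] * 10.0 ** (flat / 10.0)
    y = np.where(bsc_flat > 0, np.log(np.maximum(bsc_flat, 1e-300)), np.nan) - logk4[None, :]
    coefs = np.full((n_ax * n_lat, 2), np.nan)
    fit_ok = ok & np.all(np.isfinite(y), axis=1)
    if fit_ok.any():
        coefs[fit_ok] = (pinv @ y[fit_ok].T).T
    slope = coefs[:, 0]
    intercept = coefs[:, 1]
    physical = fit_ok & (slope < 0)
    n_flagged = int(fit_ok.sum() - physical.sum())
    a_cm = np.sqrt(np.where(physical, -slope / GAUSSIAN_FF_CONST, np.nan))
    conc = np.exp(intercept) / (BSC_AMPLITUDE_C0 * a_cm**6)
    asd = (2.0 * a_cm * 1e4).reshape(n_ax, n_lat)
    aac = (10.0 * np.log10(conc)).reshape(n_ax, n_lat)

    if include_sas:
        sas = _sas_map(frame, grid, config)

    maps = {
        "ASD": ParametricMap(asd, "ASD", "um", grid),
        "AAC": ParametricMap(aac, "AAC", "dB/cm^3", grid),
        "SAS": ParametricMap(sas, "SAS", "mm", grid),
    }
    qa = {
        "flagged_fraction": n_flagged / max(int(ok.sum()), 1),
        "n_windows": grid.n_windows,
    }
    return maps, qa
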