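"""Sliding-window spectral analysis of RF frames.

Implements the reference-phantom normalization chain: per-window power
spectra (Hann-tapered periodograms averaged across scan lines, in dB),
normalization against a tissue-mimicking phantom at matched depth,
attenuation-coefficient estimation (ACE) from the depth decay of the
normalized spectra, point attenuation compensation, and the linear-fit
parameters mid-band fit (MBF, dB), spectral slope (SS, dB/MHz) and 0-MHz
intercept (SI, dB) over the -6 dB analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from qusradiomics.config import PipelineConfig
from qusradiomics.datamodel import PhantomReference, RFFrame, ROIMask

_DB_FLOOR = 1e-300  # guards log10 of an identically zero periodogram


class EmptyGridError(ValueError):
    """ROI admits no fully-interior analysis window."""


class SpectralError(ValueError):
    """Degenerate spectral input (zero segment, bad band, rank deficiency)."""


@dataclass
class WindowGrid:
    """Raster grid of sliding analysis windows over an ROI.

    ``valid[i, j]`` is True when the window at ``(ax_origins[i],
    lat_origins[j])`` lies fully inside the ROI. The physical step per
    axis is ``win * (1 - overlap)`` rounded to whole samples/lines (at
    least one).
    """

    ax_origins: np.ndarray
    lat_origins: np.ndarray
    valid: np.ndarray
    win_samples: tuple[int, int]
    win_mm: tuple[float, float]
    overlap: float
    axial_pitch: float
    lateral_pitch: float

    @property
    def n_windows(self) -> int:
        return int(self.valid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def origins(self) -> list[tuple[int, int]]:
        """Valid window origins in deterministic raster order."""
        out = []
        for i, a in enumerate(self.ax_origins):
            for j, l in enumerate(self.lat_origins):
                if self.valid[i, j]:
                    out.append((int(a), int(l)))
        return out

    def center_depth_cm(self) -> np.ndarray:
        """Window-center depth (cm) per axial grid row."""
        centers = self.ax_origins + self.win_samples[0] / 2.0
        return centers * self.axial_pitch * 100.0


@dataclass
class NormalizedSpectrum:
    """Sample-minus-reference power spectrum (dB) of one window."""

    freqs: np.ndarray  # Hz, strictly increasing
    s_db: np.ndarray
    depth_cm: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.s_db = np.asarray(self.s_db, dtype=float)
        if self.freqs.shape != self.s_db.shape:
            raise SpectralError("frequency grid mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise SpectralError("freqs must be strictly increasing")


@dataclass
class SpectralFit:
    """Linear fit of a normalized spectrum over the analysis band."""

    MBF: float  # dB, fit value at band center
    SS: float  # dB/MHz
    SI: float  # dB, fit value at 0 MHz
    band_used: tuple[float, float]  # MHz


@dataclass
class ACEValue:
    """Total attenuation slope of the sample medium, dB/cm/MHz."""

    ace: float


@dataclass
class ParametricMap:
    """Per-window map of one QUS parameter; NaN marks outside-ROI cells."""

    values: np.ndarray
    param_id: str
    units: str
    grid: WindowGrid | None = None

    def mean(self) -> float:
        """Mean over valid (finite) windows."""
        vals = self.values[np.isfinite(self.values)]
        if vals.size == 0:
            raise EmptyGridError(f"map {self.param_id} has no valid windows")
        return float(vals.mean())


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------


def tile_roi(
    roi: ROIMask, frame: RFFrame, win_mm: float = 2.0, overlap: float = 0.92
) -> WindowGrid:
    """Tile the ROI with sliding windows of ``win_mm`` per side.

    Only windows whose full pixel set lies inside the ROI are marked
    valid. An ROI smaller than one window yields an empty grid (no
    valid windows), signalled through ``n_windows == 0``.
    """
    roi.validate_against(frame)
    ax_pitch_mm = frame.axial_pitch * 1e3
    lat_pitch_mm = frame.lateral_pitch * 1e3
    n_ax = int(round(win_mm / ax_pitch_mm))
    n_lat = int(round(win_mm / lat_pitch_mm))
    if n_ax < 4 or n_lat < 4:
        raise ValueError(
            f"window of {win_mm} mm maps to {n_ax} x {n_lat} pixels; need >= 4 per axis"
        )
    step_ax = max(1, int(round(n_ax * (1.0 - overlap))))
    step_lat = max(1, int(round(n_lat * (1.0 - overlap))))
    ax_origins = np.arange(0, frame.n_samples - n_ax + 1, step_ax)
    lat_origins = np.arange(0, frame.n_lines - n_lat + 1, step_lat)
    if ax_origins.size == 0 or lat_origins.size == 0:
        valid = np.zeros((max(ax_origins.size, 0), max(lat_origins.size, 0)), dtype=bool)
        return WindowGrid(ax_origins, lat_origins, valid, (n_ax, n_lat), (win_mm, win_mm), overlap, frame.axial_pitch, frame.lateral_pitch)
    # integral image of the mask for O(1) full-inclusion queries
    integ = np.zeros((frame.n_samples + 1, frame.n_lines + 1), dtype=np.int64)
    integ[1:, 1:] = np.cumsum(np.cumsum(roi.mask, axis=0), axis=1)
    a0 = ax_origins[:, None]
    l0 = lat_origins[None, :]
    counts = (
        integ[a0 + n_ax, l0 + n_lat]
        - integ[a0, l0 + n_lat]
        - integ[a0 + n_ax, l0]
        + integ[a0, l0]
    )
    valid = counts == n_ax * n_lat
    return WindowGrid(
        ax_origins,
        lat_origins,
        valid,
        (n_ax, n_lat),
        (win_mm, win_mm),
        overlap,
        frame.axial_pitch,
        frame.lateral_pitch,
    )


# ---------------------------------------------------------------------------
# Power spectra
# ---------------------------------------------------------------------------


def _n_fft_for(n_ax_win: int) -> int:
    n = 1
    while n < 2 * n_ax_win:
        n *= 2
    return n


def power_spectra_grid(
    samples: np.ndarray,
    ax_origins: np.ndarray,
    lat_origins: np.ndarray,
    win_samples: tuple[int, int],
    fs: float,
    n_fft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed power spectra for every (axial, lateral) grid position.

    Each scan line in a window is gated, Hann-tapered and periodogram'd;
    powers are averaged across the window's lines. Returns ``(freqs,
    power)`` with ``power`` of shape (n_ax_pos, n_lat_pos, n_freq),
    linear units.
    """
    n_ax_win, n_lat_win = win_samples
    if n_fft is None:
        n_fft = _n_fft_for(n_ax_win)
    taper = np.hanning(n_ax_win)
    idx = ax_origins[:, None] + np.arange(n_ax_win)[None, :]
    seg = samples[idx, :] * taper[None, :, None]  # (n_ax_pos, n_win, n_lines)
    spec = np.fft.rfft(seg, n=n_fft, axis=1)
    pline = spec.real**2 + spec.imag**2  # per-line power, (n_ax_pos, n_freq, n_lines)
    norm = np.sum(taper**2)
    pline /= norm
    csum = np.concatenate(
        [np.zeros((*pline.shape[:2], 1)), np.cumsum(pline, axis=2)], axis=2
    )
    power = (csum[:, :, lat_origins + n_lat_win] - csum[:, :, lat_origins]) / n_lat_win
    power = np.moveaxis(power, 1, 2)  # -> (n_ax_pos, n_lat_pos, n_freq)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return freqs, power


def window_power_spectrum(
    frame: RFFrame,
    origin: tuple[int, int],
    win_samples: tuple[int, int],
    n_fft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum (dB) of one gated window of ``frame``.

    Per-line Hann-tapered periodograms averaged in power across the
    window's scan lines. An all-zero segment raises :class:`SpectralError`.
    """
    a0, l0 = origin
    n_ax, n_lat = win_samples
    if a0 < 0 or l0 < 0 or a0 + n_ax > frame.n_samples or l0 + n_lat > frame.n_lines:
        raise ValueError("window extends outside the frame")
    seg = frame.samples[a0 : a0 + n_ax, l0 : l0 + n_lat]
    if not np.any(seg):
        raise SpectralError("all-zero RF segment")
    freqs, power = power_spectra_grid(
        seg, np.array([0]), np.array([0]), (n_ax, n_lat), frame.fs, n_fft
    )
    return freqs, 10.0 * np.log10(power[0, 0] + _DB_FLOOR)


def phantom_depth_spectra(
    phantom: PhantomReference,
    ax_origins: np.ndarray,
    n_ax_win: int,
    fs: float,
    n_fft: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference spectrum per depth: phantom power averaged over all scan
    lines and frames at each axial window origin. Returns (freqs, power_db)
    with power_db of shape (n_ax_pos, n_freq)."""
    acc = None
    count = 0
    for frame in phantom.frames:
        if abs(frame.fs - fs) > 1e-6 * fs:
            raise SpectralError("phantom sampling rate differs from sample frame")
        if frame.n_samples < ax_origins.max() + n_ax_win:
            raise SpectralError("phantom frames shallower than the analysis ROI")
        freqs, power = power_spectra_grid(
            frame.samples,
            np.asarray(ax_origins),
            np.array([0]),
            (n_ax_win, frame.n_lines),
            fs,
            n_fft,
        )
        p = power[:, 0, :]
        acc = p if acc is None else acc + p
        count += 1
    mean_power = acc / count
    return freqs, 10.0 * np.log10(mean_power + _DB_FLOOR)


def normalize_spectrum(
    sample_db: NormalizedSpectrum | tuple[np.ndarray, np.ndarray],
    phantom_db: np.ndarray,
    freqs: np.ndarray | None = None,
    depth_cm: float | None = None,
) -> NormalizedSpectrum:
    """Pointwise sample-minus-reference subtraction in dB.

    Accepts either a ``(freqs, s_db)`` pair plus ``depth_cm`` or an
    existing :class:`NormalizedSpectrum`-like object; the phantom
    spectrum must live on the same frequency grid.
    """
    if isinstance(sample_db, NormalizedSpectrum):
        freqs, s_db, depth_cm = sample_db.freqs, sample_db.s_db, sample_db.depth_cm
    else:
        freqs, s_db = sample_db
        if depth_cm is None:
            raise ValueError("depth_cm required")
    phantom_db = np.asarray(phantom_db, dtype=float)
    if phantom_db.shape != np.shape(s_db):
        raise SpectralError("frequency grid mismatch between sample and phantom")
    return NormalizedSpectrum(freqs=freqs, s_db=np.asarray(s_db) - phantom_db, depth_cm=depth_cm)


# ---------------------------------------------------------------------------
# ACE and compensation
# ---------------------------------------------------------------------------


def _ace_beta(depths_cm: np.ndarray, s_db: np.ndarray, freqs_hz: np.ndarray) -> float:
    """Attenuation-difference slope beta (dB/cm/MHz) from depth-resolved
    normalized spectra: per-frequency regression of s_db on depth gives
    m(f) dB/cm; the local attenuation difference is -m(f)/2 (two-way
    travel); beta is the least-squares through-origin slope of that
    difference against frequency in MHz."""
    d = depths_cm - depths_cm.mean()
    denom = np.sum(d**2)
    if denom <= 0:
        raise SpectralError("rank-deficient depth regression")
    m = d @ (s_db - s_db.mean(axis=0)) / denom  # dB/cm per frequency
    delta_alpha = -m / 2.0
    f_mhz = freqs_hz / 1e6
    return float(np.sum(f_mhz * delta_alpha) / np.sum(f_mhz**2))


def estimate_ace(
    spectra: Sequence[NormalizedSpectrum], alpha_ref: float, min_span_cm: float = 0.5
) -> ACEValue:
    """Total attenuation slope of the sample from depth-resolved spectra.

    Requires at least three distinct depths spanning ``min_span_cm``.
    The result is the sample-reference difference slope plus the known
    reference slope, so a sample matching the phantom returns
    ``alpha_ref`` exactly.
    """
    if len(spectra) < 3:
        raise SpectralError("need >= 3 depth-resolved spectra")
    depths = np.array([s.depth_cm for s in spectra])
    if np.unique(depths).size < 3 or depths.max() - depths.min() < min_span_cm:
        raise SpectralError("insufficient depth span for ACE")
    freqs = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != freqs.shape or not np.allclose(s.freqs, freqs):
            raise SpectralError("spectra must share a common band")
    s_db = np.stack([s.s_db for s in spectra])
    return ACEValue(ace=_ace_beta(depths, s_db, freqs) + alpha_ref)


def compensate_attenuation(
    spec: NormalizedSpectrum, ace: float, alpha_ref: float
) -> NormalizedSpectrum:
    """Point attenuation compensation at the window's depth (two-way).

    Adds ``2 (ace - alpha_ref) f_MHz depth_cm`` so that the residual
    sample-vs-reference attenuation difference is removed from the
    normalized spectrum.
    """
    if not np.isfinite(ace):
        raise SpectralError("ACE must be finite")
    f_mhz = spec.freqs / 1e6
    corr = 2.0 * (ace - alpha_ref) * f_mhz * spec.depth_cm
    return NormalizedSpectrum(freqs=spec.freqs, s_db=spec.s_db + corr, depth_cm=spec.depth_cm)


# ---------------------------------------------------------------------------
# Linear fits and band selection
# ---------------------------------------------------------------------------


def fit_linear_spectrum(
    spec: NormalizedSpectrum, band_hz: tuple[float, float]
) -> SpectralFit:
    """Ordinary least squares of s_db against frequency (MHz) over the band.

    SS is the slope, SI the intercept at 0 MHz, and MBF the fitted value
    at the band center, so MBF = SS * f_c + SI identically.
    """
    lo, hi = band_hz
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 3:
        raise SpectralError("analysis band holds fewer than 3 bins")
    f_mhz = spec.freqs[mask] / 1e6
    ss, si = np.polyfit(f_mhz, spec.s_db[mask], 1)
    f_c = 0.5 * (lo + hi) / 1e6
    return SpectralFit(
        MBF=float(ss * f_c + si),
        SS=float(ss),
        SI=float(si),
        band_used=(lo / 1e6, hi / 1e6),
    )


def band_from_reference(
    freqs_hz: np.ndarray, phantom_db: np.ndarray, drop_db: float = 6.0
) -> tuple[float, float]:
    """-6 dB band of the reference (system) spectrum.

    Contiguous interval around the spectral peak where the spectrum stays
    within ``drop_db`` of its maximum; edges are linearly interpolated
    between bins. Invariant to overall scaling (a dB shift).
    """
    phantom_db = np.asarray(phantom_db, dtype=float)
    peak = int(np.argmax(phantom_db))
    thresh = phantom_db[peak] - drop_db
    lo_idx = peak
    while lo_idx > 0 and phantom_db[lo_idx - 1] >= thresh:
        lo_idx -= 1
    hi_idx = peak
    while hi_idx < phantom_db.size - 1 and phantom_db[hi_idx + 1] >= thresh:
        hi_idx += 1
    if hi_idx - lo_idx + 1 < 3:
        raise SpectralError("-6 dB band narrower than 3 bins")
    f_lo = freqs_hz[lo_idx]
    if lo_idx > 0:
        d0, d1 = phantom_db[lo_idx - 1], phantom_db[lo_idx]
        f_lo = freqs_hz[lo_idx - 1] + (thresh - d0) / (d1 - d0) * (
            freqs_hz[lo_idx] - freqs_hz[lo_idx - 1]
        )
    f_hi = freqs_hz[hi_idx]
    if hi_idx < phantom_db.size - 1:
        d0, d1 = phantom_db[hi_idx], phantom_db[hi_idx + 1]
        f_hi = freqs_hz[hi_idx] + (thresh - d0) / (d1 - d0) * (
            freqs_hz[hi_idx + 1] - freqs_hz[hi_idx]
        )
    return float(f_lo), float(f_hi)


# ---------------------------------------------------------------------------
# ROI pipeline
# ---------------------------------------------------------------------------


@dataclass
class RoiSpectra:
    """All per-window spectra of one ROI, normalized and compensated."""

    grid: WindowGrid
    freqs: np.ndarray  # band-limited grid, Hz
    band: tuple[float, float]  # Hz
    s_db: np.ndarray  # (n_ax, n_lat, n_freq) compensated; NaN outside ROI
    s_db_raw: np.ndarray  # before attenuation compensation
    ace: ACEValue
    depth_cm: np.ndarray  # per axial grid row (window centers)


def compute_roi_spectra(
    frame: RFFrame,
    roi: ROIMask,
    phantom: PhantomReference,
    config: PipelineConfig | None = None,
) -> RoiSpectra:
    """Windowed, normalized, attenuation-compensated spectra for an ROI.

    The ACE is estimated once per ROI as the median of per-lateral-column
    depth-decay estimates (columns need >= 3 depths spanning 0.5 cm;
    if no column qualifies the pooled windows are used).
    """
    config = config or PipelineConfig()
    grid = tile_roi(roi, frame, config.window_mm, config.overlap)
    if grid.n_windows == 0:
        raise EmptyGridError("ROI admits no analysis window")
    n_ax_win, n_lat_win = grid.win_samples
    n_fft = _n_fft_for(n_ax_win)
    freqs, power = power_spectra_grid(
        frame.samples, grid.ax_origins, grid.lat_origins, grid.win_samples, frame.fs, n_fft
    )
    sample_db = 10.0 * np.log10(power + _DB_FLOOR)
    pfreqs, phantom_db = phantom_depth_spectra(
        phantom, grid.ax_origins, n_ax_win, frame.fs, n_fft
    )
    # analysis band
    if config.band_mode == "fixed":
        band = (config.fixed_band_mhz[0] * 1e6, config.fixed_band_mhz[1] * 1e6)
    else:
        valid_rows = grid.valid.any(axis=1)
        row_weights = grid.valid.sum(axis=1)[valid_rows]
        mean_ref = np.average(phantom_db[valid_rows], axis=0, weights=row_weights)
        band = band_from_reference(freqs, mean_ref)
    bmask = (freqs >= band[0]) & (freqs <= band[1])
    if bmask.sum() < 3:
        raise SpectralError("analysis band holds fewer than 3 bins")
    bfreqs = freqs[bmask]
    s_raw = sample_db[:, :, bmask] - phantom_db[:, None, bmask]
    s_raw = np.where(grid.valid[:, :, None], s_raw, np.nan)
    depth_cm = grid.center_depth_cm()

    # ACE: median over qualifying lateral columns
    betas = []
    for j in range(grid.lat_origins.size):
        rows = np.flatnonzero(grid.valid[:, j])
        if rows.size < 3:
            continue
        d = depth_cm[rows]
        if d.max() - d.min() < 0.5:
            continue
        betas.append(_ace_beta(d, s_raw[rows, j, :], bfreqs))
    if betas:
        beta = float(np.median(betas))
    else:
        rows, cols = np.nonzero(grid.valid)
        d = depth_cm[rows]
        if np.unique(d).size < 3 or d.max() - d.min() < 0.5:
            raise SpectralError("insufficient depth span in ROI for ACE")
        beta = _ace_beta(d, s_raw[rows, cols, :], bfreqs)
    ace = ACEValue(ace=beta + config.alpha_ref_db_cm_mhz)

    corr = (
        2.0
        * (ace.ace - config.alpha_ref_db_cm_mhz)
        * (bfreqs / 1e6)[None, None, :]
        * depth_cm[:, None, None]
    )
    s_comp = s_raw + corr
    return RoiSpectra(
        grid=grid,
        freqs=bfreqs,
        band=band,
        s_db=s_comp,
        s_db_raw=s_raw,
        ace=ace,
        depth_cm=depth_cm,
    )


def build_spectral_maps(
    frame: RFFrame,
    roi: ROIMask,
    phantom: PhantomReference,
    config: PipelineConfig | None = None,
    roi_spectra: RoiSpectra | None = None,
) -> tuple[dict[str, ParametricMap], ACEValue, RoiSpectra]:
    """MBF/SS/SI parametric maps plus the per-ROI ACE.

    Per-window linear fits are computed on the compensated normalized
    spectra over the analysis band.
    """
    config = config or PipelineConfig()
    rs = roi_spectra or compute_roi_spectra(frame, roi, phantom, config)
    f_mhz = rs.freqs / 1e6
    design = np.column_stack([f_mhz, np.ones_like(f_mhz)])
    pinv = np.linalg.pinv(design)
    n_ax, n_lat, _ = rs.s_db.shape
    flat = rs.s_db.reshape(n_ax * n_lat, -1)
    ok = np.all(np.isfinite(flat), axis=1)
    coefs = np.full((n_ax * n_lat, 2), np.nan)
    if ok.any():
        coefs[ok] = (pinv @ flat[ok].T).T
    ss = coefs[:, 0].reshape(n_ax, n_lat)
    si = coefs[:, 1].reshape(n_ax, n_lat)
    f_c = 0.5 * (rs.band[0] + rs.band[1]) / 1e6
    mbf = ss * f_c + si
    maps = {
        "MBF": ParametricMap(mbf, "MBF", "dB", rs.grid),
        "SS": ParametricMap(ss, "SS", "dB/MHz", rs.grid),
        "SI": ParametricMap(si, "SI", "dB", rs.grid),
    }
    return maps, rs.ace, rs
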