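"""Synthetic inputs with known ground truth.

RF simulation: each scan line is a sum of pulse echoes (Gaussian-
modulated cosine) from point scatterers at two-way delays 2z/c,
synthesized in the frequency domain so sub-sample delays are exact.
Echo spectra are shaped by the spherical Gaussian form factor at the
true effective radius and by a linear-in-frequency attenuation law
(dB/cm/MHz, two-way). This line-by-line 1-D convolution physics is
sufficient to exercise every estimator in the package; it is not a wave
solver (no diffraction, no beam profile, no multiple scattering).

Cohort simulation: two-class feature tables whose week-minus-baseline
changes follow prescribed group means and SEM-derived standard
deviations, with all remaining features drawn from a shared
distribution (pure noise with respect to the response label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from qusradiomics.backscatter import bsc_model
from qusradiomics.datamodel import PhantomReference, RFFrame, SubjectRecord
from qusradiomics.features import SCAN_FEATURE_NAMES, ScanFeatures

# default acquisition: 6 MHz-class linear array (40 MHz sampling,
# 6.3 MHz center, 3.0-8.5 MHz band, 60 mm aperture / 512 lines)
DEFAULT_FS = 40e6
DEFAULT_FC = 6.3e6
DEFAULT_BAND = (3.0e6, 8.5e6)
DEFAULT_C = 1540.0
DEFAULT_LATERAL_PITCH = 60e-3 / 512


@dataclass
class SimulationTruth:
    """Ground truth fully determining a simulated medium (given a seed)."""

    alpha_true: float = 0.5  # dB/cm/MHz
    a_eff_true: float = 25.0  # effective scatterer radius, um
    density_true: float = 24.0  # scatterers per mm^2 (2-D field)
    spacing_true: float | None = None  # mm; quasi-periodic lattice when set
    spacing_jitter: float = 0.05  # fraction of spacing_true
    impedance_var: float = 1.0  # variance of relative-impedance amplitudes
    pulse_fc: float = DEFAULT_FC  # Hz
    pulse_band: tuple[float, float] = DEFAULT_BAND  # -6 dB band, Hz

    @property
    def concentration_cm3(self) -> float:
        """Acoustic concentration n zbar^2 under the package convention
        (2-D density promoted to volume with unit elevation)."""
        return self.density_true * 100.0 * self.impedance_var


@dataclass
class ScattererField:
    """Point scatterers: positions (z, x) in metres and amplitudes."""

    positions: np.ndarray  # (N, 2)
    amplitudes: np.ndarray  # (N,)
    depth_m: float
    width_m: float


def simulate_scatterer_field(
    truth: SimulationTruth,
    depth_m: float,
    width_m: float,
    rng: np.random.Generator,
    lateral_pitch: float = DEFAULT_LATERAL_PITCH,
) -> ScattererField:
    """Random (Poisson) or jittered-lattice scatterer positions.

    Poisson mode draws ``density_true * area`` points uniformly; lattice
    mode places one axial column per scan line at ``spacing_true`` mm
    with Gaussian jitter and an independent random phase per line.
    Amplitudes are zero-mean normal with variance ``impedance_var``.
    """
    if truth.spacing_true is None:
        area_mm2 = depth_m * 1e3 * width_m * 1e3
        n = int(rng.poisson(truth.density_true * area_mm2))
        z = rng.uniform(0, depth_m, n)
        x = rng.uniform(0, width_m, n)
    else:
        d = truth.spacing_true * 1e-3
        n_lines = int(np.floor(width_m / lateral_pitch))
        zs, xs = [], []
        for j in range(n_lines):
            z0 = rng.uniform(0, d)
            kmax = int(np.ceil(depth_m / d)) + 1
            zj = z0 + np.arange(kmax) * d + rng.normal(0, truth.spacing_jitter * d, kmax)
            zj = zj[(zj >= 0) & (zj < depth_m)]
            zs.append(zj)
            xs.append(np.full(zj.size, (j + 0.5) * lateral_pitch))
        z = np.concatenate(zs) if zs else np.empty(0)
        x = np.concatenate(xs) if xs else np.empty(0)
    amps = rng.normal(0.0, np.sqrt(truth.impedance_var), z.size)
    return ScattererField(
        positions=np.column_stack([z, x]) if z.size else np.empty((0, 2)),
        amplitudes=amps,
        depth_m=depth_m,
        width_m=width_m,
    )


def _pulse_amplitude(freqs: np.ndarray, fc: float, band: tuple[float, float]) -> np.ndarray:
    """Gaussian pulse amplitude spectrum with the given -6 dB band."""
    half_bw = max(fc - band[0], band[1] - fc)
    # amplitude drops to 10^(-6/20) at half_bw from center
    sigma = half_bw / np.sqrt(2.0 * np.log(10 ** (6.0 / 20.0)))
    return np.exp(-((freqs - fc) ** 2) / (2.0 * sigma**2))


def _form_factor_amplitude(freqs: np.ndarray, a_eff_um: float, c: float) -> np.ndarray:
    """Amplitude filter whose squared magnitude follows the spherical
    Gaussian BSC shape (k^4 a^6 exp(-0.827 k^2 a^2), up to constants)."""
    a_cm = a_eff_um * 1e-4
    k = 2.0 * np.pi * freqs / (c * 100.0)
    # power scales as k^4 a^6: amplitude k^2 a^3 times half the exponential decay
    return k**2 * a_cm**3 * np.exp(-0.827 * (k * a_cm) ** 2 / 2.0)


def simulate_rf(
    field: ScattererField,
    truth: SimulationTruth,
    fs: float = DEFAULT_FS,
    depth_m: float | None = None,
    n_lines: int | None = None,
    lateral_pitch: float = DEFAULT_LATERAL_PITCH,
    c: float = DEFAULT_C,
    snr_db: float = 35.0,
    rng: np.random.Generator | None = None,
    system_id: str = "synthetic",
) -> RFFrame:
    """Synthesize one RF frame from a scatterer field.

    Scatterers are assigned to the nearest scan line; each line's
    spectrum is the pulse times the form factor times the sum of
    attenuated, delayed echoes. White noise is added at ``snr_db``
    relative to the frame RMS.
    """
    if fs < 4 * truth.pulse_fc:
        raise ValueError("sampling rate below 4x center frequency (aliasing)")
    rng = rng or np.random.default_rng(0)
    depth_m = depth_m or field.depth_m
    n_lines = n_lines or int(np.floor(field.width_m / lateral_pitch))
    n_samples = int(round(depth_m / (c / (2.0 * fs))))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = _pulse_amplitude(freqs, truth.pulse_fc, truth.pulse_band)
    shaping = shaping * _form_factor_amplitude(freqs, truth.a_eff_true, c)
    samples = np.zeros((n_samples, n_lines))
    if field.positions.shape[0]:
        cols = np.floor(field.positions[:, 1] / lateral_pitch).astype(int)
        z = field.positions[:, 0]
        keep = (cols >= 0) & (cols < n_lines) & (z < depth_m)
        cols, z, amps = cols[keep], field.positions[keep, 0], field.amplitudes[keep]
        f_mhz = freqs / 1e6
        for j in np.unique(cols):
            sel = cols == j
            zj = z[sel]  # (m,)
            aj = amps[sel]
            z_cm = zj * 100.0
            # two-way attenuation (amplitude) and delay per scatterer
            atten = 10.0 ** (-truth.alpha_true * np.outer(z_cm, f_mhz) / 10.0)
            phase = np.exp(-2j * np.pi * np.outer(2.0 * zj / c, freqs))
            spec = (aj[:, None] * atten * phase).sum(axis=0) * shaping
            samples[:, j] = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(samples**2))
    if rms == 0:
        rms = 1.0
    noise_sd = rms * 10.0 ** (-snr_db / 20.0)
    samples += rng.normal(0.0, noise_sd, samples.shape)
    return RFFrame(
        samples=samples,
        fs=fs,
        c=c,
        f_center=truth.pulse_fc,
        band=truth.pulse_band,
        lateral_pitch=lateral_pitch,
        system_id=system_id,
    )


def simulate_phantom(
    fs: float = DEFAULT_FS,
    depth_m: float = 0.03,
    width_m: float = 0.015,
    alpha_ref: float = 0.5,
    seed: int = 0,
    n_frames: int = 4,
    a_eff_um: float = 20.0,
    density_mm2: float = 24.0,
    impedance_var: float = 1.0,
    lateral_pitch: float = DEFAULT_LATERAL_PITCH,
    c: float = DEFAULT_C,
    pulse_fc: float = DEFAULT_FC,
    pulse_band: tuple[float, float] = DEFAULT_BAND,
    snr_db: float = 35.0,
) -> tuple[PhantomReference, SimulationTruth]:
    """Homogeneous reference phantom (agar/glass-bead analogue).

    The tabulated ``bsc_ref`` is computed from the same generative model
    as the frames, so reference-phantom normalization is exact in
    expectation. Returns the phantom and its generating truth.
    """
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(
        alpha_true=alpha_ref,
        a_eff_true=a_eff_um,
        density_true=density_mm2,
        impedance_var=impedance_var,
        pulse_fc=pulse_fc,
        pulse_band=pulse_band,
    )
    frames = []
    for _ in range(n_frames):
        fld = simulate_scatterer_field(truth, depth_m, width_m, rng, lateral_pitch)
        frames.append(
            simulate_rf(
                fld, truth, fs, depth_m, None, lateral_pitch, c, snr_db, rng, "synthetic-phantom"
            )
        )
    f_grid = np.linspace(0.5e6, min(15e6, fs / 2 * 0.95), 128)
    bsc = bsc_model(f_grid, a_eff_um, truth.concentration_cm3, c)
    phantom = PhantomReference(
        frames=frames, alpha_ref=alpha_ref, bsc_ref=np.column_stack([f_grid, bsc])
    )
    return phantom, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """A group-separating change feature: week, group means and SEMs.

    The per-group standard deviation is reconstructed as SEM * sqrt(n).
    """

    week: int  # 1 or 4
    mean_r: float
    sem_r: float
    mean_nr: float
    sem_nr: float


#: the two response-separating effects reported for this protocol:
#: week-1 change in ACE and week-4 change in AAC (group mean +/- SEM)
TABLE_EFFECTS: dict[str, EffectSpec] = {
    "ACE": EffectSpec(week=1, mean_r=-3.00, sem_r=0.18, mean_nr=-3.70, sem_nr=0.20),
    "AAC": EffectSpec(week=4, mean_r=5.52, sem_r=0.93, mean_nr=2.58, sem_nr=0.54),
}

#: plausible baseline (mean, sd) per feature family for synthetic cohorts
_BASELINE_DEFAULTS: dict[str, tuple[float, float]] = {
    "MBF": (-5.0, 2.0),
    "SS": (0.5, 0.2),
    "SI": (-10.0, 3.0),
    "ACE": (1.0, 0.3),
    "ASD": (50.0, 10.0),
    "AAC": (30.0, 5.0),
    "SAS": (0.30, 0.05),
    "CON": (5.0, 1.0),
    "COR": (0.5, 0.1),
    "HOM": (0.7, 0.05),
    "ENE": (0.2, 0.05),
}


def _baseline_params(name: str) -> tuple[float, float]:
    key = name.split("-")[-1] if "-" in name else name
    return _BASELINE_DEFAULTS[key]


@dataclass
class CohortSpec:
    """Synthetic two-class cohort specification.

    ``effects`` maps feature names to :class:`EffectSpec`; every other
    feature's weekly change is pure noise shared between groups. Noise
    changes have SD ``noise_delta_scale`` times the feature's baseline SD.
    """

    n_r: int = 35
    n_nr: int = 24
    effects: Mapping[str, EffectSpec] = field(default_factory=lambda: dict(TABLE_EFFECTS))
    noise_delta_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_r < 2 or self.n_nr < 2:
            raise ValueError("need >= 2 subjects per group")


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a synthetic cohort with W0/W1/W4 scans and labels.

    Week values are baseline + change; for an informative feature at its
    effect week the change is drawn per group with SD = SEM * sqrt(n);
    everywhere else changes are label-independent noise. Clinical
    pre/post sizes are generated consistently with the labels (responder
    shrinkage > 30 % or pCR; non-responders below 30 %).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    groups = [("R", spec.n_r), ("NR", spec.n_nr)]
    counter = 0
    for label, n_group in groups:
        for _ in range(n_group):
            counter += 1
            sid = f"S{counter:03d}"
            base = {}
            for name in SCAN_FEATURE_NAMES:
                mu, sd = _baseline_params(name)
                base[name] = rng.normal(mu, sd)
            tps = {"W0": ScanFeatures(dict(base))}
            for week in (1, 4):
                vals = {}
                for name in SCAN_FEATURE_NAMES:
                    mu, sd = _baseline_params(name)
                    eff = spec.effects.get(name)
                    if eff is not None and eff.week == week:
                        if label == "R":
                            dmu, dsd = eff.mean_r, eff.sem_r * np.sqrt(spec.n_r)
                        else:
                            dmu, dsd = eff.mean_nr, eff.sem_nr * np.sqrt(spec.n_nr)
                    else:
                        dmu, dsd = 0.0, spec.noise_delta_scale * sd
                    vals[name] = base[name] + rng.normal(dmu, dsd)
                tps[f"W{week}"] = ScanFeatures(vals)
            pre = float(rng.uniform(1.5, 8.0))
            if label == "R":
                pcr = bool(rng.random() < 0.3)
                shrink = 1.0 if pcr else float(rng.uniform(0.35, 0.95))
                cellularity = "very_low" if rng.random() < 0.3 else "low"
            else:
                pcr = False
                shrink = float(rng.uniform(-0.1, 0.28))
                cellularity = "moderate" if rng.random() < 0.5 else "high"
            post = max(0.0, pre * (1.0 - shrink))
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    timepoints=tps,
                    label=label,
                    clinical={
                        "pre_size_cm": pre,
                        "post_size_cm": post,
                        "cellularity": cellularity,
                        "pcr": pcr,
                    },
                )
            )
    return records


def cohort_matrix(
    records: list[SubjectRecord], week: int | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix for classification.

    ``week`` 1 or 4 yields the 62-dimensional baseline+delta vectors;
    ``week=None`` yields the 31 baseline features. Labels are encoded
    1 = responder. Subjects missing a needed timepoint are skipped.
    """
    from qusradiomics.features import SCAN_FEATURE_NAMES as NAMES
    from qusradiomics.features import VECTOR62_NAMES, build_feature_vector

    rows, labels = [], []
    if week is None:
        names = [f"{n}_W0" for n in NAMES]
        for rec in records:
            if "W0" not in rec.timepoints or rec.label is None:
                continue
            rows.append(rec.timepoints["W0"].as_array())
            labels.append(1 if rec.label == "R" else 0)
    else:
        names = list(VECTOR62_NAMES)
        for rec in records:
            if rec.label is None or "W0" not in rec.timepoints or f"W{week}" not in rec.timepoints:
                continue
            rows.append(build_feature_vector(rec, week).as_array())
            labels.append(1 if rec.label == "R" else 0)
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=int), names


# ---------------------------------------------------------------------------
# Texture fixtures
# ---------------------------------------------------------------------------


def toy_texture_images() -> dict[str, dict]:
    """Tiny maps with hand-enumerated GLCMs and features.

    Each entry carries the integer map, the offsets used, and (where
    written out) the expected normalized GLCM and Haralick features.
    """
    two_by_two = np.array([[0, 1], [0, 1]])
    glcm_22 = np.array([[0.0, 0.5], [0.5, 0.0]])  # offset (0,1), symmetric
    out = {
        "constant": {
            "map": np.zeros((4, 4), dtype=int),
            "offsets": ((0, 1), (1, 0), (1, 1), (1, -1)),
            "expected": {"CON": 0.0, "COR": 0.0, "HOM": 1.0, "ENE": 1.0},
        },
        "two_by_two": {
            "map": two_by_two,
            "offsets": ((0, 1),),
            "glcm": glcm_22,
            "expected": {"CON": 1.0, "HOM": 0.5, "ENE": 0.5},
        },
        "checkerboard": {
            "map": np.indices((6, 6)).sum(axis=0) % 2,
            "offsets": ((0, 1), (1, 0)),
        },
        "stripes": {
            # constant along rows: offset (0,1) never crosses an edge
            "map": np.tile(np.arange(4)[:, None] % 2, (1, 6)),
            "offsets": ((0, 1),),
            "expected": {"CON": 0.0},
        },
    }
    return out
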