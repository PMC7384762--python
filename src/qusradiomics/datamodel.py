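"""Core data types and on-disk formats.

Conventions
-----------
* RF sample grid: row index = axial sample (0 at the transducer face),
  column index = scan line. Depth of row *i* is ``i * axial_pitch`` with
  ``axial_pitch = c / (2 fs)`` (two-way travel).
* RF archive: one HDF5 container per scan (schema version ``qus-rf/1``)
  holding the sample arrays plus all acquisition metadata as attributes.
  Missing mandatory metadata is an error, never a default.
* ROI: either an 8-bit raster (PNG, nonzero = inside) on the RF grid, or
  a polygon JSON in physical millimetres rasterized by the
  pixel-center-inside rule.
* Feature tables: UTF-8 CSV, one row per subject x timepoint, with the
  31 canonical feature columns in fixed order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import imageio.v3 as iio
import numpy as np
from matplotlib.path import Path as MplPath

ARCHIVE_SCHEMA = "qus-rf/1"

#: metadata attributes that every archived frame must carry
_MANDATORY_FRAME_ATTRS = ("fs", "c", "f_center", "band_lo", "band_hi", "lateral_pitch")


class ArchiveError(ValueError):
    """Malformed or incomplete RF archive."""


class ROIError(ValueError):
    """Malformed region-of-interest input."""


class FeatureTableError(ValueError):
    """Malformed feature table."""


@dataclass
class RFFrame:
    """One B-scan's raw RF samples plus acquisition metadata.

    Parameters
    ----------
    samples
        2-D real array, shape (axial sample, scan line), arbitrary units.
    fs
        Sampling rate, Hz.
    c
        Assumed speed of sound, m/s.
    f_center
        Transducer center frequency, Hz.
    band
        Nominal (f_lo, f_hi) transducer bandwidth, Hz.
    lateral_pitch
        Scan-line spacing, m.
    system_id
        Free-text system identifier.
    """

    samples: np.ndarray
    fs: float
    c: float
    f_center: float
    band: tuple[float, float]
    lateral_pitch: float
    system_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (axial x lateral) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.c <= 0:
            raise ValueError("sound speed must be positive")
        f_lo, f_hi = self.band
        if not (f_lo < self.f_center < f_hi):
            raise ValueError("band must bracket the center frequency")
        if self.lateral_pitch <= 0:
            raise ValueError("lateral_pitch must be positive")

    @property
    def axial_pitch(self) -> float:
        """Axial sample spacing in metres, exactly c / (2 fs)."""
        return self.c / (2.0 * self.fs)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def depth_m(self, axial_index: float) -> float:
        """Depth (m) of an axial sample index; index 0 is the transducer face."""
        return float(axial_index) * self.axial_pitch


@dataclass
class ROIMask:
    """Boolean tumour mask congruent with a paired :class:`RFFrame`."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ROIError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def validate_against(self, frame: RFFrame) -> None:
        if self.mask.shape != frame.samples.shape:
            raise ROIError(
                f"mask shape {self.mask.shape} does not match frame {frame.samples.shape}"
            )
        if not self.mask.any():
            raise ROIError("ROI mask is empty")


@dataclass
class PhantomReference:
    """Reference-phantom acquisition with known acoustic properties.

    ``bsc_ref`` is a tabulated backscatter coefficient, rows of
    (frequency Hz, BSC sr^-1 cm^-1), strictly positive.
    """

    frames: list[RFFrame]
    alpha_ref: float  # attenuation slope, dB cm^-1 MHz^-1
    bsc_ref: np.ndarray  # (N, 2): f_hz, bsc

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("phantom reference needs at least one frame")
        if self.alpha_ref < 0:
            raise ValueError("alpha_ref must be non-negative")
        self.bsc_ref = np.asarray(self.bsc_ref, dtype=float)
        if self.bsc_ref.ndim != 2 or self.bsc_ref.shape[1] != 2:
            raise ValueError("bsc_ref must be an (N, 2) table of (f_hz, bsc)")
        if np.any(self.bsc_ref[:, 1] <= 0):
            raise ValueError("reference BSC must be strictly positive")

    def bsc_at(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Log-linear interpolation of the reference BSC onto ``freqs_hz``."""
        f = self.bsc_ref[:, 0]
        logb = np.log(self.bsc_ref[:, 1])
        return np.exp(np.interp(freqs_hz, f, logb))


@dataclass
class SubjectRecord:
    """Per-subject scan features at W0/W1/W4 plus the response label."""

    subject_id: str
    timepoints: dict  # {"W0"|"W1"|"W4": ScanFeatures}
    label: str | None = None  # "R" or "NR"
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.timepoints) - {"W0", "W1", "W4"}
        if bad:
            raise ValueError(f"unknown timepoints: {sorted(bad)}")
        if self.label is not None and self.label not in ("R", "NR"):
            raise ValueError("label must be 'R' or 'NR'")


# ---------------------------------------------------------------------------
# RF archive (HDF5)
# ---------------------------------------------------------------------------


def _write_frame(group: h5py.Group, frame: RFFrame) -> None:
    group.create_dataset("samples", data=frame.samples)
    group.attrs["fs"] = frame.fs
    group.attrs["c"] = frame.c
    group.attrs["f_center"] = frame.f_center
    group.attrs["band_lo"] = frame.band[0]
    group.attrs["band_hi"] = frame.band[1]
    group.attrs["lateral_pitch"] = frame.lateral_pitch
    group.attrs["system_id"] = frame.system_id


def _read_frame(group: h5py.Group) -> RFFrame:
    missing = [k for k in _MANDATORY_FRAME_ATTRS if k not in group.attrs]
    if missing:
        raise ArchiveError(f"frame metadata absent: {missing}")
    return RFFrame(
        samples=np.asarray(group["samples"]),
        fs=float(group.attrs["fs"]),
        c=float(group.attrs["c"]),
        f_center=float(group.attrs["f_center"]),
        band=(float(group.attrs["band_lo"]), float(group.attrs["band_hi"])),
        lateral_pitch=float(group.attrs["lateral_pitch"]),
        system_id=str(group.attrs.get("system_id", "")),
    )


def write_rf_archive(
    path: str | Path,
    frames: Sequence[RFFrame],
    phantom: PhantomReference | None = None,
) -> None:
    """Write frames (and optionally the phantom reference) to one container file."""
    with h5py.File(path, "w") as h5:
        h5.attrs["schema"] = ARCHIVE_SCHEMA
        fgrp = h5.create_group("frames")
        for i, frame in enumerate(frames):
            _write_frame(fgrp.create_group(f"{i:04d}"), frame)
        if phantom is not None:
            pgrp = h5.create_group("phantom")
            pgrp.attrs["alpha_ref"] = phantom.alpha_ref
            pgrp.create_dataset("bsc_ref", data=phantom.bsc_ref)
            pfr = pgrp.create_group("frames")
            for i, frame in enumerate(phantom.frames):
                _write_frame(pfr.create_group(f"{i:04d}"), frame)


def read_rf_archive(path: str | Path) -> tuple[list[RFFrame], PhantomReference | None]:
    """Read an RF archive; rejects unknown schema versions and incomplete metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as h5:
        schema = h5.attrs.get("schema")
        if schema != ARCHIVE_SCHEMA:
            raise ArchiveError(f"schema mismatch: found {schema!r}, expected {ARCHIVE_SCHEMA!r}")
        if "frames" not in h5:
            raise ArchiveError("archive holds no frames group")
        frames = [_read_frame(h5["frames"][k]) for k in sorted(h5["frames"])]
        phantom = None
        if "phantom" in h5:
            pgrp = h5["phantom"]
            if "alpha_ref" not in pgrp.attrs:
                raise ArchiveError("phantom metadata absent: alpha_ref")
            pframes = [_read_frame(pgrp["frames"][k]) for k in sorted(pgrp["frames"])]
            phantom = PhantomReference(
                frames=pframes,
                alpha_ref=float(pgrp.attrs["alpha_ref"]),
                bsc_ref=np.asarray(pgrp["bsc_ref"]),
            )
    return frames, phantom


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------


def rasterize_polygon_mm(
    points_mm: np.ndarray, frame: RFFrame
) -> np.ndarray:
    """Rasterize a closed polygon given in (axial mm, lateral mm) to the RF grid.

    A pixel belongs to the mask when its center lies strictly inside the
    polygon (pixel-center-inside rule). Pixel centers sit at
    (row * axial_pitch, col * lateral_pitch).
    """
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ROIError("polygon needs at least 3 (axial_mm, lateral_mm) points")
    ax_mm = np.arange(frame.n_samples) * frame.axial_pitch * 1e3
    lat_mm = np.arange(frame.n_lines) * frame.lateral_pitch * 1e3
    # restrict the point-in-polygon test to the polygon's bounding box
    r0 = int(np.searchsorted(ax_mm, pts[:, 0].min()))
    r1 = int(np.searchsorted(ax_mm, pts[:, 0].max(), side="right"))
    c0 = int(np.searchsorted(lat_mm, pts[:, 1].min()))
    c1 = int(np.searchsorted(lat_mm, pts[:, 1].max(), side="right"))
    mask = np.zeros((frame.n_samples, frame.n_lines), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    aa, ll = np.meshgrid(ax_mm[r0:r1], lat_mm[c0:c1], indexing="ij")
    centers = np.column_stack([aa.ravel(), ll.ravel()])
    # negative radius => strict interior, so centers on the boundary are out
    inside = MplPath(pts).contains_points(centers, radius=-1e-9)
    mask[r0:r1, c0:c1] = inside.reshape(aa.shape)
    return mask


def read_roi(path: str | Path, frame: RFFrame) -> ROIMask:
    """Read an ROI raster (8-bit image) or polygon JSON for ``frame``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        if doc.get("unit", "mm") != "mm":
            raise ROIError("polygon coordinates must be in mm")
        mask = rasterize_polygon_mm(np.asarray(doc["points"], dtype=float), frame)
        roi = ROIMask(mask=mask, label=str(doc.get("label", "")))
    else:
        raster = iio.imread(path)
        if raster.ndim == 3:  # collapse any colour channels
            raster = raster[..., 0]
        roi = ROIMask(mask=raster > 0)
    roi.validate_against(frame)
    return roi


def write_roi(path: str | Path, roi: ROIMask) -> None:
    """Write an ROI as an 8-bit raster (0/255)."""
    iio.imwrite(Path(path), (roi.mask.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records to CSV, one row per subject x timepoint.

    Columns: ``subject_id,timepoint,label,<31 canonical feature names>``.
    """
    from qusradiomics.features import SCAN_FEATURE_NAMES

    import pandas as pd

    rows = []
    for rec in records:
        for tp, sf in sorted(rec.timepoints.items()):
            row = {"subject_id": rec.subject_id, "timepoint": tp, "label": rec.label}
            row.update({name: sf.values[name] for name in SCAN_FEATURE_NAMES})
            rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", "timepoint", "label", *SCAN_FEATURE_NAMES])
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise FeatureTableError("duplicate subject x timepoint rows")
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[SubjectRecord]:
    """Read a feature CSV back into :class:`SubjectRecord` objects."""
    from qusradiomics.features import SCAN_FEATURE_NAMES, ScanFeatures

    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject_id", "timepoint", "label"}
    if not required.issubset(df.columns):
        raise FeatureTableError(f"missing columns: {sorted(required - set(df.columns))}")
    feature_cols = [c for c in df.columns if c not in required]
    unknown = set(feature_cols) - set(SCAN_FEATURE_NAMES)
    if unknown:
        raise FeatureTableError(f"unknown feature columns: {sorted(unknown)}")
    missing = set(SCAN_FEATURE_NAMES) - set(feature_cols)
    if missing:
        raise FeatureTableError(f"missing feature columns: {sorted(missing)}")
    if df.duplicated(subset=["subject_id", "timepoint"]).any():
        raise FeatureTableError("duplicate subject x timepoint rows")
    records: dict[str, SubjectRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        label = None if pd.isna(row["label"]) else str(row["label"])
        sf = ScanFeatures({name: float(row[name]) for name in SCAN_FEATURE_NAMES})
        rec = records.setdefault(sid, SubjectRecord(subject_id=sid, timepoints={}, label=label))
        rec.timepoints[str(row["timepoint"])] = sf
    return list(records.values())
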