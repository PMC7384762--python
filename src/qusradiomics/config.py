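"""Pipeline configuration: validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class PipelineConfig(BaseModel):
    """Feature-extraction configuration.

    Defaults mirror a 6 MHz-class linear-array breast acquisition:
    2 x 2 mm sliding window (~10 wavelengths) with 92 % overlap in both
    axes, phantom-referenced -6 dB analysis band, reference attenuation
    0.5 dB/cm/MHz.
    """

    model_config = ConfigDict(extra="forbid")

    window_mm: float = Field(2.0, gt=0)
    overlap: float = Field(0.92, ge=0, lt=1)
    band_mode: Literal["minus6dB", "fixed"] = "minus6dB"
    fixed_band_mhz: Optional[Tuple[float, float]] = None
    sound_speed: float = Field(1540.0, gt=0)
    alpha_ref_db_cm_mhz: float = Field(0.5, ge=0)
    # backscatter / SAS
    ar_order: int = Field(64, ge=2)
    sas_coherence_floor: float = Field(0.1, ge=0, le=1)
    sas_range_mm: Tuple[float, float] = (0.15, 0.8)
    # GLCM
    glcm_levels: int = Field(16, ge=2)
    glcm_offsets: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    glcm_symmetric: bool = True
    glcm_pooling: Literal["pooled", "averaged"] = "pooled"

    @model_validator(mode="after")
    def _check_band(self) -> "PipelineConfig":
        if self.band_mode == "fixed":
            if self.fixed_band_mhz is None:
                raise ValueError("band_mode='fixed' requires fixed_band_mhz")
            lo, hi = self.fixed_band_mhz
            if not lo < hi:
                raise ValueError("fixed_band_mhz must be increasing")
        lo, hi = self.sas_range_mm
        if not 0 < lo < hi:
            raise ValueError("sas_range_mm must be increasing and positive")
        return self


class StudyConfig(BaseModel):
    """Classification-study configuration (balancing, SFS, LOO)."""

    model_config = ConfigDict(extra="forbid")

    n_balance_iters: int = Field(20, ge=1)
    max_features: int = Field(4, ge=1)
    knn_k: int = 3
    knn_k_grid: Tuple[int, ...] = (1, 3, 5, 7)
    svm_c_grid: Tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: Tuple[float, ...] = (0.01, 0.1, 1.0)  # scaled by 1/n_features
    sfs_inner_folds: int = Field(3, ge=2)  # used by SVM-RBF; FLD/K-NN use inner LOO
    pooled_metrics: bool = False
    seed: int = 0


def load_config(path: str | Path) -> tuple[PipelineConfig, StudyConfig]:
    """Load a YAML config with optional ``pipeline:`` and ``study:`` sections."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(doc) - {"pipeline", "study"}
    if known:
        raise ValueError(f"unknown top-level config sections: {sorted(known)}")
    return (
        PipelineConfig(**(doc.get("pipeline") or {})),
        StudyConfig(**(doc.get("study") or {})),
    )
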