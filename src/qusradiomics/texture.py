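"""Grey-level co-occurrence texture features of parametric maps.

GLCMs are accumulated nodata-aware (both pixels of a pair must be valid)
over the four distance-1 offsets, symmetrized and normalized; the four
Haralick statistics contrast (CON), correlation (COR), homogeneity (HOM)
and energy (ENE) are computed from the pooled matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from qusradiomics.config import PipelineConfig
from qusradiomics.spectral import ParametricMap

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

#: order of the parametric maps entering texture analysis
TEXTURE_MAP_PARAMS = ("MBF", "SS", "SI", "ASD", "AAC", "SAS")
TEXTURE_STATS = ("CON", "COR", "HOM", "ENE")


class TextureError(ValueError):
    pass


@dataclass
class GLCM:
    """Normalized grey-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.levels, self.levels):
            raise TextureError("GLCM shape must be (levels, levels)")
        if np.any(self.matrix < 0):
            raise TextureError("GLCM entries must be non-negative")


@dataclass
class TextureFeatures:
    CON: float
    COR: float
    HOM: float
    ENE: float


def quantize_map(values: np.ndarray, levels: int = 16) -> np.ndarray:
    """Linear min-max quantization into ``levels`` grey levels.

    Valid (finite) pixels map to 0..levels-1; nodata pixels become -1.
    A constant map collapses into a single bin.
    """
    values = np.asarray(values, dtype=float)
    valid = np.isfinite(values)
    if not valid.any():
        raise TextureError("all-nodata map")
    vmin = values[valid].min()
    vmax = values[valid].max()
    q = np.full(values.shape, -1, dtype=np.int64)
    if vmax == vmin:
        q[valid] = 0
        return q
    scaled = (values[valid] - vmin) / (vmax - vmin) * levels
    q[valid] = np.clip(scaled.astype(np.int64), 0, levels - 1)
    return q


def compute_glcm(
    qmap: np.ndarray,
    offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
    levels: int | None = None,
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence counts of valid pixel pairs, pooled over offsets.

    A pair (p, p+offset) contributes only when both pixels are valid
    (>= 0). The pooled matrix is symmetrized when requested and
    normalized to total mass 1.
    """
    qmap = np.asarray(qmap)
    offsets = tuple(tuple(o) for o in offsets)
    if levels is None:
        levels = int(qmap.max()) + 1
    mat = np.zeros((levels, levels), dtype=float)
    rows, cols = qmap.shape
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = rows - max(0, dr)
        c0 = max(0, -dc)
        c1 = cols - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        a = qmap[r0:r1, c0:c1]
        b = qmap[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            np.add.at(mat, (a[ok], b[ok]), 1.0)
    if symmetric:
        mat = mat + mat.T
    total = mat.sum()
    if total == 0:
        raise TextureError("no valid co-occurring pair")
    return GLCM(matrix=mat / total, levels=levels, offsets=offsets, symmetric=symmetric)


def texture_features(glcm: GLCM) -> TextureFeatures:
    """Haralick CON/COR/HOM/ENE of a normalized GLCM.

    Correlation is defined as 0 for a zero-variance (degenerate) matrix.
    """
    P = glcm.matrix
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise TextureError("GLCM must be normalized to total mass 1")
    n = glcm.levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    con = float(np.sum(P * (i - j) ** 2))
    hom = float(np.sum(P / (1.0 + np.abs(i - j))))
    ene = float(np.sum(P**2))
    mu_i = float(np.sum(P * i))
    mu_j = float(np.sum(P * j))
    var_i = float(np.sum(P * (i - mu_i) ** 2))
    var_j = float(np.sum(P * (j - mu_j) ** 2))
    sigma = np.sqrt(var_i * var_j)
    cor = 0.0 if sigma == 0 else float(np.sum(P * (i - mu_i) * (j - mu_j)) / sigma)
    return TextureFeatures(CON=con, COR=cor, HOM=hom, ENE=ene)


def map_textures(
    maps: Mapping[str, ParametricMap | np.ndarray],
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Texture features of the six parametric maps.

    Returns 24 values keyed ``<PARAM>-<TEX>`` (e.g. ``AAC-CON``) in the
    canonical order. With ``glcm_pooling='averaged'`` the statistics are
    computed per offset and averaged instead of from the pooled matrix.
    """
    config = config or PipelineConfig()
    out: dict[str, float] = {}
    for param in TEXTURE_MAP_PARAMS:
        if param not in maps:
            raise TextureError(f"missing parametric map: {param}")
        m = maps[param]
        values = m.values if isinstance(m, ParametricMap) else np.asarray(m)
        q = quantize_map(values, config.glcm_levels)
        if config.glcm_pooling == "pooled":
            glcm = compute_glcm(q, config.glcm_offsets, config.glcm_levels, config.glcm_symmetric)
            feats = texture_features(glcm)
            values_by_stat = {s: getattr(feats, s) for s in TEXTURE_STATS}
        else:
            per_offset = []
            for off in config.glcm_offsets:
                glcm = compute_glcm(q, (off,), config.glcm_levels, config.glcm_symmetric)
                per_offset.append(texture_features(glcm))
            values_by_stat = {
                s: float(np.mean([getattr(f, s) for f in per_offset])) for s in TEXTURE_STATS
            }
        for stat in TEXTURE_STATS:
            out[f"{param}-{stat}"] = values_by_stat[stat]
    return out
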