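"""Scan-level and subject-level feature bookkeeping plus univariate stats.

Each scan yields exactly 31 named features: the 7 map/ROI means MBF (dB),
SS (dB/MHz), SI (dB), ACE (dB/cm/MHz), ASD (um), AAC (dB/cm^3), SAS (mm)
and 24 texture features named ``<PARAM>-<TEX>``. A subject-week vector
holds 62 values: the 31 baseline features tagged ``<name>_W0`` plus the
31 week-minus-baseline changes tagged with a Delta prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from qusradiomics.datamodel import SubjectRecord
from qusradiomics.spectral import ACEValue, ParametricMap
from qusradiomics.texture import TEXTURE_MAP_PARAMS, TEXTURE_STATS

DELTA = "Δ"  # Δ prefix of change features

MEAN_FEATURE_NAMES: tuple[str, ...] = ("MBF", "SS", "SI", "ACE", "ASD", "AAC", "SAS")
TEXTURE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{p}-{t}" for p in TEXTURE_MAP_PARAMS for t in TEXTURE_STATS
)
#: canonical ordered names of the 31 per-scan features
SCAN_FEATURE_NAMES: tuple[str, ...] = MEAN_FEATURE_NAMES + TEXTURE_FEATURE_NAMES

#: canonical ordered names of the 62 subject-week features
VECTOR62_NAMES: tuple[str, ...] = tuple(f"{n}_W0" for n in SCAN_FEATURE_NAMES) + tuple(
    f"{DELTA}{n}" for n in SCAN_FEATURE_NAMES
)


class FeatureError(ValueError):
    pass


@dataclass
class ScanFeatures:
    """The 31 named QUS features of one scan."""

    values: dict

    def __post_init__(self) -> None:
        missing = set(SCAN_FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(SCAN_FEATURE_NAMES)
        if missing or extra:
            raise FeatureError(f"feature names off-canon: missing={sorted(missing)} extra={sorted(extra)}")
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise FeatureError(f"non-finite feature {k}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in SCAN_FEATURE_NAMES], dtype=float)


@dataclass
class FeatureVector62:
    """Baseline + delta features of one subject at one follow-up week."""

    values: dict
    week: int  # 1 or 4

    def __post_init__(self) -> None:
        if set(self.values) != set(VECTOR62_NAMES):
            raise FeatureError("62-vector names off-canon")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in VECTOR62_NAMES], dtype=float)


@dataclass
class UnivariateResult:
    feature: str
    mean_r: float
    sem_r: float
    mean_nr: float
    sem_nr: float
    test: str  # "ANOVA" | "Mann-Whitney"
    p_value: float


def assemble_scan_features(
    maps: Mapping[str, ParametricMap],
    ace: ACEValue | float,
    textures: Mapping[str, float],
) -> ScanFeatures:
    """Build the 31-feature scan vector from maps, ACE and textures.

    The 6 map means are ROI averages over valid windows; ACE is the
    per-ROI scalar; textures must carry the 24 canonical names.
    """
    values: dict[str, float] = {}
    for name in MEAN_FEATURE_NAMES:
        if name == "ACE":
            values["ACE"] = float(ace.ace if isinstance(ace, ACEValue) else ace)
        else:
            if name not in maps:
                raise FeatureError(f"missing map {name}")
            values[name] = maps[name].mean()
    for name in TEXTURE_FEATURE_NAMES:
        if name not in textures:
            raise FeatureError(f"missing texture feature {name}")
        values[name] = float(textures[name])
    return ScanFeatures(values)


def build_feature_vector(subject: SubjectRecord, week: int) -> FeatureVector62:
    """62-dimensional baseline+delta vector for week 1 or 4.

    Delta features are week-minus-baseline; both scans must exist.
    """
    if week not in (1, 4):
        raise FeatureError("week must be 1 or 4")
    key = f"W{week}"
    if "W0" not in subject.timepoints or key not in subject.timepoints:
        raise FeatureError(f"subject {subject.subject_id} missing W0 or {key}")
    base = subject.timepoints["W0"].values
    wk = subject.timepoints[key].values
    values = {f"{n}_W0": float(base[n]) for n in SCAN_FEATURE_NAMES}
    values.update({f"{DELTA}{n}": float(wk[n] - base[n]) for n in SCAN_FEATURE_NAMES})
    return FeatureVector62(values=values, week=week)


def label_response(
    pre_size_cm: float,
    post_size_cm: float,
    cellularity: str = "moderate",
    pcr: bool = False,
) -> str:
    """Dichotomous response label.

    Responder (R) if pathological complete response, residual cellularity
    assessed "very low", or tumour size decreased by more than 30 %;
    otherwise non-responder (NR).
    """
    if pre_size_cm <= 0 or post_size_cm < 0:
        raise ValueError("sizes must be positive (pre) / non-negative (post)")
    if cellularity not in ("very_low", "low", "moderate", "high"):
        raise ValueError(f"unknown cellularity category {cellularity!r}")
    if pcr or post_size_cm == 0 or cellularity == "very_low":
        return "R"
    if (pre_size_cm - post_size_cm) / pre_size_cm > 0.30:
        return "R"
    return "NR"


def univariate_screen(
    values_r: Sequence[float], values_nr: Sequence[float], feature: str = ""
) -> UnivariateResult:
    """Two-group comparison with a normality gate.

    Shapiro-Wilk is applied to each group at alpha = 0.05; when both
    groups pass, a one-way ANOVA compares the means, otherwise the
    Mann-Whitney U test is used. Group means +/- SEM are reported.
    """
    r = np.asarray(values_r, dtype=float)
    nr = np.asarray(values_nr, dtype=float)
    if r.size < 2 or nr.size < 2:
        raise ValueError("need >= 2 subjects per group")

    def _sem(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(x.size))

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False  # degenerate; Shapiro undefined
        return stats.shapiro(x).pvalue > 0.05

    if _normal(r) and _normal(nr):
        test = "ANOVA"
        if np.ptp(np.concatenate([r, nr])) == 0:
            p = 1.0
        else:
            p = float(stats.f_oneway(r, nr).pvalue)
    else:
        test = "Mann-Whitney"
        try:
            p = float(stats.mannwhitneyu(r, nr, alternative="two-sided").pvalue)
        except ValueError:  # identical constant groups
            p = 1.0
    return UnivariateResult(
        feature=feature,
        mean_r=float(r.mean()),
        sem_r=_sem(r),
        mean_nr=float(nr.mean()),
        sem_nr=_sem(nr),
        test=test,
        p_value=p,
    )
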