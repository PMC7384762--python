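"""End-to-end orchestration: scans -> 31 features -> study report.

``run_extract`` turns a manifest of RF archives + ROIs + one phantom
into a feature CSV (one row per subject x timepoint) with a QA bundle
(parametric-map renders, window counts, flagged fractions). Per-scan
failures are quarantined and reported, not fatal.

``run_study`` turns a feature CSV plus a subject table into the
univariate screen and the classifier reports for baseline, week 1 and
week 4 with FLD, K-NN and SVM-RBF.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from qusradiomics import __version__
from qusradiomics.classify import ClassifierSpec, loo_evaluate
from qusradiomics.config import PipelineConfig, StudyConfig
from qusradiomics.datamodel import (
    PhantomReference,
    SubjectRecord,
    read_rf_archive,
    read_roi,
    write_feature_table,
)
from qusradiomics.features import (
    DELTA,
    SCAN_FEATURE_NAMES,
    assemble_scan_features,
    build_feature_vector,
    label_response,
    univariate_screen,
)
from qusradiomics.simulate import cohort_matrix
from qusradiomics.spectral import build_spectral_maps, compute_roi_spectra
from qusradiomics.backscatter import build_backscatter_maps
from qusradiomics.texture import map_textures

log = logging.getLogger("qusradiomics")


def _config_hash(config) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]


def extract_scan_features(
    frames,
    rois,
    phantom: PhantomReference,
    config: PipelineConfig,
):
    """31 features for one scan, averaged across its image planes.

    Each frame/ROI pair yields maps and textures; per-plane features are
    averaged (planes are treated as independent realizations of the same
    tumour). Returns (ScanFeatures, qa dict).
    """
    per_plane = []
    qa_planes = []
    for frame, roi in zip(frames, rois):
        rs = compute_roi_spectra(frame, roi, phantom, config)
        smaps, ace, rs = build_spectral_maps(frame, roi, phantom, config, roi_spectra=rs)
        bmaps, qa = build_backscatter_maps(frame, roi, phantom, config, roi_spectra=rs)
        maps = {**smaps, **bmaps}
        textures = map_textures(maps, config)
        per_plane.append(assemble_scan_features(maps, ace, textures))
        qa_planes.append({**qa, "maps": maps, "ace": ace.ace})
    if not per_plane:
        raise ValueError("scan holds no frames")
    mean_vals = {
        name: float(np.mean([sf.values[name] for sf in per_plane]))
        for name in SCAN_FEATURE_NAMES
    }
    from qusradiomics.features import ScanFeatures

    return ScanFeatures(mean_vals), qa_planes


def _render_maps(maps, out_png: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    for ax, (name, pm) in zip(axes.ravel(), maps.items()):
        im = ax.imshow(pm.values, aspect="auto", interpolation="nearest")
        ax.set_title(f"{name} ({pm.units})")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_png, dpi=80)
    plt.close(fig)


def run_extract(
    manifest: dict | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "qus_out",
    seed: int = 0,
    render_qa: bool = True,
) -> Path:
    """Extract features for every scan listed in the manifest.

    Manifest schema (YAML or dict)::

        phantom: <archive with embedded phantom>
        scans:
          - {subject_id: S001, timepoint: W0, archive: s1_w0.h5, roi: s1_w0.json}

    Writes ``features.csv``, ``qa/`` renders and ``extract_report.json``
    into ``out_dir``; returns the feature CSV path.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, dict):
        manifest = yaml.safe_load(Path(manifest).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qa_dir = out_dir / "qa"
    qa_dir.mkdir(exist_ok=True)

    _, phantom = read_rf_archive(manifest["phantom"])
    if phantom is None:
        raise ValueError("phantom archive holds no phantom reference")

    records: dict[str, SubjectRecord] = {}
    report = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "scans": [],
        "excluded": [],
    }
    for scan in manifest["scans"]:
        sid, tp = str(scan["subject_id"]), str(scan["timepoint"])
        t0 = time.time()
        try:
            frames, _ = read_rf_archive(scan["archive"])
            rois = [read_roi(scan["roi"], fr) for fr in frames]
            sf, qa_planes = extract_scan_features(frames, rois, phantom, config)
            rec = records.setdefault(sid, SubjectRecord(subject_id=sid, timepoints={}))
            rec.timepoints[tp] = sf
            if render_qa and qa_planes:
                _render_maps(qa_planes[0]["maps"], qa_dir / f"{sid}_{tp}.png")
            report["scans"].append(
                {
                    "subject_id": sid,
                    "timepoint": tp,
                    "n_windows": int(qa_planes[0]["n_windows"]),
                    "flagged_fraction": float(qa_planes[0]["flagged_fraction"]),
                    "ace": float(qa_planes[0]["ace"]),
                    "seconds": round(time.time() - t0, 3),
                }
            )
        except Exception as exc:  # quarantine, continue
            log.warning("scan %s %s failed: %s", sid, tp, exc)
            report["excluded"].append({"subject_id": sid, "timepoint": tp, "error": str(exc)})
    features_csv = out_dir / "features.csv"
    write_feature_table(list(records.values()), features_csv)
    (out_dir / "extract_report.json").write_text(json.dumps(report, indent=2))
    return features_csv


def attach_labels(records: list[SubjectRecord], subjects_csv: str | Path) -> None:
    """Label records from a subject table
    (``subject_id,pre_size_cm,post_size_cm,cellularity,pcr``)."""
    table = pd.read_csv(subjects_csv)
    by_id = {str(r.subject_id): r for r in table.itertuples()}
    for rec in records:
        row = by_id.get(rec.subject_id)
        if row is None:
            continue
        rec.label = label_response(
            float(row.pre_size_cm),
            float(row.post_size_cm),
            str(row.cellularity),
            bool(row.pcr),
        )
        rec.clinical = {
            "pre_size_cm": float(row.pre_size_cm),
            "post_size_cm": float(row.post_size_cm),
            "cellularity": str(row.cellularity),
            "pcr": bool(row.pcr),
        }


def screen_cohort(records: list[SubjectRecord], week: int) -> pd.DataFrame:
    """Univariate screen of all 31 delta features at one week."""
    rows = []
    for name in SCAN_FEATURE_NAMES:
        vals = {"R": [], "NR": []}
        for rec in records:
            if rec.label is None or "W0" not in rec.timepoints or f"W{week}" not in rec.timepoints:
                continue
            vec = build_feature_vector(rec, week)
            vals[rec.label].append(vec.values[f"{DELTA}{name}"])
        if len(vals["R"]) < 2 or len(vals["NR"]) < 2:
            continue
        res = univariate_screen(vals["R"], vals["NR"], feature=f"{DELTA}{name}")
        rows.append(
            {
                "feature": res.feature,
                "week": week,
                "mean_R": res.mean_r,
                "sem_R": res.sem_r,
                "mean_NR": res.mean_nr,
                "sem_NR": res.sem_nr,
                "test": res.test,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def run_study(
    records: list[SubjectRecord],
    study: StudyConfig | None = None,
    out_dir: str | Path | None = None,
    timepoints: tuple = (None, 1, 4),
    classifiers: tuple[str, ...] = ("FLD", "KNN", "SVM_RBF"),
) -> dict:
    """Univariate screen plus classifier reports for each timepoint.

    ``timepoints`` entries are ``None`` (baseline, 31 features) or a
    week number (62 baseline+delta features). Returns the study report
    dict; optionally writes JSON and a Markdown summary.
    """
    study = study or StudyConfig()
    report = {
        "package_version": __version__,
        "config_hash": _config_hash(study),
        "seed": study.seed,
        "screen": {},
        "models": [],
    }
    for week in (1, 4):
        df = screen_cohort(records, week)
        if not df.empty:
            report["screen"][f"W{week}"] = df.to_dict(orient="records")
    for tp in timepoints:
        X, y, names = cohort_matrix(records, tp)
        if X.size == 0 or np.unique(y).size < 2:
            continue
        for kind in classifiers:
            spec = ClassifierSpec(
                kind=kind,
                knn_k=study.knn_k,
                knn_k_grid=study.knn_k_grid,
                svm_c_grid=study.svm_c_grid,
                svm_gamma_grid=study.svm_gamma_grid,
                max_features=study.max_features,
                sfs_inner_folds=study.sfs_inner_folds,
            )
            rep = loo_evaluate(
                spec,
                X,
                y,
                n_balance_iters=study.n_balance_iters,
                seed=study.seed,
                feature_names=names,
                pooled=study.pooled_metrics,
            )
            top = sorted(rep.selection_counts.items(), key=lambda kv: -kv[1])[:4]
            report["models"].append(
                {
                    "timepoint": "baseline" if tp is None else f"W{tp}",
                    "classifier": kind,
                    **{k: round(v, 3) for k, v in rep.metrics.as_dict().items()},
                    "n_iterations": rep.n_iterations,
                    "top_features": [t[0] for t in top],
                }
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "study_report.json").write_text(json.dumps(report, indent=2))
        lines = ["# Study report", "", "| Timepoint | Classifier | %Sn | %Sp | %Acc | AUC | F1 | Features |", "|---|---|---|---|---|---|---|---|"]
        for m in report["models"]:
            lines.append(
                f"| {m['timepoint']} | {m['classifier']} | {m['Sn']:.0f} | {m['Sp']:.0f} "
                f"| {m['Acc']:.0f} | {m['AUC']:.2f} | {m['F1']:.2f} | {', '.join(m['top_features'])} |"
            )
        (out_dir / "study_report.md").write_text("\n".join(lines) + "\n")
    return report
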