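"""End-to-end orchestration: scans -> descriptors -> shape features -> statistics.

Stage boundaries sit at the pipeline's natural artifact boundaries so
every intermediate is an inspectable text file: a descriptor CSV after
extraction, a persisted PCA model plus scores CSV after feature
detection, and a JSON statistical report after analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import TorsomorphError, ValidationError
from .fourier import descriptor_from_profiles
from .frame import build_frame, landmarks_to_anatomical, to_anatomical
from .io import (
    LandmarkSet,
    PointCloud3D,
    descriptor_column_names,
    read_landmarks,
    read_point_cloud,
    write_deviation_mesh,
)
from .pca import (
    ShapeFeatureModel,
    fit_shape_pca,
    project,
    reconstruct_extreme,
)
from .slicing import torso_profiles
from .stats import derive_indices, pearson_matrix, run_model_families, zscore_table

logger = logging.getLogger("torsomorph")

SCAN_EXTENSIONS = (".ply", ".obj", ".xyz")
LANDMARK_EXTENSIONS = (".json", ".csv")


def extract_descriptor(
    cloud: PointCloud3D,
    landmarks: LandmarkSet,
    config: RunConfig | None = None,
) -> np.ndarray:
    """One participant: anatomical frame -> slices -> polar waveforms ->
    scale normalization -> flattened Fourier descriptor (420 reals)."""
    config = config or RunConfig()
    frame = build_frame(landmarks)
    cloud_a = to_anatomical(cloud, frame)
    lm_a = landmarks_to_anatomical(landmarks, frame)
    scaled = torso_profiles(
        cloud_a,
        lm_a,
        n_slices=config.n_slices,
        thickness=config.thickness_mm,
        n_theta=config.n_theta,
        smoothing=config.spline_smoothing,
        min_segment_points=config.min_segment_points,
        min_slice_points=config.min_slice_points,
        max_gap_deg=config.max_gap_deg,
        scaling_variant=config.scaling_variant,
    )
    descriptor = descriptor_from_profiles(
        scaled,
        participant_id=cloud.source_id,
        n_coeff=config.n_coeff,
        include_dc=config.include_dc,
    )
    return descriptor.flat_vector


def pair_inputs(scan_dir: str | Path, landmark_dir: str | Path) -> list[tuple[str, Path, Path]]:
    """Match scan and landmark files by participant id (file stem)."""
    scan_dir, landmark_dir = Path(scan_dir), Path(landmark_dir)
    scans = {p.stem: p for ext in SCAN_EXTENSIONS for p in sorted(scan_dir.glob(f"*{ext}"))}
    lms = {p.stem: p for ext in LANDMARK_EXTENSIONS
           for p in sorted(landmark_dir.glob(f"*{ext}"))}
    pairs = [(pid, scans[pid], lms[pid]) for pid in sorted(scans) if pid in lms]
    if not pairs:
        raise ValidationError(
            f"no matching scan/landmark pairs between {scan_dir} and {landmark_dir}"
        )
    return pairs


def extract(
    scan_dir: str | Path,
    landmark_dir: str | Path,
    config: RunConfig | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Extract the descriptor matrix for every matched participant.

    Per-participant failures are logged and skipped (the failed ids are
    returned); with ``strict`` the first failure raises instead.
    """
    config = config or RunConfig()
    rows, ids, failures = [], [], []
    for pid, scan_path, lm_path in pair_inputs(scan_dir, landmark_dir):
        try:
            cloud = read_point_cloud(scan_path)
            landmarks = read_landmarks(lm_path)
            rows.append(extract_descriptor(cloud, landmarks, config))
            ids.append(pid)
        except TorsomorphError as exc:
            if strict:
                raise
            logger.warning("participant %s skipped: %s", pid, exc)
            failures.append(pid)
    if not rows:
        raise ValidationError("every participant failed extraction")
    matrix = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index(ids, name="participant_id"),
        columns=descriptor_column_names(config.n_slices, config.n_coeff),
    )
    return matrix, failures


def features(
    matrix: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ShapeFeatureModel, pd.DataFrame]:
    """Fit the cohort shape PCA and compute per-participant scores.

    The scores table carries the retained components and, when more
    positive-variance components exist, enough extras to fill the
    stepwise candidate pool (first ``n_shape_candidates`` PCs). When
    ``out_dir`` is given the model directory, scores CSV and +/- extreme
    deviation meshes for the first ``n_extreme_pcs`` PCs are written.
    """
    config = config or RunConfig()
    model, _ = fit_shape_pca(matrix, threshold=config.variance_threshold)
    n_scores = min(max(model.n_retained, config.n_shape_candidates),
                   model.n_positive())
    score_arr = np.vstack([
        project(matrix.iloc[i].to_numpy(), model, n_components=n_scores)
        for i in range(len(matrix))
    ])
    scores = pd.DataFrame(score_arr, index=matrix.index,
                          columns=[f"PC{i + 1}" for i in range(n_scores)])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.save(out_dir / "shape_model")
        scores.to_csv(out_dir / "scores.csv", float_format="%.12e")
        n_extreme = min(config.n_extreme_pcs, model.n_retained)
        for pc in range(n_extreme):
            col = scores[f"PC{pc + 1}"]
            for tag, magnitude in (("max", float(col.max())), ("min", float(col.min()))):
                _, mesh = reconstruct_extreme(
                    model, pc, magnitude,
                    n_slices=config.n_slices, n_coeff=config.n_coeff,
                    n_theta=config.n_theta, include_dc=config.include_dc,
                )
                write_deviation_mesh(mesh, out_dir / f"pc{pc + 1}_{tag}.ply")
        config.write_manifest(out_dir, stage="features",
                              n_retained=model.n_retained,
                              n_positive=model.n_positive())
    return model, scores


ANALYSIS_COLUMNS = [
    "sum_skinfolds_mm", "stature_m", "mass_kg", "waist_girth_m", "hip_girth_m",
    "bmi", "whr", "wht5r",
]


def analyse(
    anthro: pd.DataFrame,
    scores: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Join anthropometrics with shape scores and run the full statistics.

    Returns a JSON-serializable report: per-model diagnostics for the
    three regression families plus the correlation matrix of sizes,
    indices and shape components.
    """
    config = config or RunConfig()
    merged = anthro.merge(scores, left_on="participant_id", right_index=True,
                          how="inner")
    if len(merged) < 10:
        raise ValidationError(
            f"only {len(merged)} participants join across anthro and scores tables"
        )
    merged = derive_indices(merged)
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    n_candidates = min(config.n_shape_candidates, len(pc_cols))
    use_cols = ANALYSIS_COLUMNS + pc_cols[:n_candidates]
    ztable = zscore_table(merged, columns=use_cols)

    corr = pearson_matrix(merged, columns=use_cols)
    models = run_model_families(
        ztable,
        n_shape_candidates=n_candidates,
        p_enter=config.p_enter,
        p_remove=config.p_remove,
        entry_correction=config.entry_correction,
    )
    report = {
        "n_joined": int(len(merged)),
        "models": {name: res.to_dict() for name, res in models.items()},
        "correlations": {
            "columns": use_cols,
            "r": corr.r.to_numpy().tolist(),
            "p": corr.p.to_numpy().tolist(),
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import json
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        corr.r.to_csv(out_dir / "correlations.csv", float_format="%.4f")
        config.write_manifest(out_dir, stage="analyse", n_joined=int(len(merged)))
    return report
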