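"""Cohort PCA over shape descriptors: independent torso shape features.

PCA is run on the centred (not column-standardized) descriptor matrix:
all 420 descriptor entries share the same dimensionless unit after
whole-torso scale normalization, and standardizing columns would inflate
the noise-dominated high-frequency terms. Components are ordered by
decreasing variance; retention keeps the smallest number of leading
components whose cumulative explained fraction reaches the threshold
(default 0.95). Per-participant coordinates on the retained components
are the participant's "shape feature vector" — suitable for radar plots
and as regression inputs.

Sign convention: each loading is flipped so its largest-magnitude entry
is positive, removing the inherent PCA sign ambiguity so that scores and
downstream regression coefficients are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateCohortError, ValidationError
from .fourier import (
    N_COEFF_DEFAULT,
    ShapeDescriptor,
    SliceSpectrum,
    reconstruct_profile,
    unflatten_vector,
)
from .io import DeviationMesh
from .slicing import polar_to_plane

VARIANCE_THRESHOLD_DEFAULT = 0.95


@dataclass
class ShapeFeatureModel:
    """Cohort PCA basis over flattened shape descriptors."""

    mean_descriptor: np.ndarray       # (n_features,)
    loadings: np.ndarray              # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray    # (n_components,), sample variance (ddof=1)
    explained_fraction: np.ndarray    # (n_components,), sums to 1
    n_retained: int
    threshold: float
    n_participants: int
    score_sd: np.ndarray              # per-component SD of training scores

    @property
    def n_features(self) -> int:
        return len(self.mean_descriptor)

    @property
    def n_components(self) -> int:
        return len(self.explained_variance)

    def n_positive(self, rel_tol: float = 1e-10) -> int:
        """Components whose variance exceeds ``rel_tol`` of total variance."""
        total = float(self.explained_variance.sum())
        if total == 0:
            return 0
        return int(np.sum(self.explained_variance > rel_tol * total))

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "mean_descriptor.csv", self.mean_descriptor[None, :],
                   delimiter=",", fmt="%.15e")
        np.savetxt(directory / "loadings.csv", self.loadings, delimiter=",", fmt="%.15e")
        np.savetxt(directory / "explained_variance.csv", self.explained_variance[None, :],
                   delimiter=",", fmt="%.15e")
        with open(directory / "model.json", "w") as fh:
            json.dump(
                {
                    "n_retained": self.n_retained,
                    "threshold": self.threshold,
                    "n_participants": self.n_participants,
                    "n_features": self.n_features,
                    "n_components": self.n_components,
                    "score_sd": self.score_sd.tolist(),
                    "explained_fraction": self.explained_fraction.tolist(),
                },
                fh,
                indent=1,
            )
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ShapeFeatureModel":
        directory = Path(directory)
        with open(directory / "model.json") as fh:
            meta = json.load(fh)
        return cls(
            mean_descriptor=np.loadtxt(directory / "mean_descriptor.csv", delimiter=",").ravel(),
            loadings=np.atleast_2d(np.loadtxt(directory / "loadings.csv", delimiter=",")),
            explained_variance=np.loadtxt(directory / "explained_variance.csv",
                                          delimiter=",").ravel(),
            explained_fraction=np.asarray(meta["explained_fraction"]),
            n_retained=meta["n_retained"],
            threshold=meta["threshold"],
            n_participants=meta["n_participants"],
            score_sd=np.asarray(meta["score_sd"]),
        )


def fit_shape_pca(
    descriptor_matrix: np.ndarray | pd.DataFrame,
    threshold: float = VARIANCE_THRESHOLD_DEFAULT,
) -> tuple[ShapeFeatureModel, pd.DataFrame]:
    """Fit the cohort PCA; returns the model and the training scores.

    Scores are returned as a DataFrame with columns PC1..PCm (retained
    components only), indexed like the input if it is a DataFrame.
    """
    if isinstance(descriptor_matrix, pd.DataFrame):
        index = descriptor_matrix.index
        X = descriptor_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(descriptor_matrix, dtype=float)
        index = pd.RangeIndex(len(X))
    n, p = X.shape
    if n < 3:
        raise ValidationError(f"need at least 3 participants for PCA, got {n}")
    if np.isnan(X).any():
        raise ValidationError("descriptor matrix contains missing values")
    centred = X - X.mean(axis=0)
    total_var = float((centred ** 2).sum() / (n - 1))
    if total_var <= 0:
        raise DegenerateCohortError("descriptor matrix has zero total variance")

    pca = PCA(n_components=None, svd_solver="full")
    scores_full = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # deterministic sign: largest-magnitude entry of each loading positive
    flip = np.sign(loadings[np.arange(len(loadings)),
                            np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings *= flip[:, None]
    scores_full *= flip[None, :]

    fraction = pca.explained_variance_ratio_
    n_retained = int(np.searchsorted(np.cumsum(fraction), threshold) + 1)
    n_retained = min(n_retained, len(fraction))
    score_sd = scores_full.std(axis=0, ddof=1)

    model = ShapeFeatureModel(
        mean_descriptor=pca.mean_.copy(),
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        explained_fraction=fraction.copy(),
        n_retained=n_retained,
        threshold=threshold,
        n_participants=n,
        score_sd=score_sd,
    )
    scores = pd.DataFrame(
        scores_full[:, :n_retained],
        index=index,
        columns=[f"PC{i + 1}" for i in range(n_retained)],
    )
    return model, scores


def project(
    descriptor: ShapeDescriptor | np.ndarray,
    model: ShapeFeatureModel,
    n_components: int | None = None,
) -> np.ndarray:
    """Coordinates of one descriptor on the leading components
    (``n_components`` defaults to the retained count)."""
    flat = descriptor.flat_vector if isinstance(descriptor, ShapeDescriptor) else np.asarray(descriptor, float)
    if flat.shape[-1] != model.n_features:
        raise ValidationError(
            f"descriptor dimension {flat.shape[-1]} != model dimension {model.n_features}"
        )
    m = model.n_retained if n_components is None else n_components
    return (flat - model.mean_descriptor) @ model.loadings[:m].T


def reconstruct_descriptor(scores: np.ndarray, model: ShapeFeatureModel) -> np.ndarray:
    """Inverse of :func:`project` for however many score coordinates are given."""
    scores = np.asarray(scores, dtype=float)
    m = scores.shape[-1]
    return model.mean_descriptor + scores @ model.loadings[:m]


def radar_values(scores_row: np.ndarray, model: ShapeFeatureModel,
                 n_components: int = 5) -> np.ndarray:
    """First ``n_components`` scores standardized by each component's cohort
    SD — the values plotted on the shape-feature radar diagram."""
    if n_components > model.n_retained:
        raise ValidationError(
            f"{n_components} radar components requested but only "
            f"{model.n_retained} retained"
        )
    scores_row = np.asarray(scores_row, dtype=float)
    return scores_row[:n_components] / model.score_sd[:n_components]


# ---------------------------------------------------------------------------
# PC-extreme reconstruction and lofting


def loft_slices(
    radii_matrix: np.ndarray,
    z_values: np.ndarray | None = None,
    deviations: np.ndarray | None = None,
) -> DeviationMesh:
    """Join a stack of polar rings into a closed-tube triangle mesh.

    ``radii_matrix`` is (n_slices, n_theta); adjacent rings are joined by
    triangle strips over the shared theta grid, end caps omitted. Each ring
    is centred on the longitudinal axis (slice centroid offsets are not
    part of the shape descriptor).
    """
    radii_matrix = np.atleast_2d(np.asarray(radii_matrix, dtype=float))
    n_slices, n_theta = radii_matrix.shape
    if z_values is None:
        # aspect chosen so the tube looks torso-like next to unit-size radii
        z_values = np.linspace(0.0, 2.0 * radii_matrix.mean() * n_slices / 8.0, n_slices)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    verts = []
    for k in range(n_slices):
        plane = polar_to_plane(theta, radii_matrix[k])
        ring = np.column_stack([plane, np.full(n_theta, z_values[k])])
        verts.append(ring)
    vertices = np.vstack(verts)
    faces = []
    for k in range(n_slices - 1):
        base = k * n_theta
        nxt = (k + 1) * n_theta
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            faces.append([base + j, base + j2, nxt + j])
            faces.append([base + j2, nxt + j2, nxt + j])
    dev = None if deviations is None else np.asarray(deviations, dtype=float).ravel()
    return DeviationMesh(vertices=vertices, faces=np.asarray(faces, dtype=int),
                         deviations=dev)


def reconstruct_extreme(
    model: ShapeFeatureModel,
    pc_index: int,
    magnitude: float,
    n_slices: int = 21,
    n_coeff: int = N_COEFF_DEFAULT,
    n_theta: int = 360,
    include_dc: bool = True,
) -> tuple[np.ndarray, DeviationMesh]:
    """Descriptor and deviation mesh at ``mean + magnitude * loading[pc_index]``.

    The per-vertex deviation is the reconstructed radius minus the
    mean-torso radius at the same (slice, theta), so the +m and -m
    extremes carry exactly opposite deviation fields.
    """
    if not 0 <= pc_index < model.n_retained:
        raise IndexError(
            f"pc_index {pc_index} out of range (0..{model.n_retained - 1})"
        )
    flat = model.mean_descriptor + magnitude * model.loadings[pc_index]
    mean_radii = _descriptor_radii(model.mean_descriptor, n_slices, n_coeff, n_theta, include_dc)
    ext_radii = _descriptor_radii(flat, n_slices, n_coeff, n_theta, include_dc)
    deviations = (ext_radii - mean_radii).ravel()
    mesh = loft_slices(ext_radii, deviations=deviations)
    return flat, mesh


def _descriptor_radii(flat: np.ndarray, n_slices: int, n_coeff: int,
                      n_theta: int, include_dc: bool) -> np.ndarray:
    spectra: list[SliceSpectrum] = unflatten_vector(
        flat, n_slices=n_slices, n_coeff=n_coeff, include_dc=include_dc
    )
    return np.vstack([reconstruct_profile(s, n_theta) for s in spectra])
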