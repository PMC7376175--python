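"""Local anatomical coordinate system from the bony-landmark quartet.

The frame removes between-participant differences in translation and
orientation before slicing. Axis vocabulary follows the scan-processing
convention used throughout this package:

* **transverse** axis — unit vector from the xiphoid process to the 9th
  thoracic vertebra, i.e. the anterior->posterior direction;
* **sagittal** axis — the left->right ASIS direction, orthogonalized
  against the transverse axis (Gram-Schmidt, transverse kept exact);
* **longitudinal** axis — transverse x sagittal, sign-corrected to point
  from the ASIS (pelvis) level toward the xiphoid (chest) level, i.e.
  inferior->superior.

Note this "transverse axis" names a *direction* (normal to the coronal
plane), not the transverse *plane*; slices are cut perpendicular to the
longitudinal axis.

The origin is the midpoint of xiphoid and T9 — the centre of the torso.
The two defining landmark vectors are generally not orthogonal in a real
body; keeping the xiphoid->T9 direction exact and bending the ASIS
direction is the default because the longitudinal axis is derived from
their cross product, making the first two vectors primary. Pass
``keep="sagittal"`` to preserve the ASIS direction instead for
sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryError
from .io import LandmarkSet, PointCloud3D

_MIN_ANGLE_DEG = 1.0


@dataclass
class AnatomicalFrame:
    """Origin (mm) plus a right-handed orthonormal axis triple.

    ``axes`` rows are (transverse, sagittal, longitudinal); a point p in
    scanner coordinates maps to ``axes @ (p - origin)`` so the longitudinal
    coordinate is the third component.
    """

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows = transverse, sagittal, longitudinal

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise GeometryError("frame axes are left-handed")

    @property
    def transverse(self) -> np.ndarray:
        return self.axes[0]

    @property
    def sagittal(self) -> np.ndarray:
        return self.axes[1]

    @property
    def longitudinal(self) -> np.ndarray:
        return self.axes[2]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"origin": self.origin.tolist(), "axes": self.axes.tolist()}, fh, indent=1)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AnatomicalFrame":
        with open(path) as fh:
            d = json.load(fh)
        return cls(origin=np.array(d["origin"]), axes=np.array(d["axes"]))


def build_frame(landmarks: LandmarkSet, keep: str = "transverse") -> AnatomicalFrame:
    """Construct the anatomical frame from the landmark quartet.

    Parameters
    ----------
    landmarks
        Must contain xiphoid_process, t9_vertebra, asis_left, asis_right.
    keep
        Which defining vector survives orthogonalization exactly:
        ``"transverse"`` (default, xiphoid->T9 kept) or ``"sagittal"``
        (ASIS left->right kept).
    """
    xiphoid = landmarks["xiphoid_process"]
    t9 = landmarks["t9_vertebra"]
    asis_l = landmarks["asis_left"]
    asis_r = landmarks["asis_right"]

    v_trans = t9 - xiphoid
    v_sag = asis_r - asis_l
    n_trans = np.linalg.norm(v_trans)
    n_sag = np.linalg.norm(v_sag)
    if n_trans == 0 or n_sag == 0:
        raise GeometryError("coincident landmarks give a zero-length axis vector")
    u_trans = v_trans / n_trans
    u_sag_raw = v_sag / n_sag
    cosang = abs(float(np.dot(u_trans, u_sag_raw)))
    if cosang > np.cos(np.deg2rad(_MIN_ANGLE_DEG)):
        raise GeometryError(
            "xiphoid->T9 and ASIS left->right vectors are (near-)parallel; "
            "cannot span a plane"
        )

    if keep == "transverse":
        transverse = u_trans
        sagittal = u_sag_raw - np.dot(u_sag_raw, transverse) * transverse
        sagittal /= np.linalg.norm(sagittal)
    elif keep == "sagittal":
        sagittal = u_sag_raw
        transverse = u_trans - np.dot(u_trans, sagittal) * sagittal
        transverse /= np.linalg.norm(transverse)
    else:
        raise ValueError(f"keep must be 'transverse' or 'sagittal', got {keep!r}")

    longitudinal = np.cross(transverse, sagittal)
    # Sign convention: positive longitudinal points from the ASIS (pelvis)
    # level toward the xiphoid (chest) level.
    asis_mid = 0.5 * (asis_l + asis_r)
    if np.dot(longitudinal, xiphoid - asis_mid) < 0:
        longitudinal = -longitudinal
        sagittal = -sagittal  # preserve right-handedness, keep transverse exact

    origin = 0.5 * (xiphoid + t9)
    return AnatomicalFrame(origin=origin, axes=np.vstack([transverse, sagittal, longitudinal]))


def to_anatomical(cloud: PointCloud3D, frame: AnatomicalFrame) -> PointCloud3D:
    """Express a cloud in frame coordinates (origin subtracted, projected
    onto the axis triple); component order (transverse, sagittal, longitudinal)."""
    pts = (cloud.points - frame.origin) @ frame.axes.T
    return PointCloud3D(pts, source_id=cloud.source_id)


def from_anatomical(cloud: PointCloud3D, frame: AnatomicalFrame) -> PointCloud3D:
    """Inverse of :func:`to_anatomical`."""
    pts = cloud.points @ frame.axes + frame.origin
    return PointCloud3D(pts, source_id=cloud.source_id)


def landmarks_to_anatomical(landmarks: LandmarkSet, frame: AnatomicalFrame) -> LandmarkSet:
    return landmarks.transformed(lambda p: frame.axes @ (p - frame.origin))
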