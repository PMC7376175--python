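"""Reading and writing external artifacts.

Point clouds (PLY / OBJ / XYZ), bony-landmark files (JSON / CSV),
anthropometric tables (CSV), descriptor matrices (CSV) and
deviation-colored PLY meshes. All geometry is kept in millimetres
internally; unit conversion happens here or at the statistics boundary,
nowhere else.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError, ValidationError

REQUIRED_LANDMARKS = ("xiphoid_process", "t9_vertebra", "asis_left", "asis_right")

# Aliases seen in digitising-software exports, normalised to the canonical
# lower-snake-case vocabulary.
_LANDMARK_ALIASES = {
    "xiphoid": "xiphoid_process",
    "xiphoid_process": "xiphoid_process",
    "t9": "t9_vertebra",
    "t9_vertebra": "t9_vertebra",
    "9th_thoracic_vertebra": "t9_vertebra",
    "9th_thoracic_vertebrae": "t9_vertebra",
    "thoracic_vertebra_9": "t9_vertebra",
    "asis_left": "asis_left",
    "asis_l": "asis_left",
    "left_asis": "asis_left",
    "asis_right": "asis_right",
    "asis_r": "asis_right",
    "right_asis": "asis_right",
}

ANTHRO_COLUMNS = (
    "participant_id",
    "stature_m",
    "mass_kg",
    "waist_girth_m",
    "hip_girth_m",
    "skinfold_iliac_crest_mm",
    "skinfold_supraspinale_mm",
    "skinfold_abdominal_mm",
)


@dataclass
class PointCloud3D:
    """Raw scan geometry in scanner (or anatomical) coordinates, millimetres."""

    points: np.ndarray  # (n, 3) float64, mm
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(
                f"point cloud must be (n, 3), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class LandmarkSet:
    """Named bony landmarks in mm; the quartet needed for the anatomical frame
    (xiphoid process, T9 vertebra, left/right ASIS) must be present."""

    landmarks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.landmarks = {
            str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()
        }
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.landmarks]
        if missing:
            raise ValidationError(f"missing required landmarks: {missing}")
        if np.allclose(self["asis_left"], self["asis_right"]):
            raise ValidationError("asis_left coincides with asis_right")
        if np.allclose(self["xiphoid_process"], self["t9_vertebra"]):
            raise ValidationError("xiphoid_process coincides with t9_vertebra")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.landmarks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.landmarks

    def __len__(self) -> int:
        return len(self.landmarks)

    @property
    def names(self) -> list[str]:
        return list(self.landmarks)

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn`` (a point-wise 3-vector map) to every landmark."""
        return LandmarkSet({k: fn(v) for k, v in self.landmarks.items()})


def canonical_landmark_name(raw: str) -> str:
    key = "_".join(str(raw).strip().lower().replace("-", " ").split())
    return _LANDMARK_ALIASES.get(key, key)


# ---------------------------------------------------------------------------
# point clouds


def read_point_cloud(path: str | Path, unit_scale: float = 1.0) -> PointCloud3D:
    """Read vertices from a PLY / OBJ / XYZ file, scaled into millimetres.

    Faces, colors and normals are discarded; point order is preserved.
    ``unit_scale`` multiplies every coordinate (1000 for a file in metres).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext not in {".ply", ".obj", ".xyz"}:
        raise FormatError(f"unsupported point-cloud extension {ext!r} ({path})")
    if ext == ".xyz":
        points = _read_xyz(path)
    else:
        try:
            loaded = trimesh.load(str(path), process=False)
        except Exception as exc:  # trimesh raises assorted types on bad files
            raise FormatError(f"could not parse {path}: {exc}") from exc
        points = np.asarray(loaded.vertices, dtype=float)
    if points.size == 0:
        raise FormatError(f"no vertices found in {path}")
    return PointCloud3D(points * float(unit_scale), source_id=path.stem)


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def write_point_cloud(cloud: PointCloud3D, path: str | Path) -> Path:
    """Write a point cloud; format chosen by extension (.ply ASCII, .obj, .xyz)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".xyz":
        np.savetxt(path, cloud.points, fmt="%.9g")
    elif ext == ".obj":
        with open(path, "w") as fh:
            for x, y, z in cloud.points:
                fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
    elif ext == ".ply":
        trimesh.PointCloud(cloud.points).export(str(path), encoding="ascii")
    else:
        raise FormatError(f"unsupported point-cloud extension {ext!r}")
    return path


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmarks from JSON ({name: [x,y,z]}) or CSV (name,x,y,z columns)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            try:
                raw: Mapping[str, list[float]] = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"could not parse {path}: {exc}") from exc
        items = list(raw.items())
    else:
        df = pd.read_csv(path)
        required_cols = {"name", "x", "y", "z"}
        if not required_cols.issubset(df.columns):
            raise FormatError(
                f"{path}: landmark CSV needs columns name,x,y,z; got {list(df.columns)}"
            )
        items = [(r["name"], [r["x"], r["y"], r["z"]]) for _, r in df.iterrows()]

    landmarks: dict[str, np.ndarray] = {}
    for name, xyz in items:
        canon = canonical_landmark_name(name)
        if canon in landmarks:
            raise ValidationError(f"duplicate landmark {canon!r} in {path}")
        landmarks[canon] = np.asarray(xyz, dtype=float)
    missing = [n for n in REQUIRED_LANDMARKS if n not in landmarks]
    if missing:
        raise ValidationError(f"{path}: missing required landmarks: {missing}")
    return LandmarkSet(landmarks)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({k: list(map(float, v)) for k, v in landmarks.landmarks.items()}, fh, indent=1)
    else:
        pd.DataFrame(
            [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in landmarks.landmarks.items()]
        ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# anthropometric tables


def read_anthro_table(path: str | Path) -> pd.DataFrame:
    """Read the per-participant manual-measurement table.

    Canonical units: stature / girths in metres, mass in kg, skinfolds in mm.
    Missing skinfolds are encoded as empty cells and come back as NaN.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in ANTHRO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: anthro table missing columns {missing_cols}")
    df = df.astype({c: float for c in ANTHRO_COLUMNS if c != "participant_id"})
    validate_anthro_table(df)
    return df


def validate_anthro_table(df: pd.DataFrame) -> None:
    for col in ("stature_m", "mass_kg", "waist_girth_m", "hip_girth_m",
                "skinfold_iliac_crest_mm", "skinfold_supraspinale_mm",
                "skinfold_abdominal_mm"):
        vals = df[col].dropna()
        if (vals <= 0).any():
            raise ValidationError(f"non-positive values in column {col!r}")
    odd = df["stature_m"].dropna()
    if ((odd < 1.0) | (odd > 2.5)).any():
        warnings.warn("stature outside plausible [1.0, 2.5] m range", stacklevel=2)


def write_anthro_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# descriptor matrices (participants x 420 named columns)


def descriptor_column_names(n_slices: int = 21, n_coeff: int = 10) -> list[str]:
    """Column order of the flattened descriptor: slice-major, real parts of
    the 10 retained coefficients then imaginary parts (s{slice}_k{freq}_{re|im})."""
    cols = []
    for s in range(n_slices):
        cols.extend(f"s{s}_k{k}_re" for k in range(n_coeff))
        cols.extend(f"s{s}_k{k}_im" for k in range(n_coeff))
    return cols


def write_descriptor_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, index=True, index_label="participant_id", float_format="%.12e")
    return path


def read_descriptor_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="participant_id")
    expected = descriptor_column_names()
    if list(df.columns) != expected:
        raise FormatError(f"{path}: descriptor columns do not match the canonical layout")
    return df


# ---------------------------------------------------------------------------
# deviation-colored meshes


@dataclass
class DeviationMesh:
    """A lofted torso surface with a signed per-vertex radial deviation (mm
    or scaled units) carried as the PLY "quality" property."""

    vertices: np.ndarray
    faces: np.ndarray
    deviations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.deviations is None:
            self.deviations = np.zeros(len(self.vertices))
        self.deviations = np.asarray(self.deviations, dtype=float).ravel()
        if len(self.deviations) != len(self.vertices):
            raise ValidationError(
                f"{len(self.deviations)} deviation scalars for {len(self.vertices)} vertices"
            )


def write_deviation_mesh(mesh: DeviationMesh, path: str | Path) -> Path:
    """Write an ASCII PLY whose per-vertex float "quality" property carries
    the signed radial deviation (blue/red rendering in any PLY viewer)."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.vertex_attributes["quality"] = mesh.deviations.astype(np.float32)
    tm.export(str(path), encoding="ascii", include_attributes=True)
    return path


def read_deviation_mesh(path: str | Path) -> DeviationMesh:
    tm = trimesh.load(str(path), process=False)
    quality = None
    raw = tm.metadata.get("_ply_raw") if hasattr(tm, "metadata") else None
    if raw and "vertex" in raw:
        data = raw["vertex"]["data"]
        if "quality" in data:
            quality = np.asarray(data["quality"], dtype=float).ravel()
    return DeviationMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=int),
        deviations=quality,
    )
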