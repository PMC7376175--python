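"""Torso segmentation, transverse slicing and polar radius waveforms.

The torso segment between the ASIS and xiphoid levels is cut into 21
transverse slices of 2 mm thickness at 5% intervals of segment length.
Each slice is collapsed to 2D and converted into a single-valued polar
radius waveform r(theta) about its own centroid: raw points are binned
on a uniform angle grid, empty bins are filled by periodic linear
interpolation, and a periodic cubic smoothing spline removes scanner
noise. Finally the whole torso is brought to unit centroid size so that
only shape, not scale, survives.

Angle convention: theta is measured counter-clockwise (viewed from
above, i.e. from +longitudinal) starting at the +sagittal axis
(subject's left->right); theta = 90 deg is anterior. Every participant
shares the anatomical frame, so any fixed convention preserves
between-participant comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate

from .errors import (
    GeometryError,
    ShapeTopologyError,
    SliceCoverageError,
    SparseScanError,
)
from .io import LandmarkSet, PointCloud3D

N_SLICES_DEFAULT = 21
THICKNESS_MM_DEFAULT = 2.0
N_THETA_DEFAULT = 360
MIN_SEGMENT_POINTS_DEFAULT = 1000
MIN_SLICE_POINTS_DEFAULT = 30
MAX_GAP_DEG_DEFAULT = 15.0
SPLINE_SMOOTHING_DEFAULT = 1.0  # mm^2 residual budget per angular sample
REFERENCE_LENGTH_MM_DEFAULT = 400.0


@dataclass
class TorsoSegment:
    """Points (anatomical coordinates) between the ASIS and xiphoid levels."""

    cloud: PointCloud3D
    z_low: float   # ASIS longitudinal level, mm
    z_high: float  # xiphoid longitudinal level, mm

    def __post_init__(self) -> None:
        if not self.z_high > self.z_low:
            raise GeometryError("xiphoid level must lie above ASIS level")

    @property
    def length(self) -> float:
        return self.z_high - self.z_low


@dataclass
class SliceProfile:
    """One transverse slice as a uniformly sampled polar radius waveform."""

    slice_index: int
    height_fraction: float
    centroid: np.ndarray           # 2D, (transverse-plane x, y) in mm
    radii: np.ndarray              # (n_theta,) mm, theta_j = 2*pi*j/n_theta
    n_raw_points: int

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(2)
        self.radii = np.asarray(self.radii, dtype=float)
        if not np.all(np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise GeometryError(
                f"slice {self.slice_index}: radii must be positive and finite"
            )

    @property
    def n_theta(self) -> int:
        return len(self.radii)

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_theta) / self.n_theta


@dataclass
class ScaledTorsoProfiles:
    """All slices of one torso after centroid-size normalization (size S0=1)."""

    profiles: list[SliceProfile]
    scale_factor: float
    centroid_size_before: float

    def __len__(self) -> int:
        return len(self.profiles)

    def radii_matrix(self) -> np.ndarray:
        """(n_slices, n_theta) matrix of scaled radii."""
        return np.vstack([p.radii for p in self.profiles])


def segment_torso(
    cloud: PointCloud3D,
    landmarks: LandmarkSet,
    min_points: int = MIN_SEGMENT_POINTS_DEFAULT,
) -> TorsoSegment:
    """Keep only points between the ASIS level (mean of left/right) and the
    xiphoid level, inclusive. Cloud and landmarks must already be in the
    anatomical frame (longitudinal coordinate third)."""
    z_low = 0.5 * (landmarks["asis_left"][2] + landmarks["asis_right"][2])
    z_high = landmarks["xiphoid_process"][2]
    if not z_high > z_low:
        raise GeometryError("xiphoid must be above the ASIS level in the frame")
    z = cloud.points[:, 2]
    keep = (z >= z_low) & (z <= z_high)
    n_kept = int(keep.sum())
    if n_kept < min_points:
        raise SparseScanError(
            f"only {n_kept} points inside the torso segment (minimum {min_points})"
        )
    return TorsoSegment(
        cloud=PointCloud3D(cloud.points[keep], source_id=cloud.source_id),
        z_low=float(z_low),
        z_high=float(z_high),
    )


def slice_centres(z_low: float, z_high: float, n_slices: int = N_SLICES_DEFAULT) -> np.ndarray:
    """Slice centres at equal fractions of segment length (5% for 21 slices)."""
    return z_low + np.arange(n_slices) * (z_high - z_low) / (n_slices - 1)


def extract_slices(
    segment: TorsoSegment,
    n_slices: int = N_SLICES_DEFAULT,
    thickness: float = THICKNESS_MM_DEFAULT,
    min_slice_points: int = MIN_SLICE_POINTS_DEFAULT,
) -> list[np.ndarray]:
    """Cut ``n_slices`` transverse bands of the given thickness (closed
    interval) and collapse each to 2D; returns a list of (m_k, 2) arrays."""
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    z = segment.cloud.points[:, 2]
    xy = segment.cloud.points[:, :2]
    half = thickness / 2.0
    slices = []
    for k, z_k in enumerate(slice_centres(segment.z_low, segment.z_high, n_slices)):
        members = np.abs(z - z_k) <= half
        count = int(members.sum())
        if count < min_slice_points:
            raise SliceCoverageError(
                f"slice {k} at z={z_k:.1f} mm has {count} points (minimum {min_slice_points})"
            )
        slices.append(xy[members])
    return slices


def polar_profile(
    raw_slice: np.ndarray,
    slice_index: int = 0,
    height_fraction: float = 0.0,
    n_theta: int = N_THETA_DEFAULT,
    smoothing: float = SPLINE_SMOOTHING_DEFAULT,
    max_gap_deg: float = MAX_GAP_DEG_DEFAULT,
) -> SliceProfile:
    """Convert one raw 2D slice to a smooth polar radius waveform.

    Points are expressed as (theta, r) about the slice centroid, averaged
    in ``n_theta`` uniform angular bins, gaps up to ``max_gap_deg`` filled
    by periodic linear interpolation, then a periodic cubic smoothing
    spline (FITPACK, residual budget ``smoothing`` per sample) is
    evaluated back on the uniform grid. ``smoothing=0`` interpolates the
    binned values exactly.
    """
    raw_slice = np.asarray(raw_slice, dtype=float).reshape(-1, 2)
    if len(raw_slice) == 0:
        raise SliceCoverageError(f"slice {slice_index}: no raw points")
    centroid = raw_slice.mean(axis=0)
    rel = raw_slice - centroid
    # plane components are (transverse, sagittal); theta runs CCW (seen from
    # +longitudinal) from +sagittal, so 90 deg = -transverse = anterior
    theta_pts = np.mod(np.arctan2(-rel[:, 0], rel[:, 1]), 2.0 * np.pi)
    r_pts = np.hypot(rel[:, 0], rel[:, 1])

    # bin means on the uniform grid; bin j covers theta_j +/- pi/n_theta
    bin_idx = np.mod(np.round(theta_pts / (2.0 * np.pi / n_theta)).astype(int), n_theta)
    sums = np.bincount(bin_idx, weights=r_pts, minlength=n_theta)
    counts = np.bincount(bin_idx, minlength=n_theta)
    filled = counts > 0
    _check_star_shaped(filled, n_theta, max_gap_deg, slice_index)
    binned = np.full(n_theta, np.nan)
    binned[filled] = sums[filled] / counts[filled]
    binned = _fill_gaps_periodic(binned)

    theta_grid = 2.0 * np.pi * np.arange(n_theta) / n_theta
    if smoothing > 0:
        # periodic smoothing spline: duplicate the first sample at 2*pi
        x = np.append(theta_grid, 2.0 * np.pi)
        y = np.append(binned, binned[0])
        tck = interpolate.splrep(x, y, per=1, s=float(smoothing) * n_theta, k=3)
        radii = interpolate.splev(theta_grid, tck)
    else:
        radii = binned
    return SliceProfile(
        slice_index=slice_index,
        height_fraction=height_fraction,
        centroid=centroid,
        radii=radii,
        n_raw_points=len(raw_slice),
    )


def _check_star_shaped(filled: np.ndarray, n_theta: int, max_gap_deg: float,
                       slice_index: int) -> None:
    """Reject slices with an empty angular sector wider than the infill span
    (occlusion / non-star-shaped cross-section)."""
    if filled.all():
        return
    if not filled.any():
        raise ShapeTopologyError(f"slice {slice_index}: all angular bins empty")
    # longest circular run of empty bins
    empty = ~filled
    doubled = np.concatenate([empty, empty])
    longest = run = 0
    for e in doubled:
        run = run + 1 if e else 0
        longest = max(longest, run)
    longest = min(longest, n_theta)
    gap_deg = longest * 360.0 / n_theta
    if gap_deg > max_gap_deg:
        raise ShapeTopologyError(
            f"slice {slice_index}: empty angular sector of {gap_deg:.1f} deg "
            f"exceeds the {max_gap_deg:.1f} deg infill limit"
        )


def _fill_gaps_periodic(binned: np.ndarray) -> np.ndarray:
    """Fill NaN bins by linear interpolation on the circle."""
    nan = np.isnan(binned)
    if not nan.any():
        return binned
    n = len(binned)
    idx = np.arange(n)
    good = idx[~nan]
    # wrap neighbours so interpolation is periodic
    x = np.concatenate([good, good[:1] + n])
    y = np.concatenate([binned[good], binned[good[:1]]])
    out = binned.copy()
    out[nan] = np.interp(np.where(nan)[0], x, y, period=n)
    return out


def polar_to_plane(theta: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Map (theta, r) back to (transverse, sagittal) offsets about the
    centroid, inverting the angle convention of :func:`polar_profile`."""
    return np.column_stack([-radii * np.sin(theta), radii * np.cos(theta)])


def centroid_size(profiles: list[SliceProfile]) -> float:
    """Root-sum-of-squares of all radius samples about their slice centroids
    (the geometric-morphometrics centroid size on the resampled waveforms)."""
    return float(np.sqrt(sum(float(np.sum(p.radii ** 2)) for p in profiles)))


def centroid_size_sum(profiles: list[SliceProfile]) -> float:
    """Plain sum-of-distances variant (alternative normalization)."""
    return float(sum(float(np.sum(p.radii)) for p in profiles))


def scale_torso(
    profiles: list[SliceProfile],
    target_size: float = 1.0,
    variant: str = "rss",
) -> ScaledTorsoProfiles:
    """Normalize the whole torso to a common centroid size.

    ``variant="rss"`` (default) uses root-sum-of-squares centroid size;
    ``variant="sum"`` normalizes the plain sum of radii instead. One scale
    factor is applied to every radius and slice centroid, so relative
    girths along the torso are preserved.
    """
    if variant == "rss":
        size = centroid_size(profiles)
    elif variant == "sum":
        size = centroid_size_sum(profiles)
    else:
        raise ValueError(f"unknown scaling variant {variant!r}")
    if size <= 0:
        raise GeometryError("zero centroid size; degenerate torso")
    factor = target_size / size
    scaled = [
        SliceProfile(
            slice_index=p.slice_index,
            height_fraction=p.height_fraction,
            centroid=p.centroid * factor,
            radii=p.radii * factor,
            n_raw_points=p.n_raw_points,
        )
        for p in profiles
    ]
    return ScaledTorsoProfiles(profiles=scaled, scale_factor=factor, centroid_size_before=size)


def torso_profiles(
    cloud: PointCloud3D,
    landmarks: LandmarkSet,
    n_slices: int = N_SLICES_DEFAULT,
    thickness: float = THICKNESS_MM_DEFAULT,
    n_theta: int = N_THETA_DEFAULT,
    smoothing: float = SPLINE_SMOOTHING_DEFAULT,
    min_segment_points: int = MIN_SEGMENT_POINTS_DEFAULT,
    min_slice_points: int = MIN_SLICE_POINTS_DEFAULT,
    max_gap_deg: float = MAX_GAP_DEG_DEFAULT,
    scaling_variant: str = "rss",
    reference_length: float = REFERENCE_LENGTH_MM_DEFAULT,
) -> ScaledTorsoProfiles:
    """Segment -> slice -> polar waveforms -> unit centroid size, for a cloud
    and landmarks already expressed in the anatomical frame.

    Before slicing, the segment is brought to ``reference_length`` by one
    uniform (shape-preserving) scaling, so the slice thickness and the
    spline roughness budget mean the same material fraction of every
    torso regardless of the scan's overall size: "2 mm" is 2 mm on a
    400 mm segment, i.e. 0.5% of segment length. This makes the whole
    extraction exactly invariant under uniform scaling of the input;
    the final centroid-size normalization removes the remaining common
    scale.
    """
    segment = segment_torso(cloud, landmarks, min_points=min_segment_points)
    pre = reference_length / segment.length
    if pre != 1.0:
        segment = TorsoSegment(
            cloud=PointCloud3D(segment.cloud.points * pre,
                               source_id=segment.cloud.source_id),
            z_low=segment.z_low * pre,
            z_high=segment.z_high * pre,
        )
    raw = extract_slices(segment, n_slices=n_slices, thickness=thickness,
                         min_slice_points=min_slice_points)
    profiles = [
        polar_profile(
            raw[k],
            slice_index=k,
            height_fraction=k / (n_slices - 1),
            n_theta=n_theta,
            smoothing=smoothing,
            max_gap_deg=max_gap_deg,
        )
        for k in range(n_slices)
    ]
    return scale_torso(profiles, variant=scaling_variant)
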