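"""Parametric synthetic torso cohorts with known ground truth.

No scan corpus ships with this package, so every pipeline stage is
exercised against a generative model whose answers are known exactly.
A participant's torso surface is a star-shaped tube

    r(theta, z) = base(f) * (1 + sum_m a_m * w_m(f) * cos(k_m * theta + phi_m)),

with ``f`` the height fraction between the ASIS level (f=0) and the
xiphoid level (f=1). Each mode m is a (slice-weight x angular-harmonic)
deformation — the same functional space the Fourier descriptors live in,
so injected modes map to exactly known descriptor directions and PCA
recovery can be tested against ground truth rather than approximations.
Per-participant amplitudes ``a_m`` are independent zero-mean Gaussians.

The matched anthropometric record draws stature/mass/waist/hip from a
correlated Gaussian around cohort means, and builds the sum of skinfolds
as a linear function of the mode amplitudes and the waist z-score plus
Gaussian noise, so the shape-adiposity association strength is a dial
with a computable generative R^2.

Two output routes share all shape mathematics:

* :func:`generate_torso` — surface point clouds with landmarks, given a
  random rigid motion and uniform scale (exercises the invariance the
  anatomical frame and scale normalization must deliver);
* :func:`generate_profile_radii` — exact radii on the slice x angle
  grid, for statistical experiments at cohort sizes where sampling
  millions of surface points would be pointless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import GeometryError, ValidationError
from .io import LandmarkSet, PointCloud3D
from .slicing import SliceProfile, scale_torso
from .fourier import descriptor_from_profiles

# Cohort-level anthropometric defaults (canonical units: m, kg, mm).
ANTHRO_MEANS = {"stature_m": 1.798, "mass_kg": 82.9, "waist_girth_m": 0.8606,
                "hip_girth_m": 1.0036}
ANTHRO_SDS = {"stature_m": 0.072, "mass_kg": 16.2, "waist_girth_m": 0.1019,
              "hip_girth_m": 0.073}
# correlations among (stature, mass, waist, hip); positive definite
ANTHRO_CORR = np.array([
    [1.00, 0.47, 0.12, 0.46],
    [0.47, 1.00, 0.83, 0.95],
    [0.12, 0.83, 1.00, 0.79],
    [0.46, 0.95, 0.79, 1.00],
])
SSF_MEAN_MM = 51.95
SSF_SD_MM = 26.33
SKINFOLD_SHARES = np.array([17.4, 11.7, 22.9]) / 52.0  # iliac crest, supraspinale, abdominal


@dataclass(frozen=True)
class ShapeMode:
    """One injected deformation mode.

    ``harmonic`` is the angular frequency k; ``phase`` the angular offset
    (radians); ``slice_order`` selects the slice weight
    ``w(f) = cos(slice_order * pi * f)`` (order 0 = uniform along the
    torso); ``amplitude_sd`` the between-participant SD of the
    dimensionless relative amplitude.
    """

    harmonic: int
    phase: float
    slice_order: int
    amplitude_sd: float

    def slice_weight(self, f: np.ndarray) -> np.ndarray:
        return np.cos(self.slice_order * np.pi * np.asarray(f, dtype=float))

    def angular(self, theta: np.ndarray) -> np.ndarray:
        return np.cos(self.harmonic * theta + self.phase)


# anterior weighting (k=1 peaking at theta=90deg), ellipticity (k=2), and a
# girth-taper mode (k=0, waist-vs-chest redistribution). Amplitude SDs are
# chosen so the modes' descriptor-space variances are well separated and
# ordered like the amplitudes: a k=0 mode enters the radius waveform at
# full weight while k>=1 harmonics split across +/-k, so its SD is set
# smaller to keep the ordering unambiguous for recovery tests.
DEFAULT_MODES = (
    ShapeMode(harmonic=1, phase=-np.pi / 2, slice_order=0, amplitude_sd=0.040),
    ShapeMode(harmonic=2, phase=0.0, slice_order=0, amplitude_sd=0.030),
    ShapeMode(harmonic=0, phase=0.0, slice_order=1, amplitude_sd=0.012),
)


@dataclass(frozen=True)
class SSFModel:
    """Linear generative model for the skinfold sum (mm).

    ``mode_coeffs[m]`` is the SSF change (mm) per 1-SD change of mode m's
    amplitude; ``waist_coeff`` per 1-SD of waist girth; residual noise is
    Gaussian with ``noise_sd``.
    """

    mode_coeffs: tuple[float, ...] = (10.5, -10.5, 0.0)
    waist_coeff: float = 19.0
    noise_sd: float = 10.6
    mean: float = SSF_MEAN_MM

    def signal_sd(self) -> float:
        return float(np.sqrt(sum(c ** 2 for c in self.mode_coeffs)
                             + self.waist_coeff ** 2))

    def shape_r_squared(self) -> float:
        """Fraction of SSF variance carried by the shape modes alone."""
        shape_var = sum(c ** 2 for c in self.mode_coeffs)
        total = shape_var + self.waist_coeff ** 2 + self.noise_sd ** 2
        return shape_var / total


@dataclass(frozen=True)
class CohortSpec:
    """Full generative specification of a synthetic cohort."""

    n_participants: int = 43
    seed: int = 0
    mean_radius_mm: float = 140.0
    taper: float = 0.08                  # base(f) = mean * (1 + taper*cos(2*pi*f))
    segment_length_mm: float = 400.0
    z_margin_mm: float = 25.0
    modes: tuple[ShapeMode, ...] = DEFAULT_MODES
    surface_noise_sd: float = 1.0        # mm, radial, per sampled point
    point_density: float = 0.35          # points per mm^2 of surface
    ssf_model: SSFModel = field(default_factory=SSFModel)
    missing_skinfold_fraction: float = 6.0 / 43.0
    rigid_jitter: bool = True            # random rigid motion + uniform scale per scan

    def __post_init__(self) -> None:
        total_amp = sum(3.0 * m.amplitude_sd for m in self.modes)
        if total_amp >= 0.9:
            raise ValidationError(
                "mode amplitudes large enough to risk negative radii"
            )
        _check_mode_orthogonality(self.modes)

    def base_radius(self, f: np.ndarray) -> np.ndarray:
        return self.mean_radius_mm * (1.0 + self.taper * np.cos(2.0 * np.pi * np.asarray(f)))

    def surface_radius(self, theta: np.ndarray, f: np.ndarray,
                       amplitudes: np.ndarray) -> np.ndarray:
        modulation = np.ones_like(np.asarray(theta, dtype=float))
        for a, mode in zip(amplitudes, self.modes):
            modulation = modulation + a * mode.slice_weight(f) * mode.angular(theta)
        r = self.base_radius(f) * modulation
        if np.any(r <= 0):
            raise GeometryError("negative surface radius; amplitudes too large")
        return r


def _check_mode_orthogonality(modes: tuple[ShapeMode, ...],
                              n_slices: int = 21, n_theta: int = 360) -> None:
    """Modes must be orthogonal as functions on the (slice, theta) grid."""
    f = np.linspace(0.0, 1.0, n_slices)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    fields = [np.outer(m.slice_weight(f), m.angular(theta)) for m in modes]
    for i in range(len(fields)):
        for j in range(i + 1, len(fields)):
            dot = float(np.sum(fields[i] * fields[j]))
            norm = float(np.linalg.norm(fields[i]) * np.linalg.norm(fields[j]))
            if norm > 0 and abs(dot) / norm > 1e-9:
                raise ValidationError(
                    f"modes {i} and {j} are not orthogonal on the slice/angle grid"
                )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    amplitudes: np.ndarray          # (n, n_modes), dimensionless
    ssf_true: np.ndarray            # (n,), mm, before missingness
    ssf_shape_part: np.ndarray      # (n,), mm, shape contribution alone
    missing_mask: np.ndarray        # (n,), bool, skinfolds withheld
    spec: CohortSpec


# ---------------------------------------------------------------------------
# geometry


def _participant_rng(spec: CohortSpec, participant_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(participant_index,))
    )


def draw_amplitudes(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, [m.amplitude_sd for m in spec.modes])


def generate_torso(
    spec: CohortSpec,
    participant_index: int,
    amplitudes: np.ndarray | None = None,
) -> tuple[PointCloud3D, LandmarkSet]:
    """Sample one torso point cloud plus landmarks, in scanner coordinates.

    The cloud is generated in a canonical pose (x = left->right,
    y = posterior->anterior, z = up, ASIS level at z=0) and then, when
    ``spec.rigid_jitter`` is set, given a random rigid motion and uniform
    scale so downstream invariances are genuinely exercised.
    """
    rng = _participant_rng(spec, participant_index)
    if amplitudes is None:
        amplitudes = draw_amplitudes(spec, rng)
    amplitudes = np.asarray(amplitudes, dtype=float)

    length = spec.segment_length_mm
    z_lo, z_hi = -spec.z_margin_mm, length + spec.z_margin_mm
    circumference = 2.0 * np.pi * spec.mean_radius_mm * (1.0 + spec.taper)
    n_points = int(spec.point_density * circumference * (z_hi - z_lo))
    z = rng.uniform(z_lo, z_hi, n_points)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_points)
    f = np.clip(z / length, 0.0, 1.0)
    r = spec.surface_radius(theta, f, amplitudes)
    if spec.surface_noise_sd > 0:
        r = r + rng.normal(0.0, spec.surface_noise_sd, n_points)
    points = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    def on_surface(theta_l: float, f_l: float) -> np.ndarray:
        rr = float(spec.surface_radius(np.array([theta_l]), np.array([f_l]), amplitudes)[0])
        return np.array([rr * np.cos(theta_l), rr * np.sin(theta_l), f_l * length])

    landmarks = LandmarkSet({
        "xiphoid_process": on_surface(np.pi / 2, 1.0),      # anterior, top
        "t9_vertebra": on_surface(3 * np.pi / 2, 1.0),      # posterior, top
        "asis_left": on_surface(np.deg2rad(140.0), 0.0),    # left-anterior, bottom
        "asis_right": on_surface(np.deg2rad(40.0), 0.0),    # right-anterior, bottom
    })

    if spec.rigid_jitter:
        rot = Rotation.random(rng=rng).as_matrix()
        translation = rng.uniform(-500.0, 500.0, 3)
        scale = rng.uniform(0.8, 1.25)
        transform = lambda p: scale * (p @ rot.T) + translation  # noqa: E731
        points = transform(points)
        landmarks = landmarks.transformed(transform)

    cloud = PointCloud3D(points, source_id=f"synthetic_{participant_index:04d}")
    return cloud, landmarks


def generate_profile_radii(
    spec: CohortSpec,
    amplitudes: np.ndarray,
    rng: np.random.Generator | None = None,
    n_slices: int = 21,
    n_theta: int = 360,
    radial_noise_sd: float = 0.0,
) -> np.ndarray:
    """Exact (n_slices, n_theta) surface radii on the analysis grid, with
    optional per-sample radial noise — the fast route to descriptors."""
    f = np.linspace(0.0, 1.0, n_slices)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    tt, ff = np.meshgrid(theta, f)
    radii = spec.surface_radius(tt, ff, np.asarray(amplitudes, dtype=float))
    if radial_noise_sd > 0:
        if rng is None:
            raise ValidationError("radial noise requested without an rng")
        radii = radii + rng.normal(0.0, radial_noise_sd, radii.shape)
    return radii


def profiles_from_radii(radii: np.ndarray) -> list[SliceProfile]:
    n_slices = len(radii)
    return [
        SliceProfile(slice_index=k, height_fraction=k / (n_slices - 1),
                     centroid=np.zeros(2), radii=radii[k], n_raw_points=radii.shape[1])
        for k in range(n_slices)
    ]


# ---------------------------------------------------------------------------
# cohort


def generate_anthro(
    spec: CohortSpec,
    rng: np.random.Generator,
    amplitudes: np.ndarray,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Anthropometric records matched to the drawn mode amplitudes."""
    n = spec.n_participants
    chol = np.linalg.cholesky(ANTHRO_CORR)
    z = rng.standard_normal((n, 4)) @ chol.T
    cols = ["stature_m", "mass_kg", "waist_girth_m", "hip_girth_m"]
    body = {
        c: np.maximum(ANTHRO_MEANS[c] + ANTHRO_SDS[c] * z[:, i], 0.2 * ANTHRO_MEANS[c])
        for i, c in enumerate(cols)
    }
    waist_z = (body["waist_girth_m"] - ANTHRO_MEANS["waist_girth_m"]) / ANTHRO_SDS["waist_girth_m"]

    ssf_m = spec.ssf_model
    amp_sd = np.array([m.amplitude_sd for m in spec.modes])
    amp_z = amplitudes / amp_sd
    # align coefficient vector with however many modes the spec carries
    coeffs = np.zeros(len(spec.modes))
    given = np.asarray(ssf_m.mode_coeffs, dtype=float)
    k = min(len(coeffs), len(given))
    coeffs[:k] = given[:k]
    shape_part = amp_z @ coeffs
    ssf = (ssf_m.mean + shape_part + ssf_m.waist_coeff * waist_z
           + rng.normal(0.0, ssf_m.noise_sd, n))
    ssf = np.maximum(ssf, 5.0)  # skinfolds are physically positive

    # split into the three sites with jittered shares that sum exactly to SSF
    shares = np.abs(rng.normal(SKINFOLD_SHARES, 0.02, size=(n, 3)))
    shares /= shares.sum(axis=1, keepdims=True)
    skinfolds = shares * ssf[:, None]

    n_missing = int(round(spec.missing_skinfold_fraction * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False)
    missing_mask = np.zeros(n, dtype=bool)
    missing_mask[missing_idx] = True
    skinfolds_out = skinfolds.copy()
    skinfolds_out[missing_mask] = np.nan

    table = pd.DataFrame({
        "participant_id": [f"synthetic_{i:04d}" for i in range(n)],
        **body,
        "skinfold_iliac_crest_mm": skinfolds_out[:, 0],
        "skinfold_supraspinale_mm": skinfolds_out[:, 1],
        "skinfold_abdominal_mm": skinfolds_out[:, 2],
    })
    truth = GroundTruth(
        amplitudes=amplitudes,
        ssf_true=ssf,
        ssf_shape_part=shape_part,
        missing_mask=missing_mask,
        spec=spec,
    )
    return table, truth


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[PointCloud3D, LandmarkSet]], pd.DataFrame, GroundTruth]:
    """Full cohort: point clouds + landmarks, anthro table, ground truth.

    Deterministic given ``spec`` (which carries the seed): geometry uses
    one child RNG stream per participant, the anthro model a dedicated
    stream, so the two halves can be regenerated independently.
    """
    amp_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(10_000,))
    )
    amplitudes = np.vstack([draw_amplitudes(spec, amp_rng)
                            for _ in range(spec.n_participants)])
    scans = [generate_torso(spec, i, amplitudes=amplitudes[i])
             for i in range(spec.n_participants)]
    anthro_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(20_000,))
    )
    table, truth = generate_anthro(spec, anthro_rng, amplitudes)
    return scans, table, truth


def generate_descriptor_cohort(
    spec: CohortSpec,
    n_theta: int = 360,
    radial_noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Fast route: descriptors straight from exact profile radii.

    Skips point sampling and slicing (identical mathematics from the
    radius grid onward: scale normalization then truncated Fourier).
    Returns (descriptor matrix, anthro table, ground truth).
    """
    amp_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(10_000,))
    )
    amplitudes = np.vstack([draw_amplitudes(spec, amp_rng)
                            for _ in range(spec.n_participants)])
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(30_000,))
    )
    rows = []
    ids = []
    for i in range(spec.n_participants):
        radii = generate_profile_radii(spec, amplitudes[i], rng=noise_rng,
                                       n_theta=n_theta,
                                       radial_noise_sd=radial_noise_sd)
        scaled = scale_torso(profiles_from_radii(radii))
        desc = descriptor_from_profiles(scaled, participant_id=f"synthetic_{i:04d}")
        rows.append(desc.flat_vector)
        ids.append(desc.participant_id)
    from .io import descriptor_column_names
    matrix = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="participant_id"),
                          columns=descriptor_column_names())
    anthro_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(20_000,))
    )
    table, truth = generate_anthro(spec, anthro_rng, amplitudes)
    return matrix, table, truth


# ---------------------------------------------------------------------------
# presets


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """n=43 cohort with 6 missing skinfold triplets (regression n=37)."""
    return replace(CohortSpec(seed=seed), **overrides)


def r2_preset(seed: int = 0, n: int = 2000, r2: float = 0.5, **overrides) -> CohortSpec:
    """Large cohort whose shape modes explain a planned fraction ``r2`` of
    SSF variance (waist decoupled), for generative-R^2 recovery checks."""
    total_var = SSF_SD_MM ** 2
    shape_var = r2 * total_var
    coeffs = (np.sqrt(shape_var / 2.0), -np.sqrt(shape_var / 2.0), 0.0)
    ssf = SSFModel(mode_coeffs=coeffs, waist_coeff=0.0,
                   noise_sd=float(np.sqrt((1.0 - r2) * total_var)))
    return replace(
        CohortSpec(n_participants=n, seed=seed, ssf_model=ssf,
                   missing_skinfold_fraction=0.0),
        **overrides,
    )
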