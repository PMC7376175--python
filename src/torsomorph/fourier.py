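"""Truncated Fourier descriptors of the polar radius waveforms.

Following the closed-curve shape-discrimination approach of Zahn and
Roskies, each slice's radius waveform is reduced to its first 10 complex
Fourier coefficients (frequencies k = 0..9); the higher-frequency content
of a compliant scan is low-amplitude noise. With 21 slices this leaves
210 complex coefficients — 420 reals — per participant.

Conventions (fixed, documented, and relied on by the PCA inversion):

* forward transform uses the 1/N normalization, so coefficients are
  independent of the angular sampling density:
  ``c_k = (1/N) sum_j r_j exp(-2*pi*i*k*j/N)``;
* the DC term c_0 is retained: after whole-torso scale normalization the
  per-slice DC encodes the relative girth profile along the torso
  (waist-to-chest taper), a genuine shape feature; set
  ``include_dc=False`` for the k = 1..10 variant;
* the flattened real vector is slice-major: for slice s and frequency k,
  real parts at ``s*20 + k`` and imaginary parts at ``s*20 + 10 + k``.
  c_0 imaginary entries are structurally zero for a real waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ResolutionError, ValidationError
from .slicing import ScaledTorsoProfiles, SliceProfile

N_COEFF_DEFAULT = 10


@dataclass
class SliceSpectrum:
    """First 10 complex Fourier coefficients of one slice's radius waveform."""

    coefficients: np.ndarray  # (n_coeff,) complex
    include_dc: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.include_dc and abs(self.coefficients[0].imag) > 1e-12:
            raise ValidationError("DC coefficient of a real waveform must be real")

    @property
    def n_coeff(self) -> int:
        return len(self.coefficients)


@dataclass
class ShapeDescriptor:
    """Per-participant descriptor: 21 slice spectra in slice order."""

    participant_id: str
    spectra: list[SliceSpectrum]

    @property
    def n_slices(self) -> int:
        return len(self.spectra)

    @property
    def n_complex(self) -> int:
        return sum(s.n_coeff for s in self.spectra)

    @property
    def flat_vector(self) -> np.ndarray:
        """Real flattening, slice-major, re-block then im-block per slice."""
        return flatten_spectra(self.spectra)


def slice_spectrum(
    profile: SliceProfile | np.ndarray,
    n_coeff: int = N_COEFF_DEFAULT,
    include_dc: bool = True,
) -> SliceSpectrum:
    """Truncated DFT of a uniformly sampled radius waveform (1/N convention)."""
    radii = profile.radii if isinstance(profile, SliceProfile) else np.asarray(profile, float)
    n = len(radii)
    if n < 2 * n_coeff:
        raise ResolutionError(
            f"waveform of length {n} cannot support {n_coeff} coefficients "
            f"(need at least {2 * n_coeff} samples)"
        )
    spectrum = np.fft.fft(radii) / n
    if include_dc:
        coeff = spectrum[:n_coeff]
    else:
        coeff = spectrum[1:n_coeff + 1]
    return SliceSpectrum(coefficients=coeff.copy(), include_dc=include_dc)


def assemble_descriptor(
    spectra: list[SliceSpectrum],
    participant_id: str,
    n_slices: int = 21,
) -> ShapeDescriptor:
    """Assemble per-slice spectra (slice order) into one descriptor."""
    if len(spectra) != n_slices:
        raise ValidationError(f"expected {n_slices} slice spectra, got {len(spectra)}")
    return ShapeDescriptor(participant_id=participant_id, spectra=list(spectra))


def descriptor_from_profiles(
    scaled: ScaledTorsoProfiles,
    participant_id: str,
    n_coeff: int = N_COEFF_DEFAULT,
    include_dc: bool = True,
) -> ShapeDescriptor:
    spectra = [slice_spectrum(p, n_coeff=n_coeff, include_dc=include_dc)
               for p in scaled.profiles]
    return assemble_descriptor(spectra, participant_id, n_slices=len(scaled.profiles))


def flatten_spectra(spectra: list[SliceSpectrum]) -> np.ndarray:
    blocks = []
    for s in spectra:
        blocks.append(s.coefficients.real)
        blocks.append(s.coefficients.imag)
    return np.concatenate(blocks)


def unflatten_vector(
    flat: np.ndarray,
    n_slices: int = 21,
    n_coeff: int = N_COEFF_DEFAULT,
    include_dc: bool = True,
) -> list[SliceSpectrum]:
    """Inverse of :func:`flatten_spectra`."""
    flat = np.asarray(flat, dtype=float)
    if len(flat) != n_slices * 2 * n_coeff:
        raise ValidationError(
            f"flat vector length {len(flat)} != {n_slices * 2 * n_coeff}"
        )
    spectra = []
    for s in range(n_slices):
        block = flat[s * 2 * n_coeff:(s + 1) * 2 * n_coeff]
        coeff = block[:n_coeff] + 1j * block[n_coeff:]
        if include_dc:
            # reconstruction from PCA space may carry numerical dust on the
            # structurally-zero DC imaginary entry; clamp it
            coeff[0] = coeff[0].real
        spectra.append(SliceSpectrum(coefficients=coeff, include_dc=include_dc))
    return spectra


def reconstruct_profile(
    spectrum: SliceSpectrum,
    n_theta: int,
) -> np.ndarray:
    """Invert the retained band back to a radius waveform on a uniform grid.

    For a real waveform the discarded conjugate frequencies are implied:
    ``r_j = c_0 + 2*sum_k [Re(c_k) cos(k*theta_j) - Im(c_k) sin(k*theta_j)]``.
    """
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    coeff = spectrum.coefficients
    if spectrum.include_dc:
        r = np.full(n_theta, coeff[0].real)
        harmonics = enumerate(coeff[1:], start=1)
    else:
        r = np.zeros(n_theta)
        harmonics = enumerate(coeff, start=1)
    for k, c in harmonics:
        r += 2.0 * (c.real * np.cos(k * theta) - c.imag * np.sin(k * theta))
    return r


def dc_imag_indices(n_slices: int = 21, n_coeff: int = N_COEFF_DEFAULT) -> np.ndarray:
    """Flat-vector positions of the structurally-zero c_0 imaginary entries."""
    return np.arange(n_slices) * 2 * n_coeff + n_coeff
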