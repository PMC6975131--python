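"""Exit waves, paraxial Fresnel propagation, and hologram simulation.

Conventions
-----------
Frequencies ``nu`` are in cycles per (effective) pixel on the FFT grid,
DC at index (0, 0); no fftshift is applied inside any kernel.  The paraxial
free-space propagator multiplies the spectrum by ``exp(-i chi)`` with the
chirp phase

    ``chi(nu) = pi |nu|^2 / F``

for per-pixel Fresnel number ``F``; this equals the standard
``pi lambda Delta |f|^2`` with physical frequency ``f = nu / pixel``.  The
global piston phase ``exp(i k Delta)`` is dropped.

The exit wave of a homogeneous object of thickness ``t`` is
``tau = exp(-i k delta t) * exp(-k beta t)`` with ``k = 2 pi / lambda``;
equivalently, in terms of the projected electron density
``D = rho_e * t`` (electrons/nm^2) and ``D_r0 = r0 * D``,
``tau = exp(-i lambda D_r0 - (lambda^3/lambda_r^2) C D_r0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import R0_NM
from .materials import OpticalConstants, cprime as _cprime, rescale_constants

__all__ = [
    "ComplexField",
    "Hologram",
    "frequency_sq",
    "chirp_phase",
    "exit_wave",
    "exit_wave_from_projection",
    "fresnel_propagate",
    "embed",
    "simulate_hologram",
    "simulate_hologram_from_projection",
    "linear_hologram_model",
]


@dataclass
class ComplexField:
    """A monochromatic scalar field sampled on a regular grid."""

    values: np.ndarray  # complex 2-D
    pixel_eff: float | None = None  # nm
    wavelength: float | None = None  # nm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("field values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


@dataclass
class Hologram:
    """A flat-field-corrected intensity image with its wavelength (nm) and
    per-pixel Fresnel number."""

    intensity: np.ndarray
    wavelength: float
    fresnel_number: float
    pixel_eff: float | None = None  # nm

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be 2-D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram intensity must be finite")
        # Measured flat-field-corrected intensities are non-negative with a
        # spatial mean near 1; linearized model holograms may undershoot 0
        # slightly, so negativity is not a hard error here.
        if self.fresnel_number <= 0:
            raise ValueError("fresnel_number must be positive")


def frequency_sq(shape: tuple[int, int]) -> np.ndarray:
    """``|nu|^2`` on the FFT grid, cycles^2/pixel^2, DC at (0, 0)."""
    ny = np.fft.fftfreq(shape[0])[:, None]
    nx = np.fft.fftfreq(shape[1])[None, :]
    return ny**2 + nx**2


def chirp_phase(shape: tuple[int, int], fresnel_number: float) -> np.ndarray:
    """Chirp phase ``chi = pi |nu|^2 / F`` on the FFT grid."""
    if fresnel_number <= 0:
        raise ValueError("fresnel_number must be positive")
    return math.pi * frequency_sq(shape) / fresnel_number


def exit_wave(
    thickness: np.ndarray, constants: OpticalConstants, wavelength: float
) -> ComplexField:
    """Exit wave of a homogeneous object given its projected thickness (nm).

    ``delta``/``beta`` are rescaled from the constants' reference wavelength
    via the ``lambda^2`` / ``lambda^4`` laws before use.
    """
    thickness = np.asarray(thickness, dtype=float)
    if np.any(thickness < 0):
        raise ValueError("thickness must be non-negative")
    oc = rescale_constants(constants, wavelength)
    k = 2.0 * math.pi / wavelength
    tau = np.exp(-k * oc.beta * thickness - 1j * k * oc.delta * thickness)
    return ComplexField(values=tau, wavelength=wavelength)


def exit_wave_from_projection(
    density_proj: np.ndarray, constants: OpticalConstants, wavelength: float
) -> ComplexField:
    """Exit wave from a projected electron density (electrons/nm^2).

    For mixtures of materials sharing one ``beta/delta`` ratio the exit wave
    depends only on the line integral of the electron density; this is the
    homogeneous-object generalisation of :func:`exit_wave`.
    """
    d_r0 = R0_NM * np.asarray(density_proj, dtype=float)
    lam = wavelength
    lam_r = constants.wavelength_ref
    c_ratio = constants.beta / constants.delta
    tau = np.exp(-(lam**3 / lam_r**2) * c_ratio * d_r0 - 1j * lam * d_r0)
    return ComplexField(values=tau, wavelength=wavelength)


def fresnel_propagate(field: ComplexField, fresnel_number: float) -> ComplexField:
    """Propagate a field by frequency-domain multiplication with
    ``exp(-i chi)``; unitary (total intensity conserved)."""
    chi = chirp_phase(field.values.shape, fresnel_number)
    out = np.fft.ifft2(np.fft.fft2(field.values) * np.exp(-1j * chi))
    return ComplexField(values=out, pixel_eff=field.pixel_eff, wavelength=field.wavelength)


def embed(image: np.ndarray, pad_to: tuple[int, int], fill: float = 0.0) -> np.ndarray:
    """Embed an image centrally in a constant background of shape ``pad_to``."""
    image = np.asarray(image)
    py, px = pad_to
    iy, ix = image.shape
    if py < iy or px < ix:
        raise ValueError(f"pad_to {pad_to} smaller than image {image.shape}")
    out = np.full((py, px), fill, dtype=image.dtype)
    oy, ox = (py - iy) // 2, (px - ix) // 2
    out[oy : oy + iy, ox : ox + ix] = image
    return out


def simulate_hologram(
    thickness: np.ndarray,
    constants: OpticalConstants,
    wavelength: float,
    fresnel_number: float,
    pad_to: int | tuple[int, int] | None = None,
    photons: float | None = None,
    rng: np.random.Generator | None = None,
) -> Hologram:
    """Full-propagation hologram of a homogeneous object in a unit background.

    The thickness map is embedded centrally in a zero-thickness (unit
    transmission) background of size ``pad_to`` so the Fresnel kernel is
    adequately sampled, propagated, and squared; the result corresponds to a
    flat-field-divided intensity.  Optional shot noise: ``photons`` incident
    photons per pixel, Poisson, seeded via ``rng``.
    """
    thickness = np.asarray(thickness, dtype=float)
    if pad_to is not None:
        if np.isscalar(pad_to):
            pad_to = (int(pad_to), int(pad_to))
        thickness = embed(thickness, pad_to, fill=0.0)
    tau = exit_wave(thickness, constants, wavelength)
    psi = fresnel_propagate(tau, fresnel_number)
    intensity = psi.intensity
    if photons is not None:
        if rng is None:
            rng = np.random.default_rng()
        intensity = rng.poisson(np.clip(intensity, 0, None) * photons) / photons
    return Hologram(intensity=intensity, wavelength=wavelength, fresnel_number=fresnel_number)


def simulate_hologram_from_projection(
    density_proj: np.ndarray,
    constants: OpticalConstants,
    wavelength: float,
    fresnel_number: float,
    pad_to: int | tuple[int, int] | None = None,
) -> Hologram:
    """Full-propagation hologram from a projected electron density map."""
    density_proj = np.asarray(density_proj, dtype=float)
    if pad_to is not None:
        if np.isscalar(pad_to):
            pad_to = (int(pad_to), int(pad_to))
        density_proj = embed(density_proj, pad_to, fill=0.0)
    tau = exit_wave_from_projection(density_proj, constants, wavelength)
    psi = fresnel_propagate(tau, fresnel_number)
    return Hologram(intensity=psi.intensity, wavelength=wavelength, fresnel_number=fresnel_number)


def linear_hologram_model(
    density_proj: np.ndarray,
    wavelength: float,
    fresnel_number: float,
    cprime: float,
) -> Hologram:
    """Weak-object (linear CTF) hologram of a homogeneous object.

    ``I = 1 - 2 Re F^-1[(lambda^3 C' cos chi + lambda sin chi) F[r0 D]]``
    with ``D`` the projected electron density in electrons/nm^2.  Serves as
    the analytically invertible forward model for the CTF retrieval.
    """
    d_r0 = R0_NM * np.asarray(density_proj, dtype=float)
    chi = chirp_phase(d_r0.shape, fresnel_number)
    kernel = wavelength**3 * cprime * np.cos(chi) + wavelength * np.sin(chi)
    intensity = 1.0 - 2.0 * np.real(np.fft.ifft2(kernel * np.fft.fft2(d_r0)))
    return Hologram(intensity=intensity, wavelength=wavelength, fresnel_number=fresnel_number)
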