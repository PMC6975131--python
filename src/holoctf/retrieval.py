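"""Single- and multi-energy CTF phase retrieval to projected electron density.

For a weak, homogeneous object the Fourier spectrum of each flat-field
corrected hologram ``I_i`` is linearly related to the spectrum of the
projected electron density ``D`` through the contrast transfer function

    ``k_i(nu) = lambda_i sin(chi_i) + lambda_i^3 C' cos(chi_i)``,
    ``chi_i = pi |nu|^2 / F_i``.

The least-squares one-step inversion over all energy channels is

    ``D = F^-1[ -sum_i F[I_i - 1] k_i / (sum_i 2 k_i^2 + alpha(nu)) ] / r0``

with a radially symmetric regularization ``alpha`` that is zero below the
first maximum of the mean-energy CTF and a small constant (default 1e-4)
above it.  The cosine term keeps the denominator away from zero at DC, so
low frequencies need no regularization; ``alpha`` only guards the
oscillatory zero crossings at higher frequency.  Because the channels share
one geometry, no registration or interpolation between them is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import erf

from .constants import R0_NM
from .wave_optics import Hologram, chirp_phase, frequency_sq

__all__ = [
    "RetrievalConfig",
    "ProjectionMap",
    "ctf_kernel",
    "mean_channel",
    "regularization_alpha",
    "reconstruct_multiE",
    "density_from_projection",
]


@dataclass(frozen=True)
class RetrievalConfig:
    """Channels (wavelength nm, Fresnel number), the coupling ``C'`` in
    1/nm^2, and the regularization amplitude.

    ``mean_wavelength_rule`` fixes how the mean wavelength for the alpha
    cutoff is formed from the channels: from the arithmetic mean photon
    energy (default) or the arithmetic mean wavelength.
    ``alpha_transition`` > 0 replaces the hard step by an erf ramp of that
    radial width (cycles/pixel).
    """

    channels: tuple[tuple[float, float], ...]
    cprime: float
    alpha_amplitude: float = 1e-4
    mean_wavelength_rule: Literal["mean_energy", "mean_wavelength"] = "mean_energy"
    alpha_transition: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple((float(l), float(f)) for l, f in self.channels))
        if not self.channels:
            raise ValueError("need at least one channel")
        for lam, fr in self.channels:
            if lam <= 0 or fr <= 0:
                raise ValueError("wavelengths and Fresnel numbers must be positive")
        if self.alpha_amplitude < 0:
            raise ValueError("alpha_amplitude must be non-negative")


@dataclass
class ProjectionMap:
    """Retrieved projected electron density ``D`` in electrons/nm^2."""

    D: np.ndarray
    pixel_eff: float | None = None  # nm

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if not np.all(np.isfinite(self.D)):
            raise ValueError("projection map must be finite")


def ctf_kernel(
    wavelength: float, fresnel_number: float, cprime: float, shape: tuple[int, int]
) -> np.ndarray:
    """CTF kernel ``lambda sin(chi) + lambda^3 C' cos(chi)`` on the FFT grid."""
    chi = chirp_phase(shape, fresnel_number)
    return wavelength * np.sin(chi) + wavelength**3 * cprime * np.cos(chi)


def mean_channel(config: RetrievalConfig) -> tuple[float, float]:
    """Mean-energy (or mean-wavelength) channel ``(lambda_bar, F_bar)``.

    ``F_bar`` is taken consistently with a fixed geometry, for which
    ``F * lambda`` is constant across channels: ``F_bar = mean(F_i
    lambda_i) / lambda_bar``.  Reduces to the single channel when only one
    is configured.
    """
    lams = np.array([c[0] for c in config.channels])
    frs = np.array([c[1] for c in config.channels])
    if config.mean_wavelength_rule == "mean_energy":
        lam_bar = 1.0 / np.mean(1.0 / lams)  # energy ~ 1/lambda
    else:
        lam_bar = float(np.mean(lams))
    f_bar = float(np.mean(frs * lams) / lam_bar)
    return float(lam_bar), f_bar


def alpha_cutoff_frequency(config: RetrievalConfig) -> float:
    """Radial frequency of the first CTF maximum of the mean-energy kernel.

    The first maximum of ``lambda sin chi + lambda^3 C' cos chi`` beyond DC
    sits at ``chi_1 = arctan(1 / (lambda_bar^2 C'))``, i.e.
    ``nu_1 = sqrt(chi_1 F_bar / pi)``.
    """
    lam_bar, f_bar = mean_channel(config)
    chi1 = math.atan2(1.0, lam_bar**2 * config.cprime)
    return math.sqrt(chi1 * f_bar / math.pi)


def regularization_alpha(shape: tuple[int, int], config: RetrievalConfig) -> np.ndarray:
    """Radially symmetric step regularization on the FFT grid.

    Zero inside the first maximum of the mean-energy CTF, the configured
    amplitude outside; optionally smoothed by an erf ramp.
    """
    nu = np.sqrt(frequency_sq(shape))
    nu1 = alpha_cutoff_frequency(config)
    if config.alpha_transition > 0:
        ramp = 0.5 * (1.0 + erf((nu - nu1) / (config.alpha_transition * math.sqrt(2.0))))
        return config.alpha_amplitude * ramp
    return np.where(nu >= nu1, config.alpha_amplitude, 0.0)


def reconstruct_multiE(
    holograms: Sequence[Hologram], config: RetrievalConfig
) -> ProjectionMap:
    """Invert one or more holograms to the projected electron density.

    Channels pair one-to-one with holograms in order; all holograms must
    share the grid shape.  With a single channel and ``alpha_amplitude = 0``
    this reduces algebraically to the plain single-energy CTF inversion.
    """
    if len(holograms) != len(config.channels):
        raise ValueError(
            f"{len(holograms)} holograms but {len(config.channels)} channels configured"
        )
    shape = holograms[0].intensity.shape
    for h in holograms:
        if h.intensity.shape != shape:
            raise ValueError("all holograms must share the same grid shape")
    numerator = np.zeros(shape, dtype=complex)
    denominator = regularization_alpha(shape, config)
    for holo, (lam, fr) in zip(holograms, config.channels):
        kernel = ctf_kernel(lam, fr, config.cprime, shape)
        numerator -= np.fft.fft2(holo.intensity - 1.0) * kernel
        denominator = denominator + 2.0 * kernel**2
    d_r0 = np.real(np.fft.ifft2(numerator / denominator))
    pixel = next((h.pixel_eff for h in holograms if h.pixel_eff is not None), None)
    return ProjectionMap(D=d_r0 / R0_NM, pixel_eff=pixel)


def density_from_projection(
    projection: ProjectionMap,
    thickness: np.ndarray,
    window: int = 40,
    stat: Literal["volume", "pixelwise"] = "volume",
) -> float:
    """Average electron density (electrons/nm^3) over a centered window.

    The retrieved projected density is divided by the known projected
    thickness (nm) over the centered ``window x window`` region, which must
    lie entirely on the object support.  ``stat="volume"`` (default) returns
    the physical volume average, total electrons over total column volume,
    ``sum(D) / sum(t)``; ``stat="pixelwise"`` returns the mean of the
    per-pixel ratios ``D/t`` (sensitive to thin pixels, where retrieval
    blur inflates the ratio).
    """
    thickness = np.asarray(thickness, dtype=float)
    if thickness.shape != projection.D.shape:
        raise ValueError("thickness map and projection must share shape")
    ny, nx = thickness.shape
    if window > min(ny, nx):
        raise ValueError("window larger than the map")
    oy, ox = (ny - window) // 2, (nx - window) // 2
    t_win = thickness[oy : oy + window, ox : ox + window]
    d_win = projection.D[oy : oy + window, ox : ox + window]
    if np.any(t_win <= 0):
        raise ValueError("projected thickness must be positive over the evaluation window")
    if stat == "volume":
        return float(d_win.sum() / t_win.sum())
    if stat == "pixelwise":
        return float(np.mean(d_win / t_win))
    raise ValueError("stat must be 'volume' or 'pixelwise'")
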