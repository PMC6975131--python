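"""Cone-beam geometry, the Fresnel scaling theorem, and Fresnel numbers.

A point-source (cone-beam) hologram recorded with source-sample distance
``z01`` and sample-detector distance ``z12`` is, by the Fresnel scaling
theorem, equivalent to a parallel-beam hologram at the effective distance
``z_eff = z12 / M`` sampled with the demagnified pixel ``d_eff = d / M``,
where ``M = (z01 + z12) / z01`` is the geometric magnification.

The dimensionless Fresnel number ``F = a^2 / (Delta * lambda)`` for a
resolution element ``a`` (here one effective pixel), propagation distance
``Delta`` and wavelength ``lambda`` fixes the fringe regime and the CTF
zero positions; it is the only geometry input the retrieval kernels need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .constants import NM_PER_MM, NM_PER_UM, wavelength_nm

__all__ = [
    "ConeBeamGeometry",
    "EffectiveGeometry",
    "effective_geometry",
    "fresnel_number",
    "fresnel_numbers",
]


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Source-sample distance ``z01`` (mm), sample-detector distance
    ``z12`` (mm), and physical detector pixel pitch (um)."""

    z01_mm: float
    z12_mm: float
    pixel_um: float

    def __post_init__(self) -> None:
        if self.z01_mm <= 0:
            raise ValueError("z01 must be positive")
        if self.z12_mm < 0:
            raise ValueError("z12 must be non-negative")
        if self.pixel_um <= 0:
            raise ValueError("pixel pitch must be positive")


@dataclass(frozen=True)
class EffectiveGeometry:
    """Parallel-beam equivalent of a cone-beam recording."""

    magnification: float
    z_eff_mm: float
    pixel_eff_nm: float

    @classmethod
    def from_magnification(cls, magnification: float, z12_mm: float, pixel_um: float) -> "EffectiveGeometry":
        """Effective geometry from an explicitly given magnification.

        Useful when a published magnification is to be used verbatim rather
        than recomputed from distances.
        """
        if magnification < 1:
            raise ValueError("magnification must be >= 1")
        return cls(
            magnification=magnification,
            z_eff_mm=z12_mm / magnification,
            pixel_eff_nm=pixel_um * NM_PER_UM / magnification,
        )


def effective_geometry(geom: ConeBeamGeometry) -> EffectiveGeometry:
    """Apply the Fresnel scaling theorem: M = (z01+z12)/z01, z_eff = z12/M,
    d_eff = d/M."""
    magnification = (geom.z01_mm + geom.z12_mm) / geom.z01_mm
    return EffectiveGeometry.from_magnification(magnification, geom.z12_mm, geom.pixel_um)


def fresnel_number(a_nm: float, distance_mm: float, wavelength: float) -> float:
    """Fresnel number ``F = a^2 / (Delta lambda)`` (all lengths converted to nm)."""
    if a_nm <= 0 or distance_mm <= 0 or wavelength <= 0:
        raise ValueError("resolution element, distance and wavelength must be positive")
    return a_nm**2 / (distance_mm * NM_PER_MM * wavelength)


def fresnel_numbers(eff: EffectiveGeometry, energies_kev: Sequence[float]) -> list[float]:
    """Per-pixel Fresnel numbers of the effective geometry for a list of
    photon energies (keV)."""
    return [fresnel_number(eff.pixel_eff_nm, eff.z_eff_mm, wavelength_nm(e)) for e in energies_kev]
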