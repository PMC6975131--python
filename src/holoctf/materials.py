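"""Materials, optical constants, and wavelength-scaling laws.

A hard X-ray refractive index is written ``n = 1 - delta + i*beta``.  Far
from absorption edges the decrement follows ``delta = lambda^2 r0 rho_e /
(2 pi)`` with ``rho_e`` the electron density, while the absorption index of
a light material scales as ``beta ~ lambda^4`` (equivalently the linear
attenuation coefficient ``mu = 4 pi beta / lambda ~ lambda^3``).

For a homogeneous (single-material) object the ratio ``C = beta/delta`` is
spatially constant, and the wavelength-normalised coupling

    ``C' = beta_r / (delta_r * lambda_r^2)``   [1/nm^2]

is the single parameter entering the CTF retrieval kernels; under the
scaling laws above it is independent of the reference wavelength chosen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .constants import AVOGADRO, R0_NM

__all__ = [
    "Material",
    "OpticalConstants",
    "parse_formula",
    "electron_density",
    "delta_from_density",
    "density_from_delta",
    "beta_rescaled",
    "rescale_constants",
    "attenuation_coefficient",
    "cprime",
    "mix_constants",
    "constants_from_material",
]

# Standard atomic weights (g/mol) and atomic numbers for elements common in
# soft matter and embedding media.
_ELEMENTS: dict[str, tuple[float, int]] = {
    "H": (1.008, 1),
    "He": (4.0026, 2),
    "Li": (6.94, 3),
    "B": (10.81, 5),
    "C": (12.011, 6),
    "N": (14.007, 7),
    "O": (15.999, 8),
    "F": (18.998, 9),
    "Na": (22.990, 11),
    "Mg": (24.305, 12),
    "Al": (26.982, 13),
    "Si": (28.085, 14),
    "P": (30.974, 15),
    "S": (32.06, 16),
    "Cl": (35.45, 17),
    "K": (39.098, 19),
    "Ca": (40.078, 20),
    "Mn": (54.938, 25),
    "Fe": (55.845, 26),
    "Cu": (63.546, 29),
    "Zn": (65.38, 30),
    "Br": (79.904, 35),
    "I": (126.904, 53),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula like ``"C30H62"``.

    Repeated element symbols accumulate.  Unknown symbols raise ``KeyError``.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        pos = match.end()
        symbol, digits = match.groups()
        if symbol not in _ELEMENTS:
            raise KeyError(f"unknown element symbol {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Material:
    """A chemical compound with a mass density.

    Parameters
    ----------
    name : str
    formula : str or mapping
        Molecular formula, e.g. ``"C30H62"`` or ``{"C": 30, "H": 62}``.
    mass_density : float
        Mass density in g/cm^3.
    """

    name: str
    formula: Mapping[str, int] | str
    mass_density: float

    def __post_init__(self) -> None:
        counts = parse_formula(self.formula) if isinstance(self.formula, str) else dict(self.formula)
        for sym, n in counts.items():
            if sym not in _ELEMENTS:
                raise KeyError(f"unknown element symbol {sym!r}")
            if n < 1:
                raise ValueError(f"element count must be >= 1, got {sym}={n}")
        if self.mass_density <= 0:
            raise ValueError("mass_density must be positive")
        object.__setattr__(self, "formula", counts)

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol."""
        return sum(_ELEMENTS[s][0] * n for s, n in self.formula.items())

    @property
    def electrons_per_molecule(self) -> int:
        return sum(_ELEMENTS[s][1] * n for s, n in self.formula.items())


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive-index decrements (delta, beta) at a reference wavelength.

    ``delta`` rescales as ``lambda^2`` and ``beta`` as ``lambda^4`` (valid
    far from absorption edges).
    """

    delta: float
    beta: float
    wavelength_ref: float  # nm

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.wavelength_ref <= 0:
            raise ValueError("wavelength_ref must be positive")


def electron_density(material: Material) -> float:
    """Electron density of a compound in electrons/nm^3.

    ``rho_e = Na * rho_m / M * Ne`` with Avogadro's number ``Na``, mass
    density ``rho_m``, molar mass ``M`` and electrons per molecule ``Ne``.
    """
    # g/cm^3 -> g/nm^3 carries 1e-21
    return AVOGADRO * material.mass_density * 1e-21 / material.molar_mass * material.electrons_per_molecule


def delta_from_density(rho_e: float, wavelength: float) -> float:
    """Refractive decrement ``delta = lambda^2 r0 rho_e / (2 pi)``.

    ``rho_e`` in electrons/nm^3, ``wavelength`` in nm.
    """
    import math

    if rho_e < 0:
        raise ValueError("electron density must be non-negative")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength**2 * R0_NM * rho_e / (2.0 * math.pi)


def density_from_delta(delta: float, wavelength: float) -> float:
    """Inverse of :func:`delta_from_density`; returns electrons/nm^3."""
    import math

    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * math.pi * delta / (wavelength**2 * R0_NM)


def beta_rescaled(constants: OpticalConstants, wavelength: float) -> float:
    """Absorption index at another wavelength: ``beta_r (lambda/lambda_r)^4``."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return constants.beta * (wavelength / constants.wavelength_ref) ** 4


def delta_rescaled(constants: OpticalConstants, wavelength: float) -> float:
    """Phase decrement at another wavelength: ``delta_r (lambda/lambda_r)^2``."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return constants.delta * (wavelength / constants.wavelength_ref) ** 2


def rescale_constants(constants: OpticalConstants, wavelength: float) -> OpticalConstants:
    """Optical constants re-referenced to a new wavelength via the scaling laws."""
    return OpticalConstants(
        delta=delta_rescaled(constants, wavelength),
        beta=beta_rescaled(constants, wavelength),
        wavelength_ref=wavelength,
    )


def attenuation_coefficient(beta: float, wavelength: float) -> float:
    """Linear attenuation coefficient ``mu = 4 pi beta / lambda`` in 1/nm."""
    import math

    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 4.0 * math.pi * beta / wavelength


def cprime(constants: OpticalConstants) -> float:
    """Homogeneous-object coupling ``C' = beta_r / (delta_r lambda_r^2)`` in 1/nm^2."""
    if constants.delta == 0:
        raise ZeroDivisionError("C' undefined for delta = 0 (pure absorber has no phase scale)")
    return constants.beta / (constants.delta * constants.wavelength_ref**2)


def mix_constants(
    components: Sequence[OpticalConstants], fractions: Sequence[float]
) -> OpticalConstants:
    """Volume-fraction linear combination of optical constants.

    All components must share the reference wavelength; fractions must be
    non-negative and sum to one (tolerance 1e-9).
    """
    if len(components) != len(fractions):
        raise ValueError("components and fractions must have equal length")
    if not components:
        raise ValueError("need at least one component")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    lam = components[0].wavelength_ref
    for c in components[1:]:
        if c.wavelength_ref != lam:
            raise ValueError("all components must share wavelength_ref")
    delta = sum(f * c.delta for c, f in zip(components, fractions))
    beta = sum(f * c.beta for c, f in zip(components, fractions))
    return OpticalConstants(delta=delta, beta=beta, wavelength_ref=lam)


def constants_from_material(
    material: Material, wavelength: float, beta: float = 0.0
) -> OpticalConstants:
    """Optical constants with ``delta`` derived from the stoichiometric
    electron density; ``beta`` must be supplied (tabulated) or defaults to 0.
    """
    return OpticalConstants(
        delta=delta_from_density(electron_density(material), wavelength),
        beta=beta,
        wavelength_ref=wavelength,
    )
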