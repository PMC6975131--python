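"""Physical constants and unit conventions.

All internal lengths are nanometers; photon energies cross the public
interface in keV.  Conversions:

* ``wavelength_nm = HC_EV_NM / (1000 * energy_keV)``
* 1 fL = 1e9 nm^3; 1 mm = 1e6 nm; 1 um = 1e3 nm
"""

#: Classical electron radius in nm.
R0_NM = 2.8179403e-6

#: Photon energy-wavelength product, eV * nm.
HC_EV_NM = 1239.842

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

NM_PER_MM = 1.0e6
NM_PER_UM = 1.0e3
NM3_PER_FL = 1.0e9


def wavelength_nm(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_EV_NM / (energy_kev * 1000.0)


def energy_kev(wavelength: float) -> float:
    """Photon energy in keV for a wavelength in nm."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / (wavelength * 1000.0)
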