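"""Loading of material / optical-constant tables from YAML.

The bundled table (``holoctf/data/materials.yaml``) carries snapshot
delta/beta values for water, hemoglobin and paraffin at a 7.5 keV reference;
user configs with the same layout override it.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .materials import Material, OpticalConstants, mix_constants

__all__ = ["load_material_table", "blood_constants", "material_entry"]


def _bundled_text() -> str:
    return resources.files("holoctf.data").joinpath("materials.yaml").read_text()


def load_material_table(path: str | Path | None = None) -> dict:
    """Load a material table; ``None`` loads the bundled snapshot.

    Returns a dict with ``materials`` (name -> (Material, OpticalConstants))
    and ``mixtures`` (name -> (OpticalConstants, components, fractions)).
    """
    raw = yaml.safe_load(Path(path).read_text() if path is not None else _bundled_text())
    materials: dict[str, tuple[Material, OpticalConstants]] = {}
    for name, entry in raw.get("materials", {}).items():
        mat = Material(name=name, formula=entry["formula"], mass_density=entry["mass_density"])
        oc = OpticalConstants(
            delta=float(entry["delta"]),
            beta=float(entry["beta"]),
            wavelength_ref=float(entry["wavelength_ref"]),
        )
        materials[name] = (mat, oc)
    mixtures: dict[str, tuple[OpticalConstants, list[str], list[float]]] = {}
    for name, entry in raw.get("mixtures", {}).items():
        comps = entry["components"]
        fracs = [float(f) for f in entry["fractions"]]
        missing = [c for c in comps if c not in materials]
        if missing:
            raise KeyError(f"mixture {name!r} references unknown materials {missing}")
        oc = mix_constants([materials[c][1] for c in comps], fracs)
        mixtures[name] = (oc, comps, fracs)
    return {"materials": materials, "mixtures": mixtures}


def material_entry(name: str, path: str | Path | None = None) -> tuple[Material, OpticalConstants]:
    table = load_material_table(path)
    try:
        return table["materials"][name]
    except KeyError:
        raise KeyError(f"material {name!r} not in table; have {sorted(table['materials'])}") from None


def blood_constants(path: str | Path | None = None) -> OpticalConstants:
    """Optical constants of the water/hemoglobin blood model (67.5 / 32.5 vol%)."""
    return load_material_table(path)["mixtures"]["blood"][0]
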