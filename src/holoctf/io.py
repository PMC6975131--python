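"""HDF5 / TIFF containers for holograms, projections, sinograms and volumes.

Dataset layout (HDF5):

* holograms: ``/intensity`` (n, y, x), ``/wavelength_nm`` (n,),
  ``/fresnel_number`` (n,), root attr ``pixel_eff_nm`` (optional)
* projection: ``/D`` (y, x), attr ``pixel_eff_nm``
* sinogram: ``/data`` (angle, row, col), ``/angles_deg``, attr ``pixel_eff_nm``
* volume: ``/density`` (z, y, x), attr ``voxel_nm``
* thickness phantom: ``/thickness`` (y, x), attrs ``pixel_eff_nm``, ``seed``

Round trips are bit-exact; TIFF export is 32-bit float, one page per image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile

from .retrieval import ProjectionMap
from .tomo import SinogramStack, VolumeMap
from .wave_optics import Hologram

__all__ = [
    "save_holograms",
    "load_holograms",
    "save_projection",
    "load_projection",
    "save_sinogram",
    "load_sinogram",
    "save_volume",
    "load_volume",
    "save_thickness",
    "load_thickness",
    "export_tiff",
]


def _require_attr(obj, name: str):
    if name not in obj.attrs:
        raise KeyError(f"missing required attribute {name!r} in {obj.file.filename}")
    return obj.attrs[name]


def _require_dataset(f: h5py.File, name: str) -> np.ndarray:
    if name not in f:
        raise KeyError(f"missing required dataset {name!r} in {f.filename}")
    return f[name][()]


def save_holograms(path: str | Path, holograms: Sequence[Hologram]) -> None:
    holograms = list(holograms)
    if not holograms:
        raise ValueError("nothing to save")
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=np.stack([h.intensity for h in holograms]))
        f.create_dataset("wavelength_nm", data=np.array([h.wavelength for h in holograms]))
        f.create_dataset("fresnel_number", data=np.array([h.fresnel_number for h in holograms]))
        pixel = holograms[0].pixel_eff
        if pixel is not None:
            f.attrs["pixel_eff_nm"] = pixel


def load_holograms(path: str | Path) -> list[Hologram]:
    with h5py.File(path, "r") as f:
        intensity = _require_dataset(f, "intensity")
        wavelengths = _require_dataset(f, "wavelength_nm")
        fresnels = _require_dataset(f, "fresnel_number")
        pixel = f.attrs.get("pixel_eff_nm")
    return [
        Hologram(
            intensity=i,
            wavelength=float(w),
            fresnel_number=float(fr),
            pixel_eff=None if pixel is None else float(pixel),
        )
        for i, w, fr in zip(intensity, wavelengths, fresnels)
    ]


def save_projection(path: str | Path, projection: ProjectionMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("D", data=projection.D)
        if projection.pixel_eff is not None:
            f.attrs["pixel_eff_nm"] = projection.pixel_eff


def load_projection(path: str | Path) -> ProjectionMap:
    with h5py.File(path, "r") as f:
        d = _require_dataset(f, "D")
        pixel = f.attrs.get("pixel_eff_nm")
    return ProjectionMap(D=d, pixel_eff=None if pixel is None else float(pixel))


def save_sinogram(path: str | Path, stack: SinogramStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=stack.data)
        f.create_dataset("angles_deg", data=stack.angles)
        if stack.pixel_eff is not None:
            f.attrs["pixel_eff_nm"] = stack.pixel_eff


def load_sinogram(path: str | Path) -> SinogramStack:
    with h5py.File(path, "r") as f:
        data = _require_dataset(f, "data")
        angles = _require_dataset(f, "angles_deg")
        pixel = f.attrs.get("pixel_eff_nm")
    return SinogramStack(data=data, angles=angles, pixel_eff=None if pixel is None else float(pixel))


def save_volume(path: str | Path, volume: VolumeMap, labels: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("density", data=volume.density)
        if labels is not None:
            f.create_dataset("labels", data=labels)
        f.attrs["voxel_nm"] = volume.voxel


def load_volume(path: str | Path) -> VolumeMap:
    with h5py.File(path, "r") as f:
        density = _require_dataset(f, "density")
        voxel = float(_require_attr(f, "voxel_nm"))
    return VolumeMap(density=density, voxel=voxel)


def save_thickness(path: str | Path, thickness: np.ndarray, pixel_eff: float, seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("thickness", data=np.asarray(thickness, dtype=float))
        f.attrs["pixel_eff_nm"] = pixel_eff
        if seed is not None:
            f.attrs["seed"] = seed


def load_thickness(path: str | Path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        thickness = _require_dataset(f, "thickness")
        pixel = float(_require_attr(f, "pixel_eff_nm"))
    return thickness, pixel


def export_tiff(path: str | Path, images: np.ndarray) -> None:
    """Write a 2-D image or 3-D stack as 32-bit float TIFF (one page per image)."""
    tifffile.imwrite(path, np.asarray(images, dtype=np.float32))
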