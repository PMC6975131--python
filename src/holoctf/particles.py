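"""Threshold-based particle segmentation and per-particle statistics.

Segmentation binarizes the reconstructed density at a threshold, separates
touching particles by repeated erosion, labels connected components
(26-connectivity), grows each component back by constrained dilation inside
the original mask, and discards small components.  Statistics report each
particle's volume (fL) and its mean excess electron density relative to a
reference (the embedding medium).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .constants import NM3_PER_FL
from .tomo import VolumeMap

__all__ = ["LabelVolume", "ParticleStats", "segment_particles", "particle_stats"]

# 6-connected cross for morphology; 26-connectivity for labeling.
_CROSS = ndimage.generate_binary_structure(3, 1)
_FULL = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LabelVolume:
    """Labelled particles: 0 = background, labels consecutive from 1."""

    labels: np.ndarray
    voxel: float  # nm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")

    @property
    def n_particles(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ParticleStats:
    label: int
    volume_fl: float
    mean_excess_density: float  # electrons/nm^3 relative to the reference


def segment_particles(
    volume: VolumeMap,
    threshold: float,
    n_erode: int = 2,
    n_dilate: int = 2,
    min_voxels: int = 50,
) -> LabelVolume:
    """Threshold / erode / label / constrained-dilate / size-filter.

    Dilation never leaves the original thresholded mask and never merges
    two labels (ties at a shared boundary go to the larger label value).
    An empty result is valid.
    """
    if n_erode < 0 or n_dilate < 0:
        raise ValueError("erosion/dilation counts must be non-negative")
    mask = volume.density > threshold
    core = mask
    for _ in range(n_erode):
        core = ndimage.binary_erosion(core, structure=_CROSS)
    labels, _ = ndimage.label(core, structure=_FULL)
    for _ in range(n_dilate):
        grown = ndimage.grey_dilation(labels, footprint=_CROSS)
        labels = np.where(mask & (labels == 0), grown, labels)
    # size filter + consecutive relabeling
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_voxels]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabelVolume(labels=remap[labels], voxel=volume.voxel)


def particle_stats(
    labels: LabelVolume, volume: VolumeMap, reference_density: float
) -> list[ParticleStats]:
    """Volume and mean excess density of every labelled particle."""
    if labels.labels.shape != volume.density.shape:
        raise ValueError("label grid and density volume must share shape")
    out = []
    for lab in range(1, labels.n_particles + 1):
        sel = labels.labels == lab
        count = int(sel.sum())
        if count == 0:
            raise ValueError(f"label {lab} absent from the grid")
        out.append(
            ParticleStats(
                label=lab,
                volume_fl=count * labels.voxel**3 / NM3_PER_FL,
                mean_excess_density=float(volume.density[sel].mean()) - reference_density,
            )
        )
    return out
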