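"""Seeded synthetic specimens.

Two generators are provided:

* :func:`make_particle_phantom` -- a smooth, blob-like projected-thickness
  map emulating a single cell-like conglomerate, rescaled so that its
  volume, maximum and mean projected thickness hit requested targets
  (defaults: 19.8 fL, 3.8 um max, 1.2 um mean on a 140 px grid at 38 nm).
  The silhouette is random per seed; only the three summary metrics are
  controlled.

* :func:`make_tomo_phantom` -- a 3-D cylinder of embedding medium
  (paraffin-like) containing non-overlapping ellipsoidal particles of
  elevated density, with ground-truth labels, emulating red blood cells in
  an embedded tissue plug.  Parallel-beam projections of this phantom are
  available in closed form (:func:`project_phantom`), which doubles as an
  independent oracle for voxel-space projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .constants import NM3_PER_FL, NM_PER_UM

__all__ = [
    "PhantomSpec2D",
    "PhantomMetrics",
    "make_particle_phantom",
    "phantom_metrics",
    "TomoParticle",
    "PhantomVolume3D",
    "make_tomo_phantom",
    "project_phantom",
    "project_volume",
]


@dataclass(frozen=True)
class PhantomSpec2D:
    """Targets for the projected single-particle phantom."""

    target_volume_fl: float = 19.8
    max_thickness_um: float = 3.8
    mean_thickness_um: float = 1.2
    grid: int = 140
    pixel_eff_nm: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_volume_fl <= 0:
            raise ValueError("target volume must be positive")
        if self.mean_thickness_um > self.max_thickness_um:
            raise ValueError("mean thickness cannot exceed max thickness")


@dataclass(frozen=True)
class PhantomMetrics:
    volume_fl: float
    max_thickness_um: float
    mean_thickness_um: float  # over the support; NaN for an empty map


def phantom_metrics(thickness_nm: np.ndarray, pixel_eff_nm: float) -> PhantomMetrics:
    """Volume, max and support-mean projected thickness of a thickness map."""
    t = np.asarray(thickness_nm, dtype=float)
    area = pixel_eff_nm**2
    volume_fl = float(t.sum() * area / NM3_PER_FL)
    support = t > 0
    if not support.any():
        return PhantomMetrics(0.0, 0.0, float("nan"))
    return PhantomMetrics(
        volume_fl=volume_fl,
        max_thickness_um=float(t.max() / NM_PER_UM),
        mean_thickness_um=float(t[support].mean() / NM_PER_UM),
    )


def _blob_field(spec: PhantomSpec2D, rng: np.random.Generator) -> np.ndarray:
    """Smooth non-negative field emulating the projection of a cell-like
    conglomerate: the pointwise maximum of twelve overlapping projected
    ellipsoids (cells) scattered around the grid center, Gaussian-smoothed.
    The union of mid-sized lobes yields an irregular outline with a thick
    central body, as in the projection of a clump of cells."""
    n = spec.grid
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    center = (n - 1) / 2.0
    s = np.zeros((n, n))
    for _ in range(12):
        radius = rng.uniform(0.0, 0.32) * n
        phi = rng.uniform(0, 2 * np.pi)
        cy = center + radius * np.sin(phi)
        cx = center + radius * np.cos(phi)
        a = rng.uniform(0.10, 0.22) * n
        b = rng.uniform(0.10, 0.22) * n
        theta = rng.uniform(0, np.pi)
        h = rng.uniform(0.5, 1.0)
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        s = np.maximum(s, h * np.sqrt(np.clip(1.0 - (u / a) ** 2 - (v / b) ** 2, 0.0, None)))
    return gaussian_filter(s, sigma=2.5)


def make_particle_phantom(spec: PhantomSpec2D) -> tuple[np.ndarray, PhantomMetrics]:
    """Generate a seeded thickness map (nm) hitting the spec's metrics.

    Construction: a random smooth blob field is thresholded at the quantile
    giving the support area implied by ``volume / mean_thickness``; the
    result is scaled to the maximum thickness and a power transform
    ``t -> t_max (t/t_max)^gamma`` (support- and max-preserving) sets the
    volume exactly.  Deterministic for a fixed seed.
    """
    n = spec.grid
    px_area = spec.pixel_eff_nm**2
    v_target = spec.target_volume_fl * NM3_PER_FL
    t_max = spec.max_thickness_um * NM_PER_UM
    t_mean = spec.mean_thickness_um * NM_PER_UM

    support_px = int(round(v_target / (t_mean * px_area)))
    if support_px > n * n:
        raise ValueError(
            "infeasible spec: required support area exceeds the grid "
            f"({support_px} px > {n * n} px); enlarge grid or mean thickness"
        )

    # A random lobe draw occasionally covers less area than the required
    # support; redraw deterministically (sub-streams of the seed) until
    # feasible so every seed yields a phantom.
    for attempt in range(64):
        rng = np.random.default_rng([spec.seed, attempt])
        s = _blob_field(spec, rng)
        positive = s[s > 0]
        if positive.size < support_px:
            continue
        threshold = np.partition(positive, positive.size - support_px)[
            positive.size - support_px
        ]
        t0 = np.clip(s - threshold, 0.0, None)
        if t0.max() <= 0:
            continue
        t0 *= t_max / t0.max()

        def volume_err(log_gamma: float) -> float:
            t = t_max * (t0 / t_max) ** np.exp(log_gamma)
            return float(t.sum() * px_area - v_target)

        lo, hi = np.log(0.02), np.log(50.0)
        if volume_err(lo) < 0 or volume_err(hi) > 0:
            continue
        log_gamma = brentq(volume_err, lo, hi, xtol=1e-12)
        thickness = t_max * (t0 / t_max) ** np.exp(log_gamma)
        return thickness, phantom_metrics(thickness, spec.pixel_eff_nm)
    raise RuntimeError(
        "could not realise the phantom spec after 64 draws; the requested "
        "volume/thickness combination is at the edge of feasibility"
    )


# ---------------------------------------------------------------------------
# 3-D multi-particle phantom


@dataclass(frozen=True)
class TomoParticle:
    """An axis-aligned-ish ellipsoid: center (z, y, x) and semi-axes
    (az, ay, ax), both in voxels; density contrast in electrons/nm^3."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]
    contrast: float
    label: int


@dataclass
class PhantomVolume3D:
    density: np.ndarray  # (nz, ny, nx), electrons/nm^3
    voxel: float  # nm
    labels: np.ndarray  # int, same shape
    background_density: float
    cylinder_radius: float  # voxels
    particles: list[TomoParticle] = field(default_factory=list)


def make_tomo_phantom(
    n_particles: int = 4,
    particle_volume_fl: float = 8.0,
    density_contrast: float = 55.0,
    cylinder_radius: float = 80.0,
    voxel: float = 38.0,
    grid: int = 256,
    nz: int | None = None,
    background_density: float = 310.25,
    seed: int = 0,
    max_tries: int = 2000,
) -> PhantomVolume3D:
    """Cylinder of embedding medium with ellipsoidal particles inside.

    The cylinder axis is z (the tomographic rotation axis); particles are
    random ellipsoids whose analytic volume matches ``particle_volume_fl``,
    placed by rejection sampling with non-overlapping bounding spheres.
    """
    rng = np.random.default_rng(seed)
    nz = grid if nz is None else nz
    ny = nx = grid
    # The tube may be wider than the grid (region-of-interest tomography, as
    # in a specimen plug larger than the field of view); particles are then
    # confined to the imaged interior.
    placement_radius = min(cylinder_radius, 0.85 * grid / 2.0)

    r_eq = (particle_volume_fl * NM3_PER_FL * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) / voxel
    particles: list[TomoParticle] = []
    tries = 0
    while len(particles) < n_particles:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place all particles without overlap; "
                "use fewer or smaller particles or a larger cylinder"
            )
        ratios = rng.uniform(0.7, 1.3, size=3)
        ratios /= ratios.prod() ** (1.0 / 3.0)
        semi = tuple(r_eq * r for r in ratios)  # (az, ay, ax), voxels
        r_bound = max(semi)
        margin = r_bound + 2.0
        if margin >= nz - margin or margin >= placement_radius:
            raise ValueError(
                f"particles of ~{r_eq:.1f} voxel radius do not fit the "
                "cylinder/height; use smaller particles or a larger grid"
            )
        cz = rng.uniform(margin, nz - margin)
        rho = (placement_radius - margin) * np.sqrt(rng.uniform(0, 1))
        phi = rng.uniform(0, 2 * np.pi)
        cy = ny // 2 + rho * np.sin(phi)
        cx = nx // 2 + rho * np.cos(phi)
        ok = all(
            np.hypot(np.hypot(cz - p.center[0], cy - p.center[1]), cx - p.center[2])
            > r_bound + max(p.semiaxes) + 1.0
            for p in particles
        )
        if ok:
            particles.append(
                TomoParticle(
                    center=(cz, cy, cx),
                    semiaxes=semi,
                    contrast=density_contrast,
                    label=len(particles) + 1,
                )
            )

    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]
    # center at ny//2 to match the rotation center of the FBP backend
    cyl = ((yy - ny // 2) ** 2 + (xx - nx // 2) ** 2) <= cylinder_radius**2
    density = np.broadcast_to(
        np.where(cyl, background_density, 0.0), (nz, ny, nx)
    ).astype(float).copy()
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    for p in particles:
        az, ay, ax = p.semiaxes
        cz, cy, cx = p.center
        inside = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        density[inside] += p.contrast
        labels[inside] = p.label
    return PhantomVolume3D(
        density=density,
        voxel=voxel,
        labels=labels,
        background_density=background_density,
        cylinder_radius=cylinder_radius,
        particles=particles,
    )


def project_phantom(phantom: PhantomVolume3D, angle_deg: float) -> np.ndarray:
    """Closed-form parallel projection of the phantom at one angle.

    Rays run in the x-y plane; the detector coordinate s spans the x axis at
    angle 0 and the output is the projected electron density (electrons/nm^2)
    on an (nz, n_s) grid.  Cylinder and ellipsoid chord lengths are analytic,
    so this projector is exact up to the phantom's own parameterisation and
    serves as an oracle for voxel-space projection.
    """
    nz, ny, nx = phantom.density.shape
    n_s = nx
    theta = np.deg2rad(angle_deg)
    # Detector/ray axes follow the filtered-backprojection convention used
    # downstream (skimage iradon): s = x cos(theta) - y sin(theta).
    s_hat = np.array([np.cos(theta), -np.sin(theta)])  # detector axis (x, y)
    u_hat = np.array([np.sin(theta), np.cos(theta)])  # ray direction (x, y)
    s = np.arange(n_s, dtype=float) - n_s // 2

    chord_bg = 2.0 * np.sqrt(np.clip(phantom.cylinder_radius**2 - s**2, 0.0, None))
    proj = np.tile(chord_bg * phantom.background_density, (nz, 1))

    z = np.arange(nz)
    for p in phantom.particles:
        az, ay, ax = p.semiaxes
        cz, cy, cx = p.center
        inv2 = np.array([1.0 / ax**2, 1.0 / ay**2])  # x, y
        a = inv2[0] * u_hat[0] ** 2 + inv2[1] * u_hat[1] ** 2
        # ray origin in (x, y): s * s_hat; offset from the particle center
        dx = s * s_hat[0] - (cx - nx // 2)
        dy = s * s_hat[1] - (cy - ny // 2)
        b = inv2[0] * u_hat[0] * dx + inv2[1] * u_hat[1] * dy
        c_xy = inv2[0] * dx**2 + inv2[1] * dy**2
        dz2 = ((z[:, None] - cz) / az) ** 2
        disc = b[None, :] ** 2 - a * (c_xy[None, :] + dz2 - 1.0)
        proj += p.contrast * 2.0 * np.sqrt(np.clip(disc, 0.0, None)) / a
    return proj * phantom.voxel


def project_volume(density: np.ndarray, voxel: float, axis: int = 1) -> np.ndarray:
    """Voxel-sum parallel projection of a density volume along a grid axis,
    returning projected electron density in electrons/nm^2."""
    return np.asarray(density, dtype=float).sum(axis=axis) * voxel
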