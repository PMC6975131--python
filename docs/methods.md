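# Methods

## Physical model

The specimen is modeled as a homogeneous (single-material) weak object: the
refractive index is `n = 1 − δ + iβ` with `δ(λ) = λ² r0 ρe / 2π` and, far
from absorption edges, `β(λ) = β_r (λ/λ_r)⁴` (equivalently attenuation
`μ = 4πβ/λ ∝ λ³`). Homogeneity means the ratio `C = β/δ` is spatially
constant, so a single map — the projected electron density
`D(ξ⊥) = ∫ρe dz`, electrons/nm² — describes both phase and absorption:

    τ(ξ⊥, λ) = exp(−iλ·r0·D) · exp(−(λ³/λ_r²)·C·r0·D).

Under these two scaling laws the coupling `C′ = β_r/(δ_r λ_r²)` is
independent of the reference wavelength; the per-channel CTF kernels are
`k_i = λ_i sin χ_i + λ_i³ C′ cos χ_i` with `χ_i = π|ν|²/F_i`.

Units: all lengths are nm internally, photon energies keV at the interface
(`λ[nm] = 1.239842/E[keV]`), densities electrons/nm³, projected densities
electrons/nm², volumes fL (1 fL = 10⁹ nm³). `r0 = 2.8179403e-6 nm`.

## Numerical conventions

* Frequencies are cycles per effective pixel on the unshifted FFT grid (DC
  at index (0,0)); the propagator multiplies the spectrum by `exp(−iχ)`,
  `χ = π|ν|²/F`, which equals the standard `πλΔ|f|²` for physical frequency
  `f = ν/pixel`. The global piston phase is dropped. The propagator is
  exactly unitary and was verified against the closed-form Gaussian-beam
  width `σ_out² = σ² + (2πσF)⁻²`.
* Hologram simulation embeds the object centrally in a unit background
  before propagation. The simulation study pads the 140² phantom to 1024²
  (configurable; deviations at the evaluated central window change by well
  under 0.1 percentage points between 1024² and 3742²).
* The multi-energy inversion evaluates
  `D = F⁻¹[−Σ F[I_i−1] k_i / (Σ 2k_i² + α)]/r0` with all channels on one
  shared grid — no registration or rescaling between channels, which is the
  point of energy variation at fixed geometry. At DC the denominator is
  `Σ 2(λ³C′)² > 0`, so no special-casing is needed; absolute offsets are
  only meaningful for untruncated objects.
* Regularization `α(ν)`: radially symmetric hard step, zero for
  `|ν| < ν₁` and `1e-4` beyond, where `ν₁ = √(χ₁ F̄/π)`,
  `χ₁ = arctan(1/(λ̄²C′))` is the first maximum of the mean-energy kernel.
  The mean channel uses the arithmetic mean photon energy (selectable to
  mean wavelength) and `F̄ = mean(F_i λ_i)/λ̄`, consistent with a fixed
  geometry where `F·λ` is constant. An erf-smoothed transition of
  configurable width is available; the hard step is the default.
* Optical constants are user-supplied snapshots (bundled YAML for water,
  hemoglobin, paraffin at a 7.5 keV reference) with the `λ²`/`λ⁴` rescaling
  built in; mixtures are volume-fraction linear combinations of δ and β
  with no density renormalization.

## Synthetic specimens and what they do (not) capture

**Projected particle phantom.** A conglomerate of twelve overlapping
projected ellipsoids ("cells") is thresholded at the quantile that yields
the support area implied by `volume/mean-thickness`, scaled to the target
maximum thickness, and power-transformed (`t → t_max(t/t_max)^γ`, support-
and maximum-preserving) so the volume is met exactly. Defaults target
19.8 fL, 3.8 µm maximum and 1.2 µm support-mean projected thickness on a
140² grid at 38 nm pixels; the blood model is 67.5% water / 32.5%
hemoglobin (C₂₉₃₂H₄₇₂₄N₈₂₈O₈₄₀S₈Fe₄, 1.335 g/cm³), ground-truth density
365.5 electrons/nm³ derived from the bundled δ. Draws that cannot cover the
required support are redrawn deterministically from sub-streams of the
seed, so every seed produces a phantom bit-reproducibly.

At these defaults the object is *not* strictly weak (peak phase
`λ·r0·ρe·t ≈ 0.65 rad`). The one-step CTF inversion then carries a
silhouette-dependent linearization error: on linear-model holograms the
joint inversion is exact to ~0.005% (and that test is part of the suite),
but on full Fresnel simulations the central-window density deviates by a
few tenths of a percent up to a few percent depending on the random
silhouette (joint seven-energy reconstruction: 0.07% at the default seed,
~0.02–2% typical across seeds, occasionally more). Single-energy
reconstructions additionally lose the bands near their CTF zeros and
deviate by about 1% (0.05–1.7% at the default seed). Passing tests
therefore demonstrate correct inversion and the multi-energy coverage
benefit, not that the weak-object approximation is harmless for arbitrary
strong specimens.

The central density is evaluated as the volume average `ΣD/Σt` over the
centered 40×40-pixel window (total electrons over total column volume); the
per-pixel mean of `D/t` ratios is available but diverges on thin pixels,
where retrieval blur dominates the ratio.

**3-D tube phantom.** Ellipsoidal particles (default four of 8 fL,
+55 electrons/nm³) in a paraffin-density tube whose radius (400 voxels)
exceeds the 256-pixel field of view — region-of-interest tomography, as in
practice for an embedded tissue plug. Projections are closed-form (cylinder
and ellipsoid chords), matching the voxel projector to ~1% and the
skimage radon/iradon conventions exactly (rotation center `n//2`,
`s = x cosθ − y sinθ`). Projections are extended by edge replication before
propagation so no artificial specimen/air boundary exists; an in-FOV tube
edge would be a strong-phase feature whose ringing corrupts the interior —
a condition the emulated experiment does not present. The phantom does not
model tissue texture, noise, partial coherence or detector blur.

## Pipeline choices

* Angular interpolation: linear, factor 2 (inserts midpoints, preserves
  original projections exactly).
* Truncation handling: each detector row extended with its edge value;
  128 px default in the loop (64 px default in the CLI for in-FOV data).
* Ring filter: wavelet–Fourier destriping (db9, 4 levels, Gaussian damping
  σ = 2 angle-frequency bins), applied per slice; it damps the vertical-
  detail bands at low angular frequency. Note that genuinely angle-constant
  specimen structure (a perfectly centered cylinder edge) is
  indistinguishable from a detector stripe and is damped too; for the
  nearly flat ROI backgrounds of the loop this is negligible.
* FBP: slice-wise `skimage.transform.iradon`, ramp filter default
  (hann-weighted ramp optional), parallel-beam in effective coordinates
  (Fresnel scaling already applied); the sinogram (electrons/nm²) is
  divided by the voxel size so the output is electrons/nm³ directly.
  Truncated reconstructions are shifted to a reference mean (the embedding
  medium), as absolute offsets are not recoverable from truncated data.
* Segmentation: binarize at a global threshold (background median plus half
  the expected contrast in the loop), separate touching particles by
  repeated 6-connected erosions, label with 26-connectivity, grow back by
  dilation confined to the original mask, discard components below a voxel
  count. Erosion/dilation counts default to 2 and are exposed.
* Per-particle statistics: volume = voxel count × voxel³; excess density =
  mean density over the label minus a reference (measured background
  median in the loop).

At the default loop scale (256³ voxels, 200 angles interpolated to 399,
three energies per angle; chosen to keep a single-core run under five
minutes) recovered particle volumes are within 0.2%, excess densities
within 7% and centroids within 0.1 voxel of ground truth.

## Known limitations

* One-step CTF inversion: no iterative refinement; strong objects keep a
  common-mode linearization error the energy diversity cannot remove (see
  above). Quantities measured as *contrasts* against a calibrated
  background (the tomography loop) are much less affected than absolute
  central densities.
* The `λ²`/`λ⁴` scaling ignores anomalous dispersion near absorption
  edges; per-element dispersion tables are out of scope.
* Cone-beam effects are handled solely through the Fresnel scaling theorem
  (no source-size blur, detector PSF or partial coherence).
* The wavelet destriper assumes stripes are angle-constant and specimen
  structure is not; centered cylindrically symmetric objects violate this.
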