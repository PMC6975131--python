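"""Sinogram conditioning and filtered backprojection."""

import numpy as np
import pytest

from holoctf.phantoms import make_tomo_phantom, project_phantom
from holoctf.tomo import (
    SinogramStack,
    VolumeMap,
    angular_interpolate,
    extend_truncated,
    fbp_reconstruct,
    intensity_projection,
    remove_rings_wavelet,
    shift_mean,
)


def disk_sinogram(n_angles=400, grid=128, radius=40.0):
    ph = make_tomo_phantom(n_particles=0, cylinder_radius=radius, grid=grid, nz=2, seed=0)
    angles = np.linspace(0, 180, n_angles, endpoint=False)
    data = np.stack([project_phantom(ph, a) for a in angles])
    return SinogramStack(data, angles, pixel_eff=ph.voxel), ph


def smooth_sinogram(n_angles=400, n_cols=128):
    """Stripe-free, angle-varying synthetic sinogram (moving Gaussian trace)."""
    angles = np.linspace(0, 180, n_angles, endpoint=False)
    s = np.arange(n_cols) - n_cols / 2
    trace = 40.0 * np.sin(np.deg2rad(angles) + 0.7)[:, None]
    data = (1000.0 + 500.0 * np.exp(-((s[None, :] - trace) ** 2) / (2 * 14.0**2)))[:, None, :]
    return SinogramStack(data, angles, pixel_eff=38.0)


class TestAngularInterpolate:
    def test_factor_one_identity(self):
        st = smooth_sinogram(16)
        out = angular_interpolate(st, 1)
        assert np.array_equal(out.data, st.data)

    def test_constant_stack(self):
        st = SinogramStack(np.full((5, 2, 8), 3.0), np.arange(5.0), pixel_eff=1.0)
        out = angular_interpolate(st, 2)
        assert np.allclose(out.data, 3.0)

    def test_midpoint_rule_and_counts(self):
        data = np.zeros((2, 1, 4))
        data[0] = 1.0
        data[1] = 3.0
        st = SinogramStack(data, np.array([0.0, 10.0]), pixel_eff=1.0)
        out = angular_interpolate(st, 2)
        assert out.data.shape[0] == 3
        assert np.allclose(out.data[1], 2.0)
        assert np.array_equal(out.angles, [0.0, 5.0, 10.0])
        assert np.array_equal(out.data[0], data[0]) and np.array_equal(out.data[2], data[1])

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            angular_interpolate(smooth_sinogram(8), 0)


class TestExtendTruncated:
    def test_zero_pad_identity(self):
        st = smooth_sinogram(8)
        out = extend_truncated(st, 0)
        assert np.array_equal(out.data, st.data)

    def test_edge_replication(self):
        st = smooth_sinogram(8)
        out = extend_truncated(st, 5)
        assert out.data.shape[2] == st.data.shape[2] + 10
        assert np.all(out.data[:, :, :5] == st.data[:, :, :1])
        assert np.all(out.data[:, :, -5:] == st.data[:, :, -1:])
        assert np.array_equal(out.data[:, :, 5:-5], st.data)


class TestRingFilter:
    def test_stripe_free_sinogram_nearly_unchanged(self):
        st = smooth_sinogram()
        out = remove_rings_wavelet(st)
        rel = np.linalg.norm(out.data - st.data) / np.linalg.norm(st.data)
        assert rel < 0.01

    def test_stripe_suppression(self):
        """A constant detector-column offset is damped by >= 10x."""
        st = smooth_sinogram()
        striped = st.data.copy()
        striped[:, :, 60] += 300.0
        out_clean = remove_rings_wavelet(st)
        out_striped = remove_rings_wavelet(
            SinogramStack(striped, st.angles, st.pixel_eff)
        )
        residual = np.mean(out_striped.data[:, 0, 60] - out_clean.data[:, 0, 60])
        assert abs(residual) < 300.0 / 10.0

    def test_shape_preserved(self):
        st = smooth_sinogram(101, 97)  # odd sizes exercise the wavelet padding
        out = remove_rings_wavelet(st)
        assert out.data.shape == st.data.shape

    def test_unknown_wavelet_lists_supported(self):
        with pytest.raises(ValueError, match="db9"):
            remove_rings_wavelet(smooth_sinogram(8), wavelet="nosuchwavelet")


class TestFBP:
    def test_zero_sinogram(self):
        st = SinogramStack(np.zeros((4, 2, 16)), np.array([0.0, 45.0, 90.0, 135.0]),
                           pixel_eff=38.0)
        vol = fbp_reconstruct(st)
        assert np.allclose(vol.density, 0.0)

    def test_uniform_disk_density_recovery(self):
        """Analytic disk projections reconstruct the interior density
        within 1%."""
        st, ph = disk_sinogram()
        vol = fbp_reconstruct(st, filter="ramp")
        yy, xx = np.mgrid[0:128, 0:128]
        interior = np.hypot(yy - 64, xx - 64) < 30
        mean = vol.density[0][interior].mean()
        assert mean == pytest.approx(ph.background_density, rel=0.01)

    def test_point_like_centroid(self):
        """A small particle reconstructs at the correct voxel."""
        from scipy import ndimage

        ph = make_tomo_phantom(n_particles=1, particle_volume_fl=0.05,
                               density_contrast=100.0, cylinder_radius=40,
                               grid=128, nz=32, seed=3, background_density=0.0)
        angles = np.linspace(0, 180, 200, endpoint=False)
        data = np.stack([project_phantom(ph, a) for a in angles])
        vol = fbp_reconstruct(SinogramStack(data, angles, pixel_eff=ph.voxel))
        z = int(round(ph.particles[0].center[0]))
        sl = vol.density[z]
        cy, cx = ndimage.center_of_mass(sl > 0.5 * sl.max())
        assert cy == pytest.approx(ph.particles[0].center[1], abs=1.0)
        assert cx == pytest.approx(ph.particles[0].center[2], abs=1.0)

    def test_too_few_angles_rejected(self):
        st = SinogramStack(np.zeros((1, 1, 8)), np.array([0.0]), pixel_eff=1.0)
        with pytest.raises(ValueError):
            fbp_reconstruct(st)

    def test_unknown_filter_rejected(self):
        st = smooth_sinogram(8)
        with pytest.raises(ValueError, match="filter"):
            fbp_reconstruct(st, filter="shepp")

    def test_missing_pixel_size_rejected(self):
        st = SinogramStack(np.zeros((4, 1, 8)), np.arange(4.0), pixel_eff=None)
        with pytest.raises(ValueError, match="pixel"):
            fbp_reconstruct(st)


class TestShiftMean:
    def test_mean_and_idempotence(self, rng):
        vol = VolumeMap(rng.normal(250.0, 5.0, (8, 16, 16)), voxel=38.0)
        out = shift_mean(vol, 310.25)
        assert out.density.mean() == pytest.approx(310.25)
        again = shift_mean(out, 310.25)
        assert np.allclose(again.density, out.density)

    def test_std_unchanged(self, rng):
        vol = VolumeMap(rng.normal(250.0, 5.0, (8, 16, 16)), voxel=38.0)
        out = shift_mean(vol, 310.25)
        assert out.density.std() == pytest.approx(vol.density.std(), rel=1e-12)


class TestIntensityProjection:
    def test_depth_one_is_slice(self, rng):
        vol = VolumeMap(rng.random((9, 8, 8)), voxel=1.0)
        out = intensity_projection(vol, depth=1, mode="max")
        assert np.array_equal(out, vol.density[4])

    def test_max_dominates_min(self, rng):
        vol = VolumeMap(rng.random((11, 8, 8)), voxel=1.0)
        mx = intensity_projection(vol, depth=11, mode="max")
        mn = intensity_projection(vol, depth=11, mode="min")
        assert np.all(mx >= mn)

    def test_constant_volume(self):
        vol = VolumeMap(np.full((12, 6, 6), 7.0), voxel=1.0)
        assert np.allclose(intensity_projection(vol, depth=11), 7.0)

    def test_depth_out_of_range(self):
        vol = VolumeMap(np.zeros((4, 4, 4)), voxel=1.0)
        with pytest.raises(ValueError):
            intensity_projection(vol, depth=5)
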