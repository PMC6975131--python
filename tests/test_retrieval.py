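"""Single- and multi-energy CTF inversion and its regularization."""

import numpy as np
import pytest
from scipy.optimize import brentq

from holoctf.constants import wavelength_nm
from holoctf.retrieval import (
    ProjectionMap,
    RetrievalConfig,
    alpha_cutoff_frequency,
    ctf_kernel,
    density_from_projection,
    mean_channel,
    reconstruct_multiE,
    regularization_alpha,
)
from holoctf.wave_optics import Hologram, linear_hologram_model

ENERGIES = [6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0]
FRESNEL = [2.43e-4, 2.64e-4, 2.84e-4, 3.04e-4, 3.24e-4, 3.45e-4, 3.65e-4]
CHANNELS = tuple((wavelength_nm(e), f) for e, f in zip(ENERGIES, FRESNEL))
LAM, F = CHANNELS[3]
CP = 0.134  # blood-like coupling, 1/nm^2


def smooth_density(n=512, sigma=30.0, amplitude=4e5):
    y, x = np.mgrid[0:n, 0:n] - n / 2
    return amplitude * np.exp(-(x**2 + y**2) / (2 * sigma**2))


class TestKernel:
    def test_dc_value(self):
        k = ctf_kernel(LAM, F, CP, (64, 64))
        assert k[0, 0] == pytest.approx(LAM**3 * CP)

    def test_pure_phase_zeros(self):
        """With C' = 0 the kernel is lambda*sin(chi), vanishing at chi = m pi."""
        n = 4096
        k = ctf_kernel(LAM, F, 0.0, (1, n))[0]
        chi = np.pi * np.fft.fftfreq(n) ** 2 / F
        near_pi = np.argmin(np.abs(chi - np.pi))
        # sign change across the chi = pi crossing
        assert k[near_pi - 1] * k[near_pi + 1] < 0 or abs(k[near_pi]) < 1e-6

    def test_first_root_closed_form(self):
        """First zero beyond DC satisfies tan(chi) = -lambda^2 C'."""
        kernel_1d = lambda chi: LAM * np.sin(chi) + LAM**3 * CP * np.cos(chi)
        root = brentq(kernel_1d, 1.0, np.pi)
        assert np.tan(root) == pytest.approx(-(LAM**2) * CP, rel=1e-9)


class TestRegularization:
    CONFIG = RetrievalConfig(channels=CHANNELS, cprime=CP)

    def test_zero_at_dc(self):
        alpha = regularization_alpha((128, 128), self.CONFIG)
        assert alpha[0, 0] == 0.0

    def test_amplitude_at_nyquist(self):
        alpha = regularization_alpha((128, 128), self.CONFIG)
        assert alpha[64, 64] == pytest.approx(1e-4)

    def test_radial_symmetry(self):
        alpha = regularization_alpha((128, 128), self.CONFIG)
        assert np.allclose(alpha, alpha.T)  # same radius, same value
        assert alpha[0, 10] == alpha[10, 0]

    def test_cutoff_at_first_ctf_maximum(self):
        """The step edge sits at the first maximum of the mean-energy CTF:
        chi_1 = arctan(1/(lambda_bar^2 C')), nu_1 = sqrt(chi_1 F_bar / pi)."""
        lam_bar, f_bar = mean_channel(self.CONFIG)
        chi1 = np.arctan2(1.0, lam_bar**2 * CP)
        assert alpha_cutoff_frequency(self.CONFIG) == pytest.approx(
            np.sqrt(chi1 * f_bar / np.pi)
        )

    def test_mean_energy_rule(self):
        lam_bar, _ = mean_channel(self.CONFIG)
        energies = np.array([1239.842 / 1000.0 / lam for lam, _ in CHANNELS])
        assert 1239.842 / 1000.0 / lam_bar == pytest.approx(energies.mean())

    def test_smooth_transition_monotone(self):
        cfg = RetrievalConfig(channels=CHANNELS, cprime=CP, alpha_transition=0.01)
        alpha = regularization_alpha((1, 512), cfg)[0]
        nu = np.abs(np.fft.fftfreq(512))
        order = np.argsort(nu[:256])
        assert np.all(np.diff(alpha[:256][order]) >= -1e-12)


class TestReconstruction:
    def test_unit_holograms_give_zero(self):
        holos = [Hologram(np.ones((64, 64)), lam, fr) for lam, fr in CHANNELS]
        cfg = RetrievalConfig(channels=CHANNELS, cprime=CP)
        out = reconstruct_multiE(holos, cfg)
        assert np.allclose(out.D, 0.0)

    def test_single_channel_reduces_to_direct_inversion(self):
        """One channel with alpha = 0 equals the direct quotient by 2k."""
        from holoctf.constants import R0_NM

        d = smooth_density(256)
        holo = linear_hologram_model(d, LAM, F, CP)
        cfg = RetrievalConfig(channels=((LAM, F),), cprime=CP, alpha_amplitude=0.0)
        via_multi = reconstruct_multiE([holo], cfg)
        kernel = ctf_kernel(LAM, F, CP, holo.intensity.shape)
        direct = np.real(
            np.fft.ifft2(-np.fft.fft2(holo.intensity - 1.0) / (2.0 * kernel))
        ) / R0_NM
        assert np.allclose(via_multi.D, direct, rtol=1e-10, atol=1e-6)

    @pytest.mark.parametrize("n_channels", [3, 7])
    def test_linear_model_round_trip(self, n_channels):
        """Holograms from the linear model invert back to D with relative
        L2 error below 1e-3 (alpha-limited)."""
        d = smooth_density(512)
        chans = CHANNELS[:: 3 if n_channels == 3 else 1][:n_channels]
        holos = [linear_hologram_model(d, lam, fr, CP) for lam, fr in chans]
        cfg = RetrievalConfig(channels=chans, cprime=CP)
        out = reconstruct_multiE(holos, cfg)
        assert np.linalg.norm(out.D - d) / np.linalg.norm(d) < 1e-3

    def test_linearity_in_contrast(self):
        d = smooth_density(256)
        holo = linear_hologram_model(d, LAM, F, CP)
        cfg = RetrievalConfig(channels=((LAM, F),), cprime=CP)
        base = reconstruct_multiE([holo], cfg)
        scaled = Hologram(1.0 + 0.5 * (holo.intensity - 1.0), LAM, F)
        half = reconstruct_multiE([scaled], cfg)
        assert np.allclose(half.D, 0.5 * base.D, rtol=1e-8, atol=1e-6)

    def test_multi_beats_worst_single_on_linear_data(self):
        """Spectral coverage: joint inversion error does not exceed the
        worst single-channel error, and improves on it."""
        d = smooth_density(512)
        holos = [linear_hologram_model(d, lam, fr, CP) for lam, fr in CHANNELS]
        errors = []
        for holo, chan in zip(holos, CHANNELS):
            cfg = RetrievalConfig(channels=(chan,), cprime=CP)
            out = reconstruct_multiE([holo], cfg)
            errors.append(np.linalg.norm(out.D - d) / np.linalg.norm(d))
        cfg = RetrievalConfig(channels=CHANNELS, cprime=CP)
        multi = reconstruct_multiE(holos, cfg)
        multi_err = np.linalg.norm(multi.D - d) / np.linalg.norm(d)
        assert multi_err <= max(errors)
        assert multi_err < 0.5 * max(errors)

    def test_shape_mismatch_rejected(self):
        holos = [
            Hologram(np.ones((32, 32)), *CHANNELS[0]),
            Hologram(np.ones((64, 64)), *CHANNELS[1]),
        ]
        cfg = RetrievalConfig(channels=CHANNELS[:2], cprime=CP)
        with pytest.raises(ValueError, match="shape"):
            reconstruct_multiE(holos, cfg)

    def test_channel_count_mismatch_rejected(self):
        holos = [Hologram(np.ones((32, 32)), *CHANNELS[0])]
        cfg = RetrievalConfig(channels=CHANNELS[:2], cprime=CP)
        with pytest.raises(ValueError, match="channels"):
            reconstruct_multiE(holos, cfg)


class TestDensityFromProjection:
    def test_uniform_slab_exact(self):
        proj = ProjectionMap(D=np.full((64, 64), 310.25 * 2000.0))
        t = np.full((64, 64), 2000.0)
        assert density_from_projection(proj, t, window=40) == pytest.approx(310.25)
        assert density_from_projection(proj, t, window=40, stat="pixelwise") == pytest.approx(
            310.25
        )

    def test_window_off_support_rejected(self):
        proj = ProjectionMap(D=np.zeros((64, 64)))
        with pytest.raises(ValueError, match="positive"):
            density_from_projection(proj, np.zeros((64, 64)), window=40)

    def test_unknown_stat_rejected(self):
        proj = ProjectionMap(D=np.ones((8, 8)))
        with pytest.raises(ValueError, match="stat"):
            density_from_projection(proj, np.ones((8, 8)), window=4, stat="median")
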