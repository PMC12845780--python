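"""Continuous wavelet transform: mother wavelets, scale grid, convolution."""

import warnings

import numpy as np
import pytest

import leafspec as ls
from leafspec.cwt import WaveletSpec, mother_wavelet, _kernel


def _quadrature_cwt(signal: np.ndarray, spec: WaveletSpec, scale: float, shifts) -> np.ndarray:
    """Independent trapezoid-rule oracle for W(a,b) with mirror padding."""
    n = signal.size
    radius = int(np.ceil(spec.support_radius * scale))
    padded = np.pad(signal, radius, mode="symmetric")
    x = np.arange(-radius, n + radius, dtype=float)  # positions of padded samples
    out = np.empty(len(shifts))
    for i, b in enumerate(shifts):
        integrand = padded * mother_wavelet(spec, (x - b) / scale) / np.sqrt(scale)
        out[i] = np.trapezoid(integrand, x)
    return out


class TestMotherWavelet:
    def test_gaus1_odd(self):
        spec = WaveletSpec("gaus1")
        t = np.linspace(0.1, 6.0, 40)
        assert mother_wavelet(spec, 0.0) == pytest.approx(0.0)
        np.testing.assert_allclose(
            mother_wavelet(spec, -t), -mother_wavelet(spec, t), atol=1e-12
        )

    @pytest.mark.parametrize("name", ["gaus1", "gaus2", "mexh", "morlet_real"])
    def test_zero_mean(self, name):
        t = np.linspace(-8, 8, 40001)
        integral = np.trapezoid(mother_wavelet(WaveletSpec(name), t), t)
        assert abs(integral) < 1e-8

    @pytest.mark.parametrize("name", ["gaus1", "gaus2", "mexh", "morlet_real"])
    def test_unit_l2_norm(self, name):
        t = np.linspace(-10, 10, 80001)
        norm2 = np.trapezoid(mother_wavelet(WaveletSpec(name), t) ** 2, t)
        assert norm2 == pytest.approx(1.0, abs=1e-6)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            WaveletSpec("haar")


class TestScaleGrid:
    def test_ten_scales_dyadic(self):
        assert ls.scale_grid(10) == [2, 4, 8, 16, 32, 64, 128, 256, 512, 1024]

    def test_single_scale(self):
        assert ls.scale_grid(1) == [2]

    def test_strictly_increasing_ratio_two(self):
        grid = np.array(ls.scale_grid(8))
        assert np.all(np.diff(grid) > 0)
        np.testing.assert_array_equal(grid[1:] / grid[:-1], 2)

    def test_zero_scales_rejected(self):
        with pytest.raises(ValueError):
            ls.scale_grid(0)


class TestCwtTransform:
    def test_constant_spectrum_maps_to_zero(self):
        wl = np.arange(401.0, 901.0)
        spectra = ls.SpectrumSet(["a"], wl, np.full((1, wl.size), 0.37))
        coeffs = ls.cwt_transform(spectra, scales=[2, 8, 32])
        assert np.abs(coeffs.coeff).max() < 1e-8

    def test_linearity(self, rng):
        wl = np.arange(401.0, 601.0)
        f = rng.uniform(0, 1, wl.size)
        g = rng.uniform(0, 1, wl.size)
        alpha, beta = 1.7, -0.4
        def cwt_one(sig):
            ss = ls.SpectrumSet(["x"], wl, sig[None, :])
            return ls.cwt_transform(ss, scales=[4, 16]).coeff
        lhs = cwt_one(alpha * f + beta * g)
        rhs = alpha * cwt_one(f) + beta * cwt_one(g)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize("scale", [2, 8, 32])
    def test_matches_quadrature_oracle(self, rng, scale):
        """Convolution equals direct numerical integration on a 50-point signal."""
        wl = np.arange(401.0, 451.0)
        f = rng.uniform(0.1, 0.9, wl.size)
        ss = ls.SpectrumSet(["x"], wl, f[None, :])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = ls.cwt_transform(ss, scales=[scale]).coeff[0, 0]
        want = _quadrature_cwt(f, WaveletSpec(), scale, np.arange(wl.size))
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9 * np.abs(want).max())

    def test_matches_analytic_gaussian_trough(self):
        """Closed form for a Gaussian trough under the gaus1 wavelet.

        For f(λ) = −d·exp(−(λ−c)²/2σ²) the transform is
        W(a,b) = −d·A·√(2π)·σ·a^{3/2}·(b−c)/(σ²+a²)^{3/2}
                 · exp(−(b−c)²/(2(σ²+a²))), A = √2·π^{-1/4}.
        """
        wl = np.arange(401.0, 1401.0)
        c, sigma, d = 900.0, 30.0, 0.2
        f = 0.5 - d * np.exp(-((wl - c) ** 2) / (2 * sigma**2))
        ss = ls.SpectrumSet(["x"], wl, f[None, :])
        a = 16
        got = ls.cwt_transform(ss, scales=[a]).coeff[0, 0]
        A = np.sqrt(2.0) * np.pi**-0.25
        b = wl
        s2 = sigma**2 + a**2
        want = (
            -d * A * np.sqrt(2 * np.pi) * sigma * a**1.5 * (b - c) / s2**1.5
            * np.exp(-((b - c) ** 2) / (2 * s2))
        )
        # interior comparison (constant offset contributes nothing; edges padded)
        inner = slice(200, 800)
        np.testing.assert_allclose(got[inner], want[inner], atol=2e-4 * d)

    def test_gaus1_zero_crossing_at_trough_center(self):
        """Antisymmetric response crosses zero at the absorption center."""
        wl = np.arange(401.0, 1401.0)
        c = 900.0
        f = 0.5 - 0.2 * np.exp(-((wl - c) ** 2) / (2 * 25.0**2))
        ss = ls.SpectrumSet(["x"], wl, f[None, :])
        for a in [2, 8, 32, 128]:
            row = ls.cwt_transform(ss, scales=[a]).coeff[0, 0]
            sign_flips = np.where(np.diff(np.sign(row[300:700])) != 0)[0] + 300
            crossing = wl[sign_flips[np.argmin(np.abs(wl[sign_flips] - c))]]
            assert abs(crossing - c) <= 1.0, f"scale {a}"

    def test_scale_response_peaks_near_matched_scale(self):
        """|W| over the dyadic ladder is unimodal, peaking at a ≈ √3·σ.

        Peak magnitude over shifts is ∝ a^{3/2}/(σ²+a²) (from the closed
        form above), maximized at a = √3σ; σ = 16/√3 targets scale 16.
        """
        wl = np.arange(401.0, 2401.0)
        sigma = 16.0 / np.sqrt(3.0)  # matched dyadic scale: a = 16
        f = 0.5 - 0.2 * np.exp(-((wl - 1400.0) ** 2) / (2 * sigma**2))
        ss = ls.SpectrumSet(["x"], wl, f[None, :])
        scales = [2, 4, 8, 16, 32, 64, 128]
        peaks = [
            np.abs(ls.cwt_transform(ss, scales=[a]).coeff[0, 0]).max() for a in scales
        ]
        k = int(np.argmax(peaks))
        assert scales[k] == 16
        assert np.all(np.diff(peaks[: k + 1]) > 0) and np.all(np.diff(peaks[k:]) < 0)

    def test_edge_scale_flagged(self):
        wl = np.arange(401.0, 501.0)
        ss = ls.SpectrumSet(["x"], wl, np.random.default_rng(0).uniform(size=(1, wl.size)))
        with pytest.warns(UserWarning, match="boundary padding"):
            coeffs = ls.cwt_transform(ss, scales=[8, 64])
        assert coeffs.edge_affected == [False, True]

    def test_cache_round_trip(self, tmp_path, toy_spectrum_set):
        from leafspec.cwt import read_coefficients, write_coefficients

        coeffs = ls.cwt_transform(toy_spectrum_set, scales=[4, 32])
        write_coefficients(coeffs, tmp_path / "cwt")
        back = read_coefficients(tmp_path / "cwt")
        assert back.scales == [4, 32]
        np.testing.assert_allclose(back.coeff, coeffs.coeff, atol=1e-9)

    def test_l1_norm_rescales_by_sqrt_scale(self, toy_spectrum_set):
        a = 8
        l2 = ls.cwt_transform(toy_spectrum_set, scales=[a]).coeff
        l1 = ls.cwt_transform(toy_spectrum_set, scales=[a], l1_norm=True).coeff
        np.testing.assert_allclose(l1 * np.sqrt(a), l2, rtol=1e-10)
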