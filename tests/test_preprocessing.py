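"""MSC, derivatives, Savitzky-Golay and chain composition."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from hsipipe import (
    PreprocessConfig,
    SpectralMatrix,
    apply_chain,
    default_wavelengths,
    derivative,
    fit_chain,
    msc_apply,
    msc_fit,
    savitzky_golay,
)
from hsipipe.errors import ConfigurationError

WL = default_wavelengths(36, 400, 540)  # 4 nm grid


def _matrix(values):
    values = np.atleast_2d(values)
    n = values.shape[0]
    return SpectralMatrix(values, WL[: values.shape[1]],
                          [f"s{i}" for i in range(n)], np.ones(n, dtype=int))


class TestMSC:
    def test_row_equal_to_reference_is_identity(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.9, WL.size)
        m = _matrix(np.stack([base, base]))
        ref = msc_fit(m)
        out = msc_apply(ref, m)
        np.testing.assert_allclose(out.values[0], base, rtol=1e-12)
        np.testing.assert_allclose(ref.slopes, 1.0, atol=1e-12)
        np.testing.assert_allclose(ref.intercepts, 0.0, atol=1e-12)

    def test_exact_affine_inversion(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.9, WL.size)
        m = _matrix(np.stack([base, 2.0 * base + 3.0]))
        ref = msc_fit(_matrix(np.stack([base, base])))
        out = msc_apply(ref, m)
        np.testing.assert_allclose(ref.slopes[1], 2.0, rtol=1e-9)
        np.testing.assert_allclose(ref.intercepts[1], 3.0, rtol=1e-9)
        np.testing.assert_allclose(out.values[1], base, rtol=1e-9)

    def test_corrected_rows_regress_to_unit_slope(self):
        # oracle: re-run least squares of each corrected row on the reference
        rng = np.random.default_rng(2)
        m = _matrix(rng.uniform(0.1, 0.9, (12, WL.size)))
        ref = msc_fit(m)
        out = msc_apply(ref, m)
        xbar = ref.mean_spectrum
        for row in out.values:
            slope, intercept = np.polyfit(xbar, row, 1)
            assert abs(slope - 1.0) < 1e-9
            assert abs(intercept) < 1e-9

    def test_affine_distortion_invariance(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.uniform(0.1, 0.9, (6, WL.size)))
        ref = msc_fit(m)
        distorted = _matrix(1.7 * m.values + 0.2)
        np.testing.assert_allclose(
            msc_apply(ref, distorted).values, msc_apply(ref, m).values, rtol=1e-9
        )


class TestDerivative:
    def test_linear_spectrum_gives_constant_slope(self):
        s = 0.003
        m = _matrix(s * WL)
        out = derivative(m, 1)
        np.testing.assert_allclose(out.values, s, rtol=1e-9)
        assert out.n_bands == m.n_bands - 1
        np.testing.assert_array_equal(out.wavelengths, WL[:-1])

    def test_quadratic_spectrum_gives_constant_curvature(self):
        a = 2e-6
        m = _matrix(a * WL**2)
        out = derivative(m, 2)
        np.testing.assert_allclose(out.values, 2 * a, rtol=1e-6)
        assert out.n_bands == m.n_bands - 2
        np.testing.assert_array_equal(out.wavelengths, WL[1:-1])

    def test_matches_elementwise_difference_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(0.1, 0.9, WL.size)
        dl = WL[1] - WL[0]
        first = np.array([(y[i + 1] - y[i]) / dl for i in range(y.size - 1)])
        second = np.array([
            (y[i + 1] - 2 * y[i] + y[i - 1]) / dl**2 for i in range(1, y.size - 1)
        ])
        np.testing.assert_allclose(derivative(_matrix(y), 1).values[0], first,
                                   atol=1e-12)
        np.testing.assert_allclose(derivative(_matrix(y), 2).values[0], second,
                                   atol=1e-12)

    def test_non_uniform_grid_rejected(self):
        wl = np.array([400.0, 404.0, 410.0, 414.0])
        m = SpectralMatrix(np.zeros((1, 4)), wl, ["s"], [1])
        with pytest.raises(ConfigurationError):
            derivative(m, 1)


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        m = _matrix(np.full(WL.size, 0.4))
        np.testing.assert_allclose(savitzky_golay(m, 7).values, 0.4, rtol=1e-12)

    def test_quadratic_reproduced(self):
        a, b, c = 1e-6, -3e-4, 0.5
        m = _matrix(a * WL**2 + b * WL + c)
        out = savitzky_golay(m, 9, polyorder=2)
        interior = slice(4, WL.size - 4)
        np.testing.assert_allclose(out.values[0, interior],
                                   m.values[0, interior], atol=1e-9)

    def test_noise_variance_shrinks_by_weight_norm(self):
        # oracle: white noise through an S-G filter has output variance
        # ~ sum of squared convolution weights
        window, poly = 17, 2
        weights = savgol_coeffs(window, poly)
        expected = float(weights @ weights)
        rng = np.random.default_rng(5)
        ratios = []
        wl = default_wavelengths(200, 400, 1196)
        for _ in range(200):
            y = rng.standard_normal(200)
            m = SpectralMatrix(y[None, :], wl, ["s"], [1])
            out = savitzky_golay(m, window, poly).values[0]
            interior = slice(window, 200 - window)
            ratios.append(out[interior].var() / y.var())
        assert abs(np.mean(ratios) - expected) / expected < 0.10

    def test_window_larger_than_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            savitzky_golay(_matrix(np.zeros(8)), 9)


class TestChains:
    def test_single_stage_chain_equals_direct_msc(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.uniform(0.1, 0.9, (8, WL.size)))
        out, _ = apply_chain(PreprocessConfig(["MSC"]), m)
        ref = msc_fit(m)
        np.testing.assert_array_equal(out.values, msc_apply(ref, m).values)

    def test_chain_equals_manual_composition(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.uniform(0.1, 0.9, (8, WL.size)))
        out, _ = apply_chain(PreprocessConfig(["2D", "SG"], sg_window=7), m)
        manual = savitzky_golay(derivative(m, 2), 7)
        np.testing.assert_allclose(out.values, manual.values, rtol=1e-12)

    def test_prediction_rows_never_alter_calibration_output(self):
        rng = np.random.default_rng(8)
        cal = _matrix(rng.uniform(0.1, 0.9, (8, WL.size)))
        pred_a = _matrix(rng.uniform(0.1, 0.9, (4, WL.size)))
        pred_b = _matrix(rng.uniform(0.1, 0.9, (4, WL.size)))
        cfg = PreprocessConfig(["MSC", "1D", "SG"], sg_window=5)
        out_a, _ = apply_chain(cfg, cal, pred_a)
        out_b, _ = apply_chain(cfg, cal, pred_b)
        np.testing.assert_array_equal(out_a.values, out_b.values)

    @pytest.mark.parametrize("name, stages, window", [
        ("MSC+2D+S-G (17)", ["MSC", "2D", "SG"], 17),
        ("MSC+1D+S-G (5)", ["MSC", "1D", "SG"], 5),
        ("msc+2d+sg(7)", ["MSC", "2D", "SG"], 7),
        ("MSC+2D+S-D (17)", ["MSC", "2D", "SG"], 17),
    ])
    def test_chain_name_round_trip(self, name, stages, window):
        cfg = PreprocessConfig.parse(name)
        assert cfg.stages == stages
        assert cfg.sg_window == window
        reparsed = PreprocessConfig.parse(cfg.name)
        assert reparsed.stages == cfg.stages
        assert reparsed.sg_window == cfg.sg_window

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            PreprocessConfig(["SG"], sg_window=4)
        with pytest.raises(ConfigurationError):
            PreprocessConfig(["SNV"])
        with pytest.raises(ConfigurationError):
            PreprocessConfig.parse("MSC+wavelet")
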