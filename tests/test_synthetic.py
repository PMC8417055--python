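"""Synthetic-data generator: seeding, ranges, monotone drift, round trips."""

import numpy as np
import pandas as pd
import pytest

from hsipipe import (
    DesignSpec,
    SceneSpec,
    black_white_correct,
    generate_biochemistry,
    generate_cube,
    generate_spectra,
    mean_spectrum,
    spectrum_from_biochem,
)
from hsipipe.errors import ConfigurationError
from hsipipe.synthetic import (
    ANALYTE_RANGES,
    ANALYTES,
    informative_bands,
    reference_curve,
    response_curve,
    spectral_coefficients,
)


class TestBiochemistry:
    def test_values_within_published_ranges(self, design):
        table = generate_biochemistry(design)
        assert len(table) == 180
        for analyte, (lo, hi) in ANALYTE_RANGES.items():
            assert table[analyte].between(lo, hi).all()

    def test_monotone_drift_with_drought(self, design):
        means = generate_biochemistry(design).groupby("period").mean(numeric_only=True)
        for analyte in ("MDA", "EL", "SS"):
            assert np.all(np.diff(means[analyte]) >= 0)
        assert np.all(np.diff(means["FvFm"]) <= 0)

    def test_zero_noise_matches_response_curve(self):
        spec = DesignSpec(seed=7, noise_sd=0.0)
        table = generate_biochemistry(spec)
        from hsipipe.synthetic import drought_level

        d = drought_level(table["period"].to_numpy(), spec.n_periods)
        for analyte in ANALYTES:
            np.testing.assert_allclose(
                table[analyte], response_curve(spec, analyte, d), rtol=1e-12
            )

    def test_seeding_contract(self):
        a = generate_biochemistry(DesignSpec(seed=5))
        b = generate_biochemistry(DesignSpec(seed=5))
        c = generate_biochemistry(DesignSpec(seed=6))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["MDA"], c["MDA"])

    def test_repeat_long_table_averages_to_reported(self):
        spec = DesignSpec(seed=3)
        long = generate_biochemistry(spec, keep_repeats=True)
        short = generate_biochemistry(spec)
        assert len(long) == 540
        mean_of_reps = long.groupby("sample_id", sort=False)["MDA"].mean()
        np.testing.assert_allclose(
            mean_of_reps.to_numpy(), short["MDA"].to_numpy(), rtol=1e-12
        )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            DesignSpec(n_periods=0)
        with pytest.raises(ConfigurationError):
            DesignSpec(n_bands=4)
        with pytest.raises(ConfigurationError):
            DesignSpec(wavelength_range=(1100, 400))


class TestSpectrumModel:
    def test_midpoint_gives_reference_curve(self, wavelengths):
        mid = {a: 0.5 * (lo + hi) for a, (lo, hi) in ANALYTE_RANGES.items()}
        np.testing.assert_allclose(
            spectrum_from_biochem(mid, wavelengths), reference_curve(wavelengths),
            rtol=0, atol=1e-14,
        )

    def test_difference_localized_to_coefficient_support(self, wavelengths):
        # two rows differing only in SS differ exactly where the SS column
        # of the coefficient ledger is nonzero
        mid = {a: 0.5 * (lo + hi) for a, (lo, hi) in ANALYTE_RANGES.items()}
        other = dict(mid, SS=mid["SS"] + 1.0)
        delta = spectrum_from_biochem(other, wavelengths) - spectrum_from_biochem(
            mid, wavelengths
        )
        c_ss = spectral_coefficients(wavelengths)[:, ANALYTES.index("SS")]
        lo, hi = ANALYTE_RANGES["SS"]
        np.testing.assert_allclose(delta, c_ss * (1.0 / (0.5 * (hi - lo))), atol=1e-15)

    def test_drought_raises_visible_lowers_nir(self, design, wavelengths):
        row_lo = {a: response_curve(design, a, 0.0) for a in ANALYTES}
        row_hi = {a: response_curve(design, a, 1.0) for a in ANALYTES}
        s_lo = spectrum_from_biochem(row_lo, wavelengths)
        s_hi = spectrum_from_biochem(row_hi, wavelengths)
        vis = (wavelengths >= 400) & (wavelengths <= 700)
        nir = (wavelengths >= 760) & (wavelengths <= 1000)
        assert s_hi[vis].mean() > s_lo[vis].mean()
        assert s_hi[nir].mean() < s_lo[nir].mean()

    def test_output_in_unit_interval(self, experiment):
        assert np.all(experiment.spectra.values > 0)
        assert np.all(experiment.spectra.values < 1)

    def test_out_of_range_wavelengths_rejected(self):
        mid = {a: 0.5 * (lo + hi) for a, (lo, hi) in ANALYTE_RANGES.items()}
        with pytest.raises(ConfigurationError):
            spectrum_from_biochem(mid, np.array([300.0, 500.0]))

    def test_informative_bands_nonempty_per_analyte(self, wavelengths):
        for analyte in ANALYTES:
            assert informative_bands(wavelengths, analyte).size > 0


class TestCube:
    def test_noise_free_round_trip_identity(self, wavelengths):
        scene = SceneSpec(scatter_slope_sd=0.0, baseline_sd=0.0, noise_sd=0.0)
        mid = {a: 0.5 * (lo + hi) for a, (lo, hi) in ANALYTE_RANGES.items()}
        spectrum = spectrum_from_biochem(mid, wavelengths)
        cube, refs, mask = generate_cube(scene, spectrum, wavelengths, seed=0)
        corrected, _ = black_white_correct(cube, refs)
        recovered = mean_spectrum(corrected, mask)
        np.testing.assert_allclose(recovered, spectrum, rtol=1e-9)

    def test_background_contrast_by_construction(self, wavelengths):
        scene = SceneSpec(scatter_slope_sd=0.0, baseline_sd=0.0, noise_sd=0.0)
        mid = {a: 0.5 * (lo + hi) for a, (lo, hi) in ANALYTE_RANGES.items()}
        spectrum = spectrum_from_biochem(mid, wavelengths)
        cube, refs, mask = generate_cube(scene, spectrum, wavelengths, seed=0)
        corrected, _ = black_white_correct(cube, refs)
        band = int(np.argmin(np.abs(wavelengths - 800.0)))
        leaf = corrected.values[mask.values, band].mean()
        bg = corrected.values[~mask.values, band].mean()
        np.testing.assert_allclose(
            abs(leaf - bg), abs(spectrum[band] - scene.background_reflectance),
            rtol=1e-9,
        )

    def test_degenerate_scene_rejected(self):
        with pytest.raises(ConfigurationError):
            SceneSpec(leaf_axes=(100.0, 100.0), image_height=32, image_width=32)

    def test_no_contrast_rejected(self, wavelengths):
        scene = SceneSpec(background_reflectance=0.5)
        with pytest.raises(ConfigurationError):
            generate_cube(scene, np.full(wavelengths.size, 0.5), wavelengths)


def test_spectra_deterministic_given_seed():
    a, _ = generate_spectra(DesignSpec(seed=11))
    b, _ = generate_spectra(DesignSpec(seed=11))
    np.testing.assert_array_equal(a.values, b.values)
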