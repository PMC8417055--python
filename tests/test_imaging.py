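"""Radiometric correction, segmentation and extraction."""

import numpy as np
import pytest

from hsipipe import (
    BandMathSpec,
    DN_FULL_SCALE,
    LeafMask,
    ReferenceFrames,
    SceneSpec,
    SpectralCube,
    black_white_correct,
    default_wavelengths,
    extract_mean_spectra,
    generate_cube,
    mean_spectrum,
    segment_leaf,
    spectrum_from_biochem,
)
from hsipipe.errors import ConfigurationError, ReferenceFrameError, SegmentationError
from hsipipe.synthetic import ANALYTE_RANGES

WL8 = default_wavelengths(8, 400, 1100)


def _dn_cube(fill, shape=(4, 4, 8)):
    return SpectralCube(np.full(shape, float(fill)), WL8, units="dn")


REFS = ReferenceFrames(np.full((4, 4), 1000.0), np.full((4, 4), 60000.0))


class TestBlackWhiteCorrection:
    @pytest.mark.parametrize(
        "raw_dn, expected_dn",
        [(60000.0, DN_FULL_SCALE), (1000.0, 0.0), (30500.0, DN_FULL_SCALE / 2)],
        ids=["R=W", "R=D", "R=(W+D)/2"],
    )
    def test_linear_map_endpoints_and_midpoint(self, raw_dn, expected_dn):
        corrected, valid = black_white_correct(_dn_cube(raw_dn), REFS)
        np.testing.assert_allclose(
            corrected.values, expected_dn / DN_FULL_SCALE, rtol=1e-12
        )
        assert valid.all()

    def test_rescaling_invariance(self):
        # common positive rescaling of R, W, D leaves the correction unchanged
        raw = _dn_cube(20000.0)
        base, _ = black_white_correct(raw, REFS)
        scaled_refs = ReferenceFrames(REFS.dark * 3.0, REFS.white * 3.0)
        scaled_raw = SpectralCube(raw.values * 3.0, WL8, units="dn")
        scaled, _ = black_white_correct(scaled_raw, scaled_refs)
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-12)

    def test_equal_references_raise(self):
        refs = ReferenceFrames(np.full((4, 4), 1000.0), np.full((4, 4), 1000.0))
        with pytest.raises(ReferenceFrameError):
            black_white_correct(_dn_cube(5000.0), refs)

    def test_shape_mismatch_raises(self):
        refs = ReferenceFrames(np.zeros((3, 3)), np.ones((3, 3)))
        with pytest.raises(ConfigurationError):
            black_white_correct(_dn_cube(5000.0), refs)


class TestSegmentation:
    def test_recovers_true_mask_under_default_noise(self, wavelengths):
        mid = {a: 0.5 * (lo + hi) for a, (lo, hi) in ANALYTE_RANGES.items()}
        spectrum = spectrum_from_biochem(mid, wavelengths)
        cube, refs, truth = generate_cube(SceneSpec(), spectrum, wavelengths, seed=9)
        corrected, valid = black_white_correct(cube, refs)
        mask = segment_leaf(corrected, valid=valid)
        agreement = (mask.values == truth.values).mean()
        assert agreement >= 0.99

    def test_no_contrast_raises(self):
        cube = SpectralCube(np.full((8, 8, 8), 0.4), WL8, units="reflectance")
        with pytest.raises(SegmentationError):
            segment_leaf(cube)

    def test_manual_threshold_on_two_level_image(self):
        # noise-free two-level band-math image: threshold 0.5 classifies
        # exactly the high-level pixels (brute-force oracle)
        vals = np.zeros((6, 6, 8))
        high = np.zeros((6, 6), dtype=bool)
        high[2:5, 1:4] = True
        nir_band, red_band = 4, 3  # nearest 800 / 670 nm on the 8-band grid
        vals[..., red_band] = 0.2
        vals[..., nir_band] = np.where(high, 0.7, 0.2)
        cube = SpectralCube(vals, WL8, units="reflectance")
        oracle = (vals[..., nir_band] - vals[..., red_band]) / (
            vals[..., nir_band] + vals[..., red_band]
        ) > 0.5
        mask = segment_leaf(cube, BandMathSpec(nir_nm=WL8[nir_band],
                                               red_nm=WL8[red_band], threshold=0.5))
        np.testing.assert_array_equal(mask.values, oracle)

    def test_illumination_invariance_of_ratio_band_math(self, wavelengths):
        mid = {a: 0.5 * (lo + hi) for a, (lo, hi) in ANALYTE_RANGES.items()}
        spectrum = spectrum_from_biochem(mid, wavelengths)
        cube, refs, _ = generate_cube(SceneSpec(), spectrum, wavelengths, seed=3)
        corrected, _ = black_white_correct(cube, refs)
        brighter = SpectralCube(corrected.values * 1.7, wavelengths,
                                units="reflectance")
        np.testing.assert_array_equal(
            segment_leaf(corrected).values, segment_leaf(brighter).values
        )


class TestExtraction:
    def test_single_pixel_mask_returns_that_spectrum(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.1, 0.9, (5, 5, 8))
        cube = SpectralCube(vals, WL8, units="reflectance")
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        np.testing.assert_array_equal(mean_spectrum(cube, LeafMask(mask)),
                                      vals[2, 3])

    def test_mean_commutes_with_affine_band_maps(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 0.9, (5, 5, 8))
        mask = LeafMask(rng.uniform(size=(5, 5)) > 0.5)
        cube = SpectralCube(vals, WL8, units="reflectance")
        shifted = SpectralCube(0.5 * vals + 0.1, WL8, units="reflectance")
        np.testing.assert_allclose(
            mean_spectrum(shifted, mask), 0.5 * mean_spectrum(cube, mask) + 0.1,
            rtol=1e-12,
        )

    def test_empty_mask_identifies_sample(self):
        cube = SpectralCube(np.full((4, 4, 8), 0.5), WL8, units="reflectance")
        empty = LeafMask(np.zeros((4, 4), dtype=bool))
        with pytest.raises(SegmentationError, match="S03-01"):
            extract_mean_spectra([("S03-01", 3, cube, empty)])

    def test_matrix_rows_follow_item_order(self):
        cube = SpectralCube(np.full((4, 4, 8), 0.5), WL8, units="reflectance")
        full = LeafMask(np.ones((4, 4), dtype=bool))
        matrix = extract_mean_spectra(
            [("a", 1, cube, full), ("b", 2, cube, full)]
        )
        assert matrix.sample_ids == ["a", "b"]
        assert matrix.values.shape == (2, 8)
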