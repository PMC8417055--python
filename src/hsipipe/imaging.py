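"""Radiometric correction, leaf segmentation and spectrum extraction.

The camera delivers raw digital numbers (DN).  Black/white correction
converts them to reflectance using a dark-current frame D and a
full-scale white reference W:

    C = 65552 * (R - D) / (W - D)

with 65,552 the camera's full-scale quantization value; dividing C by
the same constant gives the reflectance fraction used downstream.
Leaves are separated from the background with an NDVI-style band-math
image ((NIR - red) / (NIR + red), bands nearest 800 and 670 nm by
default), Otsu thresholding and a largest-connected-component cleanup,
and the leaf-mean spectrum of every sample is stacked into the
samples x bands matrix that all chemometric stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .containers import DN_FULL_SCALE, LeafMask, ReferenceFrames, SpectralCube, SpectralMatrix
from .errors import ConfigurationError, ReferenceFrameError, SegmentationError


def black_white_correct(
    raw: SpectralCube,
    refs: ReferenceFrames,
    max_invalid_fraction: float = 0.01,
) -> tuple[SpectralCube, np.ndarray]:
    """Convert a raw DN cube to reflectance.

    Returns the corrected cube (reflectance fraction, i.e. C / 65552)
    and a boolean 2-D array marking valid pixels; pixels where the white
    and dark references coincide carry no radiometric information and
    are flagged invalid (and later excluded from masks).  More than
    ``max_invalid_fraction`` of invalid pixels raises
    :class:`ReferenceFrameError`.
    """
    if raw.units != "dn":
        raise ConfigurationError("black_white_correct expects a DN cube")
    dark, white = refs.dark, refs.white
    if dark.ndim == 2:
        dark = dark[..., None]
        white = white[..., None]
    if dark.shape[0] != raw.shape[0] or dark.shape[1] != raw.shape[1]:
        raise ConfigurationError("reference frame shape does not match cube")
    denom = white - dark
    invalid = np.any(np.isclose(denom, 0.0), axis=2) if denom.ndim == 3 else np.isclose(denom, 0.0)
    if invalid.mean() > max_invalid_fraction:
        raise ReferenceFrameError(
            f"{invalid.mean():.1%} of pixels have white == dark reference"
        )
    safe = np.where(np.isclose(denom, 0.0), 1.0, denom)
    corrected_dn = DN_FULL_SCALE * (raw.values - dark) / safe
    corrected_dn[invalid] = np.nan
    reflectance = corrected_dn / DN_FULL_SCALE
    return SpectralCube(np.nan_to_num(reflectance, nan=0.0), raw.wavelengths,
                        units="reflectance"), ~invalid


@dataclass
class BandMathSpec:
    """How to build the scalar band-math image used for segmentation."""

    kind: str = "ndvi"          # "ndvi" (ratio) | "single" (one band)
    nir_nm: float = 800.0
    red_nm: float = 670.0
    threshold: float | None = None  # None -> Otsu
    keep_largest: bool = True


def band_math_image(cube: SpectralCube, spec: BandMathSpec) -> np.ndarray:
    if spec.kind == "single":
        return cube.values[:, :, cube.band_nearest(spec.nir_nm)]
    if spec.kind != "ndvi":
        raise ConfigurationError(f"unknown band-math kind {spec.kind!r}")
    nir = cube.values[:, :, cube.band_nearest(spec.nir_nm)]
    red = cube.values[:, :, cube.band_nearest(spec.red_nm)]
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        img = np.where(np.isclose(denom, 0.0), 0.0, (nir - red) / denom)
    return img


def segment_leaf(
    cube: SpectralCube,
    spec: BandMathSpec | None = None,
    valid: np.ndarray | None = None,
) -> LeafMask:
    """Foreground mask from band math + thresholding (+ largest component).

    The default ratio image is invariant to a global multiplicative
    illumination change; the threshold defaults to Otsu's method on the
    band-math image.  Raises :class:`SegmentationError` when the image
    has no contrast or the mask comes out empty.
    """
    spec = spec or BandMathSpec()
    if cube.units != "reflectance":
        raise ConfigurationError("segment_leaf expects a reflectance cube")
    img = band_math_image(cube, spec)
    if spec.threshold is None:
        if np.ptp(img) < 1e-12:
            raise SegmentationError("band-math image is constant: no leaf/background contrast")
        thr = float(threshold_otsu(img))
    else:
        thr = float(spec.threshold)
    mask = img > thr
    if valid is not None:
        mask &= valid
    if spec.keep_largest and mask.any():
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    if not mask.any():
        raise SegmentationError(f"empty mask at threshold {thr:.4g}")
    return LeafMask(mask)


def mean_spectrum(cube: SpectralCube, mask: LeafMask) -> np.ndarray:
    """Arithmetic mean over mask pixels, each band independently."""
    if mask.values.shape != cube.shape[:2]:
        raise ConfigurationError("mask shape does not match cube")
    if mask.pixel_count < 1:
        raise SegmentationError("cannot average over an empty mask")
    return cube.values[mask.values].mean(axis=0)


def extract_mean_spectra(
    items,
    wavelengths: np.ndarray | None = None,
) -> SpectralMatrix:
    """Stack leaf-mean spectra into a samples x bands matrix.

    *items* is an ordered iterable of ``(sample_id, period, cube, mask)``;
    row order follows the iterable (acquisition order).
    """
    ids, periods, rows = [], [], []
    wl = wavelengths
    for sample_id, period, cube, mask in items:
        if mask.pixel_count < 1:
            raise SegmentationError(f"sample {sample_id!r} has an empty mask")
        if wl is None:
            wl = cube.wavelengths
        elif cube.n_bands != len(wl):
            raise ConfigurationError(f"sample {sample_id!r} has a mismatched band count")
        ids.append(sample_id)
        periods.append(period)
        rows.append(mean_spectrum(cube, mask))
    if not rows:
        raise ConfigurationError("no samples to extract")
    return SpectralMatrix(np.stack(rows), wl, ids, np.asarray(periods))
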