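"""Seeded synthetic drought experiments.

Emulates the structure of a greenhouse drought time-course on tea
seedlings: ``n_periods`` sampling dates, ``leaves_per_period`` leaves per
date, each leaf assayed in triplicate for four stress markers
(malondialdehyde MDA, electrolyte leakage EL, dark-adapted Fv/Fm,
soluble saccharide SS), and one hyperspectral reflectance spectrum (or
image cube) per leaf.

The generative model is deliberately simple and fully disclosed in the
ground-truth ledger so every downstream stage can be tested against it:

* a latent drought level ``d`` rises linearly over periods from 0 to 1;
* each analyte follows a linear response in ``d`` inside its published
  descriptive range, plus leaf-level Gaussian variation and per-assay
  Gaussian noise (three repeats, averaged);
* a leaf's reflectance spectrum is a smooth vegetation-like reference
  curve plus absorption/plateau features (green peak ~550 nm,
  chlorophyll well ~670 nm, red-edge sigmoid 700-750 nm, water band
  ~970 nm, visible and NIR plateaus) whose amplitudes are *affine* in
  the leaf's standardized biochemistry — so a linear model can in
  principle recover the biochemistry exactly in the noise-free limit,
  and the informative bands are localized;
* image cubes place that spectrum inside an elliptical leaf over a flat
  background, apply per-pixel multiplicative scatter and additive
  baseline (so scatter correction has something to remove), and encode
  to camera digital numbers so that black/white correction inverts the
  encoding exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .containers import (
    DN_FULL_SCALE,
    LeafMask,
    ReferenceFrames,
    SpectralCube,
    SpectralMatrix,
    default_wavelengths,
)
from .errors import ConfigurationError

# Published descriptive ranges (min, max) per analyte; the generator is
# clamped/parameterized to these.
ANALYTE_RANGES: dict[str, tuple[float, float]] = {
    "MDA": (3.26, 9.61),
    "EL": (18.76, 49.70),
    "FvFm": (0.60, 0.92),
    "SS": (5.10, 13.10),
}
#: Analytes whose level rises with drought; Fv/Fm falls.
INCREASING = ("MDA", "EL", "SS")
ANALYTES = ("MDA", "EL", "FvFm", "SS")

#: Display statistics of the composite drought-damage degree (level scale).
DDD_LEVEL_MEAN = 6.07
DDD_LEVEL_SD = 1.40


@dataclass
class DesignSpec:
    """Experimental design of a synthetic drought time-course."""

    n_periods: int = 6
    leaves_per_period: int = 30
    assay_repeats: int = 3
    n_bands: int = 176
    wavelength_range: tuple[float, float] = (400.0, 1100.0)
    seed: int = 0
    #: leaf-to-leaf biological variation, as a fraction of each analyte's range
    noise_sd: float = 0.05
    #: per-assay noise (fraction of range); None -> half of noise_sd
    assay_noise_sd: float | None = None
    #: iid reflectance noise added per band to each leaf's spectrum
    spectral_noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.n_periods < 1:
            raise ConfigurationError("n_periods must be >= 1")
        if self.leaves_per_period < 1 or self.assay_repeats < 1:
            raise ConfigurationError("leaves_per_period and assay_repeats must be >= 1")
        if self.n_bands < 8:
            raise ConfigurationError("n_bands must be >= 8")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ConfigurationError("wavelength_range must be strictly increasing")
        if self.noise_sd < 0 or self.spectral_noise_sd < 0:
            raise ConfigurationError("noise levels must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_periods * self.leaves_per_period

    @property
    def assay_sd(self) -> float:
        return 0.5 * self.noise_sd if self.assay_noise_sd is None else self.assay_noise_sd

    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return default_wavelengths(self.n_bands, lo, hi)


def drought_level(period: np.ndarray | int, n_periods: int) -> np.ndarray:
    """Latent drought severity d in [0, 1], linear in sampling period."""
    period = np.asarray(period, dtype=float)
    if n_periods == 1:
        return np.zeros_like(period)
    return (period - 1.0) / (n_periods - 1.0)


def _curve_bounds(spec: DesignSpec, analyte: str) -> tuple[float, float]:
    # Inset the deterministic response so that noisy draws stay inside the
    # published [min, max] with ~3.5 sigma to spare (hard clip as safety net).
    lo, hi = ANALYTE_RANGES[analyte]
    rng_width = hi - lo
    total_sd = np.hypot(spec.noise_sd, spec.assay_sd / np.sqrt(spec.assay_repeats))
    margin = 3.5 * total_sd * rng_width
    if 2 * margin >= rng_width:
        raise ConfigurationError("noise_sd too large for the analyte range")
    return lo + margin, hi - margin


def response_curve(spec: DesignSpec, analyte: str, d: np.ndarray) -> np.ndarray:
    """Deterministic drought response of *analyte* at drought level *d*."""
    lo_m, hi_m = _curve_bounds(spec, analyte)
    d = np.asarray(d, dtype=float)
    if analyte in INCREASING:
        return lo_m + (hi_m - lo_m) * d
    return hi_m - (hi_m - lo_m) * d


def _truth_table(spec: DesignSpec) -> pd.DataFrame:
    """Per-leaf latent (assay-noise-free) biochemistry."""
    rng = np.random.default_rng([spec.seed, 1])
    periods = np.repeat(np.arange(1, spec.n_periods + 1), spec.leaves_per_period)
    d = drought_level(periods, spec.n_periods)
    out = {"period": periods}
    for analyte in ANALYTES:
        lo, hi = ANALYTE_RANGES[analyte]
        base = response_curve(spec, analyte, d)
        out[analyte] = base + spec.noise_sd * (hi - lo) * rng.standard_normal(d.size)
    df = pd.DataFrame(out)
    df.insert(0, "sample_id", [f"S{p:02d}-{i + 1:02d}" for p, i in
                               zip(periods, np.tile(np.arange(spec.leaves_per_period),
                                                    spec.n_periods))])
    return df


def generate_biochemistry(spec: DesignSpec, keep_repeats: bool = False) -> pd.DataFrame:
    """Simulate the per-sample biochemistry table.

    Each leaf's latent value is assayed ``assay_repeats`` times with
    Gaussian assay noise; by default the repeat mean is reported (one row
    per leaf).  ``keep_repeats=True`` instead returns the long table with
    one row per assay repeat.  Reported analyte values are clipped to the
    published descriptive ranges; soil moisture falls linearly from 50%
    to 10% over the time-course.  A composite drought-damage column (DDD,
    display level scale) is attached to the repeat-mean table.
    """
    truth = _truth_table(spec)
    rng = np.random.default_rng([spec.seed, 2])
    n = len(truth)
    rows = []
    for analyte in ANALYTES:
        lo, hi = ANALYTE_RANGES[analyte]
        reps = (truth[analyte].to_numpy()[:, None]
                + spec.assay_sd * (hi - lo) * rng.standard_normal((n, spec.assay_repeats)))
        rows.append(np.clip(reps, lo, hi))
    d = drought_level(truth["period"].to_numpy(), spec.n_periods)
    soil = 50.0 - 40.0 * d + (1.5 * rng.standard_normal(n) if spec.noise_sd > 0 else 0.0)
    soil = np.clip(soil, 0.0, 100.0)

    if keep_repeats:
        long = pd.DataFrame({
            "sample_id": np.repeat(truth["sample_id"].to_numpy(), spec.assay_repeats),
            "period": np.repeat(truth["period"].to_numpy(), spec.assay_repeats),
            "repeat": np.tile(np.arange(1, spec.assay_repeats + 1), n),
        })
        for analyte, reps in zip(ANALYTES, rows):
            long[analyte] = reps.reshape(-1)
        long["soil_moisture"] = np.repeat(soil, spec.assay_repeats)
        return long

    table = truth[["sample_id", "period"]].copy()
    for analyte, reps in zip(ANALYTES, rows):
        table[analyte] = reps.mean(axis=1)
    table["soil_moisture"] = soil
    table["DDD"] = _ddd_level(table)
    return table


def _ddd_level(table: pd.DataFrame) -> np.ndarray:
    """Composite drought-damage degree on the display level scale.

    Fixed composite weights (0.359, 0.341, 0.300) on the z-scores of MDA,
    EL and SS, rescaled so the column has the published level-scale mean
    and SD.  Import is deferred to avoid a module cycle.
    """
    from .drought_index import PAPER_WEIGHTS

    z = np.column_stack([
        (table[a] - table[a].mean()) / table[a].std(ddof=1) for a in ("MDA", "EL", "SS")
    ])
    y = z @ np.asarray(PAPER_WEIGHTS)
    sd = y.std(ddof=1)
    if sd == 0:
        return np.full(len(table), DDD_LEVEL_MEAN)
    return DDD_LEVEL_MEAN + DDD_LEVEL_SD * (y - y.mean()) / sd


# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------

def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


#: Spectral features: name -> (shape kind, params).  Shapes are unit-height.
_FEATURES = {
    "green_peak": ("gauss", 550.0, 30.0),
    "chlorophyll_well": ("gauss", 670.0, 22.0),
    "water_band": ("gauss", 970.0, 30.0),
    "visible_plateau": ("lowpass", 700.0, 10.0),
    "nir_plateau": ("highpass", 750.0, 10.0),
}

#: Affine feature amplitudes: feature -> {analyte: coefficient on z-score}.
#: z-scores use the fixed design standardization (range midpoint / half-range),
#: so all samples of all runs share one coefficient ledger.
_FEATURE_COEFS: dict[str, dict[str, float]] = {
    "green_peak": {"FvFm": -0.025, "MDA": 0.010},
    "chlorophyll_well": {"MDA": 0.022, "EL": 0.008},
    "water_band": {"SS": 0.030, "EL": 0.012},
    # drought combination: visible reflectance up, NIR down
    "visible_plateau": {"MDA": 0.005, "EL": 0.005, "SS": 0.005, "FvFm": -0.005},
    "nir_plateau": {"MDA": -0.0125, "EL": -0.0125, "SS": -0.0125, "FvFm": 0.0125},
}


def _feature_shape(name: str, wl: np.ndarray) -> np.ndarray:
    kind, a, b = _FEATURES[name]
    if kind == "gauss":
        return _gauss(wl, a, b)
    if kind == "lowpass":
        return _sigmoid((a - wl) / b)
    return _sigmoid((wl - a) / b)


def reference_curve(wl: np.ndarray) -> np.ndarray:
    """Vegetation-like reflectance at the design mid-point biochemistry."""
    base = 0.10 + 0.45 * _sigmoid((wl - 725.0) / 12.0)
    base = base + 0.05 * _gauss(wl, 550.0, 30.0)
    base = base - 0.04 * _gauss(wl, 670.0, 22.0)
    base = base - 0.10 * _gauss(wl, 970.0, 30.0)
    return base


def standardize_biochem(values: dict | pd.Series) -> dict[str, float]:
    """Design z-scores: (value - range midpoint) / half-range per analyte."""
    z = {}
    for analyte in ANALYTES:
        lo, hi = ANALYTE_RANGES[analyte]
        z[analyte] = (float(values[analyte]) - 0.5 * (lo + hi)) / (0.5 * (hi - lo))
    return z


def spectral_coefficients(wl: np.ndarray) -> np.ndarray:
    """Bands x 4 matrix C with spectrum = reference + C @ z (z in ANALYTES order)."""
    C = np.zeros((wl.size, len(ANALYTES)))
    for feat, coefs in _FEATURE_COEFS.items():
        shape = _feature_shape(feat, wl)
        for analyte, c in coefs.items():
            C[:, ANALYTES.index(analyte)] += c * shape
    return C


def spectrum_from_biochem(values: dict | pd.Series, wl: np.ndarray) -> np.ndarray:
    """Noise-free leaf reflectance spectrum for one biochemistry row.

    Affine in the design z-scores of (MDA, EL, FvFm, SS); equals
    :func:`reference_curve` exactly when every analyte sits at its range
    midpoint.  Output lies in (0, 1) for any biochemistry within the
    published ranges.
    """
    wl = np.asarray(wl, dtype=float)
    if wl.min() < 400.0 - 1e-9 or wl.max() > 1100.0 + 1e-9:
        raise ConfigurationError("wavelengths must lie within 400-1100 nm")
    if np.any(np.diff(wl) <= 0):
        raise ConfigurationError("wavelengths must be sorted ascending")
    z = standardize_biochem(values)
    zv = np.array([z[a] for a in ANALYTES])
    return reference_curve(wl) + spectral_coefficients(wl) @ zv


def informative_bands(wl: np.ndarray, analyte: str, rel_threshold: float = 0.1) -> np.ndarray:
    """Bands where *analyte*'s spectral coefficient exceeds ``rel_threshold``
    of its own maximum absolute value — the planted signal for selector tests."""
    c = spectral_coefficients(wl)[:, ANALYTES.index(analyte)]
    return np.flatnonzero(np.abs(c) > rel_threshold * np.abs(c).max())


# ---------------------------------------------------------------------------
# Spectral matrix and ledger
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthLedger:
    """Everything the generator knows, for parameter-recovery tests."""

    analyte_ranges: dict
    response_bounds: dict
    feature_coefs: dict
    coefficient_matrix: np.ndarray  # bands x analytes
    wavelengths: np.ndarray
    informative: dict  # analyte -> list of band indices
    truth: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "analyte_ranges": self.analyte_ranges,
            "response_bounds": self.response_bounds,
            "feature_coefs": self.feature_coefs,
            "coefficient_matrix": self.coefficient_matrix.tolist(),
            "wavelengths": self.wavelengths.tolist(),
            "informative": {k: [int(i) for i in v] for k, v in self.informative.items()},
            "truth": self.truth.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticExperiment:
    biochem: pd.DataFrame
    spectra: SpectralMatrix
    ledger: GroundTruthLedger


def generate_spectra(spec: DesignSpec) -> tuple[SpectralMatrix, pd.DataFrame]:
    """Leaf-mean spectra for every sample (bypassing the imaging stage).

    Spectra are built from the *latent* per-leaf biochemistry (the assay
    repeats observe the leaf, not the other way round), with iid Gaussian
    reflectance noise of ``spec.spectral_noise_sd`` per band.
    """
    truth = _truth_table(spec)
    wl = spec.wavelengths()
    rng = np.random.default_rng([spec.seed, 3])
    rows = np.stack([spectrum_from_biochem(r, wl) for _, r in truth.iterrows()])
    rows = rows + spec.spectral_noise_sd * rng.standard_normal(rows.shape)
    matrix = SpectralMatrix(rows, wl, truth["sample_id"].tolist(),
                            truth["period"].to_numpy())
    return matrix, truth


def generate_experiment(spec: DesignSpec) -> SyntheticExperiment:
    """Biochemistry + spectra + ground-truth ledger, all from one seed."""
    biochem = generate_biochemistry(spec)
    spectra, truth = generate_spectra(spec)
    wl = spec.wavelengths()
    ledger = GroundTruthLedger(
        analyte_ranges={k: list(v) for k, v in ANALYTE_RANGES.items()},
        response_bounds={a: list(_curve_bounds(spec, a)) for a in ANALYTES},
        feature_coefs=_FEATURE_COEFS,
        coefficient_matrix=spectral_coefficients(wl),
        wavelengths=wl,
        informative={a: informative_bands(wl, a) for a in ANALYTES},
        truth=truth,
    )
    return SyntheticExperiment(biochem, spectra, ledger)


# ---------------------------------------------------------------------------
# Image cubes
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Geometry and nuisance parameters of one synthetic leaf image."""

    image_height: int = 64
    image_width: int = 64
    leaf_center: tuple[float, float] | None = None  # (row, col); None -> centre
    leaf_axes: tuple[float, float] | None = None    # semi-axes; None -> 35%/28%
    background_reflectance: float = 0.25
    scatter_slope_sd: float = 0.05
    baseline_sd: float = 0.01
    noise_sd: float = 0.005
    dark_dn: float = 1000.0
    white_dn: float = 60000.0

    def __post_init__(self) -> None:
        if self.image_height < 4 or self.image_width < 4:
            raise ConfigurationError("image must be at least 4 x 4")
        if self.leaf_center is None:
            self.leaf_center = ((self.image_height - 1) / 2.0, (self.image_width - 1) / 2.0)
        if self.leaf_axes is None:
            self.leaf_axes = (0.35 * self.image_height, 0.28 * self.image_width)
        r0, c0 = self.leaf_center
        ar, ac = self.leaf_axes
        if ar <= 0 or ac <= 0:
            raise ConfigurationError("leaf axes must be positive")
        if (r0 - ar < 0 or r0 + ar > self.image_height - 1
                or c0 - ac < 0 or c0 + ac > self.image_width - 1):
            raise ConfigurationError("leaf ellipse must lie fully inside the image")
        if not 0.0 <= self.background_reflectance < 1.0:
            raise ConfigurationError("background reflectance must be in [0, 1)")
        if self.white_dn <= self.dark_dn:
            raise ConfigurationError("white level must exceed dark level")

    def ellipse_mask(self) -> np.ndarray:
        rr, cc = np.mgrid[0:self.image_height, 0:self.image_width]
        r0, c0 = self.leaf_center
        ar, ac = self.leaf_axes
        return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def generate_cube(
    scene: SceneSpec,
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    seed: int = 0,
) -> tuple[SpectralCube, ReferenceFrames, LeafMask]:
    """Raw-DN cube + reference frames + true mask for one leaf.

    Leaf pixels carry ``slope_px * spectrum + baseline_px + noise`` with
    per-pixel slope ~ N(1, scatter_slope_sd) and baseline ~
    N(0, baseline_sd); the background is spectrally flat.  Reflectance is
    encoded as ``DN = dark + (white - dark) * reflectance`` so black/white
    correction recovers it exactly.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if spectrum.ndim != 1 or spectrum.size != wavelengths.size:
        raise ConfigurationError("spectrum and wavelengths must be 1-D and equal length")
    contrast_band = int(np.argmin(np.abs(wavelengths - 800.0)))
    contrast = abs(spectrum[contrast_band] - scene.background_reflectance)
    if scene.noise_sd > 0 and contrast <= 3.0 * scene.noise_sd:
        raise ConfigurationError(
            "leaf/background contrast at the 800 nm band must exceed 3 x noise_sd"
        )
    rng = np.random.default_rng(seed)
    h, w = scene.image_height, scene.image_width
    mask = scene.ellipse_mask()
    refl = np.broadcast_to(scene.background_reflectance, (h, w, spectrum.size)).copy()
    slope = 1.0 + scene.scatter_slope_sd * rng.standard_normal((h, w))
    baseline = scene.baseline_sd * rng.standard_normal((h, w))
    leaf = (slope[..., None] * spectrum[None, None, :] + baseline[..., None])
    if scene.noise_sd > 0:
        leaf = leaf + scene.noise_sd * rng.standard_normal(leaf.shape)
    refl[mask] = leaf[mask]
    dark = np.full((h, w), scene.dark_dn)
    white = np.full((h, w), scene.white_dn)
    dn = dark[..., None] + (white - dark)[..., None] * refl
    cube = SpectralCube(dn, wavelengths, units="dn")
    return cube, ReferenceFrames(dark, white), LeafMask(mask)


def iter_cubes(
    spec: DesignSpec, scene: SceneSpec | None = None
) -> Iterator[tuple[str, SpectralCube, ReferenceFrames, LeafMask]]:
    """Yield (sample_id, raw cube, reference frames, true mask) per leaf.

    Cubes are generated lazily — the default 180-leaf design at desk
    scale (64 x 64 x 176) would otherwise hold ~1 GB in memory.
    """
    scene = scene or SceneSpec()
    truth = _truth_table(spec)
    wl = spec.wavelengths()
    for i, (_, row) in enumerate(truth.iterrows()):
        spectrum = spectrum_from_biochem(row, wl)
        cube, refs, mask = generate_cube(scene, spectrum, wl, seed=(spec.seed, 4, i))
        yield row["sample_id"], cube, refs, mask
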