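"""In-memory containers shared across the pipeline.

A :class:`SpectralCube` is a rows x cols x bands raster with a wavelength
axis, either in raw digital numbers (DN) straight off the camera or in
reflectance fraction after black/white correction.  A
:class:`SpectralMatrix` is the samples x bands table of leaf-mean
reflectance that all chemometric stages operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Full-scale digital number of the camera's quantization.
DN_FULL_SCALE = 65552.0


@dataclass
class SpectralCube:
    """3-D raster (rows x cols x bands) with a wavelength axis in nm."""

    values: np.ndarray
    wavelengths: np.ndarray
    units: str = "dn"  # "dn" | "reflectance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("cube must be rows x cols x bands")
        if self.values.shape[2] != self.wavelengths.size:
            raise ConfigurationError(
                f"band axis ({self.values.shape[2]}) does not match "
                f"wavelength vector ({self.wavelengths.size})"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if self.units not in ("dn", "reflectance"):
            raise ConfigurationError(f"unknown units {self.units!r}")

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_nearest(self, nm: float) -> int:
        """Index of the band whose centre wavelength is closest to *nm*."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass
class ReferenceFrames:
    """Dark-current (D) and full-scale white (W) reference frames in DN."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ConfigurationError("dark and white frames must share a shape")


@dataclass
class LeafMask:
    """Binary foreground mask over the cube's spatial grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ConfigurationError("mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class SpectralMatrix:
    """Samples x bands mean-reflectance table.

    ``values[i, j]`` is the leaf-mean reflectance of sample *i* at band
    *j*; rows are kept in acquisition (time) order, which the
    calibration/prediction split relies on.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]
    periods: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.periods = np.asarray(self.periods, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.values.shape
        if self.wavelengths.size != p:
            raise ConfigurationError("wavelength vector does not match band count")
        if len(self.sample_ids) != n or self.periods.size != n:
            raise ConfigurationError("sample_ids/periods do not match row count")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("spectral matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def select_rows(self, idx: np.ndarray) -> "SpectralMatrix":
        idx = np.asarray(idx)
        return SpectralMatrix(
            self.values[idx],
            self.wavelengths,
            [self.sample_ids[i] for i in idx],
            self.periods[idx],
        )

    def select_bands(self, idx: np.ndarray) -> "SpectralMatrix":
        idx = np.asarray(idx)
        return SpectralMatrix(
            self.values[:, idx], self.wavelengths[idx], self.sample_ids, self.periods
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"{w:g}" for w in self.wavelengths]
        )
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "period", self.periods)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralMatrix":
        df = pd.read_csv(path)
        wl = np.array([float(c) for c in df.columns[2:]])
        return cls(
            df.iloc[:, 2:].to_numpy(float),
            wl,
            df["sample_id"].astype(str).tolist(),
            df["period"].to_numpy(int),
        )


def default_wavelengths(n_bands: int = 176, low: float = 400.0, high: float = 1100.0) -> np.ndarray:
    """Band-centre grid: *n_bands* evenly spaced centres from *low* to *high*.

    With the default 176 bands over 400-1100 nm this is the 4 nm grid
    400, 404, ..., 1100 (band i at 400 + 4i nm), matching the camera's
    band spacing.
    """
    if n_bands < 2:
        raise ConfigurationError("n_bands must be >= 2")
    return np.linspace(low, high, n_bands)
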