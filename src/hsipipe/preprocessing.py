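"""Spectral preprocessing: MSC, finite-difference derivatives, Savitzky-Golay.

Stages compose left-to-right into named chains such as ``MSC+2D+S-G (17)``:
multiplicative scatter correction first, then the second finite-difference
derivative, then Savitzky-Golay smoothing with a 17-band window.  All
fitted statistics (the MSC reference mean) come from calibration rows
only and are applied unchanged to prediction rows — prediction data never
leak into fitting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectralMatrix
from .errors import ConfigurationError, DegenerateDataError

# ---------------------------------------------------------------------------
# Multiplicative scatter correction
# ---------------------------------------------------------------------------


@dataclass
class MSCReference:
    """Calibration-set mean spectrum plus the per-sample fit diagnostics."""

    mean_spectrum: np.ndarray
    slopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    intercepts: np.ndarray = field(default_factory=lambda: np.empty(0))


def msc_fit(calibration: SpectralMatrix) -> MSCReference:
    """Bandwise mean of the calibration rows — the MSC reference."""
    if calibration.n_samples < 2 or calibration.n_bands < 2:
        raise ConfigurationError("MSC needs at least 2 calibration rows and 2 bands")
    return MSCReference(calibration.values.mean(axis=0))


def msc_apply(ref: MSCReference, matrix: SpectralMatrix) -> SpectralMatrix:
    """Regress each row on the reference and invert the fitted affine map.

    For each sample i, ordinary least squares gives ``row_i ~= m_i * ref
    + b_i``; the corrected row is ``(row_i - b_i) / m_i``.  A row that is
    (numerically) uncorrelated with the reference has ``m_i ~ 0`` and is
    rejected as degenerate.
    """
    xbar = ref.mean_spectrum
    if xbar.size != matrix.n_bands:
        raise ConfigurationError("MSC reference band count does not match matrix")
    xc = xbar - xbar.mean()
    denom = float(xc @ xc)
    if denom < 1e-24:
        raise DegenerateDataError("MSC reference spectrum is constant")
    rows = matrix.values
    slopes = (rows - rows.mean(axis=1, keepdims=True)) @ xc / denom
    intercepts = rows.mean(axis=1) - slopes * xbar.mean()
    if np.any(np.abs(slopes) < 1e-12):
        bad = int(np.argmin(np.abs(slopes)))
        raise DegenerateDataError(f"sample {matrix.sample_ids[bad]!r} has MSC slope ~ 0")
    corrected = (rows - intercepts[:, None]) / slopes[:, None]
    ref.slopes, ref.intercepts = slopes, intercepts
    return SpectralMatrix(corrected, matrix.wavelengths, matrix.sample_ids, matrix.periods)


# ---------------------------------------------------------------------------
# Finite-difference derivatives
# ---------------------------------------------------------------------------


def _uniform_spacing(wavelengths: np.ndarray) -> float:
    steps = np.diff(wavelengths)
    if steps.size == 0:
        raise ConfigurationError("need at least 2 bands for a derivative")
    if np.ptp(steps) > 1e-6 * abs(steps.mean()):
        raise ConfigurationError("derivative requires a uniform wavelength grid")
    return float(steps.mean())


def derivative(matrix: SpectralMatrix, order: int) -> SpectralMatrix:
    """Forward-difference spectral derivative.

    Order 1: ``(y[i+1] - y[i]) / dl`` (loses the trailing band).
    Order 2: ``(y[i+1] - 2 y[i] + y[i-1]) / dl**2`` (loses both end bands).
    Order 0 is the identity.  The wavelength axis is trimmed to the
    retained interior bands.
    """
    if order not in (0, 1, 2):
        raise ConfigurationError("derivative order must be 0, 1 or 2")
    if order == 0:
        return matrix
    if matrix.n_bands < order + 1:
        raise ConfigurationError(f"need more than {order} bands for order {order}")
    dl = _uniform_spacing(matrix.wavelengths)
    y = matrix.values
    if order == 1:
        vals = (y[:, 1:] - y[:, :-1]) / dl
        wl = matrix.wavelengths[:-1]
    else:
        vals = (y[:, 2:] - 2.0 * y[:, 1:-1] + y[:, :-2]) / dl**2
        wl = matrix.wavelengths[1:-1]
    return SpectralMatrix(vals, wl, matrix.sample_ids, matrix.periods)


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------


def savitzky_golay(matrix: SpectralMatrix, window: int, polyorder: int = 2) -> SpectralMatrix:
    """Local least-squares polynomial smoothing with mirror edge padding."""
    if window % 2 == 0 or window < 3:
        raise ConfigurationError("S-G window must be odd and >= 3")
    if window > matrix.n_bands:
        raise ConfigurationError(
            f"S-G window {window} exceeds the {matrix.n_bands}-band axis"
        )
    if polyorder >= window:
        raise ConfigurationError("S-G polyorder must be smaller than the window")
    vals = savgol_filter(matrix.values, window, polyorder, axis=1, mode="mirror")
    return SpectralMatrix(vals, matrix.wavelengths, matrix.sample_ids, matrix.periods)


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    """An ordered preprocessing chain.

    ``stages`` is a list of stage names in execution order: ``"MSC"``,
    ``"1D"``, ``"2D"`` or ``"SG"``; the S-G stage uses ``sg_window`` and
    ``sg_polyorder``.
    """

    stages: list[str] = field(default_factory=list)
    sg_window: int = 17
    sg_polyorder: int = 2

    _VALID = ("MSC", "1D", "2D", "SG")

    def __post_init__(self) -> None:
        self.stages = [s.upper() for s in self.stages]
        for s in self.stages:
            if s not in self._VALID:
                raise ConfigurationError(f"unknown preprocessing stage {s!r}")
        if "SG" in self.stages:
            if self.sg_window % 2 == 0 or self.sg_window < 3:
                raise ConfigurationError("sg_window must be odd and >= 3")
            if self.sg_polyorder >= self.sg_window:
                raise ConfigurationError("sg_polyorder must be < sg_window")

    @property
    def name(self) -> str:
        """Human-readable chain name, e.g. ``MSC+2D+S-G (17)``."""
        parts = []
        for s in self.stages:
            parts.append(f"S-G ({self.sg_window})" if s == "SG" else s)
        return "+".join(parts) if parts else "raw"

    @classmethod
    def parse(cls, name: str, sg_polyorder: int = 2) -> "PreprocessConfig":
        """Parse chain names like ``MSC+2D+S-G (17)`` or ``msc+1d+sg(5)``."""
        if name.strip().lower() in ("", "raw", "none"):
            return cls([])
        stages: list[str] = []
        window = 17
        for token in name.split("+"):
            token = token.strip()
            m = re.fullmatch(r"S[-–]?[GD]\s*\(?\s*(\d+)\s*\)?", token, re.I)
            if m:
                stages.append("SG")
                window = int(m.group(1))
            elif token.upper() in ("MSC", "1D", "2D"):
                stages.append(token.upper())
            else:
                raise ConfigurationError(f"cannot parse chain token {token!r}")
        return cls(stages, sg_window=window, sg_polyorder=sg_polyorder)


@dataclass
class FittedChain:
    """A chain with its calibration-fitted statistics, reusable on new rows."""

    config: PreprocessConfig
    msc_ref: MSCReference | None = None

    def transform(self, matrix: SpectralMatrix) -> SpectralMatrix:
        out = matrix
        for stage in self.config.stages:
            if stage == "MSC":
                out = msc_apply(self.msc_ref, out)
            elif stage in ("1D", "2D"):
                out = derivative(out, int(stage[0]))
            else:
                out = savitzky_golay(out, self.config.sg_window, self.config.sg_polyorder)
        return out


def fit_chain(config: PreprocessConfig, calibration: SpectralMatrix) -> FittedChain:
    """Fit chain statistics on calibration rows only.

    The MSC reference is computed from the calibration matrix at the
    point in the chain where the MSC stage sits (i.e. after any earlier
    stages).
    """
    chain = FittedChain(config)
    out = calibration
    for stage in config.stages:
        if stage == "MSC":
            chain.msc_ref = msc_fit(out)
            out = msc_apply(chain.msc_ref, out)
        elif stage in ("1D", "2D"):
            out = derivative(out, int(stage[0]))
        else:
            out = savitzky_golay(out, config.sg_window, config.sg_polyorder)
    return chain


def apply_chain(
    config: PreprocessConfig,
    calibration: SpectralMatrix,
    prediction: SpectralMatrix | None = None,
) -> tuple[SpectralMatrix, SpectralMatrix | None]:
    """Fit on calibration, transform both sets; prediction rows never leak."""
    chain = fit_chain(config, calibration)
    cal_out = chain.transform(calibration)
    pred_out = chain.transform(prediction) if prediction is not None else None
    return cal_out, pred_out
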