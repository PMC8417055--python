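"""Composite drought-damage degree (DDD).

Three stress markers rise with drought — malondialdehyde (MDA),
electrolyte leakage (EL) and soluble saccharide (SS).  Each is
standardized to a z-score, the 3 x 3 correlation matrix is
eigendecomposed, and principal components are retained until their
cumulative eigenvalue fraction exceeds a threshold (0.85 by default).
Component weights are the contribution-weighted absolute loadings,
normalized to unit sum, giving the composite

    Y = w1 * z(MDA) + w2 * z(EL) + w3 * z(SS)

The published fixed weights (0.359, 0.341, 0.300) are available as the
``paper_fixed`` source; Fv/Fm is deliberately excluded (it falls with
drought).  An affine display transform maps Y onto a positive "level"
scale for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError, MeasurementError

DDD_ANALYTES = ("MDA", "EL", "SS")
PAPER_WEIGHTS = (0.359, 0.341, 0.300)


def electrolyte_leakage(c1: float, c2: float) -> float:
    """Relative permeability of conductivity: 100 * C1 / C2 (percent).

    C1 is the conductivity after vacuum infiltration, C2 after boiling
    (total electrolytes); C1 cannot exceed C2.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if np.any(c2 <= 0):
        raise MeasurementError("post-boil conductivity C2 must be positive")
    if np.any(c1 < 0) or np.any(c1 > c2):
        raise MeasurementError("need 0 <= C1 <= C2")
    out = 100.0 * c1 / c2
    return float(out) if out.ndim == 0 else out


@dataclass
class StandardizedTriplet:
    """z-scores of (MDA, EL, SS) plus the reference statistics used."""

    z: np.ndarray
    means: np.ndarray
    sds: np.ndarray


@dataclass
class DDDWeights:
    """Composite weights with their PCA provenance."""

    weights: np.ndarray                       # (w1, w2, w3) for MDA, EL, SS
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_retained: int = 0
    cumulative_contribution: float = np.nan
    source: str = "derived"                   # "derived" | "paper_fixed"
    ref_means: np.ndarray | None = None
    ref_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != 3 or np.any(self.weights <= 0):
            raise ConfigurationError("need 3 positive weights")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("weights must sum to 1")

    @classmethod
    def paper_fixed(cls, ref_means=None, ref_sds=None) -> "DDDWeights":
        return cls(np.asarray(PAPER_WEIGHTS), source="paper_fixed",
                   ref_means=ref_means, ref_sds=ref_sds)

    def to_json(self, path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_retained": self.n_retained,
            "cumulative_contribution": (None if np.isnan(self.cumulative_contribution)
                                        else self.cumulative_contribution),
            "source": self.source,
            "ref_means": None if self.ref_means is None else list(self.ref_means),
            "ref_sds": None if self.ref_sds is None else list(self.ref_sds),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def standardize(table: pd.DataFrame) -> StandardizedTriplet:
    """z-scores of MDA, EL, SS against the table's own means/SDs (ddof = 1)."""
    for a in DDD_ANALYTES:
        if a not in table:
            raise ConfigurationError(f"missing analyte column {a!r}")
    vals = table[list(DDD_ANALYTES)].to_numpy(float)
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise DegenerateDataError("an analyte has zero variance")
    return StandardizedTriplet((vals - means) / sds, means, sds)


def derive_ddd_weights(
    table: pd.DataFrame, contribution_threshold: float = 0.85
) -> DDDWeights:
    """PCA-based composite weights from a biochemistry table.

    Retains leading eigencomponents of the MDA/EL/SS correlation matrix
    until their cumulative eigenvalue fraction exceeds the threshold;
    each analyte's weight is the contribution-weighted sum of its
    absolute loadings over the retained components, normalized to unit
    sum.
    """
    if len(table) < 4:
        raise ConfigurationError("need at least 4 samples to derive weights")
    if not 0.0 < contribution_threshold <= 1.0:
        raise ConfigurationError("contribution_threshold must be in (0, 1]")
    triplet = standardize(table)
    corr = np.corrcoef(triplet.z, rowvar=False)
    weights = weights_from_correlation(corr, contribution_threshold)
    weights.ref_means = triplet.means
    weights.ref_sds = triplet.sds
    return weights


def weights_from_correlation(
    corr: np.ndarray, contribution_threshold: float = 0.85
) -> DDDWeights:
    """Composite weights from a 3 x 3 correlation matrix (see
    :func:`derive_ddd_weights` for the recipe)."""
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (3, 3):
        raise ConfigurationError("need a 3 x 3 correlation matrix")
    if not 0.0 < contribution_threshold <= 1.0:
        raise ConfigurationError("contribution_threshold must be in (0, 1]")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    contrib = evals / evals.sum()
    cum = np.cumsum(contrib)
    n_keep = 1 + int(np.argmax(cum > contribution_threshold))
    if cum[n_keep - 1] <= contribution_threshold:
        raise ConfigurationError("contribution threshold unreachable")
    # |loading| per retained component, made basis-invariant under eigenvalue
    # ties: within a tied group the individual eigenvectors are arbitrary, so
    # the rms loading over the whole group stands in for each member's
    # |loading| (it reduces to |v_j| for a non-degenerate eigenvalue).
    groups = np.concatenate([[0], np.cumsum(np.abs(np.diff(evals)) > 1e-8 * evals[0])])
    abs_loadings = np.empty_like(evecs)
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        L = np.sqrt((evecs[:, members] ** 2).sum(axis=1) / members.size)
        abs_loadings[:, members] = L[:, None]
    raw = abs_loadings[:, :n_keep] @ contrib[:n_keep]
    weights = raw / raw.sum()
    return DDDWeights(
        weights,
        eigenvalues=evals,
        n_retained=n_keep,
        cumulative_contribution=float(cum[n_keep - 1]),
        source="derived",
    )


def compute_ddd(
    values: pd.DataFrame | np.ndarray,
    weights: DDDWeights,
    standardized: bool = False,
) -> np.ndarray:
    """Composite score Y = w1 X1 + w2 X2 + w3 X3 on standardized inputs.

    *values* is either an (n, 3) array of z-scores (``standardized=True``)
    or a table/array of raw MDA, EL, SS, standardized against the
    reference statistics stored with *weights*.
    """
    if isinstance(values, pd.DataFrame):
        for a in DDD_ANALYTES:
            if a not in values:
                raise ConfigurationError(f"missing analyte column {a!r}")
        arr = values[list(DDD_ANALYTES)].to_numpy(float)
    else:
        arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[1] != 3:
        raise ConfigurationError("need the (MDA, EL, SS) triplet")
    if not standardized:
        if weights.ref_means is None or weights.ref_sds is None:
            raise ConfigurationError(
                "raw values need reference statistics stored with the weights"
            )
        arr = (arr - np.asarray(weights.ref_means)) / np.asarray(weights.ref_sds)
    return arr @ weights.weights


def to_level(
    y: np.ndarray, offset: float = 6.07, scale: float = 1.40, y_sd: float | None = None
) -> np.ndarray:
    """Affine display transform onto the positive "level" scale.

    ``level = offset + scale * y / y_sd`` — with the defaults the level
    scale reproduces the published descriptive mean (6.07) and SD (1.40)
    when ``y_sd`` is the composite's own SD.  The parameters are a
    display convention, not an estimated quantity.
    """
    y = np.asarray(y, dtype=float)
    sd = float(np.std(y, ddof=1)) if y_sd is None else float(y_sd)
    if sd <= 0:
        raise DegenerateDataError("composite scores have zero spread")
    return offset + scale * y / sd
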