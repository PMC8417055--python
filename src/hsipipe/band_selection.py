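"""Characteristic-wavelength selection: UVE, CARS and SPA.

All three selectors operate on a preprocessed calibration matrix X
(samples x bands) and a single target y, and return a
:class:`BandSubset` with per-method diagnostics:

* **UVE** (uninformative variable elimination) appends artificial
  noise bands, runs leave-one-out PLS to collect per-band regression
  coefficients, and keeps the real bands whose coefficient stability
  (mean / SD over the leave-one-out fits) exceeds what pure noise can
  reach.
* **CARS** (competitive adaptive reweighted sampling) runs a fixed
  number of Monte-Carlo PLS fits on row subsamples, shrinking the live
  band set along an exponentially decreasing retention schedule and
  resampling bands with probability proportional to |coefficient|; the
  iteration with the lowest cross-validated RMSE wins.
* **SPA** (successive projections algorithm) grows chains of minimally
  collinear bands by repeatedly adding the band with the largest
  residual norm after orthogonal projection onto the span of the chain,
  then picks the chain and length with the lowest cross-validated RMSE
  of an ordinary least-squares fit.

Hyperparameter defaults follow the originating chemometrics literature;
everything is exposed in :class:`SelectorConfig` and all sampling flows
from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DegenerateDataError, EmptySelectionError
from .regression import choose_components, contiguous_folds, pls_coefficients, pls_cv_rmse

SELECTOR_NAMES = ("UVE", "CARS", "SPA")


@dataclass
class BandSubset:
    """Selected band indices plus selector diagnostics."""

    indices: np.ndarray
    wavelengths: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.indices.size < 1:
            raise EmptySelectionError(f"{self.method}: empty band subset")
        if np.unique(self.indices).size != self.indices.size:
            raise ConfigurationError("band indices must be unique")
        if np.any(np.diff(self.indices) <= 0):
            raise ConfigurationError("band indices must be sorted ascending")
        if self.wavelengths.size != self.indices.size:
            raise ConfigurationError("wavelengths must match indices")

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    def to_json(self, path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, list):
                return [_clean(x) for x in v]
            return v

        payload = {
            "method": self.method,
            "n_selected": self.n_selected,
            "indices": self.indices.tolist(),
            "wavelengths": self.wavelengths.tolist(),
            "diagnostics": {k: _clean(v) for k, v in self.diagnostics.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SelectorConfig:
    """Hyperparameters shared by the three selectors."""

    # UVE
    uve_noise_count: int | None = None       # None -> n_bands
    uve_noise_scale: float = 1e-5            # x mean |X|
    uve_cutoff_quantile: float = 0.99
    # CARS
    cars_runs: int = 50
    cars_subsample: float = 0.8
    # SPA
    spa_min_size: int = 5
    spa_max_size: int = 30
    spa_starts: list[int] | None = None      # None -> all bands
    # shared
    pls_components: int | str = "cv"
    max_components: int = 15
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cars_subsample < 1.0:
            raise ConfigurationError("cars_subsample must be in (0, 1)")
        if self.cars_runs < 2:
            raise ConfigurationError("cars_runs must be >= 2")
        if not 0.0 < self.uve_cutoff_quantile <= 1.0:
            raise ConfigurationError("uve_cutoff_quantile must be in (0, 1]")
        if self.spa_min_size < 1 or self.spa_max_size < self.spa_min_size:
            raise ConfigurationError("need 1 <= spa_min_size <= spa_max_size")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


def _resolve_components(X, y, config: SelectorConfig) -> int:
    if config.pls_components == "cv":
        return choose_components(X, y, config.cv_folds, config.max_components)
    return int(config.pls_components)


def _check_xy(X, y, config: SelectorConfig) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ConfigurationError("X must be samples x bands, y one value per sample")
    if y.std() == 0:
        raise DegenerateDataError("target has zero variance")
    return X, y


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing value; ties broken by lower index."""
    return np.lexsort((np.arange(values.size), -values))


# ---------------------------------------------------------------------------
# UVE
# ---------------------------------------------------------------------------


def select_uve(X, y, wavelengths, config: SelectorConfig | None = None) -> BandSubset:
    """Uninformative variable elimination.

    The cutoff is the ``uve_cutoff_quantile`` quantile of |stability|
    over the artificial noise bands; real bands whose |stability|
    exceeds it are retained.
    """
    config = config or SelectorConfig()
    X, y = _check_xy(X, y, config)
    n, p = X.shape
    ncomp = min(_resolve_components(X, y, config), n - 2, p)
    if n < 2 * ncomp:
        raise ConfigurationError("UVE needs at least 2 x PLS components rows")
    k = p if config.uve_noise_count is None else int(config.uve_noise_count)
    rng = np.random.default_rng(config.seed)
    scale = config.uve_noise_scale * float(np.abs(X).mean())
    noise = rng.uniform(0.0, 1.0, size=(n, k)) * scale
    Xa = np.hstack([X, noise])

    coefs = np.empty((n, p + k))
    rows = np.arange(n)
    for i in range(n):
        keep = rows != i
        coef, _ = pls_coefficients(Xa[keep], y[keep], ncomp)
        coefs[i] = coef
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = np.where(sd > 0, coefs.mean(axis=0) / sd, np.inf)
    cutoff = float(np.quantile(np.abs(stability[p:]), config.uve_cutoff_quantile))
    retained = np.flatnonzero(np.abs(stability[:p]) > cutoff)
    if retained.size == 0:
        raise EmptySelectionError(
            f"UVE eliminated every band at cutoff {cutoff:.3g}; "
            "lower uve_cutoff_quantile"
        )
    wavelengths = np.asarray(wavelengths, dtype=float)
    return BandSubset(
        retained,
        wavelengths[retained],
        "UVE",
        diagnostics={
            "stability": stability[:p],
            "noise_stability": stability[p:],
            "cutoff": cutoff,
            "n_components": ncomp,
        },
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------


def _edf_ratios(p: int, runs: int) -> np.ndarray:
    """Exponentially decreasing retention fraction: r_1 = 1, r_N = 2 / p."""
    i = np.arange(1, runs + 1, dtype=float)
    k = np.log(p / 2.0) / (runs - 1)
    a = (p / 2.0) ** (1.0 / (runs - 1))
    return a * np.exp(-k * i)


def select_cars(X, y, wavelengths, config: SelectorConfig | None = None) -> BandSubset:
    """Competitive adaptive reweighted sampling."""
    config = config or SelectorConfig()
    X, y = _check_xy(X, y, config)
    n, p = X.shape
    ncomp_full = min(_resolve_components(X, y, config), n - 2, p)
    rng = np.random.default_rng(config.seed)
    ratios = _edf_ratios(p, config.cars_runs)
    n_sub = max(2, int(round(config.cars_subsample * n)))

    live = np.arange(p)
    subsets: list[np.ndarray] = []
    rmse_trace: list[float] = []
    sizes: list[int] = []
    for i, r in enumerate(ratios):
        rows = np.sort(rng.choice(n, size=n_sub, replace=False))
        ncomp = max(1, min(ncomp_full, live.size, n_sub - 2))
        coef, _ = pls_coefficients(X[np.ix_(rows, live)], y[rows], ncomp)
        weight = np.abs(coef)
        # forced shrink along the EDF schedule
        k = int(round(r * p))
        k = max(2, min(k, live.size))
        kept_local = _rank_desc(weight)[:k]
        kept = live[np.sort(kept_local)]
        w = weight[np.sort(kept_local)]
        # adaptive reweighted sampling among the kept bands
        if w.sum() <= 0:
            draws = kept
        else:
            draws = rng.choice(kept, size=k, replace=True, p=w / w.sum())
        live = np.unique(draws)
        ncomp_eval = max(1, min(ncomp_full, live.size))
        rmse = pls_cv_rmse(X[:, live], y, ncomp_eval, config.cv_folds)
        subsets.append(live.copy())
        rmse_trace.append(rmse)
        sizes.append(int(live.size))
    best = int(np.argmin(rmse_trace))
    idx = subsets[best]
    wavelengths = np.asarray(wavelengths, dtype=float)
    return BandSubset(
        idx,
        wavelengths[idx],
        "CARS",
        diagnostics={
            "subset_sizes": sizes,
            "cv_rmse": rmse_trace,
            "best_iteration": best,
            "edf_ratios": ratios,
            "n_components": ncomp_full,
        },
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------


def _spa_chain(Xc: np.ndarray, start: int, max_size: int, tol: float) -> tuple[list[int], list[float]]:
    """Greedy projection chain from one starting band.

    Returns the selected indices in order and the projection norm of
    each addition; stops early on rank collapse.
    """
    n, p = Xc.shape
    R = Xc.copy()
    norms0 = np.linalg.norm(Xc, axis=0)
    chain = [start]
    chain_norms = [float(norms0[start])]
    selected = np.zeros(p, dtype=bool)
    selected[start] = True
    for _ in range(max_size - 1):
        xk = R[:, chain[-1]]
        nk = float(xk @ xk)
        if nk < tol:
            break
        R = R - np.outer(xk, (xk @ R) / nk)
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        j = int(_rank_desc(norms)[0])
        if norms[j] ** 2 < tol:
            break
        chain.append(j)
        chain_norms.append(float(norms[j]))
        selected[j] = True
    return chain, chain_norms


def _ols_cv_rmse(X: np.ndarray, y: np.ndarray, folds: int) -> float:
    sq = 0.0
    n = len(y)
    for test_idx in contiguous_folds(n, folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        A = np.column_stack([np.ones(train.size), X[train]])
        beta, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        At = np.column_stack([np.ones(test_idx.size), X[test_idx]])
        resid = y[test_idx] - At @ beta
        sq += float(resid @ resid)
    return float(np.sqrt(sq / n))


def select_spa(X, y, wavelengths, config: SelectorConfig | None = None) -> BandSubset:
    """Successive projections algorithm.

    Chains are scored with the cross-validated RMSE of an ordinary
    least-squares fit on the chain's bands (the classical SPA scoring);
    chain size is limited to ``min(rows - 1, bands)``.
    """
    config = config or SelectorConfig()
    X, y = _check_xy(X, y, config)
    n, p = X.shape
    max_size = min(config.spa_max_size, n - 1 - (n // config.cv_folds), p)
    min_size = min(config.spa_min_size, max_size)
    Xc = X - X.mean(axis=0)
    tol = 1e-12 * float(np.linalg.norm(Xc) ** 2 / max(1, p)) + 1e-30
    starts = (range(p) if config.spa_starts is None
              else [int(s) for s in config.spa_starts])

    best = None  # (rmse, size, start, chain)
    all_rmse: dict[int, list[float]] = {}
    for start in starts:
        chain, chain_norms = _spa_chain(Xc, start, max_size, tol)
        if len(chain) < min_size:
            continue
        rmses = []
        for size in range(min_size, len(chain) + 1):
            rmse = _ols_cv_rmse(X[:, chain[:size]], y, config.cv_folds)
            rmses.append(rmse)
            cand = (rmse, size, start)
            if best is None or cand < (best[0], best[1], best[2]):
                best = (rmse, size, start, chain[:size], chain_norms[:size])
        all_rmse[start] = rmses
    if best is None:
        raise DegenerateDataError(
            "SPA rank collapse: no chain reached the minimum subset size"
        )
    rmse, size, start, chain, chain_norms = best
    idx = np.sort(np.asarray(chain, dtype=int))
    wavelengths = np.asarray(wavelengths, dtype=float)
    return BandSubset(
        idx,
        wavelengths[idx],
        "SPA",
        diagnostics={
            "start_band": start,
            "chain": list(chain),
            "projection_norms": chain_norms,
            "cv_rmse": rmse,
            "cv_rmse_by_size": all_rmse.get(start, []),
        },
    )


SELECTORS = {"UVE": select_uve, "CARS": select_cars, "SPA": select_spa}


def select_bands(method: str, X, y, wavelengths, config: SelectorConfig | None = None) -> BandSubset:
    method = method.upper()
    if method not in SELECTORS:
        raise ConfigurationError(f"unknown selector {method!r}")
    return SELECTORS[method](X, y, wavelengths, config)


def summarize_ranges(wavelengths_nm, gap_nm: float = 4.0) -> list[str]:
    """Collapse selected wavelengths into display intervals.

    Consecutive centres no more than *gap_nm* apart merge into one
    ``"466-535"``-style range; isolated bands print alone.
    """
    wl = np.sort(np.asarray(wavelengths_nm, dtype=float))
    if wl.size == 0:
        return []
    out = []
    lo = prev = wl[0]
    for w in wl[1:]:
        if w - prev > gap_nm + 1e-9:
            out.append(f"{lo:g}" if lo == prev else f"{lo:g}–{prev:g}")
            lo = w
        prev = w
    out.append(f"{lo:g}" if lo == prev else f"{lo:g}–{prev:g}")
    return out
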