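"""Regression back-ends: PLS (NIPALS, from scratch), SVR and RF.

PLS1 is implemented directly with the NIPALS decomposition because the
whole chemometric stack (wavelength selectors included) is built around
its regression-coefficient vector; support-vector and random-forest
regression are delegated to scikit-learn behind the same model surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import ConfigurationError, DegenerateDataError

# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS decomposition for a single response.

    Returns (W, P, q) with weights W (p x a), loadings P (p x a) and
    response loadings q (a,), computed on centered data; may stop early
    if the residual collapses.
    """
    Xr = X.copy()
    yr = y.copy()
    p = X.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    a = 0
    for a in range(n_components):
        w = Xr.T @ yr
        wn = np.linalg.norm(w)
        if wn < 1e-14:
            break
        w /= wn
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        W[:, a] = w
        P[:, a] = Xr.T @ t / tt
        q[a] = float(yr @ t) / tt
        Xr -= np.outer(t, P[:, a])
        yr = yr - q[a] * t
    else:
        a = n_components
        return W, P, q
    return W[:, :a], P[:, :a], q[:a]


def pls_coefficients(
    X: np.ndarray, y: np.ndarray, n_components: int
) -> tuple[np.ndarray, float]:
    """Centered-data PLS1 regression vector and intercept.

    ``yhat = X @ coef + intercept``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_components)
    if W.shape[1] == 0:
        coef = np.zeros(X.shape[1])
    else:
        coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, y_mean - float(x_mean @ coef)


def contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    """Contiguous index blocks for time-ordered cross-validation."""
    if k < 2 or k > n:
        raise ConfigurationError(f"cannot make {k} folds from {n} samples")
    return [idx for idx in np.array_split(np.arange(n), k)]


def pls_cv_rmse(X: np.ndarray, y: np.ndarray, n_components: int, folds: int = 5) -> float:
    """Pooled out-of-fold RMSE of a PLS1 fit over contiguous blocks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sq = 0.0
    for test_idx in contiguous_folds(len(y), folds):
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        ncomp = min(n_components, len(train) - 1, X.shape[1])
        coef, icpt = pls_coefficients(X[train], y[train], ncomp)
        resid = y[test_idx] - (X[test_idx] @ coef + icpt)
        sq += float(resid @ resid)
    return float(np.sqrt(sq / len(y)))


def choose_components(
    X: np.ndarray, y: np.ndarray, folds: int = 5, max_components: int = 15
) -> int:
    """Component count minimizing the contiguous-block RMSECV."""
    n, p = np.asarray(X).shape
    cap = max(1, min(max_components, p, n - 1 - (n // folds)))
    rmses = [pls_cv_rmse(X, y, a, folds) for a in range(1, cap + 1)]
    return 1 + int(np.argmin(rmses))


@dataclass
class PLSModel:
    """Fitted PLS1 model: ``yhat = X @ coef + intercept``."""

    coef: np.ndarray
    intercept: float
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef.size:
            raise ConfigurationError(
                f"model expects {self.coef.size} bands, got {X.shape[1]}"
            )
        return X @ self.coef + self.intercept


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | str = "cv",
    folds: int = 5,
    max_components: int = 15,
) -> PLSModel:
    """Fit PLS1; ``n_components="cv"`` picks the count by 5-fold RMSECV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise DegenerateDataError("target has zero variance")
    if n_components == "cv":
        ncomp = choose_components(X, y, folds, max_components)
    else:
        ncomp = int(n_components)
        if ncomp < 1 or ncomp > min(X.shape[0] - 1, X.shape[1]):
            raise ConfigurationError(
                f"n_components must be in [1, min(rows - 1, bands)], got {ncomp}"
            )
    coef, icpt = pls_coefficients(X, y, ncomp)
    return PLSModel(coef, icpt, ncomp)


# ---------------------------------------------------------------------------
# SVR / RF back-ends
# ---------------------------------------------------------------------------


def fit_svr(X: np.ndarray, y: np.ndarray, config: dict | None = None, seed: int = 0):
    """RBF-kernel support-vector regression on standardized inputs.

    Explicit hyperparameters in *config* (``C``, ``gamma``, ``epsilon``)
    are used as-is; otherwise a small deterministic CV grid
    (3 x 3 x 2 over C, gamma, epsilon) picks them.  The scaler is part
    of the pipeline, so it is fitted on calibration rows only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise DegenerateDataError("target has zero variance")
    config = config or {}
    if {"C", "gamma", "epsilon"} <= set(config):
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="rbf", C=config["C"], gamma=config["gamma"],
                        epsilon=config["epsilon"])),
        ])
        return pipe.fit(X, y)
    grid = {
        "svr__C": config.get("C_grid", [1.0, 10.0, 100.0]),
        "svr__gamma": config.get("gamma_grid", ["scale", 0.01, 0.1]),
        "svr__epsilon": config.get("epsilon_grid", [0.01, 0.1]),
    }
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    cv = KFold(n_splits=min(5, len(y)), shuffle=False)
    search = GridSearchCV(pipe, grid, cv=cv, scoring="neg_root_mean_squared_error")
    search.fit(X, y)
    return search.best_estimator_


def fit_rf(X: np.ndarray, y: np.ndarray, config: dict | None = None, seed: int = 0):
    """Random-forest regression (500 trees by default), seeded."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    config = config or {}
    rf = RandomForestRegressor(
        n_estimators=config.get("n_estimators", 500),
        max_depth=config.get("max_depth"),
        random_state=seed,
        n_jobs=1,
    )
    return rf.fit(X, y)


# ---------------------------------------------------------------------------
# Unified model surface
# ---------------------------------------------------------------------------

MODEL_KINDS = ("PLS", "SVM", "RF")


@dataclass
class RegressionModel:
    """One fitted model plus the provenance needed to reapply it."""

    kind: str
    estimator: object
    band_indices: np.ndarray
    chain_name: str = "raw"
    target: str = ""
    seed: int = 0
    n_input_bands: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_input_bands:
            raise ConfigurationError(
                f"model expects {self.n_input_bands} bands, got {X.shape[1]}"
            )
        yhat = (self.estimator.predict(X) if self.kind != "PLS"
                else self.estimator.predict(X))
        return np.asarray(yhat, dtype=float)


def fit_model(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    config: dict | None = None,
    chain_name: str = "raw",
    target: str = "",
    band_indices: np.ndarray | None = None,
) -> RegressionModel:
    """Fit one of the three back-ends on (already preprocessed) X."""
    kind = kind.upper()
    if kind not in MODEL_KINDS:
        raise ConfigurationError(f"unknown model kind {kind!r}")
    X = np.asarray(X, dtype=float)
    if kind == "PLS":
        est = fit_pls(X, y, **(config or {}))
    elif kind == "SVM":
        est = fit_svr(X, y, config, seed)
    else:
        est = fit_rf(X, y, config, seed)
    return RegressionModel(
        kind=kind,
        estimator=est,
        band_indices=(np.arange(X.shape[1]) if band_indices is None
                      else np.asarray(band_indices)),
        chain_name=chain_name,
        target=target,
        seed=seed,
        n_input_bands=X.shape[1],
    )


# ---------------------------------------------------------------------------
# Serialization (JSON manifest; sklearn payloads via joblib)
# ---------------------------------------------------------------------------


def save_model(model: RegressionModel, directory) -> Path:
    """Write a versioned model container: ``model.json`` (+ ``payload.pkl``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "kind": model.kind,
        "band_indices": [int(i) for i in model.band_indices],
        "chain_name": model.chain_name,
        "target": model.target,
        "seed": model.seed,
        "n_input_bands": model.n_input_bands,
    }
    if model.kind == "PLS":
        manifest["pls"] = {
            "coef": model.estimator.coef.tolist(),
            "intercept": model.estimator.intercept,
            "n_components": model.estimator.n_components,
        }
    else:
        import joblib

        joblib.dump(model.estimator, directory / "payload.pkl")
        manifest["payload"] = "payload.pkl"
    (directory / "model.json").write_text(json.dumps(manifest, indent=1))
    return directory / "model.json"


def load_model(directory) -> RegressionModel:
    directory = Path(directory)
    manifest = json.loads((directory / "model.json").read_text())
    if manifest["kind"] == "PLS":
        est = PLSModel(
            np.array(manifest["pls"]["coef"]),
            manifest["pls"]["intercept"],
            manifest["pls"]["n_components"],
        )
    else:
        import joblib

        est = joblib.load(directory / manifest["payload"])
    return RegressionModel(
        kind=manifest["kind"],
        estimator=est,
        band_indices=np.array(manifest["band_indices"], dtype=int),
        chain_name=manifest["chain_name"],
        target=manifest["target"],
        seed=manifest["seed"],
        n_input_bands=manifest["n_input_bands"],
    )
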