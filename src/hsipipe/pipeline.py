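"""Grid orchestration: preprocessing chains x selectors x models x targets.

Runs the full pipeline — time-ordered 3:1 split, preprocessing fitted on
the calibration set, wavelength selection on the calibration set, model
fitting, evaluation on the held-out prediction set — for every
configuration of a grid, collects per-configuration reports, and picks
the best configuration per target (highest Rp, ties broken by higher
RPD then lower RMSEP).  Every source of randomness derives from one
root seed via a stable per-configuration hash, so a rerun with the same
seed reproduces the manifest bit for bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .band_selection import SelectorConfig, select_bands, summarize_ranges
from .containers import SpectralMatrix
from .errors import ConfigurationError, HsiPipeError
from .evaluation import evaluate, rmsecv, split_by_time
from .preprocessing import PreprocessConfig, apply_chain, fit_chain
from .regression import fit_model
from .synthetic import ANALYTES

VALID_TARGETS = tuple(ANALYTES) + ("DDD",)


@dataclass
class GridSpec:
    """The evaluated grid of pipeline configurations."""

    chains: list[str] = field(default_factory=lambda: ["MSC+2D+S-G (17)"])
    selectors: list[str] = field(default_factory=lambda: ["UVE", "CARS", "SPA"])
    models: list[str] = field(default_factory=lambda: ["PLS", "SVM", "RF"])
    targets: list[str] = field(default_factory=lambda: list(VALID_TARGETS))
    ratio: tuple[int, int] = (3, 1)
    seed: int = 0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not (self.chains and self.selectors and self.models and self.targets):
            raise ConfigurationError("grid lists must be non-empty")
        for t in self.targets:
            if t not in VALID_TARGETS:
                raise ConfigurationError(
                    f"unknown target {t!r}; valid: {VALID_TARGETS}"
                )


def derive_seed(root: int, *parts: str) -> int:
    """Stable sub-seed below 2**31 from the root seed and config labels."""
    h = zlib.crc32("||".join(parts).encode())
    return (root * 1_000_003 + h) % (2**31 - 1)


@dataclass
class RunManifest:
    grid: dict
    reports: list[dict]
    failures: list[dict]
    best: dict

    def to_json(self) -> str:
        return json.dumps(
            {"grid": self.grid, "reports": self.reports,
             "failures": self.failures, "best": self.best},
            indent=1, sort_keys=True,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _align(biochem: pd.DataFrame, spectra: SpectralMatrix) -> pd.DataFrame:
    table = biochem.set_index("sample_id")
    missing = [s for s in spectra.sample_ids if s not in table.index]
    if missing:
        raise ConfigurationError(f"biochemistry missing samples: {missing[:5]}")
    return table.loc[spectra.sample_ids].reset_index()


def run_grid(biochem: pd.DataFrame, spectra: SpectralMatrix, grid: GridSpec) -> RunManifest:
    """Execute every grid configuration; per-configuration errors are
    recorded (not fatal) unless the whole grid fails."""
    table = _align(biochem, spectra)
    split = split_by_time(spectra.n_samples, spectra.periods, grid.ratio)
    cal_raw = spectra.select_rows(split.calibration)
    pred_raw = spectra.select_rows(split.prediction)

    reports: list[dict] = []
    failures: list[dict] = []
    for chain_name in grid.chains:
        chain_cfg = PreprocessConfig.parse(chain_name)
        cal_pp, pred_pp = apply_chain(chain_cfg, cal_raw, pred_raw)
        for target in grid.targets:
            y = table[target].to_numpy(float)
            y_cal, y_pred = y[split.calibration], y[split.prediction]
            for selector in grid.selectors:
                sel_seed = derive_seed(grid.seed, chain_cfg.name, selector, target)
                try:
                    subset = select_bands(
                        selector, cal_pp.values, y_cal, cal_pp.wavelengths,
                        SelectorConfig(seed=sel_seed, cv_folds=grid.cv_folds),
                    )
                except HsiPipeError as exc:
                    failures.append({
                        "chain": chain_cfg.name, "selector": selector,
                        "model": None, "target": target, "error": str(exc),
                    })
                    continue
                for model_kind in grid.models:
                    descriptor = f"{chain_cfg.name}+{selector}+{model_kind}"
                    mdl_seed = derive_seed(grid.seed, descriptor, target)
                    try:
                        report = _run_one(
                            chain_cfg, subset.indices, model_kind, mdl_seed,
                            cal_raw, pred_raw, cal_pp, pred_pp, y_cal, y_pred,
                            descriptor, grid.cv_folds,
                        )
                    except HsiPipeError as exc:
                        failures.append({
                            "chain": chain_cfg.name, "selector": selector,
                            "model": model_kind, "target": target,
                            "error": str(exc),
                        })
                        continue
                    reports.append({
                        "target": target,
                        "chain": chain_cfg.name,
                        "selector": selector,
                        "model": model_kind,
                        "descriptor": descriptor,
                        "n_selected": subset.n_selected,
                        "band_ranges": summarize_ranges(subset.wavelengths),
                        "band_indices": subset.indices.tolist(),
                        **{k: (v if isinstance(v, str) else float(v))
                           for k, v in report.as_row().items() if k != "Modeling method"},
                    })
    if not reports:
        raise ConfigurationError(f"every grid configuration failed: {failures}")

    best: dict = {}
    for target in grid.targets:
        rows = [r for r in reports if r["target"] == target]
        if not rows:
            continue
        rows.sort(key=lambda r: (-r["Rp"], -r["RPD"], r["RMSEP"], r["descriptor"]))
        best[target] = {
            "descriptor": rows[0]["descriptor"],
            "Rp": rows[0]["Rp"], "RPD": rows[0]["RPD"], "RMSEP": rows[0]["RMSEP"],
            "criterion": "max Rp, ties by max RPD then min RMSEP",
        }
    grid_dict = {
        "chains": list(grid.chains), "selectors": list(grid.selectors),
        "models": list(grid.models), "targets": list(grid.targets),
        "ratio": list(grid.ratio), "seed": grid.seed, "cv_folds": grid.cv_folds,
    }
    return RunManifest(grid_dict, reports, failures, best)


def _run_one(
    chain_cfg: PreprocessConfig,
    band_idx: np.ndarray,
    model_kind: str,
    seed: int,
    cal_raw: SpectralMatrix,
    pred_raw: SpectralMatrix,
    cal_pp: SpectralMatrix,
    pred_pp: SpectralMatrix,
    y_cal: np.ndarray,
    y_pred: np.ndarray,
    descriptor: str,
    folds: int,
):
    X_cal = cal_pp.values[:, band_idx]
    X_pred = pred_pp.values[:, band_idx]
    model = fit_model(model_kind, X_cal, y_cal, seed=seed,
                      chain_name=chain_cfg.name, band_indices=band_idx)

    def fit_predict(X_train_raw, y_train, X_test_raw):
        # refit the chain statistics on the fold's training block only
        train_m = SpectralMatrix(
            X_train_raw, cal_raw.wavelengths,
            [f"t{i}" for i in range(len(X_train_raw))],
            np.zeros(len(X_train_raw), dtype=int),
        )
        test_m = SpectralMatrix(
            X_test_raw, cal_raw.wavelengths,
            [f"p{i}" for i in range(len(X_test_raw))],
            np.zeros(len(X_test_raw), dtype=int),
        )
        chain = fit_chain(chain_cfg, train_m)
        Xtr = chain.transform(train_m).values[:, band_idx]
        Xte = chain.transform(test_m).values[:, band_idx]
        fold_model = fit_model(model_kind, Xtr, y_train, seed=seed,
                               chain_name=chain_cfg.name, band_indices=band_idx)
        return fold_model.predict(Xte)

    rmsecv_value = rmsecv(fit_predict, cal_raw.values, y_cal, folds)
    return evaluate(
        descriptor, y_cal, model.predict(X_cal), y_pred, model.predict(X_pred),
        rmsecv_value,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def accuracy_table(manifest: RunManifest) -> pd.DataFrame:
    """Accuracy-table CSV layout: one row per configuration."""
    rows = []
    for i, r in enumerate(manifest.reports, start=1):
        rows.append({
            "Index": r["target"],
            "Modeling method": r["descriptor"],
            "Rcal": round(r["Rcal"], 4),
            "RMSEC": round(r["RMSEC"], 4),
            "RMSECV": round(r["RMSECV"], 4),
            "Rp": round(r["Rp"], 4),
            "RMSEP": round(r["RMSEP"], 4),
            "RPD": round(r["RPD"], 4),
        })
    return pd.DataFrame(rows)


def band_table(manifest: RunManifest) -> pd.DataFrame:
    """Band-screening summary: selected counts and merged nm ranges."""
    seen = set()
    rows = []
    for r in manifest.reports:
        key = (r["target"], r["chain"], r["selector"])
        if key in seen:
            continue
        seen.add(key)
        rows.append({
            "Index": r["target"],
            "Screening method": f"{r['chain']}+{r['selector']}",
            "Number of bands": r["n_selected"],
            "Characteristic bands (nm)": ", ".join(r["band_ranges"]),
        })
    return pd.DataFrame(rows)


def write_report(manifest: RunManifest, out_dir) -> dict[str, Path]:
    """Write manifest.json, accuracy_table.csv, band_table.csv, report.md."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out / "manifest.json",
        "accuracy": out / "accuracy_table.csv",
        "bands": out / "band_table.csv",
        "markdown": out / "report.md",
    }
    manifest.write(paths["manifest"])
    accuracy_table(manifest).to_csv(paths["accuracy"], index=False)
    band_table(manifest).to_csv(paths["bands"], index=False)
    lines = ["# Pipeline run report", "", "## Best configuration per target", ""]
    for target, info in manifest.best.items():
        lines.append(
            f"- **{target}**: {info['descriptor']} "
            f"(Rp = {info['Rp']:.3f}, RPD = {info['RPD']:.2f})"
        )
    if manifest.failures:
        lines += ["", "## Failed configurations", ""]
        for f in manifest.failures:
            lines.append(f"- {f['chain']}+{f['selector']}"
                         f"+{f['model'] or '?'} [{f['target']}]: {f['error']}")
    paths["markdown"].write_text("\n".join(lines) + "\n")
    return paths
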