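"""Predictor gap-filling.

Two regimes: ordinary predictors get a deterministic per-column median
fill; the four spaceborne-lidar structure attributes (rh100, pai,
fhd_normal, cover) — missing for 20–45% of cells because of sparse orbital
sampling — are reconstructed by regression forests on the seven optical
vegetation indices, which are gap-free.  For the mid and lower label sets
the forests are refit 10 times on bootstrap subsamples of up to 200,000
rows and predictions averaged; the upper set uses a single fit on all
complete rows.  Cross-validation repeats the same sampling protocol and
reports RMSE and out-of-sample R² with bootstrap-t confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .metrics import t_interval
from .world import GEDI_PREDICTORS, MODIS_PREDICTORS

SUBSAMPLE_CAP = 200_000  # bootstrap subsample size for mid/lower refits
N_REPEATS_MID_LOWER = 10


@dataclass(frozen=True)
class ImputerParams:
    """Regression-forest capacity for gap-filling.

    Moderately sized, leaf-regularised forests over per-tree bootstrap
    subsamples: the response surface being recovered is smooth in the seven
    optical indices, so deep fully-grown trees on full bootstraps buy no
    measurable accuracy at several times the cost.
    """

    n_trees: int = 25
    min_samples_leaf: int = 5
    max_features: float | str = 1.0
    max_samples: float | None = 0.25  # per-tree bootstrap fraction (None = n)


@dataclass
class ImputerReport:
    attribute: str
    rmse_mean: float
    rmse_ci: tuple[float, float]
    r2_mean: float
    r2_ci: tuple[float, float]
    n_iter: int

    def as_row(self) -> dict:
        return {
            "attribute": self.attribute,
            "rmse_mean": self.rmse_mean,
            "rmse_ci_low": self.rmse_ci[0],
            "rmse_ci_high": self.rmse_ci[1],
            "r2_mean": self.r2_mean,
            "r2_ci_low": self.r2_ci[0],
            "r2_ci_high": self.r2_ci[1],
            "n_iter": self.n_iter,
        }


def impute_general(table: pd.DataFrame, exclude: tuple[str, ...] = GEDI_PREDICTORS) -> pd.DataFrame:
    """Median-fill every missing value outside ``exclude``.

    Observed values are never altered.  A column that is entirely missing
    cannot be median-filled and raises.
    """
    out = table.copy()
    for col in out.columns:
        if col in exclude:
            continue
        if not pd.api.types.is_numeric_dtype(out[col]):
            continue
        if out[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if out[col].isna().any():
            out[col] = out[col].fillna(out[col].median())
    return out


def _fit_forest(X: np.ndarray, y: np.ndarray, params: ImputerParams, seed: int) -> RandomForestRegressor:
    max_samples = params.max_samples if params.max_samples and len(y) >= 8 else None
    rf = RandomForestRegressor(
        n_estimators=params.n_trees,
        min_samples_leaf=params.min_samples_leaf,
        max_features=params.max_features,
        max_samples=max_samples,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _level_models(
    X: np.ndarray, y: np.ndarray, level: str, rng: np.random.Generator, params: ImputerParams
) -> list[RandomForestRegressor]:
    if level == "upper":
        return [_fit_forest(X, y, params, int(rng.integers(2**31)))]
    models = []
    size = min(SUBSAMPLE_CAP, len(y))
    for _ in range(N_REPEATS_MID_LOWER):
        idx = rng.choice(len(y), size=size, replace=True)
        models.append(_fit_forest(X[idx], y[idx], params, int(rng.integers(2**31))))
    return models


def impute_gedi(
    table: pd.DataFrame,
    level: str,
    seed: int,
    params: ImputerParams = ImputerParams(),
    attributes: tuple[str, ...] = GEDI_PREDICTORS,
    features: tuple[str, ...] = MODIS_PREDICTORS,
) -> pd.DataFrame:
    """Fill missing lidar-structure attributes from the optical indices.

    Training rows are the cells where the attribute is observed; missing
    rows are predicted and filled (observed values untouched).  The mid
    and lower levels average 10 forests refit on bootstrap subsamples; the
    upper level fits once on everything.
    """
    if level not in ("lower", "mid", "upper"):
        raise ValueError(f"unknown level {level!r}")
    out = table.copy()
    rng = np.random.default_rng(seed)
    Xall = table.loc[:, list(features)].to_numpy()
    if np.isnan(Xall).any():
        raise ValueError("feature columns must be complete before lidar gap-filling")
    for attr in attributes:
        y = table[attr].to_numpy(dtype=float)
        observed = ~np.isnan(y)
        if not observed.any():
            raise ValueError(f"no complete training rows for attribute {attr!r}")
        if observed.all():
            continue
        models = _level_models(Xall[observed], y[observed], level, rng, params)
        Xmiss = Xall[~observed]
        pred = np.mean([m.predict(Xmiss) for m in models], axis=0)
        filled = y.copy()
        filled[~observed] = pred
        out[attr] = filled
    return out


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sse = np.sum((y_true - y_pred) ** 2)
    sst = np.sum((y_true - y_true.mean()) ** 2)
    return float(1.0 - sse / sst)


def crossvalidate_imputer(
    table: pd.DataFrame,
    level: str,
    n_iter: int = 20,
    seed: int = 0,
    params: ImputerParams = ImputerParams(),
    attributes: tuple[str, ...] = GEDI_PREDICTORS,
    features: tuple[str, ...] = MODIS_PREDICTORS,
) -> list[ImputerReport]:
    """Bootstrap cross-validation of the gap-filling forests.

    Each iteration draws the training rows *with replacement* (90% of n for
    the upper level, min(200,000, n) for mid/lower); rows never drawn form
    the test set.  RMSE and out-of-sample R² (1 − SSE/SST) are summarised
    as mean ± t(0.975, n_iter−1)·sd/√n_iter.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if level not in ("lower", "mid", "upper"):
        raise ValueError(f"unknown level {level!r}")
    rng = np.random.default_rng(seed)
    reports = []
    for attr in attributes:
        sub = table.loc[table[attr].notna(), list(features) + [attr]]
        X = sub.loc[:, list(features)].to_numpy()
        y = sub[attr].to_numpy(dtype=float)
        n = len(y)
        if n < 10:
            raise ValueError(f"too few complete rows ({n}) for attribute {attr!r}")
        train_size = int(round(0.9 * n)) if level == "upper" else min(SUBSAMPLE_CAP, n)
        rmses, r2s = [], []
        for _ in range(n_iter):
            drawn = rng.choice(n, size=train_size, replace=True)
            test = np.setdiff1d(np.arange(n), drawn, assume_unique=False)
            if test.size == 0:
                raise ValueError("bootstrap draw covered every row; dataset too small for CV")
            rf = _fit_forest(X[drawn], y[drawn], params, int(rng.integers(2**31)))
            pred = rf.predict(X[test])
            rmses.append(_rmse(y[test], pred))
            r2s.append(_r2(y[test], pred))
        rm, rlo, rhi = t_interval(rmses)
        qm, qlo, qhi = t_interval(r2s)
        reports.append(
            ImputerReport(attr, rm, (rlo, rhi), qm, (qlo, qhi), n_iter)
        )
    return reports


def linear_gedi_dataset(
    n: int, signal_share: float = 0.5, seed: int = 0, missing_rate: float = 0.0
) -> pd.DataFrame:
    """Synthetic benchmark for the gap-filler with a known recoverable R².

    The lidar attributes are exact linear functions of seven standard-normal
    optical indices plus independent noise, scaled so the linear signal
    explains ``signal_share`` of the variance; ``signal_share=1`` gives a
    noiseless (perfectly predictable) response.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(MODIS_PREDICTORS)))
    out = pd.DataFrame(X, columns=list(MODIS_PREDICTORS))
    for attr in GEDI_PREDICTORS:
        w = rng.normal(size=X.shape[1])
        w /= np.linalg.norm(w)
        signal = X @ w
        noise_sd = np.sqrt((1.0 - signal_share) / signal_share) if signal_share > 0 else np.inf
        y = signal + (noise_sd * rng.standard_normal(n) if signal_share < 1.0 else 0.0)
        if missing_rate > 0:
            y = y.astype(float)
            y[rng.random(n) < missing_rate] = np.nan
        out[attr] = y
    return out
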