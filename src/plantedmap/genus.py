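"""Dominant-genus mapping over the predicted planted extent.

Inventory plots record per-species basal area and stem counts.  Each
species' *importance value* (IV) is its percent basal area plus its
percent stem count, so IVs sum to 200 within a plot; the species with
maximal IV dominates the plot.  Plot dominants are majority-voted into
grid cells, rare genera (< 60 labelled cells) are dropped, classes are
balanced by combined under/over-sampling, and a random forest then
predicts the dominant genus of every planted cell from 52 predictors (the
full stack minus roadless area and the four lidar attributes, which are
too gappy).  Accuracy is assessed by 100-fold stratified 90/10 bootstrap
cross-validation with per-genus precision/recall/F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .grid import Grid
from .metrics import t_interval
from .world import GENUS_EXCLUDED_PREDICTORS, PREDICTOR_NAMES

logger = logging.getLogger(__name__)

#: Predictors used for genus classification (52 slots).
GENUS_PREDICTORS: tuple[str, ...] = tuple(
    p for p in PREDICTOR_NAMES if p not in GENUS_EXCLUDED_PREDICTORS
)
MIN_GENUS_SAMPLES = 60


def importance_values(plot: pd.DataFrame) -> pd.DataFrame:
    """Per-species importance values for one plot.

    ``plot`` has one row per species with ``basal_area_m2`` and ``stems``.
    Returns species, genus, iv (plus the two percent shares).  A plot with
    zero total basal area falls back to stem shares alone, doubled to keep
    the 200 scale, and is flagged in the log.
    """
    if len(plot) == 0:
        raise ValueError("plot has no species records")
    if (plot["basal_area_m2"] < 0).any() or (plot["stems"] < 1).any():
        raise ValueError("basal area must be >= 0 and stem counts >= 1")
    ba = plot["basal_area_m2"].to_numpy(dtype=float)
    n = plot["stems"].to_numpy(dtype=float)
    pct_n = 100.0 * n / n.sum()
    if ba.sum() == 0:
        logger.warning("plot with zero total basal area; importance values from stem counts only")
        pct_ba = pct_n.copy()
    else:
        pct_ba = 100.0 * ba / ba.sum()
    out = plot.loc[:, ["species", "genus"]].copy()
    out["pct_basal_area"] = pct_ba
    out["pct_stems"] = pct_n
    out["iv"] = pct_ba + pct_n
    return out


def dominant_species(plot: pd.DataFrame) -> tuple[str, str]:
    """(species, genus) with the highest importance value.

    Ties break by larger basal-area share, then lexicographically smaller
    species name; tie events are logged.
    """
    iv = importance_values(plot)
    best = iv["iv"].max()
    top = iv.loc[np.isclose(iv["iv"], best)]
    if len(top) > 1:
        logger.info("importance-value tie among %s", sorted(top["species"]))
        top = top.loc[np.isclose(top["pct_basal_area"], top["pct_basal_area"].max())]
        top = top.sort_values("species")
    row = top.iloc[0]
    return str(row["species"]), str(row["genus"])


def aggregate_dominant_genus(
    plots: pd.DataFrame,
    grid: Grid,
    planted_mask: pd.Series,
    min_samples: int = MIN_GENUS_SAMPLES,
) -> tuple[pd.Series, list[str]]:
    """Grid-level dominant genus over the planted extent.

    Only plots falling in planted cells contribute.  Per cell, the
    majority genus among plot dominants wins; ties exclude the cell
    (logged).  Genera labelling fewer than ``min_samples`` cells are
    dropped together with their cells.  Returns (cell_id -> genus Series,
    retained genus list).
    """
    if len(plots) == 0:
        logger.warning("no plots supplied; empty genus training set")
        return pd.Series(dtype=object), []
    row, col = grid.locate(plots["lon"].to_numpy(), plots["lat"].to_numpy())
    inside = grid.contains(row, col)
    cell = np.full(len(plots), -1)
    cell[inside] = grid.cell_id(row[inside], col[inside])
    planted_cells = set(planted_mask.index[planted_mask.astype(bool)])
    dominants: dict[int, list[str]] = {}
    for (pid, c), plot in plots.assign(_cell=cell).groupby(["plot_id", "_cell"]):
        if c not in planted_cells:
            continue
        _, genus = dominant_species(plot)
        dominants.setdefault(int(c), []).append(genus)
    if not dominants:
        logger.warning("no plots inside the planted extent; empty genus training set")
        return pd.Series(dtype=object), []
    labels: dict[int, str] = {}
    n_ties = 0
    for c, genera in dominants.items():
        counts = pd.Series(genera).value_counts()
        top = counts[counts == counts.max()]
        if len(top) > 1:
            n_ties += 1
            continue  # tied cell carries no genus label
        labels[c] = top.index[0]
    if n_ties:
        logger.info("aggregate_dominant_genus: %d cell(s) excluded for genus ties", n_ties)
    ser = pd.Series(labels, dtype=object).sort_index()
    counts = ser.value_counts()
    retained = sorted(counts.index[counts >= min_samples])
    dropped = sorted(set(counts.index) - set(retained))
    if dropped:
        logger.info("dropping rare genera (< %d cells): %s", min_samples, dropped)
    ser = ser.loc[ser.isin(retained)]
    return ser, retained


def balance_genus_classes(training: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Equalise genus counts at the rounded mean of the original counts.

    Larger classes are undersampled without replacement, smaller classes
    oversampled with replacement; deterministic given ``seed``.
    """
    counts = training["genus"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two genera to balance")
    target = int(round(counts.mean()))
    rng = np.random.default_rng(seed)
    parts = []
    for genus in sorted(counts.index):
        sub = training.loc[training["genus"] == genus]
        if len(sub) >= target:
            idx = rng.choice(sub.index.to_numpy(), size=target, replace=False)
        else:
            idx = rng.choice(sub.index.to_numpy(), size=target, replace=True)
        parts.append(training.loc[idx])
    return pd.concat(parts).reset_index(drop=True)


@dataclass
class GenusModel:
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    forest: RandomForestClassifier = field(repr=False)
    seed: int = 0


def fit_genus_model(
    training: pd.DataFrame,
    seed: int = 0,
    feature_names: Sequence[str] = GENUS_PREDICTORS,
    n_trees: int = 100,
    balance: bool = True,
) -> GenusModel:
    """Balanced random-forest genus classifier at default hyperparameters."""
    data = balance_genus_classes(training, seed=seed) if balance else training
    X = data.loc[:, list(feature_names)].to_numpy(dtype=float)
    y = data["genus"].to_numpy()
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2**31), n_jobs=1)
    rf.fit(X, y)
    return GenusModel(tuple(sorted(set(y))), tuple(feature_names), rf, seed)


def crossvalidate_genus(
    training: pd.DataFrame,
    n_iter: int = 100,
    seed: int = 0,
    feature_names: Sequence[str] = GENUS_PREDICTORS,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Stratified 90/10 bootstrap cross-validation of the genus classifier.

    Per iteration the data is split 90/10 stratified by genus, the 90% is
    balanced (under+oversampling) and a forest fit on it, and one-vs-rest
    precision/recall/F1 per genus plus overall accuracy are scored on the
    raw 10%.  Rows: one per genus plus an "overall" row; columns carry the
    mean and t-based 95% CI (df = n_iter − 1) of each metric.
    """
    counts = training["genus"].value_counts()
    too_small = sorted(counts.index[counts < 10])
    if too_small:
        raise ValueError(f"genera too small to stratify 90/10: {too_small}")
    classes = sorted(counts.index)
    rng = np.random.default_rng(seed)
    per_class: dict[str, dict[str, list[float]]] = {
        g: {"precision": [], "recall": [], "f1": []} for g in classes
    }
    overall_acc: list[float] = []
    for _ in range(n_iter):
        it_seed = int(rng.integers(2**31))
        train_df, test_df = train_test_split(
            training, test_size=0.1, stratify=training["genus"], random_state=it_seed
        )
        model = fit_genus_model(train_df, seed=it_seed, feature_names=feature_names,
                                n_trees=n_trees, balance=True)
        Xt = test_df.loc[:, list(feature_names)].to_numpy(dtype=float)
        yt = test_df["genus"].to_numpy()
        pred = model.forest.predict(Xt)
        overall_acc.append(float((pred == yt).mean()))
        p, r, f, _ = precision_recall_fscore_support(yt, pred, labels=classes, zero_division=0)
        for g, pi, ri, fi in zip(classes, p, r, f):
            per_class[g]["precision"].append(float(pi))
            per_class[g]["recall"].append(float(ri))
            per_class[g]["f1"].append(float(fi))
    rows = []
    for g in classes:
        row: dict[str, object] = {"genus": g}
        for metric in ("precision", "recall", "f1"):
            m, lo, hi = t_interval(per_class[g][metric])
            row[metric], row[f"{metric}_ci_low"], row[f"{metric}_ci_high"] = m, lo, hi
        rows.append(row)
    m, lo, hi = t_interval(overall_acc)
    rows.append({"genus": "overall", "accuracy": m,
                 "accuracy_ci_low": lo, "accuracy_ci_high": hi})
    return pd.DataFrame(rows)


def predict_genus(model: GenusModel, cells: pd.DataFrame, planted_mask: pd.Series) -> pd.Series:
    """Dominant genus per planted cell; natural cells get NaN.

    ``cells`` is indexed by cell_id and must carry exactly the model's
    feature slots (complete, post-imputation).
    """
    missing = [f for f in model.feature_names if f not in cells.columns]
    if missing:
        raise ValueError(f"cells table lacks model features: {missing}")
    out = pd.Series(np.nan, index=planted_mask.index, dtype=object)
    planted = planted_mask.index[planted_mask.astype(bool)]
    if len(planted) == 0:
        return out
    X = cells.loc[planted, list(model.feature_names)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing predictor values; run imputation before genus prediction")
    out.loc[planted] = model.forest.predict(X)
    return out
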