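"""Validation metrics: confusion-matrix proportions, the derived
classification scores, and bootstrap-t confidence intervals.

The positive class is always "planted".  Confusion elements are reported
as proportions of all evaluated cells (they sum to 1), matching how the
map validation tables are printed.  Metrics with an undefined denominator
(e.g. precision with no positive predictions) come back as NaN with a log
note — never silently as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POSITIVE = "planted"
NEGATIVE = "natural"


@dataclass(frozen=True)
class ConfusionProportions:
    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isclose(self.tp + self.fp + self.fn + self.tn, 1.0, abs_tol=1e-9):
            raise ValueError("confusion proportions must sum to 1")


def confusion(reference: Sequence[str], predicted: Sequence[str]) -> ConfusionProportions:
    """Confusion-matrix proportions with positive = planted."""
    ref = np.asarray(reference, dtype=object)
    pred = np.asarray(predicted, dtype=object)
    if ref.shape != pred.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {pred.shape}")
    if ref.size == 0:
        raise ValueError("empty label sequences")
    for arr, name in ((ref, "reference"), (pred, "predicted")):
        bad = ~np.isin(arr, [POSITIVE, NEGATIVE])
        if bad.any():
            raise ValueError(f"{name} labels must be planted/natural; got {np.unique(arr[bad])}")
    n = ref.size
    rp, pp = ref == POSITIVE, pred == POSITIVE
    return ConfusionProportions(
        tp=float((rp & pp).sum()) / n,
        fp=float((~rp & pp).sum()) / n,
        fn=float((rp & ~pp).sum()) / n,
        tn=float((~rp & ~pp).sum()) / n,
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.info("metric %s undefined (zero denominator); returning NaN", what)
        return float("nan")
    return num / den


def metrics_from_confusion(c: ConfusionProportions) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion proportions."""
    accuracy = c.tp + c.tn
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
        logger.info("metric f1 undefined; returning NaN")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def t_interval(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Bootstrap-t interval: mean ± t(1-(1-level)/2, n-1) · sd/√n.

    Returns (mean, low, high).  With n = 20 iterations the multiplier is
    the t quantile at 19 degrees of freedom (≈ 2.093)."""
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 2:
        raise ValueError("need at least 2 values for a t interval")
    mean = float(vals.mean())
    half = float(stats.t.ppf(1 - (1 - level) / 2, df=n - 1) * vals.std(ddof=1) / np.sqrt(n))
    return mean, mean - half, mean + half


def validate_against_labels(
    predicted_type: pd.Series, labels: pd.Series
) -> dict[str, float | ConfusionProportions]:
    """Score a planted/natural map against fused labels.

    Both inputs are indexed by cell_id; the report covers the intersection
    of map cells and non-excluded labels.
    """
    common = predicted_type.index.intersection(labels.index)
    lab = labels.loc[common]
    keep = lab != "excluded"
    common = common[keep]
    if len(common) == 0:
        raise ValueError("no overlapping non-excluded cells to validate on")
    c = confusion(lab.loc[common].to_numpy(), predicted_type.loc[common].to_numpy())
    report: dict[str, float | ConfusionProportions] = dict(metrics_from_confusion(c))
    report["confusion"] = c
    report["n"] = float(len(common))
    return report


def report_frame(report: dict) -> pd.DataFrame:
    """One-row validation report table (raw values; round for display)."""
    c: ConfusionProportions = report["confusion"]
    return pd.DataFrame(
        [{
            "accuracy": report["accuracy"],
            "precision": report["precision"],
            "recall": report["recall"],
            "f1": report["f1"],
            "true_positive": c.tp,
            "false_positive": c.fp,
            "false_negative": c.fn,
            "true_negative": c.tn,
            "n_cells": int(report["n"]),
        }]
    )
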