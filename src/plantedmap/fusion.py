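"""Quality-oriented data integration (QODI).

Fuses planted/natural evidence of unequal reliability into three training
label sets.  Three sources are *in-situ grade* (ground plots and
field-verified national maps: ``insitu_cn``, ``map_jp``, ``map_kr``); three
are *map grade* planted-extent products (``map_cn``, ``sdpt``,
``gpt2015``).  With

* ``I`` — any in-situ-grade source reads planted,
* ``k`` — number of map-grade sources reading planted,

the three integration levels label a forest cell:

========  =======================  ============================
level     planted                  excluded (grey area)
========  =======================  ============================
lower     I or k = 3               not I and k in {1, 2}
mid       I or k >= 2              not I and k = 1
upper     I or k >= 1              never
========  =======================  ============================

Everything else is natural: a cell with no planted flag from any source is
natural forest, not unknown.  Excluded cells are removed from the training
set of their level.  The planted sets are nested (lower ⊆ mid ⊆ upper) and
the upper level never excludes.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .grid import Grid
from .world import PLANTED_NATURAL_SOURCES, PREDICTOR_NAMES, SOURCES

logger = logging.getLogger(__name__)

LEVELS = ("lower", "mid", "upper")
INSITU_GRADE = PLANTED_NATURAL_SOURCES          # insitu_cn, map_jp, map_kr
MAP_GRADE = ("map_cn", "sdpt", "gpt2015")

#: Raw terrestrial-ecoregion classes -> three analysis biomes.
BIOME_GROUPS = {
    "Temperate Broadleaf and Mixed": "Temperate Forest",
    "Temperate Conifer": "Temperate Forest",
    "Temperate Grassland/Savanna": "Temperate Grassland",
    "Montane and Flooded Grassland": "Temperate Grassland",
    "Tropical Moist": "Tropical Forest and Savanna",
    "Tropical Dry": "Tropical Forest and Savanna",
    "Tropical Grassland/Savanna": "Tropical Forest and Savanna",
}
MERGED_TEMPERATE = "Temperate Forest and Grassland"

FOREST_HEIGHT_M = 5.0  # FAO forest definition: minimum 5 m tree height


def aggregate_insitu(points: pd.DataFrame, grid: Grid) -> pd.Series:
    """Majority-vote in-situ points into per-cell evidence.

    Returns a Series indexed by cell_id over all grid cells with values in
    {planted, natural, absent}.  A cell's state is the strict majority of
    its point labels; exact 50/50 ties and empty cells are ``absent``.
    Points outside the grid are skipped with a logged count.
    """
    state = pd.Series("absent", index=pd.RangeIndex(grid.n_cells), dtype=object)
    if len(points) == 0:
        return state
    bad = ~points["label"].isin(["planted", "natural"])
    if bad.any():
        raise ValueError(f"point labels must be planted/natural, got {points.loc[bad, 'label'].unique()}")
    row, col = grid.locate(points["lon"].to_numpy(), points["lat"].to_numpy())
    inside = grid.contains(row, col)
    n_skipped = int((~inside).sum())
    if n_skipped:
        logger.warning("aggregate_insitu: skipped %d point(s) outside the grid", n_skipped)
    cell = grid.cell_id(row[inside], col[inside])
    planted = (points["label"].to_numpy()[inside] == "planted").astype(int)
    votes = pd.DataFrame({"cell": cell, "planted": planted}).groupby("cell")["planted"].agg(["sum", "count"])
    n_planted = votes["sum"]
    n_natural = votes["count"] - votes["sum"]
    state.loc[votes.index[n_planted > n_natural]] = "planted"
    state.loc[votes.index[n_natural > n_planted]] = "natural"
    # ties stay absent: a 50/50 cell carries no in-situ evidence
    return state


def _check_levels(level: str) -> None:
    if level not in LEVELS:
        raise ValueError(f"unknown fusion level {level!r}; expected one of {LEVELS}")


def qodi_label(evidence: pd.DataFrame, level: str) -> pd.Series:
    """Fused planted/natural/excluded label for each evidence row.

    ``evidence`` needs one column per source in :data:`SOURCES` with values
    in {planted, natural, absent} (map-grade sources never read natural).
    """
    _check_levels(level)
    missing = [s for s in SOURCES if s not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing source columns: {missing}")
    insitu_planted = np.zeros(len(evidence), dtype=bool)
    for s in INSITU_GRADE:
        insitu_planted |= evidence[s].to_numpy() == "planted"
    k = np.zeros(len(evidence), dtype=int)
    for s in MAP_GRADE:
        k += evidence[s].to_numpy() == "planted"

    label = np.full(len(evidence), "natural", dtype=object)
    if level == "lower":
        label[insitu_planted | (k == 3)] = "planted"
        label[~insitu_planted & ((k == 1) | (k == 2))] = "excluded"
    elif level == "mid":
        label[insitu_planted | (k >= 2)] = "planted"
        label[~insitu_planted & (k == 1)] = "excluded"
    else:  # upper: most liberal, no grey area
        label[insitu_planted | (k >= 1)] = "planted"
    return pd.Series(label, index=evidence.index, name=f"label_{level}")


def apply_forest_mask(cells: pd.DataFrame, height_col: str = "tree_height") -> pd.DataFrame:
    """Keep forest cells only: tree height >= 5 m, boundary inclusive.

    Missing height counts as non-forest and is dropped.
    """
    h = cells[height_col]
    keep = h.notna() & (h >= FOREST_HEIGHT_M)
    dropped = len(cells) - int(keep.sum())
    logger.info("forest mask: kept %d of %d cells (%d below %.0f m or missing)",
                int(keep.sum()), len(cells), dropped, FOREST_HEIGHT_M)
    return cells.loc[keep]


def assign_biome_group(cells: pd.DataFrame, level: str, raw_col: str = "biome_raw") -> pd.DataFrame:
    """Map the 7 raw ecoregion classes to analysis biomes.

    All levels collapse the raw classes to Temperate Grassland / Temperate
    Forest / Tropical Forest and Savanna; at mid and lower the two
    temperate groups additionally merge into one stratum (the grassland
    stratum is too thin to train on its own there).
    """
    _check_levels(level)
    raw = cells[raw_col]
    unknown = set(raw.dropna().unique()) - set(BIOME_GROUPS)
    if unknown:
        raise ValueError(f"unknown raw biome classes: {sorted(unknown)}")
    group = raw.map(BIOME_GROUPS)
    if level in ("mid", "lower"):
        group = group.replace({"Temperate Grassland": MERGED_TEMPERATE,
                               "Temperate Forest": MERGED_TEMPERATE})
    out = cells.copy()
    out["biome_group"] = group
    return out


def build_training_set(
    cells: pd.DataFrame,
    evidence: pd.DataFrame,
    predictors: pd.DataFrame,
    level: str,
    predictor_names: Iterable[str] = PREDICTOR_NAMES,
) -> pd.DataFrame:
    """Assemble the per-level training table.

    ``cells`` must already be forest-masked and biome-grouped (indexed by
    cell_id); ``evidence`` and ``predictors`` are indexed by cell_id over
    at least those cells.  One row per non-excluded cell with columns
    cell_id, level, label, biome_group, country and the predictor slots.
    """
    _check_levels(level)
    predictor_names = list(predictor_names)
    idx = cells.index
    for name, tbl in (("evidence", evidence), ("predictors", predictors)):
        if not idx.isin(tbl.index).all():
            raise ValueError(f"{name} table misaligned with grid: missing cell_ids")
    labels = qodi_label(evidence.loc[idx], level)
    keep = labels != "excluded"
    out = pd.DataFrame(
        {
            "cell_id": idx[keep],
            "level": level,
            "label": labels[keep].to_numpy(),
            "biome_group": cells.loc[keep, "biome_group"].to_numpy(),
            "country": cells.loc[keep, "country"].to_numpy(),
        }
    )
    out = pd.concat(
        [out.reset_index(drop=True),
         predictors.loc[idx[keep], predictor_names].reset_index(drop=True)],
        axis=1,
    )
    return out
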