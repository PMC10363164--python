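"""End-to-end orchestration: simulate → fuse → impute → train → predict →
genus → validate → export.

Each stage is a plain function over in-memory tables so the library can be
driven from Python; :class:`PipelineRun` threads one master seed through
every stochastic stage (sub-seeds drawn from a single generator in a fixed
order, so a fixed master seed reproduces every artifact byte for byte).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import classify, fusion, genus as genus_mod, geo, impute, metrics
from .grid import Grid
from .world import PREDICTOR_NAMES, SyntheticWorld, WorldConfig, generate_world, world_to_tables

logger = logging.getLogger(__name__)

LEVELS = ("lower", "mid", "upper")


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    seed: int = 0
    n_members: int = classify.N_MEMBERS
    genus_cv_iter: int = 100
    imputer_cv_iter: int = 0       # 0 = skip imputer cross-validation
    genus_min_samples: int = genus_mod.MIN_GENUS_SAMPLES
    run_genus_cv: bool = True

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        wd = dict(d.pop("world", {}))
        if "source_quality" in wd:
            from .world import SourceQuality

            wd["source_quality"] = {
                k: SourceQuality(**v) if isinstance(v, Mapping) else v
                for k, v in wd["source_quality"].items()
            }
        for key in ("grid_shape", "origin_lonlat"):
            if key in wd:
                wd[key] = tuple(wd[key])
        return cls(world=WorldConfig(**wd), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise ValueError(f"bad pipeline config {path}: {exc}") from exc


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: SyntheticWorld
    cells: pd.DataFrame                 # all cells (indexed by cell_id)
    forest_cells: dict[str, pd.DataFrame]   # per level, biome-grouped forest cells
    training: dict[str, pd.DataFrame]
    predictors_filled: dict[str, pd.DataFrame]
    ensembles: dict[str, dict[str, classify.BoundEnsemble]]
    records: pd.DataFrame               # percent/type per forest cell (final, post-override)
    genus_labels: dict[str, pd.Series]  # per bound, predicted genus per cell
    genus_training: pd.DataFrame | None
    genus_cv: pd.DataFrame | None
    validation: dict
    output: pd.DataFrame                # exported attribute schema


class PipelineRun:
    """Stage-by-stage executor sharing one seeded generator."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)

    def _seed(self) -> int:
        return int(self.rng.integers(2**31))

    # -- stages ------------------------------------------------------------

    def simulate(self) -> SyntheticWorld:
        self.world = generate_world(self.config.world.with_(seed=self.config.world.seed or self._seed()))
        cells, points, plots = world_to_tables(self.world)
        self.cells = cells.set_index("cell_id", drop=False)
        self.cells.attrs["cell_size_deg"] = self.world.grid.cell_size_deg
        self.points, self.plots = points, plots
        return self.world

    def fuse(self) -> dict[str, pd.DataFrame]:
        grid: Grid = self.world.grid
        insitu = fusion.aggregate_insitu(self.points, grid)
        self.evidence = self.cells.filter(like="src_").rename(columns=lambda c: c[4:])
        self.evidence["insitu_cn"] = insitu.to_numpy()
        forest = fusion.apply_forest_mask(self.cells)
        self.forest_cells, self.training = {}, {}
        predictors = self.cells.loc[:, list(PREDICTOR_NAMES)]
        for level in LEVELS:
            grouped = fusion.assign_biome_group(forest, level)
            self.forest_cells[level] = grouped
            self.training[level] = fusion.build_training_set(
                grouped, self.evidence, predictors, level
            )
        return self.training

    def impute(self) -> dict[str, pd.DataFrame]:
        """Complete the predictor table per level (lidar forests + median)."""
        self.predictors_filled = {}
        forest_idx = self.forest_cells["upper"].index  # forest mask is level-free
        base = self.cells.loc[forest_idx, list(PREDICTOR_NAMES)]
        for level in LEVELS:
            filled = impute.impute_gedi(base, level, seed=self._seed())
            self.predictors_filled[level] = impute.impute_general(filled)
            # refresh the training predictors with the filled values
            tr = self.training[level]
            tr.loc[:, list(PREDICTOR_NAMES)] = (
                self.predictors_filled[level].loc[tr["cell_id"].to_numpy()].to_numpy()
            )
        self.imputer_reports = None
        if self.config.imputer_cv_iter >= 2:
            self.imputer_reports = {
                level: impute.crossvalidate_imputer(
                    base, level, n_iter=self.config.imputer_cv_iter, seed=self._seed()
                )
                for level in LEVELS
            }
        return self.predictors_filled

    def train(self) -> dict[str, dict[str, classify.BoundEnsemble]]:
        self.ensembles = {}
        for level in LEVELS:
            self.ensembles[level] = classify.fit_bound_ensembles_by_biome(
                self.training[level], level, seed=self._seed(), n_members=self.config.n_members
            )
        return self.ensembles

    def predict(self) -> pd.DataFrame:
        forest_idx = self.forest_cells["upper"].index
        percents = {}
        for level in LEVELS:
            cells_pred = self.predictors_filled[level]
            biome = self.forest_cells[level]["biome_group"]
            percents[level] = classify.predict_percent_by_biome(
                self.ensembles[level], cells_pred, biome
            )
        records = classify.combine_bounds(
            percents["upper"].to_numpy(), percents["mid"].to_numpy(), percents["lower"].to_numpy()
        )
        records.index = forest_idx
        # national-map override: ROK everywhere, Japan where its national map covers
        country = self.cells.loc[forest_idx, "country"]
        ev = self.evidence.loc[forest_idx]
        mask = (country == "ROK") | ((country == "Japan") & (ev["map_jp"] != "absent"))
        override_label = pd.Series("natural", index=forest_idx, dtype=object)
        override_label[(country == "ROK") & (ev["map_kr"] == "planted")] = "planted"
        override_label[(country == "Japan") & (ev["map_jp"] == "planted")] = "planted"
        self.records = classify.override_with_national_maps(records, mask, override_label)
        return self.records

    def map_genus(self) -> dict[str, pd.Series]:
        grid = self.world.grid
        preds = self.predictors_filled["mid"]  # genus features exclude the lidar slots
        self.genus_labels, self.genus_models = {}, {}
        self.genus_training, self.genus_cv = None, None
        for bound, type_col in (("mean", "type"), ("upper", "type_upper"), ("lower", "type_lower")):
            planted_mask = self.records[type_col] == "planted"
            labels, retained = genus_mod.aggregate_dominant_genus(
                self.plots, grid, planted_mask, min_samples=self.config.genus_min_samples
            )
            if len(retained) < 2:
                logger.warning("bound %s: fewer than two retained genera; skipping genus map", bound)
                self.genus_labels[bound] = pd.Series(dtype=object)
                continue
            train = preds.loc[labels.index, list(genus_mod.GENUS_PREDICTORS)].copy()
            train["genus"] = labels
            model = genus_mod.fit_genus_model(train, seed=self._seed())
            self.genus_models[bound] = model
            self.genus_labels[bound] = genus_mod.predict_genus(model, preds, planted_mask)
            if bound == "mean":
                self.genus_training = train
                counts = train["genus"].value_counts()
                if self.config.run_genus_cv and self.config.genus_cv_iter >= 2:
                    if counts.min() >= 10:
                        self.genus_cv = genus_mod.crossvalidate_genus(
                            train, n_iter=self.config.genus_cv_iter, seed=self._seed()
                        )
                    else:
                        logger.warning(
                            "skipping genus cross-validation: smallest genus has "
                            "%d cells (< 10 needed to stratify)", int(counts.min())
                        )
        return self.genus_labels

    def validate(self) -> dict:
        """Score the final map against the mid-level labels of the in-situ
        country (the model's own training currency) and, synthetically,
        against the generator's truth."""
        forest_idx = self.records.index
        country = self.cells.loc[forest_idx, "country"]
        model_cells = forest_idx[(self.records["source"] == "model") & (country == "China")]
        labels = fusion.qodi_label(self.evidence.loc[model_cells], "mid")
        report = metrics.validate_against_labels(self.records.loc[model_cells, "type"], labels)

        truth = pd.Series(self.world.truth, index=self.cells.index).loc[forest_idx]
        truth_lab = truth.map({1: "planted", 0: "natural"})
        c = metrics.confusion(truth_lab.to_numpy(), self.records["type"].to_numpy())
        vs_truth = metrics.metrics_from_confusion(c)
        vs_truth["planted_fraction_pred"] = float((self.records["type"] == "planted").mean())
        vs_truth["planted_fraction_true"] = float((truth_lab == "planted").mean())
        vs_truth["fraction_error"] = abs(
            vs_truth["planted_fraction_pred"] - vs_truth["planted_fraction_true"]
        )
        self.validation = {"vs_mid_labels": report, "vs_truth": vs_truth}
        return self.validation

    def export(self) -> pd.DataFrame:
        cells = self.forest_cells["upper"]
        self.output = geo.build_output_records(cells, self.records, self.genus_labels)
        return self.output

    # -- driver ------------------------------------------------------------

    def run(self) -> PipelineResult:
        self.simulate()
        self.fuse()
        self.impute()
        self.train()
        self.predict()
        self.map_genus()
        self.validate()
        self.export()
        return self.run_result()

    def run_result(self) -> PipelineResult:
        return PipelineResult(
            config=self.config,
            world=self.world,
            cells=self.cells,
            forest_cells=self.forest_cells,
            training=self.training,
            predictors_filled=self.predictors_filled,
            ensembles=self.ensembles,
            records=self.records,
            genus_labels=self.genus_labels,
            genus_training=self.genus_training,
            genus_cv=self.genus_cv,
            validation=self.validation,
            output=self.output,
        )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    return PipelineRun(config).run()


# --------------------------------------------------------------------------
# Artifact persistence (used by the CLI)

def write_artifacts(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write every tabular artifact (CSV/GeoJSON/ASCII raster) to a
    directory; deterministic for a fixed pipeline seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, index=False, **kw)
        paths[name] = p

    cells, points, plots = world_to_tables(result.world)
    save("cells.csv", cells)
    save("points.csv", points)
    save("plots.csv", plots)
    for level, tr in result.training.items():
        save(f"training_{level}.csv", tr)
    save("records.csv", result.records.reset_index(names="cell_id"))
    save("output.csv", result.output)
    if result.genus_cv is not None:
        save("genus_cv.csv", result.genus_cv)
    rep = result.validation["vs_mid_labels"]
    save("validation.csv", metrics.report_frame(rep))
    by_country, by_genus = geo.planted_area_summary(result.output)
    save("area_by_country.csv", by_country)
    save("area_by_genus.csv", by_genus)

    grid = result.world.grid
    paths["output.geojson"] = geo.write_vector(result.output, grid, outdir / "output.geojson")
    pct = result.records["p_mean"]
    paths["percent_planted.asc"] = geo.write_raster(pct, grid, outdir / "percent_planted.asc")
    type_codes = {"Natural": 0, "Planted": 1}
    paths["type.asc"] = geo.write_raster(
        result.output["Type"], grid, outdir / "type.asc", legend=type_codes
    )
    genus_vals = result.output["Genus"].dropna()
    if len(genus_vals):
        legend = {g: i + 1 for i, g in enumerate(sorted(genus_vals.unique()))}
        paths["genus.asc"] = geo.write_raster(
            result.output["Genus"], grid, outdir / "genus.asc", legend=legend
        )
    summary = {
        "seed": result.config.seed,
        "grid_shape": list(result.config.world.grid_shape),
        "n_forest_cells": int(len(result.records)),
        "planted_cells": int((result.output["Type"] == "Planted").sum()),
        "planted_area_km2": float(by_country["area_km2"].sum()),
        "validation_vs_mid_labels": {
            k: (v if isinstance(v, float) else None) for k, v in rep.items() if k != "confusion"
        },
        "vs_truth": result.validation["vs_truth"],
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["summary.json"] = p
    return paths
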