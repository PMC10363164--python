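"""Synthetic landscape generator.

Builds a fully specified artificial study region — a spatially
autocorrelated planted/natural truth field, six imperfect evidence sources,
57 structural/climatic predictors with class-conditional shifts and
lidar-style gaps, biome strata, countries, in-situ points and inventory
plots — so that every stage of the mapping pipeline can be exercised and
scored against known truth without any external download.

The generator is deterministic for a fixed seed: every random draw flows
from one :class:`numpy.random.Generator` seeded from ``WorldConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import DEFAULT_CELL_SIZE_DEG, Grid

# --------------------------------------------------------------------------
# Predictor layout: 57 named slots, grouped as in wide-area forest mapping
# stacks (lidar structure, optical vegetation indices, bioclimate,
# topography, anthropogenic pressure, soil).
GEDI_PREDICTORS = ("rh100", "pai", "fhd_normal", "cover")
MODIS_PREDICTORS = tuple(f"modis_{i:02d}" for i in range(1, 8))
BIOCLIM_PREDICTORS = tuple(f"bio_{i:02d}" for i in range(1, 22))
TOPO_PREDICTORS = tuple(f"topo_{i:02d}" for i in range(1, 14))
ANTHRO_PREDICTORS = ("cattle", "roadless", "protected", "human_footprint")
SOIL_PREDICTORS = tuple(f"soil_{i:02d}" for i in range(1, 8))

PREDICTOR_NAMES: tuple[str, ...] = (
    GEDI_PREDICTORS + ("tree_height",) + MODIS_PREDICTORS + BIOCLIM_PREDICTORS
    + TOPO_PREDICTORS + ANTHRO_PREDICTORS + SOIL_PREDICTORS
)
assert len(PREDICTOR_NAMES) == 57

#: Predictor slots dropped for genus classification (roadless + the four
#: lidar structure attributes), leaving 52.
GENUS_EXCLUDED_PREDICTORS = ("roadless",) + GEDI_PREDICTORS

SOURCES = ("insitu_cn", "map_cn", "map_jp", "map_kr", "sdpt", "gpt2015")
#: Sources that can assert "natural" as well as "planted"; the remaining
#: (map-grade planted-extent products) only ever read planted or absent.
PLANTED_NATURAL_SOURCES = ("insitu_cn", "map_jp", "map_kr")

COUNTRIES = ("China", "DPRK", "ROK", "Japan")
#: Longitudinal share of each country band, west to east.
COUNTRY_BAND_SHARES = (0.55, 0.10, 0.10, 0.25)
#: Which country bands each evidence source covers (None = everywhere).
SOURCE_DOMAINS: dict[str, tuple[str, ...] | None] = {
    "insitu_cn": ("China",),
    "map_cn": ("China",),
    "map_jp": ("Japan",),
    "map_kr": ("ROK",),
    "sdpt": ("China", "ROK", "Japan"),
    "gpt2015": None,
}

#: Seven raw biome classes reduced to three groups downstream.
RAW_BIOMES = (
    "Temperate Broadleaf and Mixed",
    "Temperate Conifer",
    "Temperate Grassland/Savanna",
    "Montane and Flooded Grassland",
    "Tropical Moist",
    "Tropical Dry",
    "Tropical Grassland/Savanna",
)


@dataclass(frozen=True)
class SourceQuality:
    """Per-source observation model: over its covered cells the source reads
    planted with probability ``sensitivity`` given planted truth and reads
    natural (or stays silent, for planted-only products) with probability
    ``specificity`` given natural truth."""

    sensitivity: float = 0.9
    specificity: float = 0.95
    coverage: float = 1.0

    def validate(self, name: str) -> None:
        for f in ("sensitivity", "specificity", "coverage"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}.{f}={v} outside [0, 1]")


class ConfigError(ValueError):
    """Raised for an invalid WorldConfig."""


def _default_source_quality() -> dict[str, SourceQuality]:
    return {
        "insitu_cn": SourceQuality(0.9, 0.95, 1.0),
        "map_cn": SourceQuality(0.9, 0.95, 0.6),
        "map_jp": SourceQuality(0.9, 0.95, 0.9),
        "map_kr": SourceQuality(0.9, 0.95, 0.9),
        "sdpt": SourceQuality(0.9, 0.95, 0.7),
        "gpt2015": SourceQuality(0.9, 0.95, 0.7),
    }


def _default_predictor_effects() -> dict[str, float]:
    """Class-mean shifts (planted minus natural, in SD units).

    Optical vegetation indices and the leading bioclimate slots carry a
    1-SD shift — planted stands differ in phenology/greenness and are
    concentrated in particular climates — with a weaker anthropogenic
    signal.  Topography and soil are left class-neutral; they instead carry
    the genus signal (see ``genus_effect_sd``)."""
    eff: dict[str, float] = {name: 1.0 for name in MODIS_PREDICTORS}
    eff.update({name: 1.0 for name in BIOCLIM_PREDICTORS[:7]})
    eff["human_footprint"] = 0.5
    return eff


@dataclass(frozen=True)
class WorldConfig:
    grid_shape: tuple[int, int] = (100, 100)
    cell_size_deg: float = DEFAULT_CELL_SIZE_DEG
    origin_lonlat: tuple[float, float] = (110.0, 35.0)  # west edge, north edge
    planted_fraction: float = 0.3
    autocorr_length: float = 4.0
    source_quality: Mapping[str, SourceQuality] = field(default_factory=_default_source_quality)
    predictor_effects: Mapping[str, float] = field(default_factory=_default_predictor_effects)
    gedi_signal_share: float = 0.5  # variance share of lidar slots explained by the optical slots
    gedi_missing_rate: float = 0.3
    short_stature_share: float = 0.1  # cells below the 5 m forest threshold
    n_insitu_points: int = 500
    n_plots: int = 4000
    n_genera: int = 6
    genus_effect_sd: float = 1.0  # genus-mean dispersion on topo/soil slots
    seed: int = 0

    def validate(self) -> None:
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise ConfigError("grid_shape must be positive")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ConfigError("planted_fraction outside [0, 1]")
        if not 0.0 <= self.gedi_missing_rate <= 1.0:
            raise ConfigError("gedi_missing_rate outside [0, 1]")
        if not 0.0 <= self.short_stature_share <= 1.0:
            raise ConfigError("short_stature_share outside [0, 1]")
        if self.autocorr_length < 1:
            raise ConfigError("autocorr_length must be >= 1 cell")
        if self.n_genera < 1:
            raise ConfigError("n_genera must be >= 1")
        missing = [s for s in SOURCES if s not in self.source_quality]
        if missing:
            raise ConfigError(f"source_quality missing sources: {missing}")
        for name in SOURCES:
            self.source_quality[name].validate(name)
        unknown = set(self.predictor_effects) - set(PREDICTOR_NAMES)
        if unknown:
            raise ConfigError(f"unknown predictors in predictor_effects: {sorted(unknown)}")

    def grid(self) -> Grid:
        return Grid(
            n_rows=self.grid_shape[0],
            n_cols=self.grid_shape[1],
            origin_lon=self.origin_lonlat[0],
            origin_lat=self.origin_lonlat[1],
            cell_size_deg=self.cell_size_deg,
        )

    def with_(self, **kw) -> "WorldConfig":
        return replace(self, **kw)


#: Pool of genus names for plot simulation (real plantation genera of the
#: region, purely as labels).
GENUS_POOL = (
    "Cunninghamia", "Pinus", "Eucalyptus", "Larix", "Chamaecyparis",
    "Cryptomeria", "Robinia", "Abies", "Quercus", "Castanea", "Picea",
    "Betula",
)


@dataclass
class SyntheticWorld:
    """A generated landscape: truth plus everything the pipeline consumes."""

    config: WorldConfig
    grid: Grid
    truth: np.ndarray               # (n_cells,) int8, 1 = planted
    tree_height: np.ndarray         # (n_cells,) float, metres
    biome_raw: np.ndarray           # (n_cells,) object, one of RAW_BIOMES
    country: np.ndarray             # (n_cells,) object
    evidence: pd.DataFrame          # one column per source, values planted/natural/absent
    predictors: pd.DataFrame        # 57 columns, NaN = missing
    genus_field: np.ndarray         # (n_cells,) object, latent genus region
    insitu_points: pd.DataFrame     # lon, lat, label
    plots: pd.DataFrame             # plot_id, lon, lat, species, genus, basal_area_m2, stems

    @property
    def n_cells(self) -> int:
        return self.grid.n_cells


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Gaussian-smoothed white noise, restandardised to unit variance."""
    z = rng.standard_normal(shape)
    f = gaussian_filter(z, sigma=scale, mode="wrap")
    return (f - f.mean()) / f.std()


def _country_bands(n_cols: int) -> np.ndarray:
    """Country of each column: four longitudinal bands, west to east."""
    edges = np.cumsum((0.0,) + COUNTRY_BAND_SHARES)
    col_frac = (np.arange(n_cols) + 0.5) / n_cols
    idx = np.clip(np.searchsorted(edges, col_frac) - 1, 0, len(COUNTRIES) - 1)
    return np.array(COUNTRIES, dtype=object)[idx]


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full synthetic landscape for ``config``.

    The truth field is a Gaussian random field (white noise smoothed with a
    kernel of scale ``autocorr_length``) thresholded at the
    ``1 - planted_fraction`` quantile, so the realised planted share matches
    the target up to ties.  Each evidence source then observes the truth
    independently through its (sensitivity, specificity, coverage) filter;
    predictors are unit-variance Gaussians shifted between classes by
    ``predictor_effects``; the four lidar-structure slots are linear
    mixtures of the seven optical slots plus noise (variance share
    ``gedi_signal_share``) with MCAR gaps at ``gedi_missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    shape = config.grid_shape
    n = grid.n_cells

    # --- truth: thresholded smoothed random field -------------------------
    f = _smooth_field(rng, shape, config.autocorr_length).ravel()
    if config.planted_fraction <= 0.0:
        truth = np.zeros(n, dtype=np.int8)
    elif config.planted_fraction >= 1.0:
        truth = np.ones(n, dtype=np.int8)
    else:
        thr = np.quantile(f, 1.0 - config.planted_fraction)
        truth = (f > thr).astype(np.int8)

    # --- biome: an independent smoothed field cut into 7 spatial classes --
    b = _smooth_field(rng, shape, max(config.autocorr_length * 2, 2.0)).ravel()
    # south (high row index) tropical, north temperate, with grassland at
    # the dry (low-b) extreme of the temperate half.
    row = np.arange(n) // shape[1]
    southness = (row + 0.5) / shape[0] + 0.25 * b
    biome_raw = np.empty(n, dtype=object)
    tropical = southness > np.quantile(southness, 0.6)
    trop_split = rng.random(n)
    biome_raw[tropical & (trop_split < 0.5)] = "Tropical Moist"
    biome_raw[tropical & (trop_split >= 0.5) & (trop_split < 0.8)] = "Tropical Dry"
    biome_raw[tropical & (trop_split >= 0.8)] = "Tropical Grassland/Savanna"
    temperate = ~tropical
    grassy = temperate & (b < np.quantile(b[temperate] if temperate.any() else b, 0.2))
    grass_split = rng.random(n)
    biome_raw[grassy & (grass_split < 0.7)] = "Temperate Grassland/Savanna"
    biome_raw[grassy & (grass_split >= 0.7)] = "Montane and Flooded Grassland"
    wooded = temperate & ~grassy
    conifer = rng.random(n) < 0.5
    biome_raw[wooded & conifer] = "Temperate Conifer"
    biome_raw[wooded & ~conifer] = "Temperate Broadleaf and Mixed"

    country = _country_bands(shape[1])[np.arange(n) % shape[1]]

    # --- tree height: class-specific lognormals, a share of short cells ---
    short = rng.random(n) < config.short_stature_share
    mu = np.where(truth == 1, np.log(14.0), np.log(18.0))
    height = rng.lognormal(mean=mu, sigma=0.35)
    height = np.clip(height, 5.0, None)  # tall branch stays above the mask
    height[short] = rng.uniform(0.5, 5.0, size=int(short.sum()))  # < 5 m
    tree_height = height

    # --- evidence sources -------------------------------------------------
    evidence = pd.DataFrame(index=pd.RangeIndex(n))
    for name in SOURCES:
        if name == "insitu_cn":
            continue  # derived from the point sample below
        q = config.source_quality[name]
        domain = SOURCE_DOMAINS[name]
        in_domain = np.ones(n, dtype=bool) if domain is None else np.isin(country, domain)
        covered = in_domain & (rng.random(n) < q.coverage)
        reads_planted = np.where(
            truth == 1, rng.random(n) < q.sensitivity, rng.random(n) >= q.specificity
        )
        col = np.full(n, "absent", dtype=object)
        col[covered & reads_planted] = "planted"
        if name in PLANTED_NATURAL_SOURCES:
            col[covered & ~reads_planted] = "natural"
        evidence[name] = col

    # --- in-situ points: one noisy reading per sampled cell ---------------
    q_insitu = config.source_quality["insitu_cn"]
    insitu_domain = np.isin(country, SOURCE_DOMAINS["insitu_cn"])
    candidates = np.flatnonzero(insitu_domain)
    n_pts = min(config.n_insitu_points, candidates.size)
    pt_cells = rng.choice(candidates, size=n_pts, replace=False)
    pt_truth = truth[pt_cells]
    pt_reads_planted = np.where(
        pt_truth == 1,
        rng.random(n_pts) < q_insitu.sensitivity,
        rng.random(n_pts) >= q_insitu.specificity,
    )
    prow, pcol = grid.rowcol(pt_cells)
    jitter = rng.random((2, n_pts))
    s = grid.cell_size_deg
    pt_lon = grid.origin_lon + (pcol + jitter[0]) * s
    pt_lat = grid.origin_lat - (prow + jitter[1]) * s
    insitu_points = pd.DataFrame(
        {
            "lon": pt_lon,
            "lat": pt_lat,
            "label": np.where(pt_reads_planted, "planted", "natural"),
        }
    )
    insitu_col = np.full(n, "absent", dtype=object)
    insitu_col[pt_cells] = np.where(pt_reads_planted, "planted", "natural")
    evidence.insert(0, "insitu_cn", insitu_col)

    # --- predictors -------------------------------------------------------
    effects = dict(config.predictor_effects)
    pred = pd.DataFrame(index=pd.RangeIndex(n))
    t = truth.astype(float)
    for name in MODIS_PREDICTORS + BIOCLIM_PREDICTORS + TOPO_PREDICTORS + ANTHRO_PREDICTORS + SOIL_PREDICTORS:
        pred[name] = effects.get(name, 0.0) * t + rng.standard_normal(n)

    # latent genus regions: per-genus smoothed fields, argmax wins
    genera = GENUS_POOL[: config.n_genera]
    genus_scores = np.stack(
        [_smooth_field(rng, shape, max(config.autocorr_length * 2, 3.0)).ravel() for _ in genera]
    )
    genus_field = np.array(genera, dtype=object)[np.argmax(genus_scores, axis=0)]
    # genus signal lives on topography + soil (class-neutral slots)
    genus_slots = TOPO_PREDICTORS + SOIL_PREDICTORS
    genus_means = rng.normal(0.0, config.genus_effect_sd, size=(len(genera), len(genus_slots)))
    order = {g: i for i, g in enumerate(genera)}
    gidx = np.fromiter((order[g] for g in genus_field), dtype=int, count=n)
    for j, name in enumerate(genus_slots):
        pred[name] = pred[name].to_numpy() + genus_means[gidx, j]

    # lidar structure = linear mixture of the optical slots + noise
    modis_mat = pred.loc[:, MODIS_PREDICTORS].to_numpy()
    modis_std = (modis_mat - modis_mat.mean(axis=0)) / modis_mat.std(axis=0)
    r2 = config.gedi_signal_share
    gedi_scale_loc = {"rh100": (600.0, 1500.0), "pai": (1.0, 2.5), "fhd_normal": (0.3, 2.5)}
    for name in GEDI_PREDICTORS:
        w = rng.normal(size=len(MODIS_PREDICTORS))
        signal = modis_std @ (w / np.linalg.norm(w))
        latent = np.sqrt(r2) * signal + np.sqrt(1.0 - r2) * rng.standard_normal(n)
        if name == "cover":
            pred[name] = expit(latent)
        else:
            scale, loc = gedi_scale_loc[name]
            pred[name] = loc + scale * latent
    gedi_missing = rng.random(n) < config.gedi_missing_rate
    pred.loc[gedi_missing, list(GEDI_PREDICTORS)] = np.nan

    pred["tree_height"] = tree_height
    pred = pred.loc[:, list(PREDICTOR_NAMES)]

    # --- inventory plots --------------------------------------------------
    plots = _generate_plots(rng, config, grid, tree_height, genus_field, genera)

    return SyntheticWorld(
        config=config,
        grid=grid,
        truth=truth,
        tree_height=tree_height,
        biome_raw=biome_raw,
        country=country,
        evidence=evidence,
        predictors=pred,
        genus_field=genus_field,
        insitu_points=insitu_points,
        plots=plots,
    )


def _generate_plots(
    rng: np.random.Generator,
    config: WorldConfig,
    grid: Grid,
    tree_height: np.ndarray,
    genus_field: np.ndarray,
    genera: Sequence[str],
) -> pd.DataFrame:
    """Inventory plots: 1–8 species with Dirichlet basal-area shares and
    Poisson stem counts; the leading species carries the cell's latent genus
    with high probability so grid-level majority votes are meaningful."""
    forest_cells = np.flatnonzero(tree_height >= 5.0)
    if config.n_plots == 0 or forest_cells.size == 0:
        return pd.DataFrame(
            columns=["plot_id", "lon", "lat", "species", "genus", "basal_area_m2", "stems"]
        )
    cells = rng.choice(forest_cells, size=config.n_plots, replace=True)
    rows_out: list[tuple] = []
    s = grid.cell_size_deg
    for pid, cell in enumerate(cells):
        r, c = int(cell) // grid.n_cols, int(cell) % grid.n_cols
        lon = grid.origin_lon + (c + rng.random()) * s
        lat = grid.origin_lat - (r + rng.random()) * s
        n_sp = int(rng.integers(1, 9))
        shares = np.sort(rng.dirichlet(np.ones(n_sp)))[::-1]
        total_ba = rng.uniform(10.0, 40.0)
        lead_genus = genus_field[cell] if rng.random() < 0.85 else rng.choice(np.asarray(genera))
        other = [g for g in genera if g != lead_genus]
        sp_genera = [lead_genus] + list(
            rng.choice(np.asarray(other if other else genera), size=n_sp - 1, replace=True)
        )
        seen: dict[str, int] = {}
        for k in range(n_sp):
            g = sp_genera[k]
            seen[g] = seen.get(g, 0) + 1
            species = f"{g} sp{seen[g]}"
            stems = int(rng.poisson(shares[k] * 40.0)) + 1
            rows_out.append((pid, lon, lat, species, g, shares[k] * total_ba, stems))
    return pd.DataFrame(
        rows_out, columns=["plot_id", "lon", "lat", "species", "genus", "basal_area_m2", "stems"]
    )


def world_to_tables(world: SyntheticWorld) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten a world into (cell table, point table, plot table).

    The cell table has one row per grid cell and carries truth, geometry,
    country, raw biome, tree height, the six evidence columns (prefixed
    ``src_``) and the 57 predictor slots; it is the direct input to the
    fusion stage.
    """
    base = world.grid.all_cells_frame()
    base["country"] = world.country
    base["biome_raw"] = world.biome_raw
    # tree_height enters once, via the predictor block
    base["truth"] = world.truth
    base["genus_field"] = world.genus_field
    ev = world.evidence.add_prefix("src_")
    cells = pd.concat([base, ev, world.predictors], axis=1)
    return cells, world.insitu_points.copy(), world.plots.copy()
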