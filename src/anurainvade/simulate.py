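"""Synthetic worlds with known ground truth.

The generator emulates every input of the analysis — 14 smooth
bioclimatic rasters, jurisdictions (contiguous cell blocks with island
flags and native-genus lists), species with a nested taxonomy,
climatic niches and log-normal traits, and introduction records whose
outcomes are Bernoulli draws from a known logit model — so the whole
pipeline can be exercised end-to-end and its estimates compared with
the generating parameters.

The generating model is exactly the model the analysis fits: the
linear predictor is built from the same standardized covariates the
dataset module produces, plus random intercepts for family, genus,
species and location drawn from centered normals with configured SDs.
Default effect sizes and variance components echo the analysis this
package reproduces: strong positive climate-match and intentional-
release effects, an island advantage, a small negative distance
effect, and a location variance that dwarfs the taxonomic ones.

Randomness: one integer seed; each stage (world / species /
introductions) derives its own substream from (seed, stage-id), so
adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from . import climate, geo
from .dataset import INTENTIONAL_TAGS, UNINTENTIONAL_TAGS, assemble_dataset
from .glmm import RandomStructure, build_design, build_random_terms
from .rasters import Raster, RasterStack, write_ascii_grid

_STAGE_WORLD, _STAGE_SPECIES, _STAGE_INTRO = 1, 2, 3

__all__ = ["GeneratorConfig", "SyntheticWorld", "simulate_world",
           "simulate_species", "simulate_introductions", "simulate_all"]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults are the stated study scale
    (~100 species, 40 jurisdictions, ~400 species-jurisdiction pairs)."""

    seed: int = 0
    # grid: 60 x 80 cells of 0.5 degrees spanning 30 x 40 degrees
    n_grid_rows: int = 60
    n_grid_cols: int = 80
    west: float = -20.0
    south: float = -15.0
    cellsize: float = 0.5
    n_variables: int = 14
    raster_noise_sd: float = 1.0
    raster_smooth_sigma: float = 3.0

    n_jurisdictions: int = 40
    island_fraction: float = 0.3

    n_families: int = 10
    n_genera: int = 30
    n_species: int = 100
    occ_min: int = 8
    occ_max: int = 40
    niche_width: float = 1.2  # in units of per-variable field SD
    body_meanlog: float = np.log(60.0)   # mm snout-vent length
    body_sdlog: float = 0.6
    clutch_meanlog: float = np.log(800.0)  # eggs per clutch
    clutch_sdlog: float = 1.2
    body_clutch_corr: float = 0.75
    larval_stage_p: float = 0.8
    range_meanlog: float = np.log(5e5)   # km^2
    range_sdlog: float = 1.5
    habitat_max: int = 8
    missing_body_rate: float = 0.10
    missing_clutch_rate: float = 0.10

    n_records: int = 400
    intentional_fraction: float = 0.45
    unknown_fraction: float = 0.15
    percentile_q: int = 90
    #: true fixed effects keyed by design-column label (standardized scale)
    beta: dict = field(default_factory=lambda: {
        "(Intercept)": 0.3,
        "climate_match": 1.2,
        "intentionality[unintentional]": -1.5,
        "intentionality[unknown]": -0.75,
        "island": 0.8,
        "distance": -0.4,
        "larval_stage": -0.6,
    })
    #: true random-intercept SDs keyed by term label
    random_sds: dict = field(default_factory=lambda: {
        "family": 0.402,
        "family:genus": 0.429,
        "family:genus:species": 0.550,
        "location": 1.683,
    })

    def validate(self) -> None:
        if self.n_grid_rows < 4 or self.n_grid_cols < 4:
            raise ValueError("grid must be at least 4x4")
        if any(sd < 0 for sd in self.random_sds.values()):
            raise ValueError("random-effect SDs must be >= 0")
        for p in (self.island_fraction, self.intentional_fraction,
                  self.unknown_fraction, self.larval_stage_p,
                  self.missing_body_rate, self.missing_clutch_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.intentional_fraction + self.unknown_fraction > 1.0:
            raise ValueError("intentional + unknown fraction exceeds 1")


def _rng(cfg: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, plus the generating truth."""

    cfg: GeneratorConfig
    stack: RasterStack
    jurisdictions: pd.DataFrame  # jurisdiction_id, centroid_lat/lon, is_island, native_genera, cells
    jurisdiction_cells: dict[str, list[tuple[int, int]]]
    species: pd.DataFrame | None = None        # species_id, family, genus, traits
    occurrences: pd.DataFrame | None = None    # species_id, longitude, latitude
    records: pd.DataFrame | None = None        # species_id, jurisdiction_id, outcome, pathways
    truth: dict | None = None                  # beta, random_sds, per-record eta, covariates

    def write(self, out_dir: str | Path) -> None:
        """Write rasters (.asc), CSV inputs and the ground-truth JSON."""
        out = Path(out_dir)
        (out / "rasters").mkdir(parents=True, exist_ok=True)
        for name in self.stack.names:
            write_ascii_grid(self.stack.rasters[name], out / "rasters" / f"{name}.asc")
        self.jurisdictions.to_csv(out / "jurisdictions.csv", index=False)
        if self.species is not None:
            self.species.to_csv(out / "traits.csv", index=False)
        if self.occurrences is not None:
            self.occurrences.to_csv(out / "occurrences.csv", index=False)
        if self.records is not None:
            self.records.to_csv(out / "records.csv", index=False)
        if self.truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(self.truth, fh, indent=1, default=float)


def simulate_world(cfg: GeneratorConfig) -> SyntheticWorld:
    """Rasters and jurisdictions.

    Each bioclimatic field is a low-order lat/lon trend plus Gaussian-
    smoothed noise; jurisdictions tile the grid into contiguous blocks.
    """
    cfg.validate()
    rng = _rng(cfg, _STAGE_WORLD)
    nr, nc = cfg.n_grid_rows, cfg.n_grid_cols
    rows = np.arange(nr)[:, None] / max(nr - 1, 1)
    cols = np.arange(nc)[None, :] / max(nc - 1, 1)
    rasters = {}
    for v in range(cfg.n_variables):
        a, b, c = rng.normal(scale=3.0, size=3)
        trend = a * rows + b * cols + c + a * b * rows * cols
        noise = rng.normal(size=(nr, nc))
        if cfg.raster_noise_sd > 0:
            smooth = ndimage.gaussian_filter(noise, cfg.raster_smooth_sigma)
            sd = smooth.std()
            noise = smooth / sd * cfg.raster_noise_sd if sd > 0 else smooth
        else:
            noise = np.zeros((nr, nc))
        name = f"bio{v + 1:02d}"
        rasters[name] = Raster(trend + noise, cfg.west, cfg.south, cfg.cellsize)
    stack = RasterStack(rasters)

    # contiguous rectangular blocks, row-major, first n_jurisdictions kept
    n_block_rows = max(1, int(round(np.sqrt(cfg.n_jurisdictions * nr / nc))))
    n_block_cols = int(np.ceil(cfg.n_jurisdictions / n_block_rows))
    while n_block_rows * n_block_cols < cfg.n_jurisdictions:
        n_block_cols += 1
    if n_block_rows > nr or n_block_cols > nc:
        raise ValueError("grid too small for the requested number of jurisdictions")
    row_edges = np.linspace(0, nr, n_block_rows + 1).astype(int)
    col_edges = np.linspace(0, nc, n_block_cols + 1).astype(int)
    grid = stack.grid
    jur_rows, jur_cells = [], {}
    k = 0
    island_flags = rng.random(cfg.n_jurisdictions) < cfg.island_fraction
    for i in range(n_block_rows):
        for j in range(n_block_cols):
            if k >= cfg.n_jurisdictions:
                break
            cells = [(r, c)
                     for r in range(row_edges[i], row_edges[i + 1])
                     for c in range(col_edges[j], col_edges[j + 1])]
            if not cells:
                continue
            jid = f"J{k + 1:02d}"
            centers = [grid.cell_center(r, c) for r, c in cells]
            lat, lon = geo.centroid([la for _, la in centers], [lo for lo, _ in centers])
            jur_rows.append({
                "jurisdiction_id": jid,
                "centroid_lat": lat,
                "centroid_lon": lon,
                "is_island": int(island_flags[k]),
                "native_genera": "",
                "cells": ";".join(f"{r}:{c}" for r, c in cells),
            })
            jur_cells[jid] = cells
            k += 1
    if k < cfg.n_jurisdictions:
        raise ValueError("grid too small for the requested number of jurisdictions")
    return SyntheticWorld(cfg, stack, pd.DataFrame(jur_rows), jur_cells)


def simulate_species(world: SyntheticWorld, cfg: GeneratorConfig | None = None) -> SyntheticWorld:
    """Taxonomy, climatic niches, occurrences and traits.

    Occurrence cells are sampled from the cells whose standardized
    climate lies inside the species' axis-aligned niche ellipsoid
    (mean squared z-displacement from the niche center below 1); the
    ellipsoid is widened stepwise for species whose draw lands in a
    climatically extreme cell, and a species whose niche matches no
    cells raises an error naming it.
    """
    cfg = cfg or world.cfg
    rng = _rng(cfg, _STAGE_SPECIES)
    cube = world.stack.as_array()  # (v, nr, nc)
    nv, nr, nc = cube.shape
    flat = cube.reshape(nv, -1)
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    sd[sd == 0] = 1.0
    z = (flat - mean[:, None]) / sd[:, None]  # standardized climate per cell

    fam_of_genus = rng.integers(0, cfg.n_families, size=cfg.n_genera)
    genus_of_species = rng.integers(0, cfg.n_genera, size=cfg.n_species)

    sp_rows, occ_rows = [], []
    grid = world.stack.grid
    for s in range(cfg.n_species):
        sid = f"S{s + 1:03d}"
        g = int(genus_of_species[s])
        f = int(fam_of_genus[g])
        center_cell = int(rng.integers(0, nr * nc))
        width = cfg.niche_width
        for _ in range(8):
            d2 = np.mean(((z - z[:, center_cell][:, None]) / width) ** 2, axis=0)
            inside = np.flatnonzero(d2 <= 1.0)
            if inside.size >= max(climate.MIN_OCCURRENCES, cfg.occ_min):
                break
            width *= 1.5
        if inside.size == 0:
            raise ValueError(f"niche of species {sid} matches no cells")
        n_occ = int(rng.integers(cfg.occ_min, cfg.occ_max + 1))
        chosen = rng.choice(inside, size=min(n_occ, inside.size), replace=False)
        for cell in np.sort(chosen):
            r, c = divmod(int(cell), nc)
            lon, lat = grid.cell_center(r, c)
            jit = (rng.random(2) - 0.5) * 0.8 * cfg.cellsize
            occ_rows.append({"species_id": sid,
                             "longitude": lon + jit[0], "latitude": lat + jit[1]})
        # traits: correlated log body/clutch size, the rest independent
        zb, zc = rng.multivariate_normal(
            [0.0, 0.0],
            [[1.0, cfg.body_clutch_corr], [cfg.body_clutch_corr, 1.0]])
        body = np.exp(cfg.body_meanlog + cfg.body_sdlog * zb)
        clutch = np.exp(cfg.clutch_meanlog + cfg.clutch_sdlog * zc)
        sp_rows.append({
            "species_id": sid,
            "family": f"F{f + 1:02d}",
            "genus": f"G{g + 1:02d}",
            "min_body_size_mm": body,
            "min_clutch_size": clutch,
            "larval_stage": int(rng.random() < cfg.larval_stage_p),
            "range_km2": float(np.exp(cfg.range_meanlog + cfg.range_sdlog * rng.normal())),
            "habitat_count": int(rng.integers(1, cfg.habitat_max + 1)),
        })
    species = pd.DataFrame(sp_rows)
    miss_b = rng.random(cfg.n_species) < cfg.missing_body_rate
    miss_c = rng.random(cfg.n_species) < cfg.missing_clutch_rate
    species.loc[miss_b, "min_body_size_mm"] = np.nan
    species.loc[miss_c, "min_clutch_size"] = np.nan
    occurrences = pd.DataFrame(occ_rows)

    # native-genus lists: a genus is native wherever its species occur
    native: dict[str, set] = {j: set() for j in world.jurisdiction_cells}
    cell_to_jur = {}
    for jid, cells in world.jurisdiction_cells.items():
        for cell in cells:
            cell_to_jur[cell] = jid
    occ_cells = {}
    for row in occurrences.itertuples():
        cell = grid.cell_of(row.longitude, row.latitude)
        if cell is None:
            continue
        occ_cells.setdefault(row.species_id, set()).add(cell)
    genus_of = species.set_index("species_id")["genus"]
    for sid, cells in occ_cells.items():
        for cell in cells:
            jid = cell_to_jur.get(cell)
            if jid is not None:
                native[jid].add(genus_of[sid])
    world.jurisdictions = world.jurisdictions.copy()
    world.jurisdictions["native_genera"] = [
        ";".join(sorted(native[j])) for j in world.jurisdictions["jurisdiction_id"]
    ]
    world.species = species
    world.occurrences = occurrences
    return world


def compute_pair_covariates(world: SyntheticWorld,
                            pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Climate scores and centroid distances for species-jurisdiction
    pairs, via the same code paths the analysis uses (so stored
    covariates are exactly recomputable)."""
    stack = world.stack
    envelopes: dict[str, climate.ClimateEnvelope] = {}
    region_cells: dict[str, np.ndarray] = {}
    sp_centroids: dict[str, tuple[float, float]] = {}
    occ = world.occurrences
    for sid in pairs["species_id"].unique():
        pts = occ[occ["species_id"] == sid]
        training = climate.extract_cell_climate(stack, pts["longitude"], pts["latitude"])
        envelopes[sid] = climate.build_envelope(training, world.cfg.percentile_q, sid)
        sp_centroids[sid] = geo.centroid(pts["latitude"], pts["longitude"])
    cube = stack.as_array()
    for jid, cells in world.jurisdiction_cells.items():
        rc = np.array(cells)
        region_cells[jid] = cube[:, rc[:, 0], rc[:, 1]].T
    jur = world.jurisdictions.set_index("jurisdiction_id")
    score_rows, dist_rows = [], []
    for row in pairs.itertuples():
        ms = climate.climate_match_score(envelopes[row.species_id],
                                         region_cells[row.jurisdiction_id],
                                         row.species_id, row.jurisdiction_id)
        score_rows.append({"species_id": row.species_id,
                           "jurisdiction_id": row.jurisdiction_id,
                           "score": ms.score,
                           "n_cells_scored": ms.n_cells_scored,
                           "n_cells_perfect_excluded": ms.n_cells_perfect_excluded})
        d = geo.great_circle_km(
            sp_centroids[row.species_id],
            (jur.at[row.jurisdiction_id, "centroid_lat"],
             jur.at[row.jurisdiction_id, "centroid_lon"]))
        dist_rows.append({"species_id": row.species_id,
                          "jurisdiction_id": row.jurisdiction_id,
                          "distance_km": d})
    return pd.DataFrame(score_rows), pd.DataFrame(dist_rows)


def simulate_introductions(world: SyntheticWorld,
                           cfg: GeneratorConfig | None = None) -> SyntheticWorld:
    """Introduction records with outcomes drawn from the known model.

    Covariates are computed (and standardized) exactly as the analysis
    will recompute them; the latent linear predictor of every record is
    stored in the truth block for oracle tests.
    """
    cfg = cfg or world.cfg
    if world.species is None:
        raise ValueError("simulate_species must run before simulate_introductions")
    if cfg.n_records < 1:
        raise ValueError("zero introduction records requested")
    rng = _rng(cfg, _STAGE_INTRO)

    n_sp = len(world.species)
    n_jur = len(world.jurisdictions)
    all_pairs = n_sp * n_jur
    if cfg.n_records > all_pairs:
        raise ValueError("more records requested than species x jurisdiction pairs")
    chosen = rng.choice(all_pairs, size=cfg.n_records, replace=False)
    chosen.sort()
    sids = world.species["species_id"].to_numpy()
    jids = world.jurisdictions["jurisdiction_id"].to_numpy()
    pairs = pd.DataFrame({
        "species_id": sids[chosen // n_jur],
        "jurisdiction_id": jids[chosen % n_jur],
    })

    # pathways consistent with a drawn intentionality class
    u = rng.random(cfg.n_records)
    intentional = sorted(INTENTIONAL_TAGS)
    unintentional = sorted(UNINTENTIONAL_TAGS)
    pathways = []
    for ui in u:
        if ui < cfg.intentional_fraction:
            pathways.append(intentional[int(rng.integers(len(intentional)))])
        elif ui < cfg.intentional_fraction + cfg.unknown_fraction:
            pathways.append("unknown")
        else:
            pathways.append(unintentional[int(rng.integers(len(unintentional)))])
    records = pairs.copy()
    records["outcome"] = 0  # placeholder until eta is formed
    records["pathways"] = pathways

    scores, dists = compute_pair_covariates(world, pairs)
    table, _ = assemble_dataset(records, world.species, scores, dists,
                                world.jurisdictions, include_size_traits=False)

    beta = dict(cfg.beta)
    factor_cols = sorted({k.split("[")[0] for k in beta if k != "(Intercept)"})
    X, labels = build_design(table, factor_cols)
    beta_vec = np.array([beta.get(lbl, 0.0) for lbl in labels])
    eta = X @ beta_vec

    rs = RandomStructure()
    terms = build_random_terms(table, rs)
    u_draws = {}
    for t in terms:
        sd = float(cfg.random_sds.get(t.label, 0.0))
        u_t = rng.normal(0.0, sd, size=t.n_levels)
        u_draws[t.label] = u_t
        eta = eta + u_t[t.codes]

    outcome = (rng.random(len(table)) < special.expit(eta)).astype(int)
    key = table["species_id"] + "|" + table["jurisdiction_id"]
    outcome_map = dict(zip(key, outcome))
    eta_map = dict(zip(key, eta))
    rec_key = records["species_id"] + "|" + records["jurisdiction_id"]
    keep = rec_key.isin(outcome_map)  # drops pairs with undefined climate score
    records = records[keep].reset_index(drop=True)
    rec_key = rec_key[keep].reset_index(drop=True)
    records["outcome"] = [outcome_map[k] for k in rec_key]

    world.records = records
    world.truth = {
        "beta": beta,
        "random_sds": dict(cfg.random_sds),
        "random_intercepts": {lbl: list(map(float, v)) for lbl, v in u_draws.items()},
        "eta": {k: float(eta_map[k]) for k in rec_key},
        "design_labels": labels,
    }
    return world


def simulate_all(cfg: GeneratorConfig) -> SyntheticWorld:
    """World, species and introductions in one call."""
    world = simulate_world(cfg)
    simulate_species(world, cfg)
    simulate_introductions(world, cfg)
    return world
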