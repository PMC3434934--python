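import numpy as np
import pandas as pd
import pytest

from anurainvade.dataset import assemble_dataset
from anurainvade.simulate import (GeneratorConfig, compute_pair_covariates,
                                  simulate_all)


def small_config(**overrides) -> GeneratorConfig:
    """A desk-scale world: 30x40 grid, 25 species, 12 jurisdictions."""
    base = dict(
        seed=7,
        n_grid_rows=30, n_grid_cols=40,
        n_jurisdictions=12, island_fraction=0.4,
        n_families=4, n_genera=8, n_species=25,
        occ_min=8, occ_max=20,
        n_records=150,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def small_tables(small_world):
    """(with_size table, without_size table) assembled from the small world."""
    w = small_world
    pairs = w.records[["species_id", "jurisdiction_id"]]
    scores, dists = compute_pair_covariates(w, pairs)
    sd2, _ = assemble_dataset(w.records, w.species, scores, dists,
                              w.jurisdictions, include_size_traits=True)
    sd3, _ = assemble_dataset(w.records, w.species, scores, dists,
                              w.jurisdictions, include_size_traits=False)
    return sd2, sd3


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no package internals)
# ---------------------------------------------------------------------------

def oracle_gower(x, y, ranges):
    total, used = 0.0, 0
    for xi, yi, ri in zip(x, y, ranges):
        if ri > 0:
            total += abs(xi - yi) / ri
            used += 1
    assert used > 0
    return total / used


def oracle_similarity(cell, training, ranges):
    best = 0.0
    for t in training:
        s = 1.0 - oracle_gower(cell, t, ranges)
        best = max(best, s)
    return best


def oracle_match_score(training, region, q):
    """Full enumeration of the leave-one-out envelope and region score."""
    training = [list(t) for t in training]
    ranges = [max(col) - min(col) for col in zip(*training)]
    loo = []
    for j, t in enumerate(training):
        others = [u for i, u in enumerate(training) if i != j]
        loo.append(oracle_similarity(t, others, ranges))
    threshold = np.percentile(loo, 100 - q)
    sims = [oracle_similarity(c, training, ranges) for c in region]
    kept = [s for s in sims if s < 1.0 - 1e-9]
    n_excluded = len(sims) - len(kept)
    if not kept:
        return np.nan, 0, n_excluded
    score = sum(s >= threshold for s in kept) / len(kept)
    return score, len(kept), n_excluded
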