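import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import special

from anurainvade.dataset import assemble_dataset
from anurainvade.glmm import RandomStructure, build_design, build_random_terms
from anurainvade.simulate import (GeneratorConfig, compute_pair_covariates,
                                  simulate_all, simulate_species, simulate_world)
from conftest import small_config


class TestDeterminism:
    def test_same_seed_same_world(self):
        cfg = small_config()
        w1, w2 = simulate_all(cfg), simulate_all(small_config())
        for name in w1.stack.names:
            np.testing.assert_array_equal(w1.stack.rasters[name].data,
                                          w2.stack.rasters[name].data)
        pd.testing.assert_frame_equal(w1.records, w2.records)
        pd.testing.assert_frame_equal(w1.species, w2.species)

    def test_written_outputs_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_all(small_config()).write(d1)
        simulate_all(small_config()).write(d2)
        for f in sorted(d1.rglob("*")):
            if f.is_file():
                assert f.read_bytes() == (d2 / f.relative_to(d1)).read_bytes(), f.name

    def test_different_seed_differs(self):
        w1 = simulate_all(small_config())
        w2 = simulate_all(small_config(seed=8))
        assert not w1.records.equals(w2.records)


class TestWorld:
    def test_island_fraction_one(self):
        w = simulate_world(small_config(island_fraction=1.0))
        assert (w.jurisdictions["is_island"] == 1).all()

    def test_zero_noise_rasters_are_smooth_trends(self):
        w = simulate_world(small_config(raster_noise_sd=0.0))
        # a bilinear trend has exactly zero second difference along rows
        data = w.stack.rasters["bio01"].data
        second = np.diff(data, n=2, axis=0)
        np.testing.assert_allclose(second, 0.0, atol=1e-9)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_world(small_config(n_grid_rows=4, n_grid_cols=4,
                                        n_jurisdictions=400))

    def test_jurisdictions_partition_cells(self):
        w = simulate_world(small_config())
        all_cells = [c for cells in w.jurisdiction_cells.values() for c in cells]
        assert len(all_cells) == len(set(all_cells))


class TestSpecies:
    def test_trait_correlation_recovered(self):
        cfg = small_config(n_species=500, n_genera=40, n_families=10,
                           body_clutch_corr=0.9,
                           missing_body_rate=0.0, missing_clutch_rate=0.0)
        w = simulate_species(simulate_world(cfg), cfg)
        r = np.corrcoef(np.log(w.species["min_body_size_mm"]),
                        np.log(w.species["min_clutch_size"]))[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_occurrence_counts_within_configured_range(self, small_world):
        counts = small_world.occurrences.groupby("species_id").size()
        assert counts.min() >= 6  # envelope rule satisfied by construction
        assert counts.max() <= small_world.cfg.occ_max

    def test_taxonomy_is_nested(self, small_world):
        sp = small_world.species
        # each genus maps to exactly one family
        assert (sp.groupby("genus")["family"].nunique() == 1).all()


class TestIntroductions:
    def test_null_model_success_rate_half(self):
        cfg = GeneratorConfig(
            seed=123, n_grid_rows=40, n_grid_cols=50,
            n_jurisdictions=40, n_families=10, n_genera=30, n_species=250,
            n_records=10_000,
            beta={"(Intercept)": 0.0},
            random_sds={"family": 0, "family:genus": 0,
                        "family:genus:species": 0, "location": 0},
        )
        w = simulate_all(cfg)
        assert w.records["outcome"].mean() == pytest.approx(0.5, abs=0.015)

    def test_deeply_negative_intercept(self):
        cfg = small_config(beta={"(Intercept)": -10.0},
                           random_sds={"family": 0, "family:genus": 0,
                                       "family:genus:species": 0, "location": 0})
        w = simulate_all(cfg)
        assert w.records["outcome"].mean() < 0.01

    def test_zero_records_rejected(self):
        with pytest.raises(ValueError):
            simulate_all(small_config(n_records=0))

    def test_intentionality_fractions(self):
        w = simulate_all(small_config(n_records=300, n_species=30,
                                      intentional_fraction=1.0,
                                      unknown_fraction=0.0))
        from anurainvade.dataset import classify_intentionality
        classes = {classify_intentionality({p}) for p in w.records["pathways"]}
        assert classes == {"intentional"}


class TestSelfConsistency:
    def test_stored_eta_recomputable_from_world(self, small_world):
        """Rebuilding covariates and the linear predictor from the stored
        world must reproduce the recorded truth exactly."""
        w = small_world
        pairs = w.records[["species_id", "jurisdiction_id"]]
        scores, dists = compute_pair_covariates(w, pairs)
        table, _ = assemble_dataset(w.records, w.species, scores, dists,
                                    w.jurisdictions, include_size_traits=False)
        beta = w.truth["beta"]
        factor_cols = sorted({k.split("[")[0] for k in beta if k != "(Intercept)"})
        X, labels = build_design(table, factor_cols)
        eta = X @ np.array([beta.get(l, 0.0) for l in labels])
        for t in build_random_terms(table, RandomStructure()):
            eta = eta + np.asarray(w.truth["random_intercepts"][t.label])[t.codes]
        stored = np.array([w.truth["eta"][f"{s}|{j}"] for s, j in
                           zip(table["species_id"], table["jurisdiction_id"])])
        np.testing.assert_allclose(eta, stored, atol=1e-12)

    def test_trait_missingness_only_difference_between_variants(self, small_world):
        w = small_world
        pairs = w.records[["species_id", "jurisdiction_id"]]
        scores, dists = compute_pair_covariates(w, pairs)
        sd2, _ = assemble_dataset(w.records, w.species, scores, dists,
                                  w.jurisdictions, include_size_traits=True)
        sd3, _ = assemble_dataset(w.records, w.species, scores, dists,
                                  w.jurisdictions, include_size_traits=False)
        complete = set(w.species.dropna(subset=["min_body_size_mm",
                                                "min_clutch_size"])["species_id"])
        expected = sd3[sd3["species_id"].isin(complete)]
        assert len(sd2) == len(expected)
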