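import numpy as np
import pandas as pd
import pytest

from anurainvade.glmm import FitResult
from anurainvade.multimodel import (ModelTable, akaike_weights, enumerate_models,
                                    model_average, rank_models,
                                    relative_importance, top_set)


def make_fit(spec, aicc_value, coef=None, se=None, n=100):
    coef = {"(Intercept)": 0.0, **(coef or {})}
    se = {"(Intercept)": 0.1, **(se or {})}
    s_coef = pd.Series(coef)
    return FitResult(model_spec=tuple(spec), coef=s_coef,
                     se=pd.Series(se).reindex(s_coef.index).fillna(0.1),
                     variance_components=pd.DataFrame(),
                     loglik=-aicc_value / 2, k=len(coef), n=n,
                     aicc=aicc_value, converged=True)


class TestEnumerateModels:
    @pytest.mark.parametrize("m,expected", [(0, 1), (3, 8), (10, 1024)])
    def test_subset_counts(self, m, expected):
        candidates = list(range(1, m + 1))
        specs = enumerate_models(candidates)
        assert len(specs) == expected
        assert specs[0] == ()  # null model always present

    def test_guard_against_explosion(self):
        with pytest.raises(ValueError):
            enumerate_models(list(range(1, 11)) + ["a", "b", "c"])

    def test_specs_ordered_by_factor_code(self):
        specs = enumerate_models(["climate_match", "distance"])  # codes 8, 4
        assert ("distance", "climate_match") in specs


class TestAkaikeWeights:
    def test_hand_values(self):
        w = akaike_weights([0.0, 2.0])
        np.testing.assert_allclose(w, [1 / (1 + np.e**-1), 1 - 1 / (1 + np.e**-1)])
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=5e-5)

    def test_degenerate_cases(self):
        np.testing.assert_allclose(akaike_weights([0.0]), [1.0])
        np.testing.assert_allclose(akaike_weights([0.0, 0.0]), [0.5, 0.5])
        with pytest.raises(ValueError):
            akaike_weights([])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = np.sort(rng.exponential(3, size=20))
        d -= d[0]
        assert akaike_weights(d).sum() == pytest.approx(1.0, abs=1e-12)


class TestRankModels:
    def test_delta_is_difference_from_best(self):
        fits = [make_fit(("distance",), 101.17), make_fit(("island",), 100.0)]
        table = rank_models(fits)
        np.testing.assert_allclose(table.entries["delta_aicc"], [0.0, 1.17])
        assert table.entries["spec_code"].tolist() == ["7", "4"]

    def test_order_invariance(self):
        fits = [make_fit((), 105.0), make_fit(("island",), 100.0),
                make_fit(("distance",), 101.0)]
        t1 = rank_models(fits)
        t2 = rank_models(fits[::-1])
        pd.testing.assert_frame_equal(t1.entries, t2.entries)

    def test_differing_n_rejected(self):
        fits = [make_fit((), 100.0, n=100), make_fit(("island",), 99.0, n=90)]
        with pytest.raises(ValueError, match="not comparable"):
            rank_models(fits)


class TestTopSet:
    def test_strict_delta_boundary(self):
        fits = [make_fit(("island",), 100.0), make_fit(("distance",), 104.0),
                make_fit((), 103.9)]
        top = top_set(rank_models(fits), 4.0)
        # delta exactly 4 excluded, 3.9 retained
        assert top.entries["spec_code"].tolist() == ["7", "intercept_only"]
        assert top.entries["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_published_delta_pattern_all_retained(self):
        # a ten-model set whose deltas all lie below 4 keeps every model
        deltas = [0, 1.1658, 1.2094, 1.2129, 1.2226, 1.2412,
                  1.4550, 1.5907, 1.8732, 1.9438]
        table = rank_models([make_fit((), 100.0 + d) for d in deltas])
        np.testing.assert_allclose(table.entries["delta_aicc"], sorted(deltas),
                                   atol=1e-12)
        assert len(top_set(table, 4.0)) == 10


class TestModelAverage:
    def test_single_model_identity(self):
        fit = make_fit(("climate_match",), 100.0,
                       coef={"climate_match": 1.3}, se={"climate_match": 0.2})
        top = top_set(rank_models([fit]))
        avg = model_average(top, [fit]).table.set_index("coefficient")
        assert avg.loc["climate_match", "estimate"] == pytest.approx(1.3)
        assert avg.loc["climate_match", "se"] == pytest.approx(0.2)
        assert avg.loc["climate_match", "importance"] == 1.0

    def test_equal_weights_identical_models_degenerate_variance(self):
        f1 = make_fit(("island",), 100.0, coef={"island": 1.0}, se={"island": 0.2})
        f2 = make_fit(("island", "distance"), 100.0,
                      coef={"island": 1.0, "distance": 0.0},
                      se={"island": 0.2, "distance": 0.1})
        top = top_set(rank_models([f1, f2]))
        avg = model_average(top, [f1, f2]).table.set_index("coefficient")
        assert avg.loc["island", "estimate"] == pytest.approx(1.0)
        assert avg.loc["island", "se"] == pytest.approx(0.2)

    def test_hand_unconditional_se_with_absence(self):
        """w=(0.75, 0.25), beta=(1, absent), se=(0.2, -):
        full average 0.75, unconditional SE 0.4276."""
        d2 = 2 * np.log(3.0)  # exp(-d2/2) = 1/3 -> weights 0.75 / 0.25
        f1 = make_fit(("climate_match",), 100.0,
                      coef={"climate_match": 1.0}, se={"climate_match": 0.2})
        f2 = make_fit((), 100.0 + d2)
        top = top_set(rank_models([f1, f2]))
        np.testing.assert_allclose(top.entries["weight"], [0.75, 0.25])
        avg = model_average(top, [f1, f2]).table.set_index("coefficient")
        est = avg.loc["climate_match", "estimate"]
        se = avg.loc["climate_match", "se"]
        assert est == pytest.approx(0.75)
        expected_se = 0.75 * np.sqrt(0.2**2 + 0.25**2) + 0.25 * 0.75
        assert se == pytest.approx(expected_se, abs=1e-12)
        assert avg.loc["climate_match", "importance"] == pytest.approx(0.75)
        # conditional average ignores the absent model
        assert avg.loc["climate_match", "estimate_conditional"] == pytest.approx(1.0)

    def test_full_average_shrinks_toward_zero(self):
        f1 = make_fit(("climate_match",), 100.0, coef={"climate_match": 1.5})
        f2 = make_fit(("island",), 101.0, coef={"island": 0.7})
        top = top_set(rank_models([f1, f2]))
        avg = model_average(top, [f1, f2]).table.set_index("coefficient")
        for lbl in ("climate_match", "island"):
            assert abs(avg.loc[lbl, "estimate"]) <= abs(
                avg.loc[lbl, "estimate_conditional"]) + 1e-12

    def test_order_invariance(self):
        f1 = make_fit(("climate_match",), 100.0, coef={"climate_match": 1.5})
        f2 = make_fit(("island",), 101.0, coef={"island": 0.7})
        a1 = model_average(top_set(rank_models([f1, f2])), [f1, f2]).table
        a2 = model_average(top_set(rank_models([f2, f1])), [f2, f1]).table
        pd.testing.assert_frame_equal(a1, a2)


class TestRelativeImportance:
    def test_everywhere_and_nowhere(self):
        f1 = make_fit(("climate_match", "island"), 100.0,
                      coef={"climate_match": 1.0, "island": 0.5})
        f2 = make_fit(("climate_match",), 101.0, coef={"climate_match": 1.0})
        top = top_set(rank_models([f1, f2]))
        assert relative_importance(top, "climate_match") == pytest.approx(1.0)
        assert relative_importance(top, "distance") == 0.0

    def test_partial_importance_equals_model_weight(self):
        f1 = make_fit(("climate_match",), 100.0, coef={"climate_match": 1.0})
        f2 = make_fit((), 102.0)
        top = top_set(rank_models([f1, f2]))
        assert relative_importance(top, "climate_match") == pytest.approx(
            1 / (1 + np.e**-1))
        assert relative_importance(top, 8) == pytest.approx(0.7311, abs=5e-5)
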