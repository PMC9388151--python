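"""Monte-Carlo propagation, composite index, serving sizes."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_category, make_product
from foodprint.composition import infer_composition
from foodprint.impact import (
    CompositeReference,
    composite_score,
    estimate_serving_size,
    impact_once,
    monte_carlo,
    per_serving,
    sample_observation,
)
from foodprint.model import INDICATORS, EnvDatabase, ProductRecord


def scored(product, db, n_iter=1000, seed=0):
    return monte_carlo(infer_composition(product), product, db, n_iter, seed)


class TestSampleObservation:
    def test_single_observation_always_drawn(self):
        cat = make_category("c", [(2.0, 1.0, 1.0, 1.0)])
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert sample_observation(cat, False, rng).ghg_kgco2e_per_kg == 2.0

    def test_organic_subset_used_when_five_or_more(self):
        rows = [(1.0, 1, 1, 1, 1.0, True)] * 5 + [(9.0, 1, 1, 1, 1.0, False)] * 5
        cat = make_category("c", rows)
        rng = np.random.default_rng(1)
        draws = {sample_observation(cat, True, rng).ghg_kgco2e_per_kg for _ in range(50)}
        assert draws == {1.0}

    def test_organic_falls_back_below_five(self):
        rows = [(1.0, 1, 1, 1, 1.0, True)] * 4 + [(9.0, 1, 1, 1, 1.0, False)] * 6
        cat = make_category("c", rows)
        rng = np.random.default_rng(1)
        draws = {sample_observation(cat, True, rng).ghg_kgco2e_per_kg for _ in range(100)}
        assert 9.0 in draws  # conventional pool reached

    def test_weight_proportional_sampling(self):
        cat = make_category("c", [(1.0, 1, 1, 1, 3.0), (2.0, 1, 1, 1, 1.0)])
        rng = np.random.default_rng(2)
        draws = [sample_observation(cat, False, rng).ghg_kgco2e_per_kg for _ in range(4000)]
        assert np.mean(np.array(draws) == 1.0) == pytest.approx(0.75, abs=0.03)

    def test_fish_split_is_half_half(self):
        rows = [(1.0, 1, 1, 1, 1.0, False, "aquaculture")] * 3 + [
            (5.0, 1, 1, 1, 1.0, False, "capture")
        ] * 3
        cat = make_category("fish", rows, is_fish=True)
        rng = np.random.default_rng(3)
        draws = np.array(
            [sample_observation(cat, False, rng).ghg_kgco2e_per_kg for _ in range(10_000)]
        )
        assert np.mean(draws == 1.0) == pytest.approx(0.5, abs=0.02)


class TestImpactOnce:
    def test_unit_arithmetic_single_ingredient(self):
        db = EnvDatabase([make_category("c", [(2.0, 1.0, 1.0, 1.0)])])
        product = make_product("p", [None], category_ids=["c"])
        vec = impact_once(infer_composition(product), product, db, np.random.default_rng(0))
        assert vec[0] == pytest.approx(0.2)

    def test_fifty_fifty_split(self):
        db = EnvDatabase(
            [
                make_category("a", [(2.0, 0, 0, 0)]),
                make_category("b", [(4.0, 0, 0, 0)]),
            ]
        )
        product = make_product("p", [50.0, 50.0], category_ids=["a", "b"])
        vec = impact_once(infer_composition(product), product, db, np.random.default_rng(0))
        assert vec[0] == pytest.approx(0.3)

    def test_raw_equivalent_factor_dried_beef(self):
        # biltong-style: 100 g product containing 250 g raw-beef equivalent
        db = EnvDatabase([make_category("beef", [(20.0, 0, 0, 0)])])
        product = make_product("p", [None], category_ids=["beef"])
        product.ingredients[0].raw_equivalent_factor = 2.5
        vec = impact_once(infer_composition(product), product, db, np.random.default_rng(0))
        assert vec[0] == pytest.approx(5.0)

    def test_unmapped_ingredient_contributes_zero(self):
        db = EnvDatabase([make_category("a", [(2.0, 0, 0, 0)])])
        product = make_product("p", [50.0, 50.0], category_ids=["a", "a"])
        product.ingredients[1].category_id = None
        vec = impact_once(infer_composition(product), product, db, np.random.default_rng(0))
        assert vec[0] == pytest.approx(0.1)


class TestMonteCarlo:
    def test_degenerate_db_zero_spread(self):
        db = EnvDatabase([make_category("c", [(2.0, 3.0, 4.0, 5.0)])])
        product = make_product("p", [None], category_ids=["c"])
        dist = scored(product, db, n_iter=64)
        for k in INDICATORS:
            assert dist.sd[k] == pytest.approx(0.0, abs=1e-12)
            assert all(
                q == pytest.approx(dist.mean[k], abs=1e-12)
                for q in dist.quantiles[k].values()
            )

    def test_mean_matches_analytic_expectation(self, two_obs_db):
        # E[ghg per 100 g] = 0.1 * (1+3)/2 = 0.2
        product = make_product("p", [None], category_ids=["crop"])
        dist = scored(product, two_obs_db, n_iter=10_000, seed=5)
        se = dist.sd["ghg"] / np.sqrt(dist.n_iterations)
        assert abs(dist.mean["ghg"] - 0.2) < 3 * se

    def test_seed_reproducibility(self, two_obs_db):
        product = make_product("p", [None], category_ids=["crop"])
        a = scored(product, two_obs_db, n_iter=500, seed=9)
        b = scored(product, two_obs_db, n_iter=500, seed=9)
        assert a == b

    def test_quantiles_monotone(self, two_obs_db):
        product = make_product("p", [None], category_ids=["crop"])
        dist = scored(product, two_obs_db, n_iter=300, seed=1)
        for k in INDICATORS:
            values = [dist.quantiles[k][q] for q in sorted(dist.quantiles[k])]
            assert values == sorted(values)

    def test_convergence_rate_one_over_sqrt_n(self, two_obs_db):
        """SE of the MC mean shrinks consistently with 1/sqrt(n)."""
        product = make_product("p", [None], category_ids=["crop"])
        errors = {}
        for n in (100, 1000, 10_000):
            reps = [
                abs(scored(product, two_obs_db, n_iter=n, seed=s).mean["ghg"] - 0.2)
                for s in range(8)
            ]
            errors[n] = np.mean(reps)
        assert errors[10_000] < errors[100]
        # 100x more draws should shrink the error by roughly 10x (allow 3x slack)
        assert errors[10_000] < errors[100] / 3

    def test_invalid_iterations(self, two_obs_db):
        product = make_product("p", [None], category_ids=["crop"])
        with pytest.raises(ValueError):
            scored(product, two_obs_db, n_iter=0)


class TestCompositeScore:
    def _means(self, rows):
        return pd.DataFrame(rows, columns=list(INDICATORS))

    def test_corpus_maximum_scores_100(self):
        means = self._means([[10, 20, 30, 40], [1, 2, 3, 4]])
        scores, _ = composite_score(means)
        assert scores["0"].score == pytest.approx(100.0)

    def test_one_fifth_of_max_scores_20(self):
        means = self._means([[10, 20, 30, 40], [2, 4, 6, 8]])
        scores, _ = composite_score(means)
        assert scores["1"].score == pytest.approx(20.0)

    def test_zero_impact_scores_0(self):
        means = self._means([[10, 20, 30, 40], [0, 0, 0, 0]])
        scores, _ = composite_score(means)
        assert scores["1"].score == 0.0

    def test_scale_invariance_per_indicator(self):
        means = self._means([[10, 20, 30, 40], [3, 5, 7, 9], [1, 2, 3, 4]])
        scores, _ = composite_score(means)
        rescaled = means.copy()
        rescaled["water"] *= 1000.0
        scores2, _ = composite_score(rescaled)
        for pid in scores:
            assert scores2[pid].score == pytest.approx(scores[pid].score)

    def test_order_preserving(self):
        means = self._means([[10, 20, 30, 40], [5, 12, 18, 22], [4, 11, 17, 21]])
        scores, _ = composite_score(means)
        assert scores["1"].score >= scores["2"].score

    def test_all_zero_indicator_warns_and_scores_zero_component(self):
        means = self._means([[10, 0, 30, 40], [5, 0, 15, 20]])
        with pytest.warns(UserWarning, match="land"):
            scores, _ = composite_score(means)
        assert scores["0"].components["land"] == 0.0

    def test_reference_round_trip_scores_new_product(self):
        means = self._means([[10, 20, 30, 40], [2, 4, 6, 8]])
        _, reference = composite_score(means)
        again = CompositeReference.from_dict(reference.to_dict())
        new = dict(zip(INDICATORS, [1.0, 2.0, 3.0, 4.0]))
        assert again.score(new).score == pytest.approx(10.0)


class TestServingSize:
    def _corpus(self):
        a = ProductRecord("a", shelves=["S1"], serving_size_g=30.0)
        b = ProductRecord("b", shelves=["S1"], serving_size_g=50.0)
        c = ProductRecord("c", shelves=["S2"], serving_size_g=50.0)
        d = ProductRecord("d", shelves=["S3"], aisles=["A1"])
        e = ProductRecord("e", aisles=["A1"], serving_size_g=80.0)
        return [a, b, c, d, e]

    def test_own_serving_wins(self):
        corpus = self._corpus()
        product = ProductRecord("x", shelves=["S1"], serving_size_g=45.0)
        assert estimate_serving_size(product, corpus) == 45.0

    def test_shelf_mates_mean(self):
        product = ProductRecord("x", shelves=["S1"])
        assert estimate_serving_size(product, self._corpus()) == 40.0

    def test_two_shelves_mean_of_means(self):
        # shelf means 40 and 50 -> 45, not the pooled mean of 43.3
        product = ProductRecord("x", shelves=["S1", "S2"])
        assert estimate_serving_size(product, self._corpus()) == 45.0

    def test_aisle_fallback(self):
        product = ProductRecord("x", shelves=["S3"], aisles=["A1"])
        assert estimate_serving_size(product, self._corpus()) == 80.0

    def test_absent_when_no_information(self):
        product = ProductRecord("x", shelves=["S9"])
        assert estimate_serving_size(product, self._corpus()) is None


def test_per_serving_linearity():
    assert per_serving(4.0, 45.0) == pytest.approx(1.8)
    assert per_serving(4.0, 100.0) == 4.0
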