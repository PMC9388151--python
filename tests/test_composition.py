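"""Composition inference under labeling constraints.

Expected bounds were frozen from an independent brute-force enumeration of
the constrained simplex at 0.1 percentage-point resolution (tests/_oracles.py);
expected inference outputs for the prior-free cases follow by hand from the
stated policy (midpoint initialization, rescale to remaining mass, monotone
projection, clip).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import check_composition, grid_bounds
from conftest import make_product
from foodprint.composition import (
    InferencePolicy,
    PriorTable,
    build_prior_table,
    coverage_gate,
    feasible_bounds,
    infer_composition,
)
from foodprint.model import InfeasibleCompositionError


class TestPriorTable:
    def test_single_declared_sample(self):
        corpus = [make_product("a", [80.0, None], category_ids=["tomato", "oil"])]
        table = build_prior_table(corpus)
        assert table.cells[("tomato", "1")] == [80.0]

    def test_empty_when_nothing_declared(self):
        corpus = [make_product("a", [None, None])]
        assert build_prior_table(corpus).n_samples == 0

    def test_median_of_two(self):
        corpus = [
            make_product("a", [80.0, None], category_ids=["tomato", "oil"]),
            make_product("b", [60.0, None], category_ids=["tomato", "oil"]),
        ]
        assert build_prior_table(corpus).lookup("tomato", 1) == 70.0

    def test_fallback_order(self):
        table = PriorTable()
        table.add("tomato", 1, 80.0)
        table.add("oil", 2, 10.0)
        assert table.lookup("tomato", 1) == 80.0
        assert table.lookup("tomato", 2) == 80.0  # category marginal
        assert table.lookup("beans", 2) == 10.0  # rank-bucket marginal
        assert table.lookup("beans", 5) is None


class TestFeasibleBounds:
    # frozen from the grid oracle
    @pytest.mark.parametrize(
        "declared, expected_lo, expected_hi",
        [
            ([None] * 4, [25, 0, 0, 0], [100, 50, 100 / 3, 25]),
            ([None, 30.0, None], [40, 30, 0], [70, 30, 30]),
            ([None, None, 20.0, None], [30, 20, 20, 0], [60, 40, 20, 20]),
        ],
    )
    def test_matches_grid_enumeration(self, declared, expected_lo, expected_hi):
        lo, hi = feasible_bounds(make_product("p", declared))
        np.testing.assert_allclose(lo, expected_lo, atol=1e-6)
        np.testing.assert_allclose(hi, expected_hi, atol=1e-6)
        oracle = grid_bounds(declared)
        np.testing.assert_allclose(lo, oracle[0], atol=0.15)
        np.testing.assert_allclose(hi, oracle[1], atol=0.15)

    def test_forced_order_violation_is_infeasible(self):
        with pytest.raises(InfeasibleCompositionError, match="absorb"):
            feasible_bounds(make_product("p", [40.0, None]))
        assert grid_bounds([40.0, None]) is None

    def test_declared_sum_above_100_without_relaxation(self):
        policy = InferencePolicy(allow_relaxation=False)
        with pytest.raises(InfeasibleCompositionError, match="sum"):
            feasible_bounds(make_product("p", [80.0, 30.0]), policy)

    def test_information_narrows_intervals(self):
        # adding a declared value never widens any other interval
        base_lo, base_hi = feasible_bounds(make_product("p", [None, None, None, None]))
        lo, hi = feasible_bounds(make_product("p", [None, 30.0, None, None]))
        for i in (0, 2, 3):
            assert lo[i] >= base_lo[i] - 1e-9
            assert hi[i] <= base_hi[i] + 1e-9


class TestInferComposition:
    def test_fully_declared_identity(self):
        est = infer_composition(make_product("p", [60.0, 30.0, 10.0]))
        np.testing.assert_allclose(est.percents, [60, 30, 10])
        assert est.feasible

    def test_single_ingredient(self):
        est = infer_composition(make_product("p", [None]))
        np.testing.assert_allclose(est.percents, [100.0])

    def test_prior_free_three_ingredients(self):
        # midpoints (200/3, 25, 50/3) scaled by 300/325; already monotone and
        # inside bounds, so the fixed point is reached in one pass
        est = infer_composition(make_product("p", [None, None, None]))
        np.testing.assert_allclose(
            est.percents, [800 / 13, 300 / 13, 200 / 13], atol=1e-6
        )

    def test_prior_free_with_declared_middle(self):
        # midpoints of [40,70] and [0,30] are 55 and 15; they already absorb
        # the remaining 70%, so inference returns (55, 30, 15)
        est = infer_composition(make_product("p", [None, 30.0, None]))
        np.testing.assert_allclose(est.percents, [55, 30, 15], atol=1e-6)

    def test_prior_initialization_is_respected(self):
        # rank-1 prior median 80; the other unknown starts at its interval
        # midpoint 25, and (80, 25) rescales onto the simplex
        table = PriorTable()
        table.add("cat0", 1, 80.0)
        est = infer_composition(
            make_product("p", [None, None], category_ids=["cat0", "cat1"]), table
        )
        np.testing.assert_allclose(est.percents, [1600 / 21, 500 / 21], atol=1e-6)

    def test_declared_values_reproduced_exactly(self):
        est = infer_composition(make_product("p", [None, 23.75, None, 4.25]))
        assert est.percents[1] == 23.75
        assert est.percents[3] == 4.25

    def test_quid_above_100_normalized_with_raw_factor(self):
        est = infer_composition(make_product("p", [110.0]))
        np.testing.assert_allclose(est.percents, [100.0])
        np.testing.assert_allclose(est.raw_equivalent_factors, [1.1])
        assert any(note.startswith("quid_rescale") for note in est.notes)

    def test_declared_order_violation_noted_not_fatal(self):
        est = infer_composition(make_product("p", [30.0, 40.0, None]))
        assert est.feasible
        assert any("declared_order_violation" in n for n in est.notes)
        # declared values kept verbatim
        assert est.percents[0] == 30.0 and est.percents[1] == 40.0

    def test_all_unmapped_gives_zero_coverage(self):
        product = make_product("p", [None, None])
        for entry in product.ingredients:
            entry.category_id = None
        est = infer_composition(product)
        assert est.coverage == 0.0


@pytest.mark.parametrize(
    "coverage, expected", [(0.80, True), (0.75, True), (0.50, False)]
)
def test_coverage_gate_is_inclusive(coverage, expected):
    from foodprint.composition import CompositionEstimate

    est = CompositionEstimate(percents=np.array([100.0]), coverage=coverage)
    assert coverage_gate(est) is expected


# ---------------------------------------------------------------------------
# property tests


@st.composite
def labeled_products(draw):
    """A product with a feasible declared subset, built from a hidden true
    composition on the monotone simplex."""
    n = draw(st.integers(min_value=2, max_value=8))
    raw = draw(
        st.lists(
            st.floats(min_value=0.01, max_value=1.0), min_size=n, max_size=n
        )
    )
    true = np.sort(np.array(raw))[::-1]
    true = 100.0 * true / true.sum()
    mask = draw(st.lists(st.booleans(), min_size=n, max_size=n))
    declared = [float(true[i]) if mask[i] else None for i in range(n)]
    if all(d is not None for d in declared):
        declared[-1] = None
    return declared


@given(labeled_products())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_inference_respects_constraints(declared):
    """Output sums to 100, lies inside the exact bounds and is monotone
    except across the <=2% any-order exception."""
    product = make_product("p", declared)
    lo, hi = feasible_bounds(product)
    est = infer_composition(product)
    problems = check_composition(est.percents, declared, lo, hi)
    assert not problems, problems


@given(labeled_products(), st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_extra_declaration_never_widens_intervals(declared, data):
    """Monotonicity of information: fixing one more (feasible) value can only
    narrow other ingredients' feasible intervals."""
    unknown = [i for i, d in enumerate(declared) if d is None]
    if not unknown:
        return
    product = make_product("p", declared)
    lo, hi = feasible_bounds(product)
    pick = data.draw(st.sampled_from(unknown))
    est = infer_composition(product)
    richer = list(declared)
    richer[pick] = float(est.percents[pick])  # guaranteed-feasible new value
    lo2, hi2 = feasible_bounds(make_product("p", richer))
    for i in range(len(declared)):
        if i == pick:
            continue
        assert hi2[i] - lo2[i] <= hi[i] - lo[i] + 1e-6


def test_error_decreases_with_declared_information(small_corpus):
    """Mean absolute composition error shrinks as more percentages are
    declared (trend over the synthetic corpus)."""
    from foodprint.synthetic import SyntheticConfig, generate_corpus
    from foodprint.lexicon import assign_categories

    errors = {}
    for fraction in (0.0, 0.5, 1.0):
        corpus = generate_corpus(
            SyntheticConfig(n_products=200, declared_fraction=fraction, seed=3)
        )
        for product in corpus.products:
            assign_categories(product, corpus.lexicon)
        prior = build_prior_table(corpus.products)
        truth = corpus.truth.set_index(["product_id", "rank"])["true_percent"]
        abs_errors = []
        for product in corpus.products:
            est = infer_composition(product, prior)
            for entry in product.ingredients:
                abs_errors.append(
                    abs(
                        est.percent_at(entry.rank)
                        - truth[(product.product_id, entry.rank)]
                    )
                )
        errors[fraction] = float(np.mean(abs_errors))
    assert errors[1.0] < errors[0.5] < errors[0.0]
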