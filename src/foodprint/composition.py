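"""Infer percent-by-mass composition from ordered ingredient lists.

UK/EU labeling rules constrain a product's composition: percentages are
non-negative, sum to 100, are non-increasing in list order (ingredients are
listed by decreasing mass), and any QUID-declared percentage is fixed.  An
exception in the regulations allows ingredients at or below 2% to be listed
in any order, so monotonicity is not enforced between two ingredients whose
current estimates are both <= 2%.

Unknown percentages are initialized from priors built from the declared
percentages of similar products (same category and rank bucket), then
projected onto the constraint polytope by an iterated
scale / pool-adjacent-violators / clip scheme.  Inference is fully
deterministic — there is no random number generation here.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import InfeasibleCompositionError, ProductRecord

__all__ = [
    "RANK_BUCKETS",
    "rank_bucket",
    "PriorTable",
    "build_prior_table",
    "InferencePolicy",
    "CompositionEstimate",
    "feasible_bounds",
    "infer_composition",
    "coverage_gate",
]

#: Rank buckets used for prior cells; ranks >= 5 share the "5+" bucket
#: because long ingredient tails are sparse.
RANK_BUCKETS = ("1", "2", "3", "4", "5+")

#: UK rule: ingredients at or below this percentage may be listed in any order.
TWO_PERCENT = 2.0


def rank_bucket(rank: int) -> str:
    return str(rank) if rank < 5 else "5+"


@dataclass
class PriorTable:
    """Empirical samples of declared percentages, keyed by
    (category_id, rank_bucket), with per-category and per-bucket marginals
    for fallback.  Cells are only ever built from declared values."""

    cells: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    category_marginals: dict[str, list[float]] = field(default_factory=dict)
    bucket_marginals: dict[str, list[float]] = field(default_factory=dict)

    def add(self, category_id: str | None, rank: int, declared_percent: float) -> None:
        if declared_percent <= 0:
            raise ValueError("prior samples must be > 0")
        bucket = rank_bucket(rank)
        if category_id is not None:
            self.cells.setdefault((category_id, bucket), []).append(declared_percent)
            self.category_marginals.setdefault(category_id, []).append(declared_percent)
        self.bucket_marginals.setdefault(bucket, []).append(declared_percent)

    def lookup(self, category_id: str | None, rank: int) -> float | None:
        """Median of the most specific non-empty sample:
        (category, bucket) -> category marginal -> bucket marginal."""
        bucket = rank_bucket(rank)
        if category_id is not None:
            cell = self.cells.get((category_id, bucket))
            if cell:
                return statistics.median(cell)
            marginal = self.category_marginals.get(category_id)
            if marginal:
                return statistics.median(marginal)
        marginal = self.bucket_marginals.get(bucket)
        if marginal:
            return statistics.median(marginal)
        return None

    @property
    def n_samples(self) -> int:
        return sum(len(v) for v in self.bucket_marginals.values())


def build_prior_table(corpus: list[ProductRecord]) -> PriorTable:
    """Collect declared percentages from a (category-mapped) corpus.

    One sample is appended per declared (category, rank bucket) occurrence;
    an empty corpus yields a valid empty table.
    """
    table = PriorTable()
    for product in corpus:
        for entry in product.ingredients:
            if entry.declared_percent is not None:
                table.add(entry.category_id, entry.rank, entry.declared_percent)
    return table


@dataclass
class InferencePolicy:
    """Knobs of the inference step (all deterministic)."""

    coverage_threshold: float = 0.75
    two_percent_relaxation: bool = True
    allow_relaxation: bool = True
    tol: float = 1e-6
    max_iter: int = 100


@dataclass
class CompositionEstimate:
    """Result of composition inference for one product.

    ``percents`` aligns with ingredient ranks and sums to 100 (QUID excess
    above 100 is normalized away and carried in ``raw_equivalent_factors``).
    ``coverage`` is the mass fraction assigned to a mapped category.
    """

    percents: np.ndarray
    coverage: float
    feasible: bool = True
    notes: list[str] = field(default_factory=list)
    raw_equivalent_factors: np.ndarray | None = None

    def percent_at(self, rank: int) -> float:
        return float(self.percents[rank - 1])


# ---------------------------------------------------------------------------
# constraint assembly


def _declared_vector(product: ProductRecord) -> np.ndarray:
    """Declared percents by rank index; NaN where absent."""
    n = product.n_ingredients
    declared = np.full(n, np.nan)
    for entry in product.ingredients:
        if entry.declared_percent is not None:
            declared[entry.rank - 1] = entry.declared_percent
    return declared


def _effective_declared(
    declared: np.ndarray, allow_relaxation: bool
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Normalize QUID declarations so the declared total fits within 100.

    When the declared sum exceeds 100 (dried/concentrated ingredients), all
    declared values are rescaled by 100/sum and the excess is carried as a
    raw-equivalent factor, so raw-commodity mass is preserved for impact
    accounting while the composition stays a proper 0–100 vector.
    """
    notes: list[str] = []
    factors = np.ones_like(declared)
    fixed = ~np.isnan(declared)
    total = np.nansum(declared)
    effective = declared.copy()
    if total > 100 + 1e-9:
        if not allow_relaxation:
            raise InfeasibleCompositionError(
                f"declared percentages sum to {total:.4g} > 100"
            )
        scale = 100.0 / total
        effective[fixed] = declared[fixed] * scale
        factors[fixed] = 1.0 / scale
        notes.append(f"quid_rescale:declared sum {total:.4g} scaled to 100")
    elif np.any(declared[fixed] > 100):
        # unreachable when total <= 100, kept as a guard
        raise InfeasibleCompositionError("a declared percentage exceeds 100")
    return effective, factors, notes


def _enforced_pairs(
    effective: np.ndarray, two_percent_relaxation: bool
) -> tuple[list[int], list[str]]:
    """Adjacent pairs (i, i+1) on which monotonicity is enforced.

    Declared pairs that themselves violate the ordering are accepted verbatim
    (labels are ground truth) with a relaxation note; pairs of declared
    values both at or below 2% fall under the any-order exception.
    """
    n = len(effective)
    notes: list[str] = []
    pairs: list[int] = []
    for i in range(n - 1):
        a, b = effective[i], effective[i + 1]
        if not np.isnan(a) and not np.isnan(b) and b > a + 1e-9:
            if two_percent_relaxation and a <= TWO_PERCENT and b <= TWO_PERCENT:
                notes.append(f"two_percent_order:ranks {i + 1},{i + 2}")
            else:
                notes.append(
                    f"declared_order_violation:ranks {i + 1},{i + 2} "
                    f"({a:.4g} < {b:.4g})"
                )
            continue
        pairs.append(i)
    return pairs, notes


def _diagnose_infeasibility(effective: np.ndarray, pairs: list[int]) -> str:
    """Best-effort human-readable reason why the polytope is empty."""
    n = len(effective)
    fixed = ~np.isnan(effective)
    chained = set(pairs)
    remaining = 100.0 - np.nansum(effective)
    # free slots after a declared value are capped by it (through the chain)
    caps = []
    for j in range(n):
        if fixed[j]:
            continue
        cap = 100.0
        for i in range(j - 1, -1, -1):
            if i not in chained:
                break
            if fixed[i]:
                cap = effective[i]
                break
        caps.append(cap)
    if caps and sum(caps) < remaining - 1e-9:
        return (
            f"undeclared ingredients can absorb at most {sum(caps):.4g}% under the "
            f"ordering constraint but {remaining:.4g}% of mass remains unassigned"
        )
    # free slots before a declared value must each be at least that value
    floor_total = np.nansum(effective)
    for j in range(n):
        if fixed[j]:
            continue
        floor = 0.0
        for i in range(j, n):
            if fixed[i]:
                floor = effective[i]
                break
            if i not in chained:
                break
        floor_total += floor
    if floor_total > 100 + 1e-9:
        return (
            f"ordering forces undeclared ingredients above declared values; "
            f"minimum total {floor_total:.4g}% > 100"
        )
    return "declared percentages and ordering constraints are jointly infeasible"


def feasible_bounds(
    product: ProductRecord, policy: InferencePolicy | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-ingredient bounds [lo, hi] (in percent) over the labeling
    polytope {p >= 0, sum p = 100, p1 >= p2 >= ... (enforced pairs), declared
    fixed}, computed by linear programming.

    Raises :class:`InfeasibleCompositionError` when the declared values admit
    no feasible composition, naming the violated constraint.
    """
    policy = policy or InferencePolicy()
    if product.n_ingredients == 0:
        raise InfeasibleCompositionError(
            f"product {product.product_id!r} has no ingredients"
        )
    declared = _declared_vector(product)
    effective, _, _ = _effective_declared(declared, policy.allow_relaxation)
    pairs, _ = _enforced_pairs(effective, policy.two_percent_relaxation)
    return _bounds_for(effective, pairs, product.product_id)


def _bounds_for(
    effective: np.ndarray, pairs: list[int], product_id: str = "?"
) -> tuple[np.ndarray, np.ndarray]:
    n = len(effective)
    fixed = ~np.isnan(effective)
    if n == 1:
        if fixed[0] and abs(effective[0] - 100.0) > 1e-6:
            raise InfeasibleCompositionError(
                f"product {product_id!r}: single ingredient declared at "
                f"{effective[0]:.4g}%, must be 100%"
            )
        return np.array([100.0]), np.array([100.0])

    a_ub = np.zeros((len(pairs), n))
    for row, i in enumerate(pairs):
        a_ub[row, i + 1] = 1.0
        a_ub[row, i] = -1.0
    b_ub = np.zeros(len(pairs))
    a_eq = np.ones((1, n))
    b_eq = np.array([100.0])
    var_bounds = [
        (effective[i], effective[i]) if fixed[i] else (0.0, 100.0) for i in range(n)
    ]

    lo = np.empty(n)
    hi = np.empty(n)
    for i in range(n):
        if fixed[i]:
            lo[i] = hi[i] = effective[i]
            continue
        for sign, out in ((1.0, lo), (-1.0, hi)):
            c = np.zeros(n)
            c[i] = sign
            res = linprog(
                c,
                A_ub=a_ub if len(pairs) else None,
                b_ub=b_ub if len(pairs) else None,
                A_eq=a_eq,
                b_eq=b_eq,
                bounds=var_bounds,
                method="highs",
            )
            if not res.success:
                raise InfeasibleCompositionError(
                    f"product {product_id!r}: "
                    + _diagnose_infeasibility(effective, pairs)
                )
            out[i] = sign * res.fun
    # polish LP round-off so bounds are clean percentages
    lo = np.clip(np.round(lo, 9), 0.0, 100.0)
    hi = np.clip(np.round(hi, 9), 0.0, 100.0)
    return lo, hi


# ---------------------------------------------------------------------------
# projection machinery


def _pava_decreasing(values: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences
    (unit weights, L2)."""
    blocks: list[list[float]] = []  # each [sum, count]
    for v in values:
        blocks.append([float(v), 1])
        while len(blocks) > 1 and blocks[-2][0] / blocks[-2][1] < blocks[-1][0] / blocks[-1][1]:
            s, c = blocks.pop()
            blocks[-1][0] += s
            blocks[-1][1] += c
    out = np.empty(len(values))
    pos = 0
    for s, c in blocks:
        out[pos : pos + c] = s / c
        pos += c
    return out


def _project_order(
    p: np.ndarray,
    fixed: np.ndarray,
    pairs: set[int],
    two_percent_relaxation: bool,
) -> np.ndarray:
    """Monotone projection respecting fixed entries.

    Maximal runs of free entries between fixed entries are pooled by PAVA and
    then clamped to the fixed neighbours they are chained to.  Pairs whose
    current estimates are both <= 2% are exempt (any-order rule) and act as
    chain breaks.
    """
    n = len(p)
    out = p.copy()

    def chain_break(i: int) -> bool:
        if i not in pairs:
            return True
        if two_percent_relaxation and out[i] <= TWO_PERCENT and out[i + 1] <= TWO_PERCENT:
            return True
        return False

    # segments of consecutive indices connected by active chain constraints
    start = 0
    while start < n:
        end = start
        while end < n - 1 and not chain_break(end):
            end += 1
        segment = np.arange(start, end + 1)
        free = segment[~fixed[segment]]
        if len(free):
            # PAVA over the free run(s); fixed entries inside the segment act
            # as clamps on both sides
            out_seg = out[segment].copy()
            runs: list[list[int]] = []
            current: list[int] = []
            for idx in segment:
                if fixed[idx]:
                    if current:
                        runs.append(current)
                        current = []
                else:
                    current.append(idx)
            if current:
                runs.append(current)
            for run in runs:
                lo_clamp, hi_clamp = 0.0, 100.0
                first, last = run[0], run[-1]
                if first - 1 >= start and fixed[first - 1]:
                    hi_clamp = out[first - 1]
                if last + 1 <= end and fixed[last + 1]:
                    lo_clamp = out[last + 1]
                projected = _pava_decreasing(out[run])
                out[run] = np.clip(projected, lo_clamp, hi_clamp)
            del out_seg
        start = end + 1
    return out


def infer_composition(
    product: ProductRecord,
    prior: PriorTable | None = None,
    policy: InferencePolicy | None = None,
) -> CompositionEstimate:
    """Infer the full percent-by-mass vector of a product.

    Declared values are fixed (QUID-normalized when their sum exceeds 100);
    each unknown is initialized to the median of the most specific non-empty
    prior cell, falling back to the midpoint of its feasible interval, then
    the unknown vector is iterated through (a) rescaling to the remaining
    mass, (b) order projection, (c) clipping to the feasible bounds, until
    the composition changes by less than ``policy.tol`` or ``policy.max_iter``
    iterations.
    """
    policy = policy or InferencePolicy()
    prior = prior or PriorTable()
    if not product.scorable:
        raise InfeasibleCompositionError(
            f"product {product.product_id!r} has no ingredients"
        )
    n = product.n_ingredients
    declared = _declared_vector(product)
    effective, factors, notes = _effective_declared(declared, policy.allow_relaxation)
    pairs, order_notes = _enforced_pairs(effective, policy.two_percent_relaxation)
    notes.extend(order_notes)
    fixed = ~np.isnan(effective)

    if n == 1:
        p = np.array([100.0])
        if fixed[0] and abs(effective[0] - 100.0) > 1e-6:
            if not policy.allow_relaxation:
                raise InfeasibleCompositionError(
                    f"product {product.product_id!r}: single ingredient declared "
                    f"at {effective[0]:.4g}%"
                )
            notes.append("declared_rescaled:single ingredient set to 100")
        return _finalize(product, p, factors, True, notes)

    if fixed.all():
        total = effective.sum()
        if abs(total - 100.0) > 1e-6:
            if not policy.allow_relaxation:
                raise InfeasibleCompositionError(
                    f"product {product.product_id!r}: fully declared composition "
                    f"sums to {total:.4g}"
                )
            effective = effective * (100.0 / total)
            notes.append(f"declared_rescaled:sum {total:.4g} scaled to 100")
        return _finalize(product, effective, factors, True, notes)

    lo, hi = _bounds_for(effective, pairs, product.product_id)

    p = effective.copy()
    free = ~fixed
    for i in np.flatnonzero(free):
        entry = product.ingredient_at(i + 1)
        guess = prior.lookup(entry.category_id, entry.rank)
        if guess is None:
            guess = 0.5 * (lo[i] + hi[i])
        p[i] = guess

    target = 100.0 - effective[fixed].sum()
    pair_set = set(pairs)
    converged = False
    for _ in range(policy.max_iter):
        previous = p.copy()
        # (a) rescale unknowns onto the remaining mass
        s = p[free].sum()
        if s <= 0:
            p[free] = target / free.sum()
        else:
            p[free] *= target / s
        # (b) order projection
        p = _project_order(p, fixed, pair_set, policy.two_percent_relaxation)
        # (c) clip to the feasible box
        p[free] = np.clip(p[free], lo[free], hi[free])
        if np.max(np.abs(p - previous)) < policy.tol:
            converged = True
            break
    if not converged:
        notes.append("max_iterations_reached")

    # exact mass balance: move any residual into free entries, proportional to
    # their remaining slack so the box constraints are preserved
    residual = 100.0 - p.sum()
    if abs(residual) > 1e-12:
        slack = (hi[free] - p[free]) if residual > 0 else (p[free] - lo[free])
        total_slack = slack.sum()
        if total_slack > 0:
            p[free] += residual * slack / total_slack
        else:
            p[free] += residual / free.sum()
    return _finalize(product, p, factors, True, notes)


def _finalize(
    product: ProductRecord,
    percents: np.ndarray,
    factors: np.ndarray,
    feasible: bool,
    notes: list[str],
) -> CompositionEstimate:
    mapped = np.array(
        [entry.category_id is not None for entry in product.ingredients]
    )
    coverage = float(percents[mapped].sum() / 100.0) if mapped.any() else 0.0
    return CompositionEstimate(
        percents=percents,
        coverage=min(max(coverage, 0.0), 1.0),
        feasible=feasible,
        notes=notes,
        raw_equivalent_factors=factors,
    )


def coverage_gate(estimate: CompositionEstimate, threshold: float = 0.75) -> bool:
    """True iff at least ``threshold`` of the estimated mass was sorted into
    a food category (inclusive, default 75%)."""
    return estimate.coverage >= threshold
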