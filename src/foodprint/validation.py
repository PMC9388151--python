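"""Masking-based accuracy validation and aisle-level aggregation.

The protocol: take products whose composition is fully known from pack
(all — or all but one — ingredients declared, declared sum 100), compute a
"known" impact score from that composition, then hide randomly chosen subsets
of n declared percentages (keeping the list order), re-estimate the
composition with the inference algorithm, re-score, and compare.  Accuracy is
the log2 ratio estimated/known (0 = identical) and the percent difference
(estimated − known) / known; mischaracterization rates count trials outside
ratio bands [2/3, 3/2] and [1/2, 2].

Known and estimated scores for one product share the same Monte-Carlo seed,
so with nothing masked the two scores are identical by construction.
Composite scores are computed against reference maxima frozen from the
known-score corpus, so all trials live on one scale.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import InferencePolicy, PriorTable, infer_composition
from .model import INDICATORS, EnvDatabase, FoodprintError, ProductRecord
from .impact import CompositeReference, composite_score, monte_carlo

__all__ = [
    "MaskingTrial",
    "AccuracySummary",
    "select_validation_set",
    "known_scores",
    "mask_and_estimate",
    "run_masking_experiment",
    "summarize_accuracy",
    "aisle_profiles",
    "trials_to_frame",
]


class ValidationSetError(FoodprintError):
    pass


@dataclass
class MaskingTrial:
    """One masking trial: hide ``masked_ranks``, re-estimate, re-score."""

    product_id: str
    masked_ranks: frozenset[int]
    known_score: float
    estimated_score: float
    known_impacts: dict[str, float]
    estimated_impacts: dict[str, float]
    n_ingredients: int
    percent_known: float  # share of mass still declared after masking

    @property
    def n_mask(self) -> int:
        return len(self.masked_ranks)

    @property
    def ratio(self) -> float:
        return self.estimated_score / self.known_score

    @property
    def log_ratio(self) -> float:
        return math.log2(self.ratio)


@dataclass
class AccuracySummary:
    """Aggregate accuracy over a set of trials."""

    n_trials: int
    mean_percent_diff: float
    ci_low: float
    ci_high: float
    fraction_within_10pct: float
    fraction_within_25pct: float
    fraction_outside_two_thirds_three_halves: float
    fraction_outside_half_double: float
    mean_abs_log_ratio: float
    per_indicator: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n_trials": self.n_trials,
            "mean_percent_diff": self.mean_percent_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "fraction_within_10pct": self.fraction_within_10pct,
            "fraction_within_25pct": self.fraction_within_25pct,
            "fraction_outside_two_thirds_three_halves": self.fraction_outside_two_thirds_three_halves,
            "fraction_outside_half_double": self.fraction_outside_half_double,
            "mean_abs_log_ratio": self.mean_abs_log_ratio,
        }
        out["per_indicator"] = self.per_indicator
        return out


def select_validation_set(
    corpus: Sequence[ProductRecord], tol: float = 1e-6
) -> list[ProductRecord]:
    """Products usable as validation ground truth.

    Criteria: more than one ingredient; percent composition declared for all
    or all but one ingredient; declared sum equal to 100 (for the
    all-but-one case, the missing ingredient's percent is filled with the
    sum-to-100 residual).  Returns modified copies — the input corpus is not
    touched.
    """
    from copy import deepcopy

    selected = []
    for product in corpus:
        n = product.n_ingredients
        if n < 2:
            continue
        declared = [e for e in product.ingredients if e.declared_percent is not None]
        missing = [e for e in product.ingredients if e.declared_percent is None]
        total = sum(e.declared_percent for e in declared)
        if len(missing) == 0:
            if abs(total - 100.0) <= tol:
                selected.append(deepcopy(product))
        elif len(missing) == 1:
            residual = 100.0 - total
            if residual >= -tol:
                copy = deepcopy(product)
                copy.ingredient_at(missing[0].rank).declared_percent = max(
                    residual, tol
                )
                selected.append(copy)
    return selected


def _product_seed(seed: int, product_id: str) -> np.random.SeedSequence:
    """Stable per-product seed so known and estimated trials share draws."""
    digest = sum(ord(c) * (31**k % 1000003) for k, c in enumerate(product_id))
    return np.random.SeedSequence([seed, digest % (2**31)])


def known_scores(
    products: Sequence[ProductRecord],
    db: EnvDatabase,
    n_iter: int = 1000,
    seed: int = 0,
    policy: InferencePolicy | None = None,
) -> tuple[pd.DataFrame, CompositeReference]:
    """Known mean impacts and the frozen composite reference.

    The known score of each product uses its fully declared composition and
    a per-product Monte-Carlo seed derived from ``seed``.
    """
    rows = {}
    for product in products:
        estimate = infer_composition(product, PriorTable(), policy)
        dist = monte_carlo(
            estimate, product, db, n_iter, _product_seed(seed, product.product_id)
        )
        rows[product.product_id] = dist.mean
    means = pd.DataFrame.from_dict(rows, orient="index")[list(INDICATORS)]
    _, reference = composite_score(means)
    return means, reference


def _mask(product: ProductRecord, ranks: frozenset[int]) -> ProductRecord:
    from copy import deepcopy

    masked = deepcopy(product)
    for entry in masked.ingredients:
        if entry.rank in ranks:
            entry.declared_percent = None
    return masked


def _combinations(
    ranks: list[int], n_mask: int, max_combos: int, rng: np.random.Generator
) -> list[frozenset[int]]:
    total = math.comb(len(ranks), n_mask)
    if total <= max_combos:
        return [frozenset(c) for c in itertools.combinations(ranks, n_mask)]
    seen: set[frozenset[int]] = set()
    while len(seen) < max_combos:
        pick = frozenset(rng.choice(ranks, size=n_mask, replace=False).tolist())
        seen.add(pick)
    return sorted(seen, key=sorted)


def mask_and_estimate(
    product: ProductRecord,
    n_mask: int,
    prior: PriorTable,
    db: EnvDatabase,
    reference: CompositeReference,
    known_means: dict[str, float],
    *,
    max_combos: int = 100,
    n_iter: int = 1000,
    seed: int = 0,
    policy: InferencePolicy | None = None,
) -> list[MaskingTrial]:
    """All masking trials of one validation product at a given ``n_mask``.

    ``n_mask`` ranges from 2 to the ingredient count (0 is allowed as the
    no-masking control, giving a log ratio of exactly 0).  Up to
    ``max_combos`` unique combinations are drawn with a seeded generator.
    """
    n = product.n_ingredients
    declared_ranks = product.declared_ranks
    if n_mask == 0:
        combos = [frozenset()]
    elif 2 <= n_mask <= len(declared_ranks):
        rng = np.random.default_rng(_product_seed(seed + 1, product.product_id))
        combos = _combinations(declared_ranks, n_mask, max_combos, rng)
    else:
        raise ValueError(
            f"n_mask must be 0 or in [2, {len(declared_ranks)}], got {n_mask}"
        )

    total_mass = sum(
        e.declared_percent for e in product.ingredients if e.declared_percent
    )
    known = reference.score(known_means).score
    trials = []
    for combo in combos:
        masked = _mask(product, combo)
        estimate = infer_composition(masked, prior, policy)
        dist = monte_carlo(
            estimate, masked, db, n_iter, _product_seed(seed, product.product_id)
        )
        est = reference.score(dist.mean).score
        still_known = sum(
            e.declared_percent
            for e in masked.ingredients
            if e.declared_percent is not None
        )
        trials.append(
            MaskingTrial(
                product_id=product.product_id,
                masked_ranks=combo,
                known_score=known,
                estimated_score=est,
                known_impacts=dict(known_means),
                estimated_impacts=dist.mean,
                n_ingredients=n,
                percent_known=100.0 * still_known / total_mass if total_mass else 0.0,
            )
        )
    return trials


def run_masking_experiment(
    validation_set: Sequence[ProductRecord],
    db: EnvDatabase,
    prior: PriorTable,
    n_mask_grid: Sequence[int | str] = ("all",),
    *,
    max_combos: int = 100,
    n_iter: int = 200,
    seed: int = 0,
    policy: InferencePolicy | None = None,
) -> list[MaskingTrial]:
    """Masking trials over a validation set and a grid of ``n_mask`` values.

    Grid entries are integers or ``"all"`` (mask every ingredient, the
    rank-only worst case).  Products where an entry exceeds the ingredient
    count are skipped for that entry.
    """
    if not validation_set:
        raise ValidationSetError("validation set is empty")
    means, reference = known_scores(
        validation_set, db, n_iter=n_iter, seed=seed, policy=policy
    )
    trials: list[MaskingTrial] = []
    for product in validation_set:
        known_means = means.loc[product.product_id].to_dict()
        for entry in n_mask_grid:
            n_mask = product.n_ingredients if entry == "all" else int(entry)
            if entry != "all" and not (
                n_mask == 0 or 2 <= n_mask <= product.n_ingredients
            ):
                continue
            trials.extend(
                mask_and_estimate(
                    product,
                    n_mask,
                    prior,
                    db,
                    reference,
                    known_means,
                    max_combos=max_combos,
                    n_iter=n_iter,
                    seed=seed,
                    policy=policy,
                )
            )
    return trials


def summarize_accuracy(trials: Sequence[MaskingTrial]) -> AccuracySummary:
    """Accuracy summary over trials; trials with a known score of 0 are
    excluded with a warning."""
    usable = [t for t in trials if t.known_score > 0]
    if len(usable) < len(trials):
        warnings.warn(
            f"excluded {len(trials) - len(usable)} trial(s) with known score 0",
            stacklevel=2,
        )
    if not usable:
        raise ValidationSetError("no usable trials (all known scores were 0)")
    ratios = np.array([t.ratio for t in usable])
    pct_diff = (ratios - 1.0) * 100.0
    mean = float(pct_diff.mean())
    se = float(pct_diff.std(ddof=1) / math.sqrt(len(pct_diff))) if len(pct_diff) > 1 else 0.0
    summary = AccuracySummary(
        n_trials=len(usable),
        mean_percent_diff=mean,
        ci_low=mean - 1.96 * se,
        ci_high=mean + 1.96 * se,
        fraction_within_10pct=float(np.mean(np.abs(ratios - 1) <= 0.10)),
        fraction_within_25pct=float(np.mean(np.abs(ratios - 1) <= 0.25)),
        fraction_outside_two_thirds_three_halves=float(
            np.mean((ratios < 2 / 3) | (ratios > 3 / 2))
        ),
        fraction_outside_half_double=float(np.mean((ratios < 0.5) | (ratios > 2.0))),
        mean_abs_log_ratio=float(np.mean(np.abs(np.log2(ratios)))),
    )
    for k in INDICATORS:
        known = np.array([t.known_impacts[k] for t in usable])
        est = np.array([t.estimated_impacts[k] for t in usable])
        ok = known > 0
        if not ok.any():
            continue
        r = est[ok] / known[ok]
        summary.per_indicator[k] = {
            "mean_percent_diff": float((r - 1).mean() * 100.0),
            "fraction_within_10pct": float(np.mean(np.abs(r - 1) <= 0.10)),
            "fraction_within_25pct": float(np.mean(np.abs(r - 1) <= 0.25)),
        }
    return summary


def trials_to_frame(trials: Sequence[MaskingTrial]) -> pd.DataFrame:
    """Flatten trials into a table (one row per trial)."""
    rows = []
    for t in trials:
        row = {
            "product_id": t.product_id,
            "n_ingredients": t.n_ingredients,
            "n_mask": t.n_mask,
            "masked_ranks": "|".join(str(r) for r in sorted(t.masked_ranks)),
            "percent_known": t.percent_known,
            "known_score": t.known_score,
            "estimated_score": t.estimated_score,
        }
        if t.known_score > 0:
            row["log_ratio"] = t.log_ratio
        for k in INDICATORS:
            row[f"known_{k}"] = t.known_impacts[k]
            row[f"estimated_{k}"] = t.estimated_impacts[k]
        rows.append(row)
    return pd.DataFrame(rows)


def aisle_profiles(
    corpus: Sequence[ProductRecord],
    env_scores: dict[str, float],
    nutrition_numeric: dict[str, float],
) -> tuple[pd.DataFrame, float, float]:
    """Per-Aisle mean ± SEM of the composite environmental score and the
    numeric (1–5) nutrition score, plus the Spearman rank correlation between
    the two across Aisle means.

    Products categorized to several Aisles contribute to each of them; Aisles
    with fewer than two products have no SEM.
    """
    buckets: dict[str, list[tuple[float, float]]] = {}
    for product in corpus:
        pid = product.product_id
        if pid not in env_scores or pid not in nutrition_numeric:
            continue
        for aisle in product.aisles:
            buckets.setdefault(aisle, []).append(
                (env_scores[pid], nutrition_numeric[pid])
            )
    rows = []
    for aisle, values in sorted(buckets.items()):
        env = np.array([v[0] for v in values])
        nut = np.array([v[1] for v in values])
        rows.append(
            {
                "aisle": aisle,
                "n_products": len(values),
                "env_mean": float(env.mean()),
                "env_sem": float(stats.sem(env)) if len(env) > 1 else np.nan,
                "nutrition_mean": float(nut.mean()),
                "nutrition_sem": float(stats.sem(nut)) if len(nut) > 1 else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame) >= 2:
        with warnings.catch_warnings():
            # a constant column (e.g. every aisle at the same mean) has no
            # defined rank correlation; report NaN quietly
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho, pval = stats.spearmanr(frame["env_mean"], frame["nutrition_mean"])
        return frame, float(rho), float(pval)
    return frame, float("nan"), float("nan")
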