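"""Monte-Carlo impact estimation and the composite 0–100 environmental index.

For each Monte-Carlo iteration, one production observation is drawn for every
mapped ingredient with probability proportional to its production-share
weight; the ingredient's contribution is

    (percent / 100) * raw_equivalent_factor * intensity_per_kg * 0.1 kg,

i.e. impacts are reported per 100 g of final product.  Organic ingredients
draw from the organic subset of their category when it holds at least five
observations, otherwise from all observations.  Fish categories first choose
aquaculture vs capture with probability 0.5 each, then draw within that
system.  Unmapped ingredients contribute nothing (they are handled by the
coverage gate upstream).

The composite index linearly rescales each indicator to 0–100 against the
corpus maximum, averages the four scaled values with equal weight, and
rescales the average to 0–100 again — so a score of 50 means half the impact
of the highest-impact product, on average across indicators.  The reference
maxima can be frozen and reused to score new products on the same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import CompositionEstimate
from .model import (
    INDICATORS,
    EnvDatabase,
    FoodCategory,
    FoodprintError,
    ProductionObservation,
    ProductRecord,
)

__all__ = [
    "QUANTILES",
    "MIN_ORGANIC_OBSERVATIONS",
    "ImpactDistribution",
    "CompositeScore",
    "CompositeReference",
    "sample_observation",
    "impact_once",
    "monte_carlo",
    "composite_score",
    "estimate_serving_size",
    "per_serving",
]

#: Quantiles of the Monte-Carlo distribution that are reported.
QUANTILES = (5, 10, 25, 50, 75, 90, 95)

#: Minimum number of organic observations required before an organic
#: ingredient is restricted to organic production systems.
MIN_ORGANIC_OBSERVATIONS = 5

#: kg of product represented by a per-100 g functional unit.
KG_PER_100G = 0.1

_FISH_SYSTEMS = ("aquaculture", "capture")


@dataclass
class ImpactDistribution:
    """Per-indicator mean/SD/quantiles of impact per 100 g of product."""

    mean: dict[str, float]
    sd: dict[str, float]
    quantiles: dict[str, dict[int, float]]
    n_iterations: int
    seed: int | None = None

    def mean_vector(self) -> np.ndarray:
        return np.array([self.mean[k] for k in INDICATORS])


@dataclass
class CompositeScore:
    """Composite 0–100 score plus the four per-indicator scaled components."""

    score: float
    components: dict[str, float] = field(default_factory=dict)


def _normalized_weights(observations: list[ProductionObservation]) -> np.ndarray:
    w = np.array([o.weight for o in observations], dtype=float)
    total = w.sum()
    if total <= 0:
        return np.full(len(observations), 1.0 / len(observations))
    return w / total


def _observation_pool(
    category: FoodCategory, organic: bool
) -> list[ProductionObservation]:
    if organic:
        subset = category.organic_observations()
        if len(subset) >= MIN_ORGANIC_OBSERVATIONS:
            return subset
    return category.observations


def sample_observation(
    category: FoodCategory, organic: bool, rng: np.random.Generator
) -> ProductionObservation:
    """Draw one production observation, weight-proportionally.

    Applies the organic-subset rule and, for fish categories, the 50:50
    aquaculture/capture split before the weighted draw.
    """
    if not category.observations:
        raise FoodprintError(f"category {category.category_id!r} is empty")
    pool = _observation_pool(category, organic)
    if category.is_fish:
        system = _FISH_SYSTEMS[int(rng.random() < 0.5)]
        subset = [o for o in pool if o.system_label == system]
        if subset:
            pool = subset
    index = rng.choice(len(pool), p=_normalized_weights(pool))
    return pool[index]


def _sample_intensity_matrix(
    category: FoodCategory, organic: bool, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 4) matrix of intensity draws for one ingredient's category."""
    pool = _observation_pool(category, organic)
    intensities = np.array([o.intensities() for o in pool])
    if category.is_fish:
        labels = np.array([o.system_label for o in pool])
        out = np.empty((n, 4))
        pick_capture = rng.random(n) < 0.5
        for system, mask in (
            ("capture", pick_capture),
            ("aquaculture", ~pick_capture),
        ):
            count = int(mask.sum())
            if count == 0:
                continue
            sub = np.flatnonzero(labels == system)
            if len(sub) == 0:
                sub = np.arange(len(pool))
            sub_obs = [pool[i] for i in sub]
            idx = rng.choice(sub, size=count, p=_normalized_weights(sub_obs))
            out[mask] = intensities[idx]
        return out
    idx = rng.choice(len(pool), size=n, p=_normalized_weights(pool))
    return intensities[idx]


def _ingredient_masses(
    estimate: CompositionEstimate, product: ProductRecord
) -> list[tuple[str, bool, float]]:
    """(category_id, organic, raw-commodity kg per 100 g product) per mapped
    ingredient."""
    factors = (
        estimate.raw_equivalent_factors
        if estimate.raw_equivalent_factors is not None
        else np.ones(product.n_ingredients)
    )
    rows = []
    for entry in product.ingredients:
        if entry.category_id is None:
            continue
        i = entry.rank - 1
        mass = (
            (estimate.percents[i] / 100.0)
            * entry.raw_equivalent_factor
            * factors[i]
            * KG_PER_100G
        )
        organic = entry.organic or product.is_organic_product
        rows.append((entry.category_id, organic, mass))
    return rows


def _draw_matrix(
    estimate: CompositionEstimate,
    product: ProductRecord,
    db: EnvDatabase,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, 4) matrix of per-100 g impact draws for a whole product."""
    total = np.zeros((n, 4))
    for category_id, organic, mass in _ingredient_masses(estimate, product):
        if category_id not in db or mass == 0:
            continue
        total += mass * _sample_intensity_matrix(db[category_id], organic, n, rng)
    return total


def impact_once(
    estimate: CompositionEstimate,
    product: ProductRecord,
    db: EnvDatabase,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Monte-Carlo draw: four-indicator impact vector per 100 g."""
    return _draw_matrix(estimate, product, db, 1, rng)[0]


def monte_carlo(
    estimate: CompositionEstimate,
    product: ProductRecord,
    db: EnvDatabase,
    n_iter: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> ImpactDistribution:
    """Monte-Carlo impact distribution from ``n_iter`` draws.

    Reproducible given ``seed``; ``n_iter`` must be >= 1.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draws = _draw_matrix(estimate, product, db, n_iter, rng)
    mean = {k: float(draws[:, i].mean()) for i, k in enumerate(INDICATORS)}
    ddof = 1 if n_iter > 1 else 0
    sd = {k: float(draws[:, i].std(ddof=ddof)) for i, k in enumerate(INDICATORS)}
    quantiles = {
        k: {
            q: float(np.percentile(draws[:, i], q)) for q in QUANTILES
        }
        for i, k in enumerate(INDICATORS)
    }
    seed_value = seed if isinstance(seed, (int, type(None))) else None
    return ImpactDistribution(
        mean=mean, sd=sd, quantiles=quantiles, n_iterations=n_iter, seed=seed_value
    )


# ---------------------------------------------------------------------------
# composite index


@dataclass
class CompositeReference:
    """Frozen scaling constants of a scored corpus.

    ``indicator_max`` holds the corpus-maximum mean impact per indicator;
    ``mean_scaled_max`` the maximum of the equal-weight average of the four
    scaled indicators.  Scores are only comparable within one reference.
    """

    indicator_max: dict[str, float]
    mean_scaled_max: float

    @classmethod
    def from_means(cls, means: pd.DataFrame) -> "CompositeReference":
        maxima = {k: float(means[k].max()) for k in INDICATORS}
        scaled = _scale_indicators(means, maxima)
        mean_scaled = scaled.mean(axis=1)
        return cls(indicator_max=maxima, mean_scaled_max=float(mean_scaled.max()))

    def score(self, means: dict[str, float] | pd.Series) -> CompositeScore:
        components = {}
        for k in INDICATORS:
            m = self.indicator_max.get(k, 0.0)
            components[k] = 100.0 * float(means[k]) / m if m > 0 else 0.0
        avg = float(np.mean(list(components.values())))
        score = 100.0 * avg / self.mean_scaled_max if self.mean_scaled_max > 0 else 0.0
        return CompositeScore(score=score, components=components)

    def to_dict(self) -> dict:
        return {
            "indicator_max": self.indicator_max,
            "mean_scaled_max": self.mean_scaled_max,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CompositeReference":
        return cls(
            indicator_max={k: float(v) for k, v in data["indicator_max"].items()},
            mean_scaled_max=float(data["mean_scaled_max"]),
        )


def _scale_indicators(means: pd.DataFrame, maxima: dict[str, float]) -> pd.DataFrame:
    scaled = pd.DataFrame(index=means.index)
    for k in INDICATORS:
        m = maxima[k]
        if m > 0:
            scaled[k] = 100.0 * means[k] / m
        else:
            warnings.warn(
                f"indicator {k!r} is zero across the whole corpus; its scaled "
                "component is defined as 0",
                stacklevel=3,
            )
            scaled[k] = 0.0
    return scaled


def composite_score(
    corpus_means: pd.DataFrame,
) -> tuple[dict[str, CompositeScore], CompositeReference]:
    """Composite 0–100 scores for a corpus of per-product mean impacts.

    ``corpus_means`` is indexed by product id with one column per indicator
    (``ghg``, ``land``, ``water``, ``eutro``).  Returns the per-product
    scores and the frozen :class:`CompositeReference` used to compute them.
    """
    if corpus_means.empty:
        raise ValueError("corpus_means must contain at least one product")
    reference = CompositeReference.from_means(corpus_means)
    scores = {
        str(pid): reference.score(row) for pid, row in corpus_means.iterrows()
    }
    return scores, reference


# ---------------------------------------------------------------------------
# serving sizes


def estimate_serving_size(
    product: ProductRecord, corpus: list[ProductRecord]
) -> float | None:
    """Serving size in g: the product's own if declared, else the average of
    per-Shelf means over the product's Shelves, else per-Aisle means.

    Products categorized to several Shelves (Aisles) receive the mean of the
    per-Shelf (per-Aisle) means.  Returns ``None`` when no serving
    information exists anywhere relevant in the corpus.
    """
    if product.serving_size_g is not None:
        return float(product.serving_size_g)
    for attr in ("shelves", "aisles"):
        labels = getattr(product, attr)
        level_means = []
        for label in labels:
            sizes = [
                p.serving_size_g
                for p in corpus
                if p.serving_size_g is not None
                and p.product_id != product.product_id
                and label in getattr(p, attr)
            ]
            if sizes:
                level_means.append(float(np.mean(sizes)))
        if level_means:
            return float(np.mean(level_means))
    return None


def per_serving(score_per_100g: float, serving_size_g: float) -> float:
    """Linear conversion of a per-100 g quantity to per serving."""
    return score_per_100g * serving_size_g / 100.0
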