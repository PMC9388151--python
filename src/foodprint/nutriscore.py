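"""NutriScore nutrient profiling (2017 tables).

NutriScore sums penalty points for energy, saturated fat, sugars and sodium
(0–10 each) and subtracts reward points for protein, fiber and the
fruit/vegetable/nut/oil share (``fvno``), giving a total from −15 to 40 that
maps to letters A–E.  Protein points are not counted when the penalty sum
reaches 11 unless the fvno component is at its exemption level (5 points for
foods, 10 for beverages); cheese is exempt from the cap.  Beverages use their
own energy/sugar/fvno ladders and letter cut-points (and, because their fvno
component reaches 10 points, can total as low as −20); added fats replace the
saturated-fat component with the saturated/total fat ratio.

The thresholds are read from an editable YAML resource
(``data/nutriscore_2017.yaml``) so other table revisions can be swapped in.
Scores are additionally reported on two convenience scales used for
averaging and fine-grained comparison: a numeric 1 (A) to 5 (E), and a 0–100
scale that maps total −15 -> 0 and 40 -> 100 linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .model import FoodprintError, NutritionPanel, ProductRecord

__all__ = [
    "FOOD_TYPES",
    "NutriScoreResult",
    "load_thresholds",
    "component_points",
    "total_score",
    "letter_and_scales",
    "nutri_score",
    "score_product",
]

FOOD_TYPES = ("general", "beverage", "cheese", "added_fat")

_LETTER_NUMERIC = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}

_PENALTY_COMPONENTS = ("energy", "saturated_fat", "sugars", "sodium")
_REWARD_COMPONENTS = ("protein", "fiber", "fvno")


class NutriScoreError(FoodprintError):
    pass


@lru_cache(maxsize=4)
def load_thresholds(path: str | None = None) -> dict:
    """Load the threshold resource (the bundled 2017 tables by default)."""
    if path is None:
        text = (resources.files("foodprint") / "data" / "nutriscore_2017.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@dataclass
class NutriScoreResult:
    """Component points, total, letter and the two derived scales."""

    negative_points: dict[str, int]
    positive_points: dict[str, int]
    total: int
    letter: str
    numeric: int
    scaled: float
    food_type: str = "general"
    protein_counted: bool = True


def _band_points(value: float, thresholds: list[float]) -> int:
    """One point per threshold strictly exceeded."""
    return sum(value > t for t in thresholds)


def component_points(
    panel: NutritionPanel,
    food_type: str = "general",
    thresholds: dict | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Penalty and reward component points for a nutrition panel.

    ``food_type`` selects the table variant; cheese shares the general
    component tables (its special treatment is in the protein cap), and
    added fats replace saturated fat with the saturated/total fat ratio.
    """
    if food_type not in FOOD_TYPES:
        raise NutriScoreError(
            f"unknown food_type {food_type!r}; expected one of {FOOD_TYPES}"
        )
    tables = (thresholds or load_thresholds())["components"]
    general = tables["general"]
    variant = tables.get("beverage", {}) if food_type == "beverage" else {}

    energy_t = variant.get("energy_kj", general["energy_kj"])
    sugars_t = variant.get("sugars_g", general["sugars_g"])
    fvno_table = variant.get("fvno", general["fvno"])

    if food_type == "added_fat":
        if panel.total_fat_g is None:
            raise NutriScoreError(
                "added_fat scoring needs total_fat_g on the nutrition panel "
                "(saturated/total fat ratio component)"
            )
        ratio = (
            100.0 * panel.saturated_fat_g / panel.total_fat_g
            if panel.total_fat_g > 0
            else 0.0
        )
        satfat_points = _band_points(
            ratio, tables["added_fat"]["saturated_fat_ratio_percent"]
        )
    else:
        satfat_points = _band_points(panel.saturated_fat_g, general["saturated_fat_g"])

    negative = {
        "energy": _band_points(panel.energy_kj, energy_t),
        "saturated_fat": satfat_points,
        "sugars": _band_points(panel.sugars_g, sugars_t),
        "sodium": _band_points(panel.sodium_mg, general["sodium_mg"]),
    }
    fvno_points = 0
    for t, pts in zip(fvno_table["thresholds"], fvno_table["points"]):
        if panel.fvno_percent > t:
            fvno_points = pts
    positive = {
        "protein": _band_points(panel.protein_g, general["protein_g"]),
        "fiber": _band_points(panel.fiber_g, general["fiber_g"]),
        "fvno": fvno_points,
    }
    return negative, positive


def total_score(
    points: tuple[dict[str, int], dict[str, int]],
    food_type: str = "general",
    thresholds: dict | None = None,
) -> tuple[int, bool]:
    """Total = penalties − counted rewards, applying the protein-cap rule.

    Returns ``(total, protein_counted)``.
    """
    negative, positive = points
    rule = (thresholds or load_thresholds())["protein_cap"]
    neg_sum = sum(negative.values())
    exemption = rule["fvno_exemption_points"].get(
        food_type, rule["fvno_exemption_points"]["general"]
    )
    protein_counted = True
    if neg_sum >= rule["negative_threshold"] and positive["fvno"] < exemption:
        if not (food_type == "cheese" and rule.get("cheese_exempt", True)):
            protein_counted = False
    counted = positive["fiber"] + positive["fvno"]
    if protein_counted:
        counted += positive["protein"]
    return neg_sum - counted, protein_counted


def letter_and_scales(
    total: int,
    food_type: str = "general",
    thresholds: dict | None = None,
) -> tuple[str, int, float]:
    """Letter class, numeric 1–5 and the 0–100 scaled score for a total.

    The scaled score is the affine map total −15 -> 0, 40 -> 100 (clipped at
    0 for beverage totals below −15).
    """
    low = -20 if food_type == "beverage" else -15
    if not (low <= total <= 40):
        raise NutriScoreError(
            f"total {total} out of range [{low}, 40] for food_type {food_type!r}"
        )
    table_key = "beverage" if food_type == "beverage" else "general"
    cuts = (thresholds or load_thresholds())["letters"][table_key]
    letter = None
    for name, (lo, hi) in cuts.items():
        if lo <= total <= hi:
            letter = name
            break
    if letter is None:  # pragma: no cover - tables partition the range
        raise NutriScoreError(f"no letter band covers total {total}")
    scaled = max(0.0, min(100.0, 100.0 * (total + 15) / 55.0))
    return letter, _LETTER_NUMERIC[letter], scaled


def nutri_score(
    panel: NutritionPanel,
    food_type: str = "general",
    thresholds: dict | None = None,
) -> NutriScoreResult:
    """Full NutriScore for one nutrition panel."""
    points = component_points(panel, food_type, thresholds)
    total, protein_counted = total_score(points, food_type, thresholds)
    letter, numeric, scaled = letter_and_scales(total, food_type, thresholds)
    return NutriScoreResult(
        negative_points=points[0],
        positive_points=points[1],
        total=total,
        letter=letter,
        numeric=numeric,
        scaled=scaled,
        food_type=food_type,
        protein_counted=protein_counted,
    )


def _infer_food_type(product: ProductRecord) -> str:
    if product.food_type is not None:
        return product.food_type
    labels = " ".join(product.aisles + product.shelves).lower()
    if product.is_drink:
        return "beverage"
    if "cheese" in labels:
        return "cheese"
    if any(k in labels for k in ("oils", "butter", "margarine", "spreads")):
        return "added_fat"
    return "general"


def score_product(
    product: ProductRecord, thresholds: dict | None = None
) -> NutriScoreResult:
    """NutriScore for a product, deriving the table variant from the product.

    The variant is the product's explicit ``food_type`` when set, else
    beverage for drinks, else a cheese/added-fat heuristic on the taxonomy
    labels.  Alcoholic beverages are rejected: NutriScore does not account
    for alcohol.
    """
    if product.is_alcoholic:
        raise NutriScoreError(
            f"product {product.product_id!r} is alcoholic; NutriScore does not "
            "account for alcohol"
        )
    if product.nutrition is None:
        raise NutriScoreError(
            f"product {product.product_id!r} has no nutrition panel"
        )
    return nutri_score(product.nutrition, _infer_food_type(product), thresholds)
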