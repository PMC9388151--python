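"""Domain model: products, ingredients, nutrition panels and the
environmental-intensity database.

All impact intensities are expressed per kg of raw commodity; product-level
results are reported per 100 g of final product.  Ingredient lists are ordered
by decreasing mass (rank 1 = most abundant), mirroring UK/EU labeling rules,
and declared percentages follow the QUID convention (they may exceed 100 for
dried or concentrated ingredients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "INDICATORS",
    "INDICATOR_UNITS",
    "FoodprintError",
    "SchemaError",
    "InfeasibleCompositionError",
    "IngredientEntry",
    "NutritionPanel",
    "ProductRecord",
    "ProductionObservation",
    "FoodCategory",
    "EnvDatabase",
]

#: The four environmental indicators, in canonical order.
INDICATORS = ("ghg", "land", "water", "eutro")

INDICATOR_UNITS = {
    "ghg": "kg CO2e per 100 g",
    "land": "m2 per 100 g",
    "water": "scarcity-weighted L eq per 100 g",
    "eutro": "g PO4e per 100 g",
}


class FoodprintError(Exception):
    """Base class for all package errors."""


class SchemaError(FoodprintError):
    """Malformed input data (bad row, unknown column, duplicate id...)."""


class InfeasibleCompositionError(FoodprintError):
    """Declared percentages admit no composition satisfying the labeling
    constraints (non-negative, sum to 100, non-increasing by rank)."""


@dataclass
class IngredientEntry:
    """One entry of an ordered ingredient list.

    Parameters
    ----------
    name
        Free text as printed on pack.
    rank
        Position in the list, 1 = most abundant.
    declared_percent
        QUID percentage when printed on pack; may exceed 100 for dried
        ingredients (e.g. "110% beef" in biltong).  ``None`` when absent.
    category_id
        Environmental-database category, assigned by the lexicon.
    organic
        Whether the ingredient is labeled organic.
    raw_equivalent_factor
        Mass of raw commodity per unit mass of this ingredient in the final
        product (> 1 for dried/concentrated ingredients).
    """

    name: str
    rank: int
    declared_percent: float | None = None
    category_id: str | None = None
    organic: bool = False
    raw_equivalent_factor: float = 1.0

    def validate(self, product_id: str = "?") -> None:
        if self.rank < 1:
            raise SchemaError(
                f"product {product_id!r}, ingredient {self.name!r}: rank must be >= 1"
            )
        if self.declared_percent is not None and not self.declared_percent > 0:
            raise SchemaError(
                f"product {product_id!r}, ingredient {self.name!r}: "
                f"declared_percent must be > 0, got {self.declared_percent}"
            )
        if not self.raw_equivalent_factor > 0:
            raise SchemaError(
                f"product {product_id!r}, ingredient {self.name!r}: "
                "raw_equivalent_factor must be > 0"
            )


@dataclass
class NutritionPanel:
    """Per-100 g nutrition declaration.

    ``fvno_percent`` is the share of the product that is fruit, vegetables,
    legumes, nuts, or olive/walnut/rapeseed oil (the NutriScore reward
    component).  ``total_fat_g`` is only needed for the added-fat NutriScore
    variant (saturated/total fat ratio) and may be left ``None`` otherwise.
    """

    energy_kj: float = 0.0
    saturated_fat_g: float = 0.0
    sugars_g: float = 0.0
    sodium_mg: float = 0.0
    protein_g: float = 0.0
    fiber_g: float = 0.0
    fvno_percent: float = 0.0
    total_fat_g: float | None = None

    def validate(self, product_id: str = "?") -> None:
        for name in (
            "energy_kj",
            "saturated_fat_g",
            "sugars_g",
            "sodium_mg",
            "protein_g",
            "fiber_g",
            "fvno_percent",
        ):
            value = getattr(self, name)
            if value < 0:
                raise SchemaError(
                    f"product {product_id!r}, field {name!r}: must be >= 0, got {value}"
                )
        if self.fvno_percent > 100:
            raise SchemaError(
                f"product {product_id!r}, field 'fvno_percent': must be <= 100"
            )
        if self.total_fat_g is not None and self.total_fat_g < 0:
            raise SchemaError(
                f"product {product_id!r}, field 'total_fat_g': must be >= 0"
            )


@dataclass
class ProductRecord:
    """One retail product: taxonomy, ordered ingredients, nutrition, serving.

    A product may belong to several Departments/Aisles/Shelves (retailer
    taxonomies are not trees); the taxonomy lists may be empty.
    """

    product_id: str
    retailer: str = ""
    departments: list[str] = field(default_factory=list)
    aisles: list[str] = field(default_factory=list)
    shelves: list[str] = field(default_factory=list)
    ingredients: list[IngredientEntry] = field(default_factory=list)
    nutrition: NutritionPanel | None = None
    serving_size_g: float | None = None
    is_drink: bool = False
    is_organic_product: bool = False
    is_alcoholic: bool = False
    #: Optional override of the NutriScore table variant
    #: ("general", "beverage", "cheese", "added_fat").
    food_type: str | None = None

    @property
    def n_ingredients(self) -> int:
        return len(self.ingredients)

    @property
    def scorable(self) -> bool:
        """Products need a non-empty ingredient list to be scored."""
        return bool(self.ingredients)

    @property
    def declared_ranks(self) -> list[int]:
        return [e.rank for e in self.ingredients if e.declared_percent is not None]

    def ingredient_at(self, rank: int) -> IngredientEntry:
        for entry in self.ingredients:
            if entry.rank == rank:
                return entry
        raise KeyError(rank)

    def validate(self) -> None:
        ranks = [e.rank for e in self.ingredients]
        if ranks != list(range(1, len(ranks) + 1)):
            raise SchemaError(
                f"product {self.product_id!r}: ingredient ranks must be "
                f"consecutive integers starting at 1, got {ranks}"
            )
        for entry in self.ingredients:
            entry.validate(self.product_id)
        if self.nutrition is not None:
            self.nutrition.validate(self.product_id)
        if self.serving_size_g is not None and not self.serving_size_g > 0:
            raise SchemaError(
                f"product {self.product_id!r}: serving_size_g must be > 0"
            )


@dataclass
class ProductionObservation:
    """One farm/system-level record of the four impact intensities per kg,
    with a production-share sampling weight for the Monte Carlo draw."""

    ghg_kgco2e_per_kg: float
    land_m2_per_kg: float
    water_scarcity_leq_per_kg: float
    eutrophication_gpo4e_per_kg: float
    weight: float = 1.0
    organic: bool = False
    system_label: str = ""

    def intensities(self) -> tuple[float, float, float, float]:
        """Intensity vector in canonical :data:`INDICATORS` order."""
        return (
            self.ghg_kgco2e_per_kg,
            self.land_m2_per_kg,
            self.water_scarcity_leq_per_kg,
            self.eutrophication_gpo4e_per_kg,
        )

    def validate(self, category_id: str = "?") -> None:
        for value, name in zip(self.intensities(), INDICATORS):
            if value < 0:
                raise SchemaError(
                    f"category {category_id!r}: negative {name} intensity {value}"
                )
        if self.weight < 0:
            raise SchemaError(f"category {category_id!r}: negative weight")


@dataclass
class FoodCategory:
    """A food category of the environmental database with its production
    observations.  Fish categories are sampled with a 50:50 split between
    aquaculture and capture systems."""

    category_id: str
    name: str
    observations: list[ProductionObservation] = field(default_factory=list)
    is_fish: bool = False

    def organic_observations(self) -> list[ProductionObservation]:
        return [o for o in self.observations if o.organic]

    def system_subset(self, label: str) -> list[ProductionObservation]:
        return [o for o in self.observations if o.system_label == label]

    def validate(self) -> None:
        if not self.observations:
            raise SchemaError(f"category {self.category_id!r} has no observations")
        for obs in self.observations:
            obs.validate(self.category_id)


class EnvDatabase:
    """Collection of :class:`FoodCategory`, keyed by ``category_id``."""

    def __init__(self, categories: list[FoodCategory] | None = None):
        self._categories: dict[str, FoodCategory] = {}
        for cat in categories or []:
            self.add(cat)

    def add(self, category: FoodCategory) -> None:
        if category.category_id in self._categories:
            raise SchemaError(f"duplicate category_id {category.category_id!r}")
        self._categories[category.category_id] = category

    def __getitem__(self, category_id: str) -> FoodCategory:
        return self._categories[category_id]

    def __contains__(self, category_id: object) -> bool:
        return category_id in self._categories

    def __len__(self) -> int:
        return len(self._categories)

    def __iter__(self) -> Iterator[FoodCategory]:
        return iter(self._categories.values())

    @property
    def category_ids(self) -> list[str]:
        return list(self._categories)

    def validate(self) -> None:
        for cat in self:
            cat.validate()
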