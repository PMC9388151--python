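"""Readers and writers for product corpora and environmental databases.

Two product formats are supported:

* JSON — a list of objects, one per product, with an ``ingredients`` array
  in pack order (see :func:`read_products` for the field names);
* long CSV — one row per ingredient, product-level columns repeated, with
  taxonomy lists joined by ``|``.

The environmental database is a CSV with one row per production observation:
``category_id, name, is_fish, ghg, land, water, eutro, weight, organic,
system_label``.  A missing ``weight`` column defaults every weight to 1.0.

Writers and readers round-trip all fields (floats bit-identically: floats are
serialized with ``repr``).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .model import (
    EnvDatabase,
    FoodCategory,
    IngredientEntry,
    NutritionPanel,
    ProductionObservation,
    ProductRecord,
    SchemaError,
)

__all__ = [
    "read_products",
    "write_products",
    "read_env_db",
    "write_env_db",
]

_PANEL_FIELDS = (
    "energy_kj",
    "saturated_fat_g",
    "sugars_g",
    "sodium_mg",
    "protein_g",
    "fiber_g",
    "fvno_percent",
    "total_fat_g",
)

_PRODUCT_BOOLS = ("is_drink", "is_organic_product", "is_alcoholic")

_ENV_COLUMNS = {
    "category_id",
    "name",
    "is_fish",
    "ghg",
    "land",
    "water",
    "eutro",
    "weight",
    "organic",
    "system_label",
}


def _parse_percent(value, product_id: str, field: str) -> float | None:
    """Parse a declared percentage; accepts "60", "60%", 60.0, None/NaN."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        value = value.strip().rstrip("%").strip()
        if not value:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"product {product_id!r}, field {field!r}: cannot parse {value!r}"
        ) from None


def _parse_optional_float(value, product_id: str, field: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"product {product_id!r}, field {field!r}: cannot parse {value!r}"
        ) from None


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes", "t")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return bool(value)


def _taxonomy_from_json(obj: dict, key: str) -> list[str]:
    value = obj.get(key, [])
    if isinstance(value, str):
        return [value] if value else []
    return [str(v) for v in value]


def _product_from_json(obj: dict) -> ProductRecord:
    pid = str(obj.get("product_id", ""))
    if not pid:
        raise SchemaError("product with missing 'product_id'")
    ingredients = []
    for i, ing in enumerate(obj.get("ingredients", [])):
        name = ing.get("name")
        if name is None:
            raise SchemaError(f"product {pid!r}, ingredient #{i + 1}: missing 'name'")
        rank = int(ing["rank"]) if "rank" in ing and ing["rank"] is not None else i + 1
        ingredients.append(
            IngredientEntry(
                name=str(name),
                rank=rank,
                declared_percent=_parse_percent(
                    ing.get("declared_percent"), pid, "declared_percent"
                ),
                category_id=ing.get("category_id") or None,
                organic=_parse_bool(ing.get("organic")),
                raw_equivalent_factor=float(ing.get("raw_equivalent_factor", 1.0)),
            )
        )
    panel = None
    if "nutrition" in obj and obj["nutrition"] is not None:
        nut = obj["nutrition"]
        kwargs = {}
        for fieldname in _PANEL_FIELDS:
            if fieldname in nut and nut[fieldname] is not None:
                kwargs[fieldname] = float(nut[fieldname])
        panel = NutritionPanel(**kwargs)
    product = ProductRecord(
        product_id=pid,
        retailer=str(obj.get("retailer", "")),
        departments=_taxonomy_from_json(obj, "departments"),
        aisles=_taxonomy_from_json(obj, "aisles"),
        shelves=_taxonomy_from_json(obj, "shelves"),
        ingredients=ingredients,
        nutrition=panel,
        serving_size_g=_parse_optional_float(
            obj.get("serving_size_g"), pid, "serving_size_g"
        ),
        is_drink=_parse_bool(obj.get("is_drink")),
        is_organic_product=_parse_bool(obj.get("is_organic_product")),
        is_alcoholic=_parse_bool(obj.get("is_alcoholic")),
        food_type=obj.get("food_type") or None,
    )
    product.validate()
    return product


def _products_from_csv(path: Path) -> list[ProductRecord]:
    frame = pd.read_csv(path, dtype={"product_id": str}, float_precision="round_trip")
    required = {"product_id", "rank", "ingredient_name"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"product CSV missing columns: {sorted(missing)}")
    products = []
    for pid, group in frame.groupby("product_id", sort=False):
        group = group.sort_values("rank")
        first = group.iloc[0]
        ingredients = []
        for _, row in group.iterrows():
            name = row["ingredient_name"]
            if not isinstance(name, str) or not name:
                # a single empty-ingredient sentinel row encodes a product
                # with no usable ingredient list
                continue
            ingredients.append(
                IngredientEntry(
                    name=name,
                    rank=int(row["rank"]),
                    declared_percent=_parse_percent(
                        row.get("declared_percent"), pid, "declared_percent"
                    ),
                    category_id=(
                        str(row["category_id"])
                        if "category_id" in row and isinstance(row["category_id"], str)
                        else None
                    ),
                    organic=_parse_bool(row.get("ingredient_organic")),
                    raw_equivalent_factor=(
                        float(row["raw_equivalent_factor"])
                        if "raw_equivalent_factor" in row
                        and not pd.isna(row["raw_equivalent_factor"])
                        else 1.0
                    ),
                )
            )
        panel_kwargs = {}
        for fieldname in _PANEL_FIELDS:
            if fieldname in group.columns and not pd.isna(first[fieldname]):
                panel_kwargs[fieldname] = float(first[fieldname])
        product = ProductRecord(
            product_id=str(pid),
            retailer=str(first.get("retailer", "")) if "retailer" in group.columns else "",
            departments=_split_taxonomy(first.get("departments")),
            aisles=_split_taxonomy(first.get("aisles")),
            shelves=_split_taxonomy(first.get("shelves")),
            ingredients=ingredients,
            nutrition=NutritionPanel(**panel_kwargs) if panel_kwargs else None,
            serving_size_g=_parse_optional_float(
                first.get("serving_size_g"), pid, "serving_size_g"
            ),
            is_drink=_parse_bool(first.get("is_drink")),
            is_organic_product=_parse_bool(first.get("is_organic_product")),
            is_alcoholic=_parse_bool(first.get("is_alcoholic")),
            food_type=(
                str(first["food_type"])
                if "food_type" in group.columns and isinstance(first["food_type"], str)
                else None
            ),
        )
        product.validate()
        products.append(product)
    return products


def _split_taxonomy(value) -> list[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return []
    return [part for part in str(value).split("|") if part]


def read_products(path: str | Path, format: str | None = None) -> list[ProductRecord]:
    """Read a product corpus from JSON or long-format CSV.

    ``format`` is inferred from the file suffix when not given.  Ingredient
    order is preserved exactly as in the file; ranks are assigned from file
    order when absent (JSON only).  Duplicate product ids raise
    :class:`~foodprint.model.SchemaError`.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path) as fh:
            raw = json.load(fh)
        products = [_product_from_json(obj) for obj in raw]
    elif fmt == "csv":
        products = _products_from_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    seen: set[str] = set()
    for product in products:
        if product.product_id in seen:
            raise SchemaError(f"duplicate product_id {product.product_id!r}")
        seen.add(product.product_id)
    return products


def _product_to_json(product: ProductRecord) -> dict:
    obj: dict = {
        "product_id": product.product_id,
        "retailer": product.retailer,
        "departments": product.departments,
        "aisles": product.aisles,
        "shelves": product.shelves,
        "ingredients": [
            {
                "name": e.name,
                "rank": e.rank,
                "declared_percent": e.declared_percent,
                "category_id": e.category_id,
                "organic": e.organic,
                "raw_equivalent_factor": e.raw_equivalent_factor,
            }
            for e in product.ingredients
        ],
        "serving_size_g": product.serving_size_g,
        "is_drink": product.is_drink,
        "is_organic_product": product.is_organic_product,
        "is_alcoholic": product.is_alcoholic,
        "food_type": product.food_type,
    }
    if product.nutrition is not None:
        obj["nutrition"] = {f: getattr(product.nutrition, f) for f in _PANEL_FIELDS}
    return obj


def write_products(
    products: list[ProductRecord], path: str | Path, format: str | None = None
) -> None:
    """Write a corpus as JSON or long CSV (see :func:`read_products`)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump([_product_to_json(p) for p in products], fh, indent=1)
        return
    rows = []
    for p in products:
        base = {
            "product_id": p.product_id,
            "retailer": p.retailer,
            "departments": "|".join(p.departments),
            "aisles": "|".join(p.aisles),
            "shelves": "|".join(p.shelves),
            "serving_size_g": p.serving_size_g,
            "is_drink": p.is_drink,
            "is_organic_product": p.is_organic_product,
            "is_alcoholic": p.is_alcoholic,
            "food_type": p.food_type,
        }
        if p.nutrition is not None:
            base.update({f: getattr(p.nutrition, f) for f in _PANEL_FIELDS})
        if not p.ingredients:
            rows.append({**base, "rank": 1, "ingredient_name": ""})
        for e in p.ingredients:
            rows.append(
                {
                    **base,
                    "rank": e.rank,
                    "ingredient_name": e.name,
                    "declared_percent": e.declared_percent,
                    "category_id": e.category_id,
                    "ingredient_organic": e.organic,
                    "raw_equivalent_factor": e.raw_equivalent_factor,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_env_db(path: str | Path) -> EnvDatabase:
    """Read an environmental-intensity database CSV (one row per observation).

    Unknown columns and negative intensities raise
    :class:`~foodprint.model.SchemaError`; a missing ``weight`` column
    defaults all weights to 1.0.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    unknown = set(frame.columns) - _ENV_COLUMNS
    if unknown:
        raise SchemaError(f"environmental DB has unknown columns: {sorted(unknown)}")
    required = {"category_id", "ghg", "land", "water", "eutro"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"environmental DB missing columns: {sorted(missing)}")
    db = EnvDatabase()
    for cid, group in frame.groupby("category_id", sort=False):
        first = group.iloc[0]
        observations = []
        for _, row in group.iterrows():
            obs = ProductionObservation(
                ghg_kgco2e_per_kg=float(row["ghg"]),
                land_m2_per_kg=float(row["land"]),
                water_scarcity_leq_per_kg=float(row["water"]),
                eutrophication_gpo4e_per_kg=float(row["eutro"]),
                weight=float(row["weight"]) if "weight" in group.columns else 1.0,
                organic=_parse_bool(row.get("organic")),
                system_label=(
                    str(row["system_label"])
                    if "system_label" in group.columns
                    and isinstance(row["system_label"], str)
                    else ""
                ),
            )
            obs.validate(str(cid))
            observations.append(obs)
        db.add(
            FoodCategory(
                category_id=str(cid),
                name=str(first["name"]) if "name" in group.columns else str(cid),
                observations=observations,
                is_fish=_parse_bool(first.get("is_fish")),
            )
        )
    return db


def write_env_db(db: EnvDatabase, path: str | Path) -> None:
    rows = []
    for cat in db:
        for obs in cat.observations:
            rows.append(
                {
                    "category_id": cat.category_id,
                    "name": cat.name,
                    "is_fish": cat.is_fish,
                    "ghg": obs.ghg_kgco2e_per_kg,
                    "land": obs.land_m2_per_kg,
                    "water": obs.water_scarcity_leq_per_kg,
                    "eutro": obs.eutrophication_gpo4e_per_kg,
                    "weight": obs.weight,
                    "organic": obs.organic,
                    "system_label": obs.system_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
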