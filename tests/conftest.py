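import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from foodprint.lexicon import assign_categories
from foodprint.model import (
    EnvDatabase,
    FoodCategory,
    IngredientEntry,
    ProductionObservation,
    ProductRecord,
)
from foodprint.synthetic import SyntheticConfig, generate_corpus


def make_product(product_id, declared, category_ids=None, **kwargs):
    """Product with n ingredients from a list of declared percents (None =
    undeclared)."""
    ingredients = []
    for i, d in enumerate(declared):
        cid = category_ids[i] if category_ids else f"cat{i}"
        ingredients.append(
            IngredientEntry(name=f"ingredient {i}", rank=i + 1,
                            declared_percent=d, category_id=cid)
        )
    return ProductRecord(product_id=product_id, ingredients=ingredients, **kwargs)


def make_category(category_id, intensity_rows, is_fish=False, name=None):
    """Category from rows of (ghg, land, water, eutro[, weight, organic, system])."""
    observations = []
    for row in intensity_rows:
        ghg, land, water, eutro = row[:4]
        observations.append(
            ProductionObservation(
                ghg_kgco2e_per_kg=ghg,
                land_m2_per_kg=land,
                water_scarcity_leq_per_kg=water,
                eutrophication_gpo4e_per_kg=eutro,
                weight=row[4] if len(row) > 4 else 1.0,
                organic=row[5] if len(row) > 5 else False,
                system_label=row[6] if len(row) > 6 else "",
            )
        )
    return FoodCategory(
        category_id=category_id, name=name or category_id,
        observations=observations, is_fish=is_fish,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Mixed corpus at the study's default declared fraction (10.4%)."""
    corpus = generate_corpus(SyntheticConfig(n_products=60, seed=42))
    for product in corpus.products:
        assign_categories(product, corpus.lexicon)
    return corpus


@pytest.fixture(scope="session")
def declared_corpus():
    """Fully declared corpus: every product qualifies for validation."""
    corpus = generate_corpus(
        SyntheticConfig(
            n_products=40, declared_fraction=1.0, ingredients_max=8, seed=7
        )
    )
    for product in corpus.products:
        assign_categories(product, corpus.lexicon)
    return corpus


@pytest.fixture
def two_obs_db():
    """One category with two equal-weight observations, ghg 1 and 3."""
    return EnvDatabase(
        [make_category("crop", [(1.0, 2.0, 10.0, 0.5), (3.0, 4.0, 30.0, 1.5)])]
    )
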