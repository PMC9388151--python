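"""Map free-text ingredient names onto environmental-database food categories.

Ingredient names on pack are messy: mixed case, QUID percentages, "organic"
markers, and parenthetical sub-ingredient lists ("pesto (basil, oil)").
:func:`normalize_name` cleans a raw name; :func:`map_ingredient` resolves it
to a category through, in order: an exact synonym match, the longest matching
aggregate-fallback keyword (broad classes such as "other vegetables"), and
finally the first mappable parenthetical sub-ingredient.  Unresolvable names
stay unmapped and simply contribute no impact (they count against the
75%-coverage presentation rule downstream).

A starter lexicon is shipped as editable CSV resources
(``data/lexicon.csv``, ``data/fallbacks.csv``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .model import EnvDatabase, IngredientEntry, ProductRecord

__all__ = ["Lexicon", "normalize_name", "map_ingredient", "assign_categories"]

_PERCENT_RE = re.compile(r"\(?\s*\d+(?:[.,]\d+)?\s*%\s*\)?")
_PAREN_RE = re.compile(r"\(([^()]*)\)")
_PUNCT_RE = re.compile(r"[^\w\s-]")
_WS_RE = re.compile(r"\s+")


def _clean(text: str) -> str:
    text = text.lower()
    text = _PERCENT_RE.sub(" ", text)
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def split_parentheticals(raw: str) -> tuple[str, list[str]]:
    """Split ``"pesto (basil, olive oil)"`` into ``("pesto", ["basil", "olive oil"])``.

    Sub-ingredients are only consulted when the parent name cannot be mapped.
    """
    subs: list[str] = []

    def _collect(match: re.Match) -> str:
        inner = match.group(1)
        if "%" not in inner:
            subs.extend(part.strip() for part in inner.split(",") if part.strip())
        return " "

    parent = _PAREN_RE.sub(_collect, raw)
    return parent, subs


def normalize_name(raw: str) -> tuple[str, bool]:
    """Normalize a raw ingredient name.

    Lowercases, strips punctuation and percent annotations, removes
    parenthetical sub-lists, and removes an "organic" token, returning it as
    a flag: ``"Organic Tomatoes (32%)"`` -> ``("tomatoes", True)``.
    """
    parent, _ = split_parentheticals(raw)
    cleaned = _clean(parent)
    tokens = cleaned.split()
    organic = "organic" in tokens
    tokens = [t for t in tokens if t != "organic"]
    return " ".join(tokens), organic


@dataclass
class Lexicon:
    """Synonym table plus aggregate fallbacks.

    ``entries`` maps a normalized name to a category id; ``aggregate_fallbacks``
    maps a broad-class keyword (matched as a substring of the normalized name,
    longest keyword wins) to an aggregate category such as "other fruits".
    """

    entries: dict[str, str] = field(default_factory=dict)
    aggregate_fallbacks: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(
        cls, entries_path: str | Path, fallbacks_path: str | Path | None = None
    ) -> "Lexicon":
        """Load from CSVs with columns ``synonym,category_id`` and
        ``keyword,category_id``."""
        entries = {}
        with open(entries_path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[_clean(row["synonym"])] = row["category_id"]
        fallbacks = {}
        if fallbacks_path is not None:
            with open(fallbacks_path, newline="") as fh:
                for row in csv.DictReader(fh):
                    fallbacks[_clean(row["keyword"])] = row["category_id"]
        return cls(entries=entries, aggregate_fallbacks=fallbacks)

    @classmethod
    def bundled(cls) -> "Lexicon":
        """The starter lexicon shipped with the package."""
        data = resources.files("foodprint") / "data"
        return cls.from_csv(
            str(data / "lexicon.csv"), str(data / "fallbacks.csv")
        )

    @classmethod
    def for_database(cls, db: EnvDatabase, extend_bundled: bool = True) -> "Lexicon":
        """Identity lexicon over a database's category names, optionally
        merged with the bundled synonyms (restricted to categories present)."""
        lex = cls.bundled() if extend_bundled else cls()
        entries = {
            k: v for k, v in lex.entries.items() if v in db
        }
        fallbacks = {
            k: v for k, v in lex.aggregate_fallbacks.items() if v in db
        }
        for cat in db:
            entries[_clean(cat.name)] = cat.category_id
            entries[_clean(cat.category_id)] = cat.category_id
        return cls(entries=entries, aggregate_fallbacks=fallbacks)

    def lookup(self, normalized: str) -> str | None:
        """Exact synonym match, else longest aggregate-fallback keyword.

        Fallback keywords match anywhere in the name provided they end at a
        word boundary, so "fruit" catches both "exotic fruit mix" and
        "dragonfruit" but not "fruitcake".
        """
        if normalized in self.entries:
            return self.entries[normalized]
        best: str | None = None
        best_len = 0
        for keyword, category in self.aggregate_fallbacks.items():
            if len(keyword) > best_len and re.search(
                re.escape(keyword) + r"\b", normalized
            ):
                best, best_len = category, len(keyword)
        return best


def map_ingredient(entry: IngredientEntry, lexicon: Lexicon) -> str | None:
    """Resolve an ingredient entry to a category id, or ``None`` if unmapped.

    The parent name is mapped first; parenthetical sub-ingredients are only
    used when the parent is unmapped, in which case the first mappable
    sub-ingredient wins.
    """
    parent_raw, subs = split_parentheticals(entry.name)
    parent, _ = normalize_name(parent_raw)
    category = lexicon.lookup(parent) if parent else None
    if category is not None:
        return category
    for sub in subs:
        name, _ = normalize_name(sub)
        if name:
            category = lexicon.lookup(name)
            if category is not None:
                return category
    return None


def assign_categories(product: ProductRecord, lexicon: Lexicon) -> ProductRecord:
    """Fill ``category_id`` and the organic flag on every ingredient, in place.

    An ingredient already carrying a ``category_id`` is left untouched, so
    curated assignments survive re-mapping.  Returns the product for chaining.
    """
    for entry in product.ingredients:
        _, organic = normalize_name(entry.name)
        if organic:
            entry.organic = True
        if entry.category_id is None:
            entry.category_id = map_ingredient(entry, lexicon)
    return product
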