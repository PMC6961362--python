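"""Product catalogue, active-ingredient dictionary and WHO-criticality classification.

An antimicrobial-containing product is described by its composition — a short
list of antimicrobial active ingredients (AAIs) with optional label strengths.
Each AAI carries a WHO human-medicine criticality category; a product is
classified by the *set* of distinct categories present in its composition
(e.g. ``"Highest priority+High priority"`` or ``"Other only"``).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "WhoCategory",
    "ActiveIngredient",
    "AAIConcentration",
    "ProductLabel",
    "CategoryCombination",
    "AaiDictionary",
    "canonicalize",
    "load_aai_dictionary",
    "load_builtin_dictionary",
    "load_products",
    "products_from_frame",
    "load_reference_catalog",
    "classify_product",
    "contains_category",
    "tabulate_categories",
    "count_distinct_aais",
]


class WhoCategory(enum.Enum):
    """WHO ranking of antimicrobial classes for human medicine."""

    HIGHEST_PRIORITY = "Highest priority"
    HIGH_PRIORITY = "High priority"
    HIGHLY_IMPORTANT = "Highly important"
    OTHER = "Other"

    def __lt__(self, other: "WhoCategory") -> bool:
        if not isinstance(other, WhoCategory):
            return NotImplemented
        return CATEGORY_ORDER.index(self) < CATEGORY_ORDER.index(other)


#: Canonical ordering used when combining categories into a label.
CATEGORY_ORDER: tuple[WhoCategory, ...] = (
    WhoCategory.HIGHEST_PRIORITY,
    WhoCategory.HIGH_PRIORITY,
    WhoCategory.HIGHLY_IMPORTANT,
    WhoCategory.OTHER,
)

_WS = re.compile(r"\s+")


def canonicalize(name: str) -> str:
    """Canonical form of an AAI name.

    Lowercases, strips, collapses internal whitespace and unifies the
    British ``sulpha`` spelling to ``sulfa`` so that e.g.
    ``"Sulphamethoxazole "`` and ``"sulfamethoxazole"`` collide.
    """
    out = _WS.sub(" ", str(name).strip().lower())
    return out.replace("sulpha", "sulfa")


@dataclass(frozen=True)
class ActiveIngredient:
    name: str
    who_category: WhoCategory
    aai_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", canonicalize(self.name))


@dataclass(frozen=True)
class AAIConcentration:
    """One composition entry: an AAI plus its optional label strength.

    ``strength`` is mass of AAI per unit of product (mg/g or mg/ml). It is
    carried for completeness but not used by ADD_kg pricing, which costs the
    labelled dose of *product*.
    """

    aai: str
    strength: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "aai", canonicalize(self.aai))
        if self.strength is not None and not self.strength > 0:
            raise ValueError(f"strength must be > 0, got {self.strength!r}")


@dataclass(frozen=True)
class ProductLabel:
    """A commercial antimicrobial-containing product as read off its label."""

    product_id: str
    name: str
    composition: tuple[AAIConcentration, ...]
    dosing: "DoseInstruction | None" = None
    package_amount: float = 100.0  # grams (or ml for liquids) per pack
    pure_aai: bool = True
    route_options: frozenset[str] = frozenset({"water"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "composition", tuple(self.composition))
        object.__setattr__(self, "route_options", frozenset(self.route_options))
        if len(self.composition) < 1:
            raise ValueError(f"{self.product_id}: composition must be non-empty")
        if not self.package_amount > 0:
            raise ValueError(f"{self.product_id}: package_amount must be > 0")
        if not self.route_options:
            raise ValueError(f"{self.product_id}: route_options must be non-empty")
        bad = self.route_options - {"water", "feed"}
        if bad:
            raise ValueError(f"{self.product_id}: unknown routes {sorted(bad)}")

    @property
    def n_aais(self) -> int:
        return len(self.composition)

    @property
    def aai_names(self) -> tuple[str, ...]:
        return tuple(c.aai for c in self.composition)


@dataclass(frozen=True)
class CategoryCombination:
    """Set of distinct WHO categories present in a product, with canonical label."""

    categories: tuple[WhoCategory, ...]

    def __post_init__(self) -> None:
        ordered = tuple(c for c in CATEGORY_ORDER if c in set(self.categories))
        object.__setattr__(self, "categories", ordered)

    @property
    def label(self) -> str:
        if len(self.categories) == 1:
            return f"{self.categories[0].value} only"
        return "+".join(c.value for c in self.categories)


class AaiDictionary:
    """Case/whitespace/spelling-insensitive lookup of AAIs by name or alias."""

    def __init__(self, ingredients: Iterable[ActiveIngredient],
                 aliases: Mapping[str, str] | None = None):
        self._by_name: dict[str, ActiveIngredient] = {}
        for ing in ingredients:
            if ing.name in self._by_name:
                raise ValueError(f"duplicate AAI name {ing.name!r}")
            self._by_name[ing.name] = ing
        self._aliases: dict[str, str] = {}
        for alias, target in (aliases or {}).items():
            a, t = canonicalize(alias), canonicalize(target)
            if a in self._by_name:
                continue  # alias shadowed by a real entry
            self._aliases[a] = t

    def lookup(self, name: str) -> ActiveIngredient:
        key = canonicalize(name)
        key = self._aliases.get(key, key)
        try:
            return self._by_name[key]
        except KeyError:
            raise KeyError(f"unknown AAI {name!r}") from None

    def __contains__(self, name: str) -> bool:
        key = canonicalize(name)
        return key in self._by_name or self._aliases.get(key) in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(self._by_name.values())


def load_aai_dictionary(path) -> AaiDictionary:
    """Read an AAI dictionary CSV (columns ``name, who_category, aai_class``
    and optional pipe-separated ``alias``).

    Duplicate canonical names and unknown category tokens are hard errors.
    An empty file yields an empty dictionary.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"name", "who_category", "aai_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ingredients: list[ActiveIngredient] = []
    aliases: dict[str, str] = {}
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = canonicalize(row["name"])
        if name in seen:
            raise ValueError(f"{path}: duplicate AAI name {row['name']!r}")
        seen.add(name)
        token = str(row["who_category"]).strip().upper()
        try:
            cat = WhoCategory[token]
        except KeyError:
            raise ValueError(
                f"{path} row {i + 2}: unknown WHO category {row['who_category']!r}"
                f" for AAI {row['name']!r}"
            ) from None
        ingredients.append(ActiveIngredient(name, cat, str(row["aai_class"]).strip()))
        alias_cell = row.get("alias")
        if isinstance(alias_cell, str) and alias_cell.strip():
            for alias in alias_cell.split("|"):
                if alias.strip():
                    aliases[alias] = name
    return AaiDictionary(ingredients, aliases)


def load_builtin_dictionary() -> AaiDictionary:
    """The dictionary shipped with the package (37 AAIs, 13 classes)."""
    with resources.as_file(
        resources.files("amucost.data").joinpath("aai_dictionary.csv")
    ) as p:
        return load_aai_dictionary(p)


def parse_composition(text: str) -> tuple[AAIConcentration, ...]:
    """Parse ``"aai:strength|aai"`` composition strings (strength optional)."""
    entries = []
    for part in str(text).split("|"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            aai, strength = part.split(":", 1)
            entries.append(AAIConcentration(aai, float(strength)))
        else:
            entries.append(AAIConcentration(part))
    return tuple(entries)


def load_products(path) -> list[ProductLabel]:
    """Read a products CSV into :class:`ProductLabel` records.

    Expected columns: ``product_id, name, composition, package_amount_g,
    pure_aai, route_options`` plus dose columns ``dose_amount_g`` and at least
    one of ``dose_per_water_l`` / ``dose_per_feed_kg``.
    """
    return products_from_frame(pd.read_csv(path))


def products_from_frame(df: pd.DataFrame) -> list[ProductLabel]:
    """DataFrame counterpart of :func:`load_products`."""
    from .dosing import DoseInstruction

    products = []
    for _, row in df.iterrows():
        water = row.get("dose_per_water_l")
        feed = row.get("dose_per_feed_kg")
        dosing = None
        if pd.notna(row.get("dose_amount_g")):
            dosing = DoseInstruction(
                amount=float(row["dose_amount_g"]),
                per_volume_water=float(water) if pd.notna(water) else None,
                per_mass_feed=float(feed) if pd.notna(feed) else None,
            )
        products.append(
            ProductLabel(
                product_id=str(row["product_id"]),
                name=str(row.get("name", row["product_id"])),
                composition=parse_composition(row["composition"]),
                dosing=dosing,
                package_amount=float(row["package_amount_g"]),
                pure_aai=bool(int(row["pure_aai"])),
                route_options=frozenset(str(row["route_options"]).split("|")),
            )
        )
    return products


def load_reference_catalog() -> list[ProductLabel]:
    """The built-in 214-product reference catalogue.

    Compositions are stored compactly (one row per distinct composition with a
    product count) and expanded to one :class:`ProductLabel` per product with
    a generic 1 g/L water dose and 100 g package, sufficient for
    classification and tabulation.
    """
    from .dosing import DoseInstruction

    with resources.as_file(
        resources.files("amucost.data").joinpath("reference_catalog.csv")
    ) as p:
        df = pd.read_csv(p)
    dose = DoseInstruction(amount=1.0, per_volume_water=1.0)
    products = []
    k = 0
    for _, row in df.iterrows():
        comp = parse_composition(row["composition"])
        for _ in range(int(row["n_products"])):
            k += 1
            products.append(
                ProductLabel(
                    product_id=f"R{k:03d}",
                    name="+".join(c.aai for c in comp),
                    composition=comp,
                    dosing=dose,
                )
            )
    return products


def classify_product(product: ProductLabel, dictionary: AaiDictionary) -> CategoryCombination:
    """Classify a product by the distinct WHO categories of its AAIs.

    Deterministic and invariant to composition order. Unresolvable AAI names
    raise ``KeyError`` naming the AAI and product.
    """
    cats = set()
    for conc in product.composition:
        try:
            cats.add(dictionary.lookup(conc.aai).who_category)
        except KeyError:
            raise KeyError(
                f"product {product.product_id!r}: unknown AAI {conc.aai!r}"
            ) from None
    return CategoryCombination(tuple(cats))


def contains_category(product: ProductLabel, category: WhoCategory,
                      dictionary: AaiDictionary) -> bool:
    """True iff any AAI in the composition belongs to ``category``."""
    return category in classify_product(product, dictionary).categories


def count_distinct_aais(products: Sequence[ProductLabel],
                        dictionary: AaiDictionary | None = None) -> int:
    """Number of distinct canonical AAI names across all compositions.

    When a dictionary is given, alias spellings resolve to their canonical
    entry before counting; unknown names fall back to plain canonicalization.
    """
    names: set[str] = set()
    for p in products:
        for name in p.aai_names:
            if dictionary is not None and name in dictionary:
                name = dictionary.lookup(name).name
            names.add(name)
    return len(names)


def tabulate_categories(
    products: Sequence[ProductLabel],
    dictionary: AaiDictionary,
    usage: pd.DataFrame | None = None,
    prices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Category-combination summary table (one row per observed label).

    Parameters
    ----------
    usage : optional DataFrame with columns ``product_id, farm_id, flock_id``
        (one row per product use); drives the farm/flock usage columns.
    prices : optional DataFrame with columns ``product_id, price_cents``
        (standardized ADD_kg prices); drives the mean/SE price columns.

    Product counts across rows partition the catalogue. Rows are sorted by
    descending count then label.
    """
    if not products:
        return pd.DataFrame(
            columns=["label", "n_products", "pct_products", "n_farms", "pct_farms",
                     "n_flocks", "pct_flocks", "mean_price_cents", "se_price_cents"]
        )
    recs = []
    for p in products:
        recs.append({"product_id": p.product_id,
                     "label": classify_product(p, dictionary).label})
    prod = pd.DataFrame(recs)
    total = len(prod)
    rows = []
    n_farms_total = n_flocks_total = 0
    if usage is not None and len(usage):
        n_farms_total = usage["farm_id"].nunique()
        n_flocks_total = usage[["farm_id", "flock_id"]].drop_duplicates().shape[0]
    for label, grp in prod.groupby("label"):
        row = {
            "label": label,
            "n_products": len(grp),
            "pct_products": round(100.0 * len(grp) / total, 1),
            "n_farms": pd.NA, "pct_farms": pd.NA,
            "n_flocks": pd.NA, "pct_flocks": pd.NA,
            "mean_price_cents": pd.NA, "se_price_cents": pd.NA,
        }
        ids = set(grp["product_id"])
        if usage is not None and len(usage):
            sub = usage[usage["product_id"].isin(ids)]
            row["n_farms"] = sub["farm_id"].nunique()
            row["pct_farms"] = round(100.0 * row["n_farms"] / n_farms_total, 1)
            row["n_flocks"] = sub[["farm_id", "flock_id"]].drop_duplicates().shape[0]
            row["pct_flocks"] = round(100.0 * row["n_flocks"] / n_flocks_total, 1)
        if prices is not None and len(prices):
            sub = prices[prices["product_id"].isin(ids)]["price_cents"]
            if len(sub):
                row["mean_price_cents"] = float(sub.mean())
                row["se_price_cents"] = (
                    float(sub.std(ddof=1) / len(sub) ** 0.5) if len(sub) > 1 else pd.NA
                )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["n_products", "label"], ascending=[False, True], ignore_index=True
    )
    return out
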