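"""ADD_kg pricing engine.

Standardizes a retail package price to the cost of one *animal daily dose for
a 1 kg bird* (ADD_kg): the label's therapeutic dilution factor times the
daily water (225 ml) or feed (63 g) intake of a 1 kg chicken, costed at the
package's unit price and expressed in cents of one US dollar (₵).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .catalog import ProductLabel

__all__ = [
    "DEFAULT_FX_VND_PER_USD",
    "DoseInstruction",
    "IntakeConstants",
    "PriceRecord",
    "AddKgPrice",
    "dilution_factor",
    "addkg_amount",
    "price_per_addkg",
    "aai_price_share",
    "price_table",
]

#: VND per US$ used to express prices in ₵ (config scalar, not a live feed).
DEFAULT_FX_VND_PER_USD = 23_319.0


@dataclass(frozen=True)
class DoseInstruction:
    """Label dosing: ``amount`` grams (or ml) of product per ``per_volume_water``
    litres of drinking water and/or ``per_mass_feed`` kilograms of feed.

    ``amount_high`` captures a labelled dose range; the effective amount is
    the range midpoint (``dose_policy`` may select ``low``/``mid``/``high``).
    """

    amount: float
    per_volume_water: float | None = None
    per_mass_feed: float | None = None
    amount_high: float | None = None

    def __post_init__(self) -> None:
        if self.per_volume_water is None and self.per_mass_feed is None:
            raise ValueError("dose needs at least one of water/feed carriers")
        for val, name in [(self.amount, "amount"),
                          (self.per_volume_water, "per_volume_water"),
                          (self.per_mass_feed, "per_mass_feed"),
                          (self.amount_high, "amount_high")]:
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be > 0, got {val!r}")

    @property
    def routes(self) -> frozenset[str]:
        r = set()
        if self.per_volume_water is not None:
            r.add("water")
        if self.per_mass_feed is not None:
            r.add("feed")
        return frozenset(r)

    def effective_amount(self, policy: str = "mid") -> float:
        if self.amount_high is None:
            return self.amount
        if policy == "low":
            return self.amount
        if policy == "high":
            return self.amount_high
        if policy == "mid":
            return 0.5 * (self.amount + self.amount_high)
        raise ValueError(f"unknown dose policy {policy!r}")


@dataclass(frozen=True)
class IntakeConstants:
    """Daily intake of a 1 kg chicken."""

    water_ml_per_kg_day: float = 225.0
    feed_g_per_kg_day: float = 63.0

    def __post_init__(self) -> None:
        if not (self.water_ml_per_kg_day > 0 and self.feed_g_per_kg_day > 0):
            raise ValueError("intake constants must be > 0")


@dataclass(frozen=True)
class PriceRecord:
    """One farmer purchase-price observation for a product."""

    product_id: str
    farm_id: str
    district: str  # CAO_LANH or THAP_MUOI
    price_vnd: float
    date: str | None = None

    def __post_init__(self) -> None:
        if not self.price_vnd > 0:
            raise ValueError(f"price_vnd must be > 0, got {self.price_vnd!r}")


@dataclass(frozen=True)
class AddKgPrice:
    """Standardized cost of one product-ADD_kg, in ₵."""

    product_id: str
    farm_id: str
    price_cents: float
    route_used: str

    def __post_init__(self) -> None:
        if not self.price_cents > 0:
            raise ValueError("price_cents must be > 0")


def dilution_factor(d: DoseInstruction, route: str, dose_policy: str = "mid") -> float:
    """Product amount per unit carrier: g/L of water or g/kg of feed."""
    amount = d.effective_amount(dose_policy)
    if route == "water":
        if d.per_volume_water is None:
            raise ValueError("label has no water indication")
        return amount / d.per_volume_water
    if route == "feed":
        if d.per_mass_feed is None:
            raise ValueError("label has no feed indication")
        return amount / d.per_mass_feed
    raise ValueError(f"unknown route {route!r}")


def addkg_amount(d: DoseInstruction, k: IntakeConstants = IntakeConstants(),
                 dose_policy: str = "mid") -> tuple[float, str]:
    """Grams of product dosing one 1 kg bird for one day, and the route used.

    Water is preferred whenever the label offers it.
    """
    if d.per_volume_water is not None:
        df = dilution_factor(d, "water", dose_policy)
        return df * k.water_ml_per_kg_day / 1000.0, "water"
    df = dilution_factor(d, "feed", dose_policy)
    return df * k.feed_g_per_kg_day / 1000.0, "feed"


def price_per_addkg(
    product: ProductLabel,
    record: PriceRecord,
    k: IntakeConstants = IntakeConstants(),
    fx: float = DEFAULT_FX_VND_PER_USD,
    dose_policy: str = "mid",
) -> AddKgPrice:
    """Standardize one VND package price to ₵ per product-ADD_kg.

    ``price_cents = price_vnd / fx * 100 / package_amount * addkg_amount``;
    linear in ``price_vnd`` and inverse in ``package_amount``.
    """
    if record.product_id != product.product_id:
        raise ValueError(
            f"record {record.product_id!r} does not match product {product.product_id!r}"
        )
    if not fx > 0:
        raise ValueError("fx must be > 0")
    if product.dosing is None:
        raise ValueError(f"product {product.product_id!r} has no dose instruction")
    if not product.package_amount > 0:
        raise ValueError(f"product {product.product_id!r}: package_amount must be > 0")
    grams, route = addkg_amount(product.dosing, k, dose_policy)
    cents_per_unit = record.price_vnd / fx * 100.0 / product.package_amount
    return AddKgPrice(
        product_id=product.product_id,
        farm_id=record.farm_id,
        price_cents=cents_per_unit * grams,
        route_used=route,
    )


def aai_price_share(a: AddKgPrice, n_aais: int) -> float:
    """₵ attributed to each AAI: the product ADD_kg price divided by the
    number of AAIs. Counts outside {1, 2, 4} are accepted with a warning."""
    if n_aais <= 0:
        raise ValueError(f"n_aais must be positive, got {n_aais}")
    if n_aais not in (1, 2, 4):
        import warnings

        warnings.warn(f"unusual AAI count {n_aais}; dividing anyway", stacklevel=2)
    return a.price_cents / n_aais


def price_table(
    products: Iterable[ProductLabel],
    records: Iterable[PriceRecord],
    k: IntakeConstants = IntakeConstants(),
    fx: float = DEFAULT_FX_VND_PER_USD,
    dose_policy: str = "mid",
) -> pd.DataFrame:
    """Standardize a batch of price records against a product catalogue.

    Returns one row per record: ``product_id, farm_id, district, price_vnd,
    price_cents, route_used, n_aais, aai_share_cents``.
    """
    by_id = {p.product_id: p for p in products}
    rows = []
    for r in records:
        try:
            p = by_id[r.product_id]
        except KeyError:
            raise KeyError(f"price record references unknown product {r.product_id!r}")
        a = price_per_addkg(p, r, k, fx, dose_policy)
        rows.append({
            "product_id": r.product_id,
            "farm_id": r.farm_id,
            "district": r.district,
            "price_vnd": r.price_vnd,
            "price_cents": a.price_cents,
            "route_used": a.route_used,
            "n_aais": p.n_aais,
            "aai_share_cents": aai_price_share(a, p.n_aais),
        })
    return pd.DataFrame(
        rows,
        columns=["product_id", "farm_id", "district", "price_vnd", "price_cents",
                 "route_used", "n_aais", "aai_share_cents"],
    )


def load_price_records(path) -> list[PriceRecord]:
    """Read ``prices.csv`` (product_id, farm_id, district, price_vnd)."""
    df = pd.read_csv(path)
    return [
        PriceRecord(
            product_id=str(r["product_id"]),
            farm_id=str(r["farm_id"]),
            district=str(r["district"]),
            price_vnd=float(r["price_vnd"]),
        )
        for _, r in df.iterrows()
    ]
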