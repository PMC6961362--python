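"""Synthetic farm-diary generator.

Emits product catalogues, farmer price records and flock diaries with the
statistical structure the downstream analytics assume: weekly AMU and
disease probabilities declining from their week-1 anchors (0.76 and 0.56), a
mid-cycle mortality peak averaging 2.8 deaths/100 birds/week, farm-level
random price variation, a district price shift and product-price choice that
increases with flock age. All randomness flows from a single seed through
ordered sub-streams, so each artefact is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .catalog import load_builtin_dictionary, parse_composition
from .diaries import GrowthCurve
from .dosing import DEFAULT_FX_VND_PER_USD, DoseInstruction, IntakeConstants, addkg_amount

__all__ = ["GeneratorConfig", "generate_catalog", "generate_diaries", "simulate"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generator, calibrated to the study-scale defaults."""

    n_farms: int = 102
    n_flocks: int = 203
    n_products: int = 214
    n_price_records: int = 775

    flock_size_median: float = 300.0
    flock_size_sigma: float = 0.67  # lognormal; IQR ~200-495 around median 300
    flock_size_range: tuple[int, int] = (100, 2000)
    cycle_median: float = 18.0
    cycle_sd: float = 3.0  # IQR ~16-20
    cycle_range: tuple[int, int] = (12, 24)

    amu_week1_p: float = 0.76
    amu_slope: float = 0.40  # logistic decline per week of age
    disease_week1_p: float = 0.56
    disease_slope: float = 0.15

    mort_base: float = 0.0115
    mort_peak_amp: float = 0.060  # Gaussian bump over weeks ~5-10
    mort_peak_week: float = 7.5
    mort_peak_sd: float = 2.0

    pure_aai_p: float = 0.719

    # product-level log-price model (₵ scale after exp)
    price_mu: float = -1.32
    farm_sd: float = 0.20
    price_resid_sd: float = 0.50
    district_beta: float = 0.468
    pure_beta: float = 0.152
    two_aai_beta: float = 0.102
    product_sd: float = 0.30  # spread of product base prices

    # week-level log-price model for products chosen during the cycle;
    # week_price_mu is calibrated so the default run spends ~3.91 ₵/bird/cycle
    week_price_mu: float = -1.10
    age_beta: float = 0.153
    week_district_beta: float = 0.514
    week_resid_sd: float = 0.25

    treat_days: float = 3.0
    disease_treat_days: float = 5.0

    growth: GrowthCurve = field(default_factory=GrowthCurve)
    intake: IntakeConstants = field(default_factory=IntakeConstants)
    fx: float = DEFAULT_FX_VND_PER_USD

    def p_amu(self, week: np.ndarray | float) -> np.ndarray | float:
        return _sigmoid(_logit(self.amu_week1_p)
                        - self.amu_slope * (np.asarray(week, float) - 1.0))

    def p_disease(self, week: np.ndarray | float) -> np.ndarray | float:
        return _sigmoid(_logit(self.disease_week1_p)
                        - self.disease_slope * (np.asarray(week, float) - 1.0))

    def mortality_rate(self, week: np.ndarray | float) -> np.ndarray | float:
        week = np.asarray(week, float)
        bump = np.exp(-0.5 * ((week - self.mort_peak_week) / self.mort_peak_sd) ** 2)
        return self.mort_base + self.mort_peak_amp * bump


def _reference_compositions() -> pd.DataFrame:
    with resources.as_file(
        resources.files("amucost.data").joinpath("reference_catalog.csv")
    ) as p:
        return pd.read_csv(p)


def generate_catalog(cfg: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Draw a product catalogue whose category-combination shares follow the
    reference catalogue's composition frequencies in expectation.

    The single four-AAI composition is always included (as the last product)
    when the catalogue has room for it. Returns a ``products.csv``-shaped
    DataFrame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[0])
    ref = _reference_compositions()
    multi = ref[ref["composition"].str.count(r"\|") >= 3]
    small = ref.drop(multi.index)
    weights = small["n_products"].to_numpy(float)
    weights /= weights.sum()
    n_sampled = cfg.n_products - (1 if cfg.n_products >= 2 else 0)
    idx = rng.choice(small.index.to_numpy(), size=n_sampled, p=weights)
    comps = [small.loc[i, "composition"] for i in idx]
    if cfg.n_products >= 2:
        comps.append(multi["composition"].iloc[0])

    rows = []
    for j, comp in enumerate(comps, start=1):
        route_draw = rng.random()
        dose = float(rng.choice([0.5, 1.0, 1.0, 2.0]))
        water_l = feed_kg = np.nan
        if route_draw < 0.70:
            routes, water_l = "water", 1.0
        elif route_draw < 0.85:
            routes, water_l, feed_kg = "water|feed", 1.0, 1.0
        else:
            routes, feed_kg = "feed", 1.0
        n_aais = comp.count("|") + 1
        pure = int(rng.random() < cfg.pure_aai_p)
        rows.append({
            "product_id": f"P{j:03d}",
            "name": comp.replace("|", "+"),
            "composition": comp,
            "package_amount_g": float(rng.choice([10.0, 20.0, 50.0, 100.0])),
            "pure_aai": pure,
            "route_options": routes,
            "dose_amount_g": dose,
            "dose_per_water_l": water_l,
            "dose_per_feed_kg": feed_kg,
            "n_aais": n_aais,
            # latent base log price drives age-increasing product choice
            "base_log_price": cfg.price_mu
            + cfg.pure_beta * pure
            + cfg.two_aai_beta * (n_aais == 2)
            + rng.normal(0.0, cfg.product_sd),
        })
    return pd.DataFrame(rows)


def _farm_frame(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    farms = []
    for i in range(1, cfg.n_farms + 1):
        farms.append({
            "farm_id": f"F{i:03d}",
            "district": "CAO_LANH" if i % 2 else "THAP_MUOI",
            "farm_effect": rng.normal(0.0, cfg.farm_sd),
            "owner_age_group": rng.choice(["<36", "36-54", ">54"], p=[0.3, 0.5, 0.2]),
            "owner_gender": rng.choice(["M", "F"], p=[0.8, 0.2]),
            "owner_experience": rng.choice(["0-2", ">2-4", ">4"], p=[0.3, 0.4, 0.3]),
            "owner_education": rng.choice(
                ["post_high", "primary", "secondary", "high_school"],
                p=[0.1, 0.3, 0.4, 0.2]),
        })
    return pd.DataFrame(farms)


def generate_diaries(
    cfg: GeneratorConfig, products: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate flock diaries and farmer price records against a catalogue.

    Returns ``(flock_weeks, prices, farms)`` DataFrames shaped like the CSV
    interfaces. Diary rows are long format: one row per AMU event, one empty
    row for weeks without AMU. Event prices follow the week-level log-price
    model; purchase records follow the product-level model; both share the
    per-farm random effect.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_farms = np.random.default_rng(ss[1])
    rng = np.random.default_rng(ss[2])
    farms = _farm_frame(cfg, rng_farms)
    base_prices = products["base_log_price"].to_numpy()

    # grams of product per ADD_kg, for usage amounts and VND back-conversion
    addkg_g = []
    for _, p in products.iterrows():
        d = DoseInstruction(
            amount=float(p["dose_amount_g"]),
            per_volume_water=None if pd.isna(p["dose_per_water_l"]) else float(p["dose_per_water_l"]),
            per_mass_feed=None if pd.isna(p["dose_per_feed_kg"]) else float(p["dose_per_feed_kg"]),
        )
        addkg_g.append(addkg_amount(d, cfg.intake)[0])
    addkg_g = np.asarray(addkg_g)

    week_rows = []
    flock_no = 0
    farm_cycle = farms.to_dict("records")
    while flock_no < cfg.n_flocks:
        farm = farm_cycle[flock_no % cfg.n_farms]
        flock_no += 1
        flock_id = f"K{flock_no:03d}"
        size = int(np.clip(
            round(np.exp(np.log(cfg.flock_size_median)
                         + cfg.flock_size_sigma * rng.normal())),
            *cfg.flock_size_range))
        cycle_len = int(np.clip(round(rng.normal(cfg.cycle_median, cfg.cycle_sd)),
                                *cfg.cycle_range))
        birds = size
        caolanh = 1.0 if farm["district"] == "CAO_LANH" else 0.0
        for t in range(1, cycle_len + 1):
            deaths = int(rng.binomial(birds, min(1.0, cfg.mortality_rate(t))))
            disease = bool(rng.random() < cfg.p_disease(t))
            used = rng.random() < cfg.p_amu(t)
            base = {
                "farm_id": farm["farm_id"], "flock_id": flock_id,
                "week_of_age": t, "birds_start": birds, "deaths": deaths,
                "disease": int(disease),
            }
            if used and birds > 0:
                target = (cfg.week_price_mu + farm["farm_effect"]
                          + cfg.age_beta * np.log(t)
                          + cfg.week_district_beta * caolanh)
                log_price = target + rng.normal(0.0, cfg.week_resid_sd)
                j = int(np.argmin(np.abs(base_prices - target)))
                price_cents = float(np.exp(log_price))
                days = cfg.disease_treat_days if disease else cfg.treat_days
                weight = float(cfg.growth(t))
                expense_cents = price_cents * birds * weight * days
                amount_g = addkg_g[j] * birds * weight * days
                week_rows.append({
                    **base,
                    "product_id": products["product_id"].iloc[j],
                    "amount_used_g": amount_g,
                    "expense_vnd": expense_cents / 100.0 * cfg.fx,
                    "addkg_price_cents": price_cents,
                })
            else:
                week_rows.append({**base, "product_id": np.nan,
                                  "amount_used_g": np.nan, "expense_vnd": np.nan,
                                  "addkg_price_cents": np.nan})
            birds -= deaths

    flock_weeks = pd.DataFrame(week_rows)

    price_rows = []
    farm_recs = farms.to_dict("records")
    # purchases spread evenly over farms: keeps the farm design balanced,
    # which the REML variance estimate rewards
    for i in range(cfg.n_price_records):
        farm = farm_recs[i % cfg.n_farms]
        j = int(rng.integers(len(products)))
        p = products.iloc[j]
        caolanh = 1.0 if farm["district"] == "CAO_LANH" else 0.0
        log_price = (cfg.price_mu + farm["farm_effect"]
                     + cfg.district_beta * caolanh
                     + cfg.pure_beta * float(p["pure_aai"])
                     + cfg.two_aai_beta * (float(p["n_aais"]) == 2.0)
                     + rng.normal(0.0, cfg.price_resid_sd))
        price_cents = np.exp(log_price)
        # invert the ADD_kg standardization so the pricing engine round-trips
        price_vnd = price_cents / 100.0 * cfg.fx * float(p["package_amount_g"]) / addkg_g[j]
        price_rows.append({
            "product_id": p["product_id"], "farm_id": farm["farm_id"],
            "district": farm["district"], "price_vnd": price_vnd,
        })
    prices = pd.DataFrame(price_rows)
    return flock_weeks, prices, farms.drop(columns=["farm_effect"])


def simulate(cfg: GeneratorConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Run catalogue + diary generation from one seed.

    Returns DataFrames keyed ``products, flock_weeks, prices, farms``.
    """
    products = generate_catalog(cfg, seed)
    flock_weeks, prices, farms = generate_diaries(cfg, products, seed)
    return {"products": products, "flock_weeks": flock_weeks,
            "prices": prices, "farms": farms}
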