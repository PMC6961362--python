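"""Flock-diary data model and descriptive analytics.

One record per flock × week-of-age: birds at the start of the week, deaths,
a clinical-disease flag and zero or more antimicrobial-use (AMU) events with
their expense. Analytics cover weekly AMU probability, expense series per
flock/bird/kg, disease and mortality stratification with Kruskal-Wallis
comparisons, and the use-frequency vs price correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "AmuEvent",
    "FlockWeek",
    "GrowthCurve",
    "MORTALITY_CUTOFF",
    "load_flock_weeks",
    "weekly_amu_probability",
    "expense_series",
    "cumulative_expense_per_bird",
    "weekly_mortality",
    "mortality_class",
    "stratify_expense",
    "frequency_price_correlation",
    "product_use_frequency",
    "disease_week_tally",
]

#: Weekly deaths per 100 birds separating "low" from "high" mortality weeks.
MORTALITY_CUTOFF = 2.8


@dataclass(frozen=True)
class AmuEvent:
    product_id: str
    expense_cents: float
    addkg_price_cents: float | None = None

    def __post_init__(self) -> None:
        if self.expense_cents < 0:
            raise ValueError("expense_cents must be >= 0")


@dataclass(frozen=True)
class FlockWeek:
    farm_id: str
    flock_id: str
    week_of_age: int
    birds_start: int
    deaths: int
    disease: bool
    amu_events: tuple[AmuEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "amu_events", tuple(self.amu_events))
        if self.week_of_age < 1:
            raise ValueError("week_of_age must be >= 1")
        if self.birds_start < 0 or self.deaths < 0:
            raise ValueError("birds_start and deaths must be >= 0")
        if self.deaths > self.birds_start:
            raise ValueError(
                f"{self.flock_id} week {self.week_of_age}: deaths "
                f"({self.deaths}) exceed birds_start ({self.birds_start})"
            )

    @property
    def used_amu(self) -> bool:
        return len(self.amu_events) > 0

    @property
    def expense_cents(self) -> float:
        return sum(e.expense_cents for e in self.amu_events)


class GrowthCurve:
    """Gompertz weight-by-week curve ``w(t) = w_inf * exp(-b * exp(-k t))`` (kg).

    Positive and non-decreasing for positive parameters; injectable because
    external weight references rarely publish coefficients.
    """

    def __init__(self, w_inf: float = 2.2, b: float = 3.2, k: float = 0.18):
        if not (w_inf > 0 and b > 0 and k > 0):
            raise ValueError("Gompertz parameters must be > 0")
        self.w_inf, self.b, self.k = w_inf, b, k

    def __call__(self, week: float | np.ndarray) -> float | np.ndarray:
        return self.w_inf * np.exp(-self.b * np.exp(-self.k * np.asarray(week, float)))

    @classmethod
    def from_yaml(cls, path) -> "GrowthCurve":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if cfg.get("form", "gompertz") != "gompertz":
            raise ValueError(f"unsupported growth form {cfg.get('form')!r}")
        return cls(w_inf=float(cfg.get("w_inf", 2.2)), b=float(cfg.get("b", 3.2)),
                   k=float(cfg.get("k", 0.18)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"form": "gompertz", "w_inf": self.w_inf, "b": self.b, "k": self.k}, fh
            )


def load_flock_weeks(path, fx: float | None = None,
                     addkg: pd.DataFrame | None = None) -> list[FlockWeek]:
    """Read long-format ``flock_weeks.csv`` into :class:`FlockWeek` records.

    One row per AMU event; no-AMU weeks have empty product fields. Expenses
    recorded in VND are converted to ₵ with ``fx`` (VND per US$); pass
    ``fx=None`` if the file already carries ``expense_cents``. ``addkg``
    optionally joins a mean ADD_kg price per product onto events.
    """
    return flock_weeks_from_frame(pd.read_csv(path), fx=fx, addkg=addkg)


def flock_weeks_from_frame(df: pd.DataFrame, fx: float | None = None,
                           addkg: pd.DataFrame | None = None) -> list[FlockWeek]:
    """DataFrame counterpart of :func:`load_flock_weeks`.

    When the frame carries a per-event ``addkg_price_cents`` column it is
    used directly; otherwise ``addkg`` supplies per-product mean prices.
    """
    price_map: dict[str, float] = {}
    if addkg is not None and len(addkg):
        price_map = addkg.groupby("product_id")["price_cents"].mean().to_dict()
    weeks: list[FlockWeek] = []
    keys = ["farm_id", "flock_id", "week_of_age"]
    for (farm, flock, week), grp in df.groupby(keys, sort=True):
        first = grp.iloc[0]
        events = []
        for _, r in grp.iterrows():
            if pd.isna(r.get("product_id")) or str(r.get("product_id")) == "":
                continue
            if fx is not None:
                cents = float(r["expense_vnd"]) / fx * 100.0
            else:
                cents = float(r["expense_cents"])
            pid = str(r["product_id"])
            event_price = r.get("addkg_price_cents")
            if event_price is not None and pd.notna(event_price):
                events.append(AmuEvent(pid, cents, float(event_price)))
            else:
                events.append(AmuEvent(pid, cents, price_map.get(pid)))
        weeks.append(FlockWeek(
            farm_id=str(farm), flock_id=str(flock), week_of_age=int(week),
            birds_start=int(first["birds_start"]), deaths=int(first["deaths"]),
            disease=bool(int(first["disease"])), amu_events=tuple(events),
        ))
    return weeks


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, float)
    n = len(values)
    mean = float(values.mean()) if n else math.nan
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, se


def weekly_amu_probability(weeks: Sequence[FlockWeek]) -> pd.DataFrame:
    """Per-age probability that a flock used antimicrobials.

    ``p = (#flocks with >=1 AMU event) / (#flocks observed)`` at each age,
    with binomial ``SE = sqrt(p (1-p) / n)``. Ages with no observed flocks
    are omitted.
    """
    rows = []
    frame = pd.DataFrame({
        "week": [w.week_of_age for w in weeks],
        "flock": [(w.farm_id, w.flock_id) for w in weeks],
        "amu": [w.used_amu for w in weeks],
    })
    for week, grp in frame.groupby("week", sort=True):
        per_flock = grp.groupby("flock")["amu"].any()
        n = len(per_flock)
        p = float(per_flock.mean())
        rows.append({"week_of_age": int(week), "n_flocks": n, "p_amu": p,
                     "se": math.sqrt(p * (1 - p) / n)})
    return pd.DataFrame(rows, columns=["week_of_age", "n_flocks", "p_amu", "se"])


def expense_series(weeks: Sequence[FlockWeek],
                   curve: GrowthCurve | None = None) -> pd.DataFrame:
    """Weekly expense summaries per flock, per bird and per kg of live bird.

    Flock-week expense is the sum of its event expenses; per-bird divides by
    ``birds_start`` and per-kg further by the week's estimated bird weight.
    Weeks with events but zero birds are excluded from the per-bird/per-kg
    means (and flagged via the ``n_flagged`` attribute of the result).
    Means and SEs are across flocks within each age.
    """
    curve = curve or GrowthCurve()
    recs, flagged = [], 0
    for w in weeks:
        exp = w.expense_cents
        if w.birds_start == 0 and w.used_amu:
            flagged += 1
            per_bird = per_kg = math.nan
        elif w.birds_start == 0:
            per_bird = per_kg = math.nan
        else:
            per_bird = exp / w.birds_start
            per_kg = exp / (w.birds_start * float(curve(w.week_of_age)))
        recs.append({"week_of_age": w.week_of_age, "expense": exp,
                     "per_bird": per_bird, "per_kg": per_kg})
    frame = pd.DataFrame(recs)
    rows = []
    for week, grp in frame.groupby("week_of_age", sort=True):
        flock_mean, flock_se = _mean_se(grp["expense"].to_numpy())
        bird = grp["per_bird"].dropna().to_numpy()
        kg = grp["per_kg"].dropna().to_numpy()
        bird_mean, bird_se = _mean_se(bird) if len(bird) else (math.nan, math.nan)
        kg_mean, kg_se = _mean_se(kg) if len(kg) else (math.nan, math.nan)
        rows.append({
            "week_of_age": int(week), "n_flocks": len(grp),
            "expense_per_flock_mean": flock_mean, "expense_per_flock_se": flock_se,
            "expense_per_bird_mean": bird_mean, "expense_per_bird_se": bird_se,
            "expense_per_kg_mean": kg_mean, "expense_per_kg_se": kg_se,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_flagged"] = flagged
    # crude grand means across all flock-week observations
    out.attrs["grand_expense_per_flock"] = _mean_se(frame["expense"].to_numpy())
    out.attrs["grand_expense_per_bird"] = _mean_se(frame["per_bird"].dropna().to_numpy())
    out.attrs["grand_expense_per_kg"] = _mean_se(frame["per_kg"].dropna().to_numpy())
    return out


def cumulative_expense_per_bird(weeks: Sequence[FlockWeek]) -> tuple[float, float]:
    """Mean ± SE across flocks of (total cycle expense / birds at restocking)."""
    frame = pd.DataFrame({
        "flock": [(w.farm_id, w.flock_id) for w in weeks],
        "week": [w.week_of_age for w in weeks],
        "expense": [w.expense_cents for w in weeks],
        "birds": [w.birds_start for w in weeks],
    })
    per_flock = []
    for _, grp in frame.groupby("flock"):
        start_birds = grp.sort_values("week")["birds"].iloc[0]
        if start_birds > 0:
            per_flock.append(grp["expense"].sum() / start_birds)
    return _mean_se(np.asarray(per_flock))


def weekly_mortality(week: FlockWeek) -> float:
    """Deaths per 100 birds present at the start of the week."""
    if week.birds_start == 0:
        raise ValueError(
            f"{week.flock_id} week {week.week_of_age}: mortality undefined for 0 birds"
        )
    return 100.0 * week.deaths / week.birds_start


def mortality_class(week: FlockWeek, cutoff: float = MORTALITY_CUTOFF) -> str:
    """``"high"`` when weekly mortality is >= cutoff (per 100 birds)."""
    return "high" if weekly_mortality(week) >= cutoff else "low"


def stratify_expense(
    weeks: Sequence[FlockWeek],
    by: str = "disease",
    metric: str = "per_flock",
    curve: GrowthCurve | None = None,
    cutoff: float = MORTALITY_CUTOFF,
) -> dict:
    """Group expense comparison with a tie-corrected Kruskal-Wallis test.

    ``by`` is ``"disease"`` (with/without clinical signs) or ``"mortality"``
    (low/high weekly mortality). ``metric`` is ``per_flock``, ``per_bird``,
    ``per_kg`` or ``addkg_price`` (mean ADD_kg price of products used that
    week; AMU weeks only).
    """
    curve = curve or GrowthCurve()
    groups: dict[str, list[float]] = {}
    for w in weeks:
        if by == "disease":
            key = "disease" if w.disease else "no_disease"
        elif by == "mortality":
            if w.birds_start == 0:
                continue
            key = mortality_class(w, cutoff)
        else:
            raise ValueError(f"unknown stratifier {by!r}")
        if metric == "per_flock":
            val = w.expense_cents
        elif metric == "per_bird":
            if w.birds_start == 0:
                continue
            val = w.expense_cents / w.birds_start
        elif metric == "per_kg":
            if w.birds_start == 0:
                continue
            val = w.expense_cents / (w.birds_start * float(curve(w.week_of_age)))
        elif metric == "addkg_price":
            prices = [e.addkg_price_cents for e in w.amu_events
                      if e.addkg_price_cents is not None]
            if not prices:
                continue
            val = float(np.mean(prices))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        groups.setdefault(key, []).append(val)
    if len(groups) < 2:
        present = sorted(groups)
        raise ValueError(f"need >=2 non-empty groups, got {present}")
    for name, vals in groups.items():
        if not vals:
            raise ValueError(f"group {name!r} is empty")
    labels = sorted(groups)
    samples = [np.asarray(groups[k], float) for k in labels]
    if np.ptp(np.concatenate(samples)) == 0:
        statistic, pvalue = 0.0, 1.0  # scipy rejects all-identical pooled data
    else:
        statistic, pvalue = stats.kruskal(*samples)
    out = {
        "by": by, "metric": metric,
        "kw_statistic": float(statistic), "p_value": float(pvalue),
        "groups": {},
    }
    for k, vals in zip(labels, samples):
        mean, se = _mean_se(vals)
        out["groups"][k] = {"n": int(len(vals)), "mean": mean, "se": se}
    return out


def product_use_frequency(weeks: Sequence[FlockWeek]) -> pd.Series:
    """Number of flock-weeks in which each product was used."""
    counts: dict[str, int] = {}
    for w in weeks:
        for pid in {e.product_id for e in w.amu_events}:
            counts[pid] = counts.get(pid, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def frequency_price_correlation(weeks: Sequence[FlockWeek],
                                prices: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation between per-product use frequency (number of
    weeks used) and mean ADD_kg price.

    ``prices`` needs columns ``product_id, price_cents``. Requires >=3
    products with both quantities; constant vectors are an error.
    """
    freq = product_use_frequency(weeks)
    mean_price = prices.groupby("product_id")["price_cents"].mean()
    common = freq.index.intersection(mean_price.index)
    if len(common) < 3:
        raise ValueError(f"need >=3 products with frequency and price, got {len(common)}")
    f = freq.loc[common].to_numpy(float)
    p = mean_price.loc[common].to_numpy(float)
    if np.ptp(f) == 0 or np.ptp(p) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, pval = stats.spearmanr(f, p)
    return float(rho), float(pval)


def disease_week_tally(weeks: Sequence[FlockWeek]) -> dict:
    """Counts and percentages of observed weeks with/without disease."""
    n = len(weeks)
    with_d = sum(1 for w in weeks if w.disease)
    out = {"n_weeks": n, "with_disease": with_d, "without_disease": n - with_d,
           "pct_with_disease": None, "pct_without_disease": None}
    if n:
        out["pct_with_disease"] = round(100.0 * with_d / n, 2)
        out["pct_without_disease"] = round(100.0 * (n - with_d) / n, 2)
    return out
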