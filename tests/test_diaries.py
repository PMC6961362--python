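import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amucost.diaries import (
    AmuEvent,
    FlockWeek,
    GrowthCurve,
    cumulative_expense_per_bird,
    disease_week_tally,
    expense_series,
    frequency_price_correlation,
    mortality_class,
    stratify_expense,
    weekly_amu_probability,
    weekly_mortality,
)

from _oracles import kruskal_wallis_oracle, spearman_oracle


def _week(flock="K1", week=1, birds=100, deaths=0, disease=False, expenses=(),
          farm="F1", product="P1"):
    events = tuple(AmuEvent(product, e) for e in expenses)
    return FlockWeek(farm_id=farm, flock_id=flock, week_of_age=week,
                     birds_start=birds, deaths=deaths, disease=disease,
                     amu_events=events)


class _FlatCurve:
    """Stub growth curve with constant weight (kg)."""

    def __init__(self, w):
        self.w = w

    def __call__(self, week):
        return self.w


class TestWeeklyAmuProbability:
    def test_two_of_three(self):
        weeks = [_week("K1", expenses=(1.0,)), _week("K2", expenses=(2.0,)),
                 _week("K3")]
        out = weekly_amu_probability(weeks)
        assert out.loc[0, "p_amu"] == pytest.approx(2 / 3)
        assert out.loc[0, "n_flocks"] == 3

    def test_all_using(self):
        weeks = [_week("K1", expenses=(1.0,)), _week("K2", expenses=(1.0,))]
        out = weekly_amu_probability(weeks)
        assert out.loc[0, "p_amu"] == 1.0
        assert out.loc[0, "se"] == 0.0

    def test_empty_ages_omitted(self):
        weeks = [_week("K1", week=1), _week("K1", week=3)]
        out = weekly_amu_probability(weeks)
        assert list(out["week_of_age"]) == [1, 3]

    def test_probability_bounds(self, small_weeks):
        out = weekly_amu_probability(small_weeks)
        assert ((out["p_amu"] >= 0) & (out["p_amu"] <= 1)).all()
        assert (out["se"] >= 0).all()


class TestExpenseSeries:
    def test_worked_example(self):
        weeks = [_week(birds=400, expenses=(50.0, 30.0))]
        out = expense_series(weeks, _FlatCurve(0.5))
        row = out.iloc[0]
        assert row["expense_per_flock_mean"] == pytest.approx(80.0)
        assert row["expense_per_bird_mean"] == pytest.approx(0.20)
        assert row["expense_per_kg_mean"] == pytest.approx(0.40)

    def test_no_events_all_zero(self):
        out = expense_series([_week()], _FlatCurve(1.0))
        assert out.iloc[0]["expense_per_flock_mean"] == 0.0
        assert out.iloc[0]["expense_per_bird_mean"] == 0.0

    def test_zero_bird_week_flagged_and_excluded(self):
        weeks = [_week(birds=0, expenses=(10.0,)), _week("K2", birds=100,
                                                        expenses=(10.0,))]
        out = expense_series(weeks, _FlatCurve(1.0))
        assert out.attrs["n_flagged"] == 1
        assert out.iloc[0]["expense_per_bird_mean"] == pytest.approx(0.1)

    def test_event_order_invariance(self):
        a = _week(expenses=(5.0, 7.0, 11.0))
        b = _week(expenses=(11.0, 5.0, 7.0))
        assert a.expense_cents == b.expense_cents

    def test_per_kg_vs_per_bird_heavy_birds(self):
        out = expense_series([_week(birds=100, expenses=(30.0,))], _FlatCurve(2.0))
        assert out.iloc[0]["expense_per_kg_mean"] <= out.iloc[0]["expense_per_bird_mean"]

    def test_cumulative_per_bird(self):
        weeks = [_week(week=1, birds=100, expenses=(50.0,)),
                 _week(week=2, birds=90, expenses=(50.0,))]
        mean, se = cumulative_expense_per_bird(weeks)
        assert mean == pytest.approx(1.0)  # 100 cents over 100 starting birds


class TestMortality:
    def test_rate(self):
        assert weekly_mortality(_week(birds=500, deaths=10)) == pytest.approx(2.0)

    def test_zero_deaths(self):
        assert weekly_mortality(_week(birds=500, deaths=0)) == 0.0

    def test_cutoff_boundary_is_high(self):
        assert mortality_class(_week(birds=500, deaths=14)) == "high"
        assert mortality_class(_week(birds=500, deaths=13)) == "low"

    def test_zero_birds_undefined(self):
        with pytest.raises(ValueError):
            weekly_mortality(_week(birds=0, deaths=0))

    def test_deaths_cannot_exceed_birds(self):
        with pytest.raises(ValueError):
            _week(birds=5, deaths=6)


class TestStratifyExpense:
    def test_matches_bruteforce_oracle(self):
        weeks = ([_week(f"K{i}", disease=True, expenses=(float(v),))
                  for i, v in enumerate([1, 2, 3])]
                 + [_week(f"L{i}", disease=False, expenses=(float(v),))
                    for i, v in enumerate([4, 5, 6])])
        res = stratify_expense(weeks, by="disease", metric="per_flock")
        expected = kruskal_wallis_oracle([[1, 2, 3], [4, 5, 6]])
        assert res["kw_statistic"] == pytest.approx(expected)

    def test_identical_groups(self):
        weeks = [_week("K1", disease=True, expenses=(5.0,)),
                 _week("K2", disease=False, expenses=(5.0,))]
        res = stratify_expense(weeks, by="disease")
        assert res["kw_statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_single_group_is_error(self):
        weeks = [_week("K1", disease=True, expenses=(5.0,))]
        with pytest.raises(ValueError, match="groups"):
            stratify_expense(weeks, by="disease")

    def test_group_means(self):
        weeks = ([_week(f"K{i}", disease=True, expenses=(100.0,)) for i in range(3)]
                 + [_week(f"L{i}", disease=False, expenses=(40.0,)) for i in range(3)])
        res = stratify_expense(weeks, by="disease")
        assert res["groups"]["disease"]["mean"] == pytest.approx(100.0)
        assert res["groups"]["no_disease"]["mean"] == pytest.approx(40.0)

    def test_mortality_stratifier(self):
        weeks = [_week("K1", birds=100, deaths=5, expenses=(10.0,)),
                 _week("K2", birds=100, deaths=0, expenses=(20.0,))]
        res = stratify_expense(weeks, by="mortality")
        assert set(res["groups"]) == {"high", "low"}

    def test_addkg_price_metric(self):
        weeks = [
            FlockWeek("F1", "K1", 1, 100, 0, True,
                      (AmuEvent("P1", 10.0, 0.5),)),
            FlockWeek("F1", "K2", 1, 100, 0, False,
                      (AmuEvent("P2", 10.0, 0.9),)),
        ]
        res = stratify_expense(weeks, by="disease", metric="addkg_price")
        assert res["groups"]["disease"]["mean"] == pytest.approx(0.5)

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 5), min_size=2, max_size=8),
                    min_size=2, max_size=3))
    def test_kw_agrees_with_oracle_small_inputs(self, samples):
        pooled = [v for g in samples for v in g]
        weeks = []
        i = 0
        for gi, g in enumerate(samples):
            for v in g:
                weeks.append(_week(f"K{i}", disease=(gi == 0),
                                   expenses=(float(v),)))
                i += 1
        # fold groups 2+ into the non-disease arm to keep two strata
        if len(samples) > 2:
            samples = [samples[0], [v for g in samples[1:] for v in g]]
        if len(set(pooled)) == 1:
            res = stratify_expense(weeks, by="disease")
            assert res["kw_statistic"] == 0.0
        else:
            res = stratify_expense(weeks, by="disease")
            assert res["kw_statistic"] == pytest.approx(
                kruskal_wallis_oracle(samples), rel=1e-9)


class TestFrequencyPriceCorrelation:
    def _weeks_for(self, freqs):
        weeks = []
        i = 0
        for pid, f in freqs.items():
            for _ in range(f):
                weeks.append(_week(f"K{i}", expenses=(1.0,), product=pid))
                i += 1
        return weeks

    def test_monotone_is_one(self):
        weeks = self._weeks_for({"P1": 1, "P2": 2, "P3": 3})
        prices = pd.DataFrame({"product_id": ["P1", "P2", "P3"],
                               "price_cents": [0.1, 0.2, 0.3]})
        rho, _ = frequency_price_correlation(weeks, prices)
        assert rho == pytest.approx(1.0)

    def test_hand_ranked_oracle(self):
        weeks = self._weeks_for({"P1": 1, "P2": 2, "P3": 3})
        prices = pd.DataFrame({"product_id": ["P1", "P2", "P3"],
                               "price_cents": [0.3, 0.1, 0.2]})
        rho, _ = frequency_price_correlation(weeks, prices)
        assert rho == pytest.approx(spearman_oracle([1, 2, 3], [3, 1, 2]))
        assert rho == pytest.approx(-0.5)

    def test_constant_vector_is_error(self):
        weeks = self._weeks_for({"P1": 1, "P2": 1, "P3": 1})
        prices = pd.DataFrame({"product_id": ["P1", "P2", "P3"],
                               "price_cents": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="constant"):
            frequency_price_correlation(weeks, prices)

    def test_too_few_products_is_error(self):
        weeks = self._weeks_for({"P1": 1, "P2": 2})
        prices = pd.DataFrame({"product_id": ["P1", "P2"],
                               "price_cents": [0.1, 0.2]})
        with pytest.raises(ValueError, match=">=3"):
            frequency_price_correlation(weeks, prices)


class TestDiseaseWeekTally:
    def test_printed_totals_fixture(self):
        weeks = ([_week(f"K{i}", disease=True) for i in range(1113)]
                 + [_week(f"L{i}", disease=False) for i in range(2835)])
        tally = disease_week_tally(weeks)
        assert tally["n_weeks"] == 3948
        assert tally["pct_with_disease"] == 28.19
        assert tally["pct_without_disease"] == 71.81

    def test_all_disease(self):
        tally = disease_week_tally([_week(disease=True)])
        assert tally["pct_with_disease"] == 100.0
        assert tally["pct_without_disease"] == 0.0

    def test_empty(self):
        tally = disease_week_tally([])
        assert tally["n_weeks"] == 0
        assert tally["pct_with_disease"] is None

    @given(st.lists(st.booleans(), max_size=30))
    def test_partition_conservation(self, flags):
        weeks = [_week(f"K{i}", disease=f) for i, f in enumerate(flags)]
        tally = disease_week_tally(weeks)
        assert tally["with_disease"] + tally["without_disease"] == tally["n_weeks"]


class TestGrowthCurve:
    def test_positive_and_nondecreasing(self):
        curve = GrowthCurve()
        weights = curve(np.arange(1, 25))
        assert (weights > 0).all()
        assert (np.diff(weights) >= 0).all()

    def test_yaml_round_trip(self, tmp_path):
        curve = GrowthCurve(w_inf=1.9, b=3.0, k=0.2)
        p = tmp_path / "growth.yaml"
        curve.to_yaml(p)
        loaded = GrowthCurve.from_yaml(p)
        assert loaded.w_inf == curve.w_inf
        assert float(loaded(10)) == pytest.approx(float(curve(10)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GrowthCurve(w_inf=-1)
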