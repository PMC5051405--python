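"""Catastrophic-expenditure counting: analytic vs Monte Carlo, variants."""

import numpy as np
import pytest

from ecea import (
    build_income_model,
    build_pregnancy_ledger,
    catastrophic_cases,
    generate_country,
    poverty_headcount,
    threshold_sweep,
)


def _three_se_bound(params, income, result_mc):
    """3x binomial SE of the MC count, quintile by quintile, in case units."""
    ledger = build_pregnancy_ledger(params)
    m = np.round(ledger.oop_incurring_per_quintile)
    p = np.divide(
        result_mc.cases_by_quintile.values,
        ledger.oop_incurring_per_quintile,
        out=np.zeros(5),
        where=ledger.oop_incurring_per_quintile > 0,
    )
    return 3 * np.sqrt(np.maximum(m * p * (1 - p), 0.0)) + 1e-9


class TestCatastrophicCases:
    def test_india_count_and_concentration(self, india, india_income):
        res = catastrophic_cases(india, income=india_income)
        assert 16_180 <= res.total <= 52_590
        assert res.cases_by_quintile.shares[0] >= 0.99

    def test_niger_count_and_spread(self, niger, niger_income):
        res = catastrophic_cases(niger, income=niger_income)
        assert res.total == pytest.approx(6150, rel=0.20)
        assert res.cases_by_quintile.bottom_two_share == pytest.approx(0.30, abs=0.05)

    def test_incidence_conventions(self, india, niger):
        """Niger incidence ≈1.8% and India ≈0.4% under the quintile denominator."""
        assert catastrophic_cases(niger).incidence == pytest.approx(0.018, abs=0.004)
        assert catastrophic_cases(india).incidence == pytest.approx(0.004, abs=0.002)
        q = catastrophic_cases(india, incidence_convention="quintile")
        a = catastrophic_cases(india, incidence_convention="age")
        assert q.total == a.total  # denominator changes, counts do not
        assert q.incidence != a.incidence

    def test_cases_bounded_by_care_using_deliveries(self, india, niger):
        for params in (india, niger):
            ledger = build_pregnancy_ledger(params)
            res = catastrophic_cases(params)
            assert np.all(
                res.cases_by_quintile.values <= ledger.oop_incurring_per_quintile + 1e-9
            )

    @pytest.mark.parametrize("fixture", ["india", "niger"])
    def test_analytic_matches_monte_carlo_within_3_se(self, fixture, request):
        params = request.getfixturevalue(fixture)
        income = build_income_model(params)
        ana = catastrophic_cases(params, income=income, method="analytic")
        mc = catastrophic_cases(params, income=income, method="mc", seed=42)
        bound = _three_se_bound(params, income, mc)
        assert np.all(np.abs(ana.cases_by_quintile.values - mc.cases_by_quintile.values) <= bound)

    def test_mc_seeded_and_reproducible(self, niger, niger_income):
        a = catastrophic_cases(niger, income=niger_income, method="mc", seed=3)
        b = catastrophic_cases(niger, income=niger_income, method="mc", seed=3)
        c = catastrophic_cases(niger, income=niger_income, method="mc", seed=4)
        assert np.array_equal(a.cases_by_quintile.values, b.cases_by_quintile.values)
        assert not np.array_equal(a.cases_by_quintile.values, c.cases_by_quintile.values)

    def test_unreachable_threshold_counts_nobody(self, india, india_income):
        """τ=1 with incomes far above every OOP bill yields zero cases."""
        rich = india.replace(gdp_per_capita=10_000_000.0)
        res = catastrophic_cases(rich, threshold=1.0)
        assert res.total == pytest.approx(0.0, abs=1e-6)

    def test_vanishing_threshold_counts_every_care_user(self, niger):
        res = catastrophic_cases(niger, threshold=1e-9)
        ledger = build_pregnancy_ledger(niger)
        assert res.total == pytest.approx(ledger.oop_incurring_per_quintile.sum())

    def test_bad_method_and_threshold_rejected(self, india):
        with pytest.raises(ValueError, match="method"):
            catastrophic_cases(india, method="bootstrap")
        with pytest.raises(ValueError, match="threshold"):
            catastrophic_cases(india, threshold=0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_costs_and_national_income(self, seed):
        params = generate_country(seed)
        base = catastrophic_cases(params).cases_by_quintile.values
        pricier = params.replace(
            oop_medical_by_quintile=tuple(2 * c for c in params.oop_medical_by_quintile)
        )
        richer = params.replace(gdp_per_capita=2 * params.gdp_per_capita)
        assert np.all(catastrophic_cases(pricier).cases_by_quintile.values >= base - 1e-9)
        assert np.all(catastrophic_cases(richer).cases_by_quintile.values <= base + 1e-9)


class TestThresholdSweep:
    def test_totals_decrease_with_threshold(self, india, niger):
        for params in (india, niger):
            totals = [r.total for r in threshold_sweep(params, thresholds=(0.10, 0.20, 0.40))]
            assert totals[0] >= totals[1] >= totals[2]

    def test_single_threshold_consistent_with_direct_call(self, niger, niger_income):
        (swept,) = threshold_sweep(niger, income=niger_income, thresholds=(0.10,))
        direct = catastrophic_cases(niger, income=niger_income, threshold=0.10)
        assert np.array_equal(swept.cases_by_quintile.values, direct.cases_by_quintile.values)

    def test_empty_sweep_rejected(self, india):
        with pytest.raises(ValueError):
            threshold_sweep(india, thresholds=())


class TestPovertyHeadcount:
    def test_zero_line_counts_nobody(self, niger, niger_income):
        assert poverty_headcount(niger, income=niger_income, poverty_line=0.0).total == 0

    def test_line_above_everyone_counts_nobody(self, niger, niger_income):
        res = poverty_headcount(niger, income=niger_income, poverty_line=1e9)
        assert res.total == pytest.approx(0.0, abs=1e-3)

    def test_missing_line_is_a_configuration_error(self, niger):
        with pytest.raises(ValueError, match="poverty_line"):
            poverty_headcount(niger)

    def test_analytic_matches_monte_carlo_at_large_n(self, niger, niger_income):
        """Crossing probabilities vs 10^6 conditional draws per quintile."""
        ana = poverty_headcount(niger, income=niger_income, poverty_line=200.0)
        mc = poverty_headcount(
            niger, income=niger_income, poverty_line=200.0, method="mc", seed=11, mc_draws=1_000_000
        )
        from ecea import build_pregnancy_ledger

        incurring = build_pregnancy_ledger(niger).oop_incurring_per_quintile
        p = np.divide(ana.cases_by_quintile.values, incurring, out=np.zeros(5), where=incurring > 0)
        se_counts = incurring * np.sqrt(p * (1 - p) / 1_000_000)
        assert np.all(
            np.abs(ana.cases_by_quintile.values - mc.cases_by_quintile.values)
            <= 3 * se_counts + 1e-9
        )

    def test_cases_require_crossing_not_just_paying(self, niger, niger_income):
        """Everyone already below the line is not newly impoverished."""
        lo_line = 5.0  # below essentially all Niger incomes
        res = poverty_headcount(niger, income=niger_income, poverty_line=lo_line)
        bill = max(niger.oop_medical_by_quintile) + max(niger.oop_transport_by_quintile)
        ceiling = float(niger_income.cdf(lo_line + bill)) - 0.0
        assert res.total <= build_pregnancy_ledger(niger).oop_incurring_per_quintile.sum() * ceiling / 0.2
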