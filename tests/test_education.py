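"""Education effect estimation and the +1-year counterfactual."""

import numpy as np
import pandas as pd
import pytest

from ecea import (
    EducationEffect,
    apply_policy,
    education_cost,
    effect_sensitivity,
    fit_education_effect,
    generate_education_dataset,
    maternal_deaths,
    oop_costs,
)
from ecea.impoverishment import catastrophic_cases


class TestFitEducationEffect:
    def test_noiseless_data_recovers_slope_exactly(self):
        ds = generate_education_dataset(n_countries=40, noise_sd=0.0, seed=1)
        eff = fit_education_effect(ds.data)
        # the OLS slope is exact; the relative reduction rescales it by the
        # sample (not generating) mean rate, so it is near-exact
        slope_hat = -eff.relative_reduction * ds.data.pregnancy_rate.mean()
        assert slope_hat == pytest.approx(ds.true_slope, abs=1e-12)
        assert eff.relative_reduction == pytest.approx(0.18, rel=0.05)
        assert eff.se == pytest.approx(0.0, abs=1e-9)
        assert eff.source == "fitted"

    def test_noisy_data_recovers_within_two_se(self):
        ds = generate_education_dataset(seed=2)
        eff = fit_education_effect(ds.data)
        assert abs(eff.relative_reduction - 0.18) <= 2 * eff.se

    def test_flat_data_gives_zero_effect(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {"education_years": rng.uniform(4, 10, 50), "pregnancy_rate": np.full(50, 0.2)}
        )
        assert fit_education_effect(data).relative_reduction == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        flat_x = pd.DataFrame({"education_years": [5.0] * 10, "pregnancy_rate": np.linspace(0.1, 0.3, 10)})
        with pytest.raises(ValueError, match="variance"):
            fit_education_effect(flat_x)
        short = pd.DataFrame({"education_years": [4, 9], "pregnancy_rate": [0.3, 0.1]})
        with pytest.raises(ValueError, match="3"):
            fit_education_effect(short)
        withnan = pd.DataFrame(
            {"education_years": [4, 6, 9.0], "pregnancy_rate": [0.3, np.nan, 0.1]}
        )
        with pytest.raises(ValueError, match="missing"):
            fit_education_effect(withnan)

    def test_ci_coverage_over_replicates(self):
        """Across 200 seeded synthetic datasets the 95% CI covers the truth
        at close to its nominal rate (93-97%)."""
        hits = 0
        for seed in range(200):
            ds = generate_education_dataset(seed=seed)
            lo, hi = fit_education_effect(ds.data).confidence_interval()
            hits += lo <= 0.18 <= hi
        assert 0.93 <= hits / 200 <= 0.97


class TestEducationCost:
    def test_niger_cost(self, niger):
        # 1 021 000 / 5 * $72
        assert education_cost(niger) == pytest.approx(14_702_400)
        assert education_cost(niger) == pytest.approx(15e6, rel=0.02)

    def test_india_cost(self, india):
        assert education_cost(india) == pytest.approx(3011e6, rel=0.02)

    def test_free_schooling_costs_nothing(self, india):
        assert education_cost(india.replace(education_cost_per_pupil=0.0)) == 0.0


class TestApplyPolicy:
    def test_india_averted_outcomes(self, india, india_income):
        impact = apply_policy(india, income=india_income)
        assert impact.deaths_averted.total == pytest.approx(1200, rel=0.05)
        assert impact.oop_averted.total == pytest.approx(3_050_000, rel=0.10)
        base = catastrophic_cases(india, income=india_income).total
        assert impact.catastrophic_averted.total == pytest.approx(0.18 * base, rel=1e-9)

    def test_niger_averted_outcomes(self, niger, niger_income):
        impact = apply_policy(niger, income=niger_income)
        assert impact.deaths_averted.total == pytest.approx(160, rel=0.05)
        assert impact.catastrophic_averted.total == pytest.approx(1110, rel=0.20)

    @pytest.mark.parametrize("e", [0.05, 0.10, 0.18, 0.25, 0.30])
    def test_linearity_in_effect(self, niger, niger_income, e):
        """Averted quantities are exactly e times the baseline outcomes."""
        impact = apply_policy(niger, income=niger_income, effect=EducationEffect(e))
        assert np.allclose(impact.deaths_averted.values, e * maternal_deaths(niger).values, rtol=1e-9)
        assert np.allclose(impact.oop_averted.values, e * oop_costs(niger).values, rtol=1e-9)
        cata = catastrophic_cases(niger, income=niger_income).cases_by_quintile.values
        assert np.allclose(impact.catastrophic_averted.values, e * cata, rtol=1e-9)

    def test_null_effect_averts_nothing_but_still_costs(self, india, india_income):
        impact = apply_policy(india, income=india_income, effect=EducationEffect(0.0))
        assert impact.deaths_averted.total == 0
        assert impact.oop_averted.total == 0
        assert impact.catastrophic_averted.total == 0
        assert impact.education_cost == education_cost(india)

    def test_discounting_strictly_shrinks_benefits(self, niger, niger_income):
        plain = apply_policy(niger, income=niger_income, discount=False)
        disc = apply_policy(niger, income=niger_income, discount=True)
        assert 0 < disc.deaths_averted.total < plain.deaths_averted.total
        assert 0 < disc.oop_averted.total < plain.oop_averted.total
        assert disc.education_cost == plain.education_cost  # paid up front

    def test_discount_factor_bounded_by_extreme_years(self, india, india_income):
        """The per-age weighting keeps the factor between the 0- and 4-year factors."""
        disc = apply_policy(india, income=india_income, discount=True)
        plain = apply_policy(india, income=india_income, discount=False)
        ratio = disc.deaths_averted.total / plain.deaths_averted.total
        assert 1.03**-4 < ratio < 1.0


class TestEffectSensitivity:
    def test_18_to_11_percent_cuts_everything_by_39_percent(self, india, india_income):
        table = effect_sensitivity(
            india, income=india_income, effects=[EducationEffect(0.18), EducationEffect(0.11)]
        )
        expected = 11 / 18 - 1  # -38.9%
        for col in ("deaths_averted_rel_change", "oop_averted_rel_change", "catastrophic_averted_rel_change"):
            assert table[col].iloc[1] == pytest.approx(expected, rel=1e-12)

    def test_identical_effects_change_nothing(self, niger, niger_income):
        table = effect_sensitivity(
            niger, income=niger_income, effects=[EducationEffect(0.18), EducationEffect(0.18)]
        )
        assert table["deaths_averted_rel_change"].iloc[1] == pytest.approx(0.0, abs=1e-15)

    def test_halving_the_effect_halves_the_impacts(self, niger, niger_income):
        table = effect_sensitivity(
            niger, income=niger_income, effects=[EducationEffect(0.18), EducationEffect(0.09)]
        )
        assert table["deaths_averted_rel_change"].iloc[1] == pytest.approx(-0.5, rel=1e-12)

    def test_empty_effects_rejected(self, india):
        with pytest.raises(ValueError):
            effect_sensitivity(india, effects=[])
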