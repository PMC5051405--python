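"""Medical impoverishment: catastrophic health expenditure and poverty headcount.

A delivery's OOP payment (medical + transport, per quintile) is *catastrophic*
when it exceeds a fraction τ of the woman's annual income (default τ = 10%, a
common threshold; 20% and 40% are standard sensitivity settings). Each
OOP-incurring delivery is assigned an income from the calibrated gamma
distribution, conditional on its quintile band, and counted if

    c_q + t_q > τ · income   ⇔   income < (c_q + t_q) / τ.

Two computation paths exist. The analytic path multiplies the per-quintile
count of OOP-incurring deliveries by the conditional gamma CDF — exact and
deterministic, the default. The Monte Carlo path draws one income per
delivery, mirroring the simulation formulation, and serves as a seeded
cross-check of the analytic path.

The poverty-headcount variant instead counts deliveries whose income is above
the poverty line before paying and below it after: line ≤ income <
line + c_q + t_q.

Women who do not use care incur no OOP cost and therefore can never be
counted, even where forgoing care is itself impoverishing; that structural
exclusion is inherent to the OOP-based metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import QuintileOutcomes, build_pregnancy_ledger
from .income import (
    IncomeModel,
    build_income_model,
    prob_income_below,
    prob_income_in_band,
    sample_incomes_in_quintile,
)
from .params import CountryParameters, N_QUINTILES

__all__ = [
    "ImpoverishmentResult",
    "catastrophic_cases",
    "poverty_headcount",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ImpoverishmentResult:
    """Cases of impoverishment per quintile, with the convention used."""

    cases_by_quintile: QuintileOutcomes
    threshold: float  # tau for catastrophic, the line for headcount
    method: str  # "analytic" | "mc"
    incidence: float  # total cases / pregnant adolescents

    @property
    def total(self) -> float:
        return self.cases_by_quintile.total

    def to_frame(self) -> pd.DataFrame:
        df = self.cases_by_quintile.to_frame("cases")
        df["threshold"] = self.threshold
        df["method"] = self.method
        return df


def _incidence_denominator(params: CountryParameters, convention: str) -> float:
    """Pregnant-adolescent denominator for the incidence proportion.

    ``"quintile"`` (default): (N/5)·Σ p_q — the convention consistent with the
    per-quintile survey rates. ``"age"``: (N/5)·Σ π_a — consistent with the
    per-age totals used for deaths. The two differ because the underlying
    survey profiles differ; both are exposed.
    """
    cohort = params.population_15_19 / 5.0
    if convention == "quintile":
        return cohort * float(np.sum(params.pregnant_by_quintile))
    if convention == "age":
        return cohort * float(np.sum(params.pregnant_by_age))
    raise ValueError(f"incidence convention must be 'quintile' or 'age', got {convention!r}")


def _case_counts(
    incurring: np.ndarray,
    probability,  # callable(quintile 1..5) -> analytic probability
    method: str,
    income: IncomeModel,
    exceeds,  # callable(incomes, q) -> bool array, used by the MC path
    seed,
    mc_draws,
) -> np.ndarray:
    if method == "analytic":
        return incurring * np.array([probability(q) for q in range(1, N_QUINTILES + 1)])
    if method == "mc":
        rng = np.random.default_rng(seed)
        cases = np.zeros(N_QUINTILES)
        for q in range(1, N_QUINTILES + 1):
            m = int(round(incurring[q - 1])) if mc_draws is None else int(mc_draws)
            if m == 0 or incurring[q - 1] == 0:
                continue
            draws = sample_incomes_in_quintile(income, q, m, rng)
            cases[q - 1] = incurring[q - 1] * float(np.mean(exceeds(draws, q)))
        return cases
    raise ValueError(f"method must be 'analytic' or 'mc', got {method!r}")


def catastrophic_cases(
    params: CountryParameters,
    income: IncomeModel | None = None,
    method: str = "analytic",
    seed: int | None = 0,
    threshold: float | None = None,
    mc_draws: int | None = None,
    incidence_convention: str = "quintile",
    quintile_mode: str = "share",
) -> ImpoverishmentResult:
    """Count cases of catastrophic health expenditure per quintile.

    ``threshold`` overrides the τ stored in ``params``. With ``method="mc"``,
    each OOP-incurring delivery receives a seeded income draw from its
    quintile band (``mc_draws`` overrides the per-quintile draw count, in
    which case the empirical exceedance fraction is rescaled to the delivery
    count).
    """
    tau = params.catastrophic_threshold if threshold is None else threshold
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"catastrophic threshold must lie in (0, 1], got {tau}")
    income = build_income_model(params) if income is None else income
    ledger = build_pregnancy_ledger(params, quintile_mode=quintile_mode)
    unit_cost = np.asarray(params.oop_medical_by_quintile) + np.asarray(
        params.oop_transport_by_quintile
    )
    cases = _case_counts(
        ledger.oop_incurring_per_quintile,
        probability=lambda q: prob_income_below(income, unit_cost[q - 1] / tau, q),
        method=method,
        income=income,
        exceeds=lambda draws, q: unit_cost[q - 1] > tau * draws,
        seed=seed,
        mc_draws=mc_draws,
    )
    denom = _incidence_denominator(params, incidence_convention)
    return ImpoverishmentResult(
        cases_by_quintile=QuintileOutcomes(cases, units="cases"),
        threshold=tau,
        method=method,
        incidence=float(cases.sum() / denom) if denom > 0 else 0.0,
    )


def poverty_headcount(
    params: CountryParameters,
    income: IncomeModel | None = None,
    poverty_line: float | None = None,
    method: str = "analytic",
    seed: int | None = 0,
    mc_draws: int | None = None,
    incidence_convention: str = "quintile",
    quintile_mode: str = "share",
) -> ImpoverishmentResult:
    """Count deliveries pushed below the poverty line by their OOP payment.

    A case requires crossing the line: income ≥ line before paying and
    income − (c_q + t_q) < line after. ``poverty_line`` falls back to
    ``params.poverty_line``; one of the two must be set.
    """
    line = params.poverty_line if poverty_line is None else poverty_line
    if line is None:
        raise ValueError(
            "poverty_line must be given as an argument or set in the country parameters"
        )
    if line < 0:
        raise ValueError(f"poverty_line must be >= 0, got {line}")
    income = build_income_model(params) if income is None else income
    ledger = build_pregnancy_ledger(params, quintile_mode=quintile_mode)
    unit_cost = np.asarray(params.oop_medical_by_quintile) + np.asarray(
        params.oop_transport_by_quintile
    )
    if line == 0:
        # Post-payment income is floored at zero (payments cannot exceed
        # ability to pay), so nobody can fall strictly below a zero line.
        cases = np.zeros(N_QUINTILES)
    else:
        cases = _case_counts(
            ledger.oop_incurring_per_quintile,
            probability=lambda q: prob_income_in_band(income, line, line + unit_cost[q - 1], q),
            method=method,
            income=income,
            exceeds=lambda draws, q: (draws >= line) & (draws - unit_cost[q - 1] < line),
            seed=seed,
            mc_draws=mc_draws,
        )
    denom = _incidence_denominator(params, incidence_convention)
    return ImpoverishmentResult(
        cases_by_quintile=QuintileOutcomes(cases, units="cases"),
        threshold=float(line),
        method=method,
        incidence=float(cases.sum() / denom) if denom > 0 else 0.0,
    )


def threshold_sweep(
    params: CountryParameters,
    income: IncomeModel | None = None,
    thresholds=(0.10, 0.20, 0.40),
    **kwargs,
) -> list[ImpoverishmentResult]:
    """Catastrophic-case counts across a list of thresholds τ.

    Totals are monotone non-increasing in τ (a higher bar admits fewer
    cases).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    income = build_income_model(params) if income is None else income
    return [
        catastrophic_cases(params, income=income, threshold=tau, **kwargs)
        for tau in thresholds
    ]
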