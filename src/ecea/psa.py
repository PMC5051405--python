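"""Probabilistic sensitivity analysis (PSA).

All key inputs — MMR, the age-specific mortality relative risks, the OOP cost
vectors and the education effect — are varied simultaneously across Monte
Carlo trials (default 1000). Each parameter is assigned a distribution
moment-matched to its mean (the point value) and a standard deviation:

* gamma for non-negative quantities: k = m²/s², θ = s²/m;
* beta for proportions: ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν;
* logistic: location m, scale s·√3/π.

Only the education effect has a published SE (2 percentage points); every
other input defaults to sd = 10% of its mean, overridable per parameter. The
full deterministic pipeline is re-run per trial and the 2.5th/97.5th
percentiles of each outcome (linear interpolation between order statistics)
form the 95% uncertainty range (UR). The income-distribution moments (GDP
per capita, Gini) are held fixed unless a spec explicitly includes them, in
which case the income model is re-calibrated inside each trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import maternal_deaths, oop_costs
from .education import EducationEffect, apply_policy, education_cost
from .impoverishment import catastrophic_cases
from .income import IncomeModel, build_income_model
from .params import CountryParameters

__all__ = [
    "ParameterDistributionSpec",
    "UncertaintyResult",
    "SpecError",
    "default_parameter_specs",
    "sample_parameter",
    "run_psa",
    "psa_frame",
]

_FAMILIES = ("gamma", "beta", "logistic")
_INCOME_PARAMS = ("gdp_per_capita", "gini")


class SpecError(ValueError):
    """A distribution spec cannot be moment-matched to its parameter."""


@dataclass(frozen=True)
class ParameterDistributionSpec:
    """Sampling distribution for one ``CountryParameters`` field.

    Exactly one of ``sd`` (absolute, same units as the parameter) or
    ``rel_sd`` (fraction of each mean element) must be given; vector fields
    are drawn elementwise and independently.
    """

    parameter: str
    family: str
    sd: float | None = None
    rel_sd: float | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise SpecError(f"{self.parameter}: unknown family {self.family!r}")
        if (self.sd is None) == (self.rel_sd is None):
            raise SpecError(f"{self.parameter}: give exactly one of sd or rel_sd")
        v = self.sd if self.sd is not None else self.rel_sd
        if v < 0:
            raise SpecError(f"{self.parameter}: sd must be >= 0, got {v}")


def default_parameter_specs(params: CountryParameters) -> list[ParameterDistributionSpec]:
    """The default PSA design: vary MMR, RRs, costs and the education effect."""
    return [
        ParameterDistributionSpec("mmr", "gamma", rel_sd=0.10),
        ParameterDistributionSpec("rr_by_age", "gamma", rel_sd=0.10),
        ParameterDistributionSpec("oop_medical_by_quintile", "gamma", rel_sd=0.10),
        ParameterDistributionSpec("oop_transport_by_quintile", "gamma", rel_sd=0.10),
        ParameterDistributionSpec("education_effect", "logistic", sd=params.education_effect_se),
    ]


def sample_parameter(
    family: str, mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` moment-matched draws for one scalar parameter element."""
    if sd == 0.0:
        return np.full(n, float(mean))
    if family == "gamma":
        if mean <= 0:
            raise SpecError(f"gamma needs mean > 0 when sd > 0, got mean={mean}")
        k = (mean / sd) ** 2
        return rng.gamma(shape=k, scale=sd**2 / mean, size=n)
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise SpecError(f"beta needs mean in (0, 1), got {mean}")
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        if nu <= 0:
            raise SpecError(
                f"beta infeasible: sd={sd} too large for mean={mean} "
                f"(needs sd² < mean·(1−mean))"
            )
        return rng.beta(mean * nu, (1.0 - mean) * nu, size=n)
    if family == "logistic":
        return rng.logistic(loc=mean, scale=sd * math.sqrt(3.0) / math.pi, size=n)
    raise SpecError(f"unknown family {family!r}")


@dataclass(frozen=True)
class UncertaintyResult:
    """Point estimate with its 95% uncertainty range (2.5/97.5 percentiles)."""

    point: float
    lo: float
    hi: float
    n_trials: int
    seed: int

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"lo={self.lo} exceeds hi={self.hi}")


def _pipeline_outcomes(
    params: CountryParameters,
    income: IncomeModel,
    threshold: float | None,
    discount: bool,
) -> dict[str, float]:
    deaths = maternal_deaths(params)
    oop = oop_costs(params)
    cata = catastrophic_cases(params, income=income, threshold=threshold)
    impact = apply_policy(params, income=income, discount=discount, threshold=threshold)
    return {
        "deaths_total": deaths.total,
        "deaths_bottom_two_share": deaths.bottom_two_share,
        "oop_total": oop.total,
        "oop_bottom_two_share": oop.bottom_two_share,
        "catastrophic_total": cata.total,
        "catastrophic_bottom_two_share": cata.cases_by_quintile.bottom_two_share,
        "deaths_averted": impact.deaths_averted.total,
        "oop_averted": impact.oop_averted.total,
        "catastrophic_averted": impact.catastrophic_averted.total,
        "education_cost": impact.education_cost,
    }


def _resolve_means(params: CountryParameters, spec: ParameterDistributionSpec) -> np.ndarray:
    try:
        value = getattr(params, spec.parameter)
    except AttributeError:
        raise SpecError(f"unknown parameter {spec.parameter!r}") from None
    if value is None:
        raise SpecError(f"{spec.parameter} is unset; cannot vary it")
    return np.atleast_1d(np.asarray(value, dtype=float))


def run_psa(
    params: CountryParameters,
    specs: list[ParameterDistributionSpec] | None = None,
    n_trials: int = 1000,
    seed: int = 0,
    threshold: float | None = None,
    discount: bool = False,
) -> dict[str, UncertaintyResult]:
    """Joint Monte Carlo over ``specs``; 95% URs for every pipeline outcome.

    Deterministic for a fixed seed: parameters are drawn up front in spec
    order from a single generator, then the deterministic pipeline is re-run
    per trial.
    """
    if n_trials < 2:
        raise ValueError(f"n_trials must be >= 2, got {n_trials}")
    if specs is None:
        specs = default_parameter_specs(params)
    rng = np.random.default_rng(seed)
    draws: list[tuple[ParameterDistributionSpec, bool, np.ndarray]] = []
    for spec in specs:
        means = _resolve_means(params, spec)
        is_vector = np.ndim(getattr(params, spec.parameter)) > 0
        sds = (
            np.full_like(means, spec.sd) if spec.sd is not None else spec.rel_sd * means
        )
        try:
            mat = np.column_stack(
                [
                    sample_parameter(spec.family, m, s, n_trials, rng)
                    for m, s in zip(means, sds)
                ]
            )
        except SpecError as exc:
            raise SpecError(f"{spec.parameter}: {exc}") from exc
        if spec.parameter == "education_effect":
            mat = np.clip(mat, 0.0, 1.0 - 1e-9)  # logistic tails leave [0, 1)
        draws.append((spec, is_vector, mat))

    base_income = build_income_model(params)
    vary_income = any(s.parameter in _INCOME_PARAMS for s in specs)
    samples: dict[str, list[float]] = {}
    for t in range(n_trials):
        changes = {}
        for spec, is_vector, mat in draws:
            changes[spec.parameter] = tuple(mat[t]) if is_vector else float(mat[t, 0])
        trial_params = params.replace(**changes)
        income = build_income_model(trial_params) if vary_income else base_income
        for name, value in _pipeline_outcomes(trial_params, income, threshold, discount).items():
            samples.setdefault(name, []).append(value)

    point = _pipeline_outcomes(params, base_income, threshold, discount)
    results = {}
    for name, values in samples.items():
        lo, hi = np.percentile(np.asarray(values), [2.5, 97.5])
        results[name] = UncertaintyResult(
            point=point[name], lo=float(lo), hi=float(hi), n_trials=n_trials, seed=seed
        )
    return results


def psa_frame(results: dict[str, UncertaintyResult]) -> pd.DataFrame:
    """Tabulate PSA results: one row per outcome with point, lo, hi."""
    return pd.DataFrame(
        [
            {"outcome": k, "point": r.point, "lo": r.lo, "hi": r.hi, "n_trials": r.n_trials}
            for k, r in results.items()
        ]
    )
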