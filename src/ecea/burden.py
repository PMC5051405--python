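"""Adolescent maternal deaths and out-of-pocket (OOP) expenditure per quintile.

The burden model is a deterministic accounting chain:

  pregnancies per age a        P_a = (N/5) · π_a
  deaths per age               D_a = P_a · r_a · MMR / 100 000
  pregnancies per quintile q   P_q = (Σ_a P_a) · p_q / Σ p_q      (share rule)
  complicated deliveries       X_q = κ · P_q
  OOP-incurring deliveries     U_q = u_q · X_q
  OOP expenditure              C_q = U_q · (c_q + t_q)

where N is the population of women 15–19, π_a the per-age pregnancy
proportions, r_a the maternal-mortality relative risks vs ages 20–24 (here
4.6 at age 15), p_q the per-quintile pregnancy proportions, κ the complicated
fraction, u_q skilled-birth-attendance coverage, and c_q/t_q the medical and
transport OOP costs of a complicated delivery.

The per-age and per-quintile pregnancy proportions come from different survey
cross-sections and are not consistent as absolute rates, so the two are
reconciled: the per-age profile fixes the total, and the per-quintile profile
enters only as normalized shares. The alternative — absolute per-quintile
counts (N/5)·p_q, with the per-age profile rescaled to match — is available as
``quintile_mode="absolute"`` for sensitivity exploration.

Deaths are allocated to quintiles by the pregnancy shares alone: mortality
risk is assumed independent of quintile conditional on pregnancy. OOP costs
are incurred only by the U_q deliveries that use care; the model applies no
survivorship adjustment to the cost base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import CountryParameters, N_QUINTILES

__all__ = [
    "QuintileOutcomes",
    "PregnancyLedger",
    "build_pregnancy_ledger",
    "deaths_by_age",
    "maternal_deaths",
    "oop_costs",
]

AGES = (15, 16, 17, 18, 19)


@dataclass(frozen=True, eq=False)
class QuintileOutcomes:
    """A per-quintile result vector (poorest → richest) with its total."""

    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_QUINTILES,):
            raise ValueError(f"expected {N_QUINTILES} quintile values, got shape {v.shape}")
        if np.any(v < -1e-9):
            raise ValueError(f"quintile values must be non-negative, got {v}")
        object.__setattr__(self, "values", np.maximum(v, 0.0))

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def shares(self) -> np.ndarray:
        t = self.total
        return self.values / t if t > 0 else np.zeros(N_QUINTILES)

    @property
    def bottom_two_share(self) -> float:
        return float(self.shares[:2].sum())

    def scaled(self, factor: float) -> "QuintileOutcomes":
        return QuintileOutcomes(self.values * factor, units=self.units)

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "quintile": [f"Q{i}" for i in range(1, N_QUINTILES + 1)] + ["total"],
                name: list(self.values) + [self.total],
                "share": list(self.shares) + [1.0 if self.total > 0 else 0.0],
            }
        )
        if self.units:
            df["units"] = self.units
        return df


@dataclass(frozen=True)
class PregnancyLedger:
    """Pregnancy counts reconciled across the age and quintile profiles.

    Invariant: Σ per_age == Σ per_quintile (both parameterizations describe
    the same pregnancies).
    """

    per_age: np.ndarray  # pregnancies at ages 15..19
    per_quintile: np.ndarray  # pregnancies per quintile, poorest -> richest
    complicated_per_quintile: np.ndarray
    oop_incurring_per_quintile: np.ndarray  # complicated deliveries that use care

    @property
    def total(self) -> float:
        return float(self.per_age.sum())


def build_pregnancy_ledger(
    params: CountryParameters, quintile_mode: str = "share"
) -> PregnancyLedger:
    """Count pregnancies, complicated deliveries and care-using deliveries.

    ``quintile_mode="share"`` (default): the per-age profile sets the total,
    the per-quintile profile is used as normalized shares.
    ``quintile_mode="absolute"``: per-quintile counts are (N/5)·p_q and the
    per-age profile is rescaled to that total.
    """
    if quintile_mode not in ("share", "absolute"):
        raise ValueError(f"quintile_mode must be 'share' or 'absolute', got {quintile_mode!r}")
    cohort = params.population_15_19 / 5.0
    pi = np.asarray(params.pregnant_by_age)
    pq = np.asarray(params.pregnant_by_quintile)
    if pq.sum() <= 0:
        raise ValueError("pregnant_by_quintile sums to zero: quintile split undefined")
    per_age = cohort * pi
    if quintile_mode == "share":
        per_quintile = per_age.sum() * pq / pq.sum()
    else:
        per_quintile = cohort * pq
        per_age = (
            per_age * per_quintile.sum() / per_age.sum()
            if per_age.sum() > 0
            else np.zeros_like(per_age)
        )
    complicated = params.complicated_fraction * per_quintile
    incurring = complicated * np.asarray(params.usage_by_quintile)
    return PregnancyLedger(
        per_age=per_age,
        per_quintile=per_quintile,
        complicated_per_quintile=complicated,
        oop_incurring_per_quintile=incurring,
    )


def deaths_by_age(params: CountryParameters) -> np.ndarray:
    """Maternal deaths at ages 15..19: (N/5)·π_a·r_a·MMR/100 000.

    Pregnancies carried to term proxy the live-birth denominator; the
    published 15–49 MMR applies at the reference ages and is scaled by r_a
    where adolescent risk is elevated.
    """
    cohort = params.population_15_19 / 5.0
    return (
        cohort
        * np.asarray(params.pregnant_by_age)
        * np.asarray(params.rr_by_age)
        * params.mmr
        / 100_000.0
    )


def maternal_deaths(
    params: CountryParameters, quintile_mode: str = "share"
) -> QuintileOutcomes:
    """Adolescent maternal deaths per income quintile.

    The age model gives the total; the quintile split follows the pregnancy
    shares, so the equity decomposition of deaths is exactly the normalized
    per-quintile pregnancy vector.
    """
    total = deaths_by_age(params).sum()
    ledger = build_pregnancy_ledger(params, quintile_mode=quintile_mode)
    shares = ledger.per_quintile / ledger.per_quintile.sum() if ledger.total > 0 else np.zeros(5)
    return QuintileOutcomes(total * shares, units="deaths")


def oop_costs(params: CountryParameters, quintile_mode: str = "share") -> QuintileOutcomes:
    """Total OOP expenditure (medical + transport) per quintile, US$2014."""
    ledger = build_pregnancy_ledger(params, quintile_mode=quintile_mode)
    unit_cost = np.asarray(params.oop_medical_by_quintile) + np.asarray(
        params.oop_transport_by_quintile
    )
    return QuintileOutcomes(ledger.oop_incurring_per_quintile * unit_cost, units="US$2014")
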