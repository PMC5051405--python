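"""Gamma income model calibrated to GDP per capita and the Gini index.

Annual individual income is modelled as Gamma(k, θ). For a gamma distribution
the Gini index depends on the shape alone,

    G(k) = Γ(k + 1/2) / (√π · Γ(k + 1)),

so the calibration is two exact moment conditions: invert G(k) = Gini for the
shape k, then set the scale θ = (GDP per capita) / k so the mean kθ equals
GDP per capita. Income quintiles are the population quantile bands at
0.2/0.4/0.6/0.8 — deterministic and sample-size-free, rather than re-ranked
from a finite sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .params import CountryParameters, N_QUINTILES

__all__ = [
    "IncomeModel",
    "gamma_gini",
    "gini_to_shape",
    "build_income_model",
    "prob_income_below",
    "sample_incomes",
    "sample_incomes_in_quintile",
    "empirical_gini",
]

# Bisection bracket for the shape; covers Gini from ~0.018 up to ~0.99.
_SHAPE_LO, _SHAPE_HI = 1e-3, 1e3


def gamma_gini(shape: float) -> float:
    """Gini index of a gamma distribution with the given shape (any scale)."""
    if shape <= 0:
        raise ValueError(f"shape must be > 0, got {shape}")
    return math.exp(gammaln(shape + 0.5) - gammaln(shape + 1.0)) / math.sqrt(math.pi)


def gini_to_shape(gini: float) -> float:
    """Invert :func:`gamma_gini`: the shape whose gamma Gini equals ``gini``.

    G(k) is strictly decreasing in k, so the root is unique; Brent's method on
    [1e-3, 1e3] resolves it to ~1e-12.
    """
    if not 0.0 < gini < 1.0:
        raise ValueError(f"gini must lie in (0, 1), got {gini}")
    if not gamma_gini(_SHAPE_HI) < gini < gamma_gini(_SHAPE_LO):
        raise ValueError(f"gini={gini} outside the invertible range of the gamma family")
    return float(
        optimize.brentq(
            lambda k: gamma_gini(k) - gini, _SHAPE_LO, _SHAPE_HI, xtol=1e-13, rtol=8.9e-16
        )
    )


@dataclass(frozen=True)
class IncomeModel:
    """Calibrated gamma income distribution with quintile boundaries.

    ``quintile_bounds`` are the 20/40/60/80th-percentile incomes (US$2014);
    quintile q occupies the band between bounds q-1 and q (0 and +inf at the
    ends), each holding exactly 20% of the population.
    """

    shape: float
    scale: float
    quintile_bounds: tuple[float, float, float, float]

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be > 0")
        b = self.quintile_bounds
        if not all(b[i] < b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"quintile_bounds must be strictly increasing, got {b}")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def gini(self) -> float:
        return gamma_gini(self.shape)

    @cached_property
    def _dist(self):
        return stats.gamma(a=self.shape, scale=self.scale)

    def cdf(self, x) -> np.ndarray:
        return self._dist.cdf(x)

    def ppf(self, q) -> np.ndarray:
        return self._dist.ppf(q)

    def quintile_band(self, quintile: int) -> tuple[float, float]:
        """(low, high) income bounds of quintile ``quintile`` in 1..5."""
        if not 1 <= quintile <= N_QUINTILES:
            raise ValueError(f"quintile must be in 1..{N_QUINTILES}, got {quintile}")
        lo = 0.0 if quintile == 1 else self.quintile_bounds[quintile - 2]
        hi = math.inf if quintile == N_QUINTILES else self.quintile_bounds[quintile - 1]
        return lo, hi


def build_income_model(params: CountryParameters) -> IncomeModel:
    """Calibrate the income model for one country (mean = GDP per capita)."""
    shape = gini_to_shape(params.gini)
    scale = params.gdp_per_capita / shape
    bounds = stats.gamma(a=shape, scale=scale).ppf([0.2, 0.4, 0.6, 0.8])
    return IncomeModel(shape=shape, scale=scale, quintile_bounds=tuple(float(b) for b in bounds))


def prob_income_below(model: IncomeModel, threshold: float, quintile: int) -> float:
    """P(income < threshold | income in the given quintile band).

    Each band has probability mass exactly 0.2, so the conditional probability
    is (F(min(threshold, hi)) − F(lo))⁺ / 0.2 with F the gamma CDF.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    lo, hi = model.quintile_band(quintile)
    if threshold <= lo:
        return 0.0
    mass = float(model.cdf(min(threshold, hi)) - model.cdf(lo))
    return min(max(mass, 0.0) / 0.2, 1.0)


def prob_income_in_band(model: IncomeModel, lo_inc: float, hi_inc: float, quintile: int) -> float:
    """P(lo_inc <= income < hi_inc | quintile band); used by the poverty headcount."""
    blo, bhi = model.quintile_band(quintile)
    lo_eff, hi_eff = max(lo_inc, blo), min(hi_inc, bhi)
    if hi_eff <= lo_eff:
        return 0.0
    mass = float(model.cdf(hi_eff) - model.cdf(lo_eff))
    return min(max(mass, 0.0) / 0.2, 1.0)


def sample_incomes(model: IncomeModel, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` incomes from the calibrated distribution, reproducibly."""
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.gamma(shape=model.shape, scale=model.scale, size=n)


def sample_incomes_in_quintile(
    model: IncomeModel, quintile: int, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw incomes conditional on membership of one quintile band.

    Inverse-CDF sampling of a uniform on the band's probability interval
    [0.2(q-1), 0.2q]; exact, no rejection step.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    model.quintile_band(quintile)  # validates the index
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(0.2 * (quintile - 1), 0.2 * quintile, size=n)
    return np.asarray(model.ppf(u))


def empirical_gini(incomes: np.ndarray) -> float:
    """Sample Gini coefficient (mean absolute difference / 2·mean)."""
    x = np.sort(np.asarray(incomes, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * x) / (n * np.sum(x))) - (n + 1.0) / n)
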