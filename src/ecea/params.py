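"""Country parameter sets: the full input vector for one country's analysis.

A :class:`CountryParameters` holds everything the pipeline needs — population of
women aged 15–19, maternal mortality ratio (MMR), the age profile of pregnancy,
the quintile profiles of pregnancy, healthcare usage and out-of-pocket (OOP)
costs, the income-distribution moments (GDP per capita, Gini), and the
education-policy inputs. All monetary fields are US$2014 by contract; no
currency conversion is performed anywhere in the package.

Configs are YAML (JSON is a YAML subset and is accepted). Percentage-like
fields may be written either as proportions (``0.19``) or as percentages
(``19`` with ``percent: true``); the explicit flag exists to prevent silent
100x errors. Internally everything is a proportion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "CountryParameters",
    "ParameterError",
    "SchemaError",
    "ValidationError",
    "available_fixtures",
    "load_country",
    "save_country",
]

N_AGES = 5  # ages 15..19
N_QUINTILES = 5


class ParameterError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ParameterError):
    """A required field is missing or has the wrong structure."""


class ValidationError(ParameterError):
    """A field value violates a model invariant."""


# Fields divided by 100 when the config declares `percent: true`.
_PERCENT_FIELDS = frozenset(
    {
        "complicated_fraction",
        "pregnant_by_age",
        "pregnant_by_quintile",
        "usage_by_quintile",
        "education_effect",
        "education_effect_se",
    }
)

_REQUIRED_FIELDS = (
    "name",
    "population_15_19",
    "mmr",
    "complicated_fraction",
    "rr_by_age",
    "pregnant_by_age",
    "pregnant_by_quintile",
    "usage_by_quintile",
    "oop_medical_by_quintile",
    "oop_transport_by_quintile",
    "gdp_per_capita",
    "gini",
)

# Quintile-length vector fields; a scalar in the config broadcasts to 5 entries.
_QUINTILE_FIELDS = (
    "pregnant_by_quintile",
    "usage_by_quintile",
    "oop_medical_by_quintile",
    "oop_transport_by_quintile",
)


def _as_vector(name: str, value, length: int) -> tuple[float, ...]:
    if isinstance(value, (int, float)):
        return (float(value),) * length
    if not isinstance(value, Sequence) or isinstance(value, str):
        raise SchemaError(f"{name!r} must be a number or a sequence of {length} numbers")
    vec = tuple(float(v) for v in value)
    if len(vec) != length:
        raise ValidationError(
            f"{name!r} must have exactly {length} entries, got {len(vec)}: {value!r}"
        )
    return vec


@dataclass(frozen=True)
class CountryParameters:
    """Validated input vector for one country.

    Proportions are stored on the [0, 1] scale. Quintile vectors are ordered
    poorest → richest; age vectors cover ages 15, 16, 17, 18, 19.
    """

    name: str
    population_15_19: float
    mmr: float  # maternal deaths per 100 000 live births, women 15-49
    complicated_fraction: float  # share of deliveries that are complicated
    rr_by_age: tuple[float, ...]  # maternal-mortality RR vs ages 20-24
    pregnant_by_age: tuple[float, ...]
    pregnant_by_quintile: tuple[float, ...]
    usage_by_quintile: tuple[float, ...]  # skilled-birth-attendance coverage
    oop_medical_by_quintile: tuple[float, ...]  # US$2014 per complicated delivery
    oop_transport_by_quintile: tuple[float, ...]  # US$2014
    gdp_per_capita: float  # US$2014, mean of the income distribution
    gini: float
    education_effect: float = 0.18  # relative reduction in pregnancy per +1 year
    education_effect_se: float = 0.02
    education_cost_per_pupil: float = 0.0  # US$2014 per pupil per year
    catastrophic_threshold: float = 0.10  # OOP > tau * income counts as catastrophic
    poverty_line: float | None = None  # US$2014/year, for the headcount variant
    discount_rate: float = 0.03

    def __post_init__(self):
        for name in ("rr_by_age", "pregnant_by_age"):
            object.__setattr__(self, name, _as_vector(name, getattr(self, name), N_AGES))
        for name in _QUINTILE_FIELDS:
            object.__setattr__(self, name, _as_vector(name, getattr(self, name), N_QUINTILES))
        self._validate()

    def _validate(self) -> None:
        def err(msg):
            raise ValidationError(f"{self.name or 'parameters'}: {msg}")

        if not self.population_15_19 > 0:
            err(f"population_15_19 must be > 0, got {self.population_15_19}")
        if self.mmr < 0:
            err(f"mmr must be >= 0, got {self.mmr}")
        if not 0 < self.gini < 1:
            err(f"gini must lie in (0, 1), got {self.gini}")
        if self.gdp_per_capita <= 0:
            err(f"gdp_per_capita must be > 0, got {self.gdp_per_capita}")
        for name in (
            "complicated_fraction",
            "education_effect",
            "education_effect_se",
            "catastrophic_threshold",
            "discount_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                err(f"{name} must lie in [0, 1], got {v}")
        for name in ("pregnant_by_age", "pregnant_by_quintile", "usage_by_quintile"):
            for v in getattr(self, name):
                if not 0 <= v <= 1:
                    err(f"{name} entries must lie in [0, 1], got {v}")
        for name in ("rr_by_age", "oop_medical_by_quintile", "oop_transport_by_quintile"):
            for v in getattr(self, name):
                if v < 0:
                    err(f"{name} entries must be >= 0, got {v}")
        if self.poverty_line is not None and self.poverty_line < 0:
            err(f"poverty_line must be >= 0, got {self.poverty_line}")

    def replace(self, **changes) -> "CountryParameters":
        """Return a copy with ``changes`` applied and re-validated."""
        return dataclasses.replace(self, **changes)

    def to_dict(self, percent: bool = False) -> dict:
        """Plain-python dict suitable for YAML/JSON serialization."""
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        if d["poverty_line"] is None:
            del d["poverty_line"]
        if percent:
            for name in _PERCENT_FIELDS:
                v = d[name]
                d[name] = [x * 100 for x in v] if isinstance(v, list) else v * 100
        d["percent"] = percent
        return d


def available_fixtures() -> list[str]:
    """Names of the country parameter sets shipped with the package."""
    pkg = resources.files("ecea.data")
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def _parse(raw: dict, origin: str) -> CountryParameters:
    if not isinstance(raw, dict):
        raise SchemaError(f"{origin}: config must be a mapping, got {type(raw).__name__}")
    raw = dict(raw)
    percent = bool(raw.pop("percent", False))
    missing = [f for f in _REQUIRED_FIELDS if f not in raw]
    if missing:
        raise SchemaError(f"{origin}: missing required field(s): {', '.join(missing)}")
    known = {f.name for f in dataclasses.fields(CountryParameters)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{origin}: unknown field(s): {', '.join(sorted(unknown))}")
    if percent:
        for name in _PERCENT_FIELDS & set(raw):
            v = raw[name]
            raw[name] = (
                [x / 100 for x in v] if isinstance(v, (list, tuple)) else v / 100
            )
    return CountryParameters(**raw)


def load_country(source: str | Path) -> CountryParameters:
    """Load and validate a country parameter set.

    ``source`` is either a path to a YAML/JSON config or the name of a
    packaged fixture (see :func:`available_fixtures`, e.g. ``"india"``,
    ``"niger"``).
    """
    name = str(source)
    if name in available_fixtures() and not Path(name).exists():
        text = resources.files("ecea.data").joinpath(f"{name}.yaml").read_text()
        return _parse(yaml.safe_load(text), origin=name)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"no such config file or packaged fixture: {source!r} "
            f"(fixtures: {', '.join(available_fixtures())})"
        )
    return _parse(yaml.safe_load(path.read_text()), origin=str(path))


def save_country(params: CountryParameters, path: str | Path) -> Path:
    """Serialize ``params`` to YAML so that ``load_country`` round-trips exactly."""
    path = Path(path)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
    return path
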