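"""Full-pipeline orchestration: CSV tables, bar-chart figures and a manifest.

``run_full`` executes every stage for one country config and writes, into one
output directory: ``deaths.csv``, ``oop.csv``, ``impoverishment.csv``,
``policy.csv``, optionally ``poverty_headcount.csv`` and ``psa.csv``, the
matching per-quintile bar charts, and ``manifest.json`` recording the exact
inputs (config path, options, seed, package version, timestamp). The CSVs are
the numeric interface — every total in a file equals the library-level total
exactly; the figures are a convenience layer over them.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .burden import QuintileOutcomes, maternal_deaths, oop_costs
from .education import apply_policy
from .impoverishment import catastrophic_cases, poverty_headcount
from .income import build_income_model
from .params import CountryParameters, load_country
from .psa import psa_frame, run_psa

__all__ = ["RunManifest", "run_full"]

log = logging.getLogger("ecea")


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one run of the pipeline."""

    config: str
    subcommand: str
    seed: int
    threshold: float
    effect: float
    trials: int | None
    outdir: str
    timestamp: str
    version: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _bar_chart(qo: QuintileOutcomes, title: str, ylabel: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(range(1, 6), qo.values, color="#4878a8")
    ax.set_xticks(range(1, 6))
    ax.set_xticklabels([f"Q{i}" for i in range(1, 6)])
    ax.set_xlabel("income quintile (poorest → richest)")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_full(
    config: str | Path,
    outdir: str | Path,
    seed: int = 0,
    threshold: float | None = None,
    effect: float | None = None,
    discount: bool = False,
    poverty_line: float | None = None,
    psa: bool = False,
    trials: int = 1000,
    figures: bool = True,
) -> dict[str, Path]:
    """Run the whole analysis for one country; returns {name: written path}.

    The config is loaded and validated before anything is written, so an
    invalid config produces no partial outputs.
    """
    params: CountryParameters = load_country(config)  # validates before any I/O
    income = build_income_model(params)
    tau = params.catastrophic_threshold if threshold is None else threshold
    eff_params = params if effect is None else params.replace(education_effect=effect)

    log.info("loaded %s: population 15-19 = %s, MMR = %s", params.name,
             f"{params.population_15_19:,.0f}", params.mmr)
    deaths = maternal_deaths(params)
    oop = oop_costs(params)
    impov = catastrophic_cases(eff_params, income=income, threshold=tau, seed=seed)
    impact = apply_policy(eff_params, income=income, discount=discount, threshold=tau)
    log.info("deaths total = %.0f, OOP total = $%.0f, catastrophic cases = %.0f",
             deaths.total, oop.total, impov.total)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save(name: str, frame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path

    save("deaths", deaths.to_frame("deaths"))
    save("oop", oop.to_frame("oop_usd"))
    save("impoverishment", impov.to_frame())
    policy = impact.to_frame()
    policy["education_cost"] = impact.education_cost
    save("policy", policy)
    if poverty_line is not None:
        save(
            "poverty_headcount",
            poverty_headcount(params, income=income, poverty_line=poverty_line, seed=seed).to_frame(),
        )
    if psa:
        log.info("running PSA: %d trials, seed %d", trials, seed)
        save("psa", psa_frame(run_psa(eff_params, n_trials=trials, seed=seed,
                                      threshold=tau, discount=discount)))

    if figures:
        _bar_chart(deaths, f"{params.name}: adolescent maternal deaths", "deaths",
                   outdir / "deaths.png")
        _bar_chart(oop, f"{params.name}: OOP expenditure", "US$2014", outdir / "oop.png")
        _bar_chart(impov.cases_by_quintile,
                   f"{params.name}: catastrophic expenditure (τ={tau:.0%})", "cases",
                   outdir / "impoverishment.png")
        _bar_chart(impact.deaths_averted,
                   f"{params.name}: deaths averted (+1 year education)", "deaths averted",
                   outdir / "deaths_averted.png")
        written.update({p.stem + "_png": p for p in outdir.glob("*.png")})

    manifest = RunManifest(
        config=str(config),
        subcommand="run",
        seed=seed,
        threshold=tau,
        effect=eff_params.education_effect,
        trials=trials if psa else None,
        outdir=str(outdir),
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
        version=__version__,
    )
    manifest.write(outdir / "manifest.json")
    written["manifest"] = outdir / "manifest.json"
    return written
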