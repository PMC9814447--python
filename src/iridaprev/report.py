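"""Population-stratified estimation and report rendering.

Builds one row per population (carrier frequency per thousand, genetic
prevalence per million, 95% CIs), applying the P/LP + flag filter once and
gating out populations whose effective allele number is too small for a
meaningful binomial interval.  Rendering keeps full precision in JSON and
rounds display units half-even to 2 decimals, the convention every published
cell follows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .estimator import (
    AnStrategy,
    estimate_population,
    pool_allele_frequencies,
)
from .variants import Population, VariantRecord, filter_for_estimation

__all__ = ["ReportConfig", "ReportRow", "PrevalenceReport", "build_report", "render"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ReportConfig:
    level: float = 0.95
    method: str = "approx"
    an_strategy: str = "mean"
    #: Minimum effective allele number for a population to be analysed.
    gate_alleles: int = 10_000
    seed: int | None = None


@dataclass(frozen=True)
class ReportRow:
    population: Population
    status: str  # analysed | not_analysed
    prevalence_per_million: float | None = None
    prevalence_ci_per_million: tuple[float, float] | None = None
    carrier_per_thousand: float | None = None
    carrier_ci_per_thousand: tuple[float, float] | None = None
    q_sum: float | None = None
    ac_total: int | None = None
    an_effective: int | None = None
    n_observed: int = 0
    n_missing: int = 0


@dataclass(frozen=True)
class PrevalenceReport:
    rows: tuple[ReportRow, ...]
    n_variants_input: int
    n_variants_included: int
    config: ReportConfig = field(default_factory=ReportConfig)


def build_report(
    records: list[VariantRecord],
    populations: list[Population],
    config: ReportConfig | None = None,
) -> PrevalenceReport:
    """Estimate carrier frequency and prevalence for each requested population.

    Deterministic given inputs.  A population with no usable data or with an
    effective allele number below ``config.gate_alleles`` is reported
    ``not_analysed`` with no numbers (the study excluded the Ashkenazi
    Jewish and Finnish strata on sample-size grounds).
    """
    if not populations:
        raise ConfigurationError("no populations requested")
    config = config or ReportConfig()
    strategy = AnStrategy(config.an_strategy)
    included = filter_for_estimation(records)

    rows: list[ReportRow] = []
    for pop in populations:
        pooled = pool_allele_frequencies(included, pop, strategy)
        gated = (
            pooled.an_effective is None
            or pooled.an_effective < config.gate_alleles
            or pooled.n_observed == 0
        )
        if gated:
            rows.append(
                ReportRow(
                    population=pop,
                    status="not_analysed",
                    n_observed=pooled.n_observed,
                    n_missing=pooled.n_missing,
                )
            )
            continue
        prevalence, carrier = estimate_population(pooled, config.level, config.method)
        rows.append(
            ReportRow(
                population=pop,
                status="analysed",
                prevalence_per_million=prevalence.per_million,
                prevalence_ci_per_million=(
                    prevalence.ci_low * 1e6,
                    prevalence.ci_high * 1e6,
                ),
                carrier_per_thousand=carrier.per_thousand,
                carrier_ci_per_thousand=(carrier.ci_low * 1e3, carrier.ci_high * 1e3),
                q_sum=pooled.q_sum,
                ac_total=pooled.ac_total,
                an_effective=pooled.an_effective,
                n_observed=pooled.n_observed,
                n_missing=pooled.n_missing,
            )
        )
    return PrevalenceReport(
        rows=tuple(rows),
        n_variants_input=len(records),
        n_variants_included=len(included),
        config=config,
    )


def _fmt(x: float | None) -> str:
    # Python round() is half-even, matching the published rounding.
    return "" if x is None else f"{round(x, 2):.2f}"


def _fmt_ci(ci: tuple[float, float] | None) -> str:
    return "" if ci is None else f"[{_fmt(ci[0])}, {_fmt(ci[1])}]"


_COLUMNS = [
    "population",
    "status",
    "prevalence_per_million",
    "prevalence_95ci",
    "carrier_per_thousand",
    "carrier_95ci",
]


def _display_cells(row: ReportRow) -> list[str]:
    return [
        row.population.value,
        row.status,
        _fmt(row.prevalence_per_million),
        _fmt_ci(row.prevalence_ci_per_million),
        _fmt(row.carrier_per_thousand),
        _fmt_ci(row.carrier_ci_per_thousand),
    ]


def render(report: PrevalenceReport, format: str = "markdown") -> str:
    """Render a report as ``csv``, ``json`` or ``markdown`` text.

    Pure: the same report always yields byte-identical output.  JSON carries
    full-precision values alongside the 2-decimal display strings; CSV and
    markdown show display precision only.
    """
    if format == "csv":
        lines = [",".join(_COLUMNS)]
        for row in report.rows:
            cells = _display_cells(row)
            lines.append(",".join(f'"{c}"' if "," in c else c for c in cells))
        return "\n".join(lines) + "\n"

    if format == "markdown":
        lines = [
            "| " + " | ".join(_COLUMNS) + " |",
            "|" + "|".join(["---"] * len(_COLUMNS)) + "|",
        ]
        for row in report.rows:
            lines.append("| " + " | ".join(_display_cells(row)) + " |")
        return "\n".join(lines) + "\n"

    if format == "json":
        payload = {
            "metadata": {
                "n_variants_input": report.n_variants_input,
                "n_variants_included": report.n_variants_included,
                "level": report.config.level,
                "method": report.config.method,
                "an_strategy": report.config.an_strategy,
                "gate_alleles": report.config.gate_alleles,
                "seed": report.config.seed,
            },
            "rows": [
                {
                    "population": row.population.value,
                    "status": row.status,
                    "prevalence_per_million": row.prevalence_per_million,
                    "prevalence_ci_per_million": row.prevalence_ci_per_million,
                    "carrier_per_thousand": row.carrier_per_thousand,
                    "carrier_ci_per_thousand": row.carrier_ci_per_thousand,
                    "q_sum": row.q_sum,
                    "ac_total": row.ac_total,
                    "an_effective": row.an_effective,
                    "n_observed": row.n_observed,
                    "n_missing": row.n_missing,
                    "display": dict(zip(_COLUMNS, _display_cells(row))),
                }
                for row in report.rows
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    raise ConfigurationError(
        f"unknown format {format!r}; expected csv, json or markdown"
    )


def report_from_json(text: str, config: ReportConfig | None = None) -> PrevalenceReport:
    """Rebuild a report from its JSON rendering (full-precision fields)."""
    payload = json.loads(text)
    meta = payload["metadata"]
    cfg = config or ReportConfig(
        level=meta["level"],
        method=meta["method"],
        an_strategy=meta["an_strategy"],
        gate_alleles=meta["gate_alleles"],
        seed=meta["seed"],
    )
    rows = tuple(
        ReportRow(
            population=Population(r["population"]),
            status=r["status"],
            prevalence_per_million=r["prevalence_per_million"],
            prevalence_ci_per_million=(
                tuple(r["prevalence_ci_per_million"])
                if r["prevalence_ci_per_million"]
                else None
            ),
            carrier_per_thousand=r["carrier_per_thousand"],
            carrier_ci_per_thousand=(
                tuple(r["carrier_ci_per_thousand"])
                if r["carrier_ci_per_thousand"]
                else None
            ),
            q_sum=r["q_sum"],
            ac_total=r["ac_total"],
            an_effective=r["an_effective"],
            n_observed=r["n_observed"],
            n_missing=r["n_missing"],
        )
        for r in payload["rows"]
    )
    return PrevalenceReport(
        rows=rows,
        n_variants_input=meta["n_variants_input"],
        n_variants_included=meta["n_variants_included"],
        config=cfg,
    )
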