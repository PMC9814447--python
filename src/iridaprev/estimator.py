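"""Hardy-Weinberg carrier-frequency and genetic-prevalence estimation.

For an autosomal-recessive disorder with independent biallelic pathogenic
sites at frequencies q_i, a haplotype carries at least one pathogenic allele
with probability 1 - prod_i(1 - q_i), so under random mating

    genetic prevalence  = [1 - prod_i(1 - q_i)]^2  ~  (sum_i q_i)^2
    carrier frequency   = 2 (1 - sum_i q_i) sum_i q_i  ~  2 sum_i q_i

with the approximations accurate to O(sum q) relative error for rare
alleles.  q_i is estimated directly by the observed AC_i/AN_i in a reference
cohort; the pooled count (sum AC_i, effective AN) is treated as one binomial
proportion, whose 95% Wilson score interval is transformed onto the carrier
scale (doubling) and the prevalence scale (squaring) - both monotone on the
relevant domain, so endpoint mapping is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .variants import Population, VariantRecord

__all__ = [
    "PooledAlleleFrequency",
    "PrevalenceEstimate",
    "CarrierEstimate",
    "AnStrategy",
    "pool_allele_frequencies",
    "genetic_prevalence",
    "carrier_frequency",
    "wilson_interval",
    "estimate_population",
    "GNOMAD_V2_ALLELES",
]

#: 2 x 141,456 individuals: the default effective allele number for the
#: gnomAD v2.1.1 exomes+genomes cohort.
GNOMAD_V2_ALLELES = 2 * 141_456


@dataclass(frozen=True)
class PooledAlleleFrequency:
    """Pooled pathogenic allele frequency sum q_i for one population."""

    population: Population
    q_sum: float
    ac_total: int
    an_effective: int | None
    n_variants: int
    n_missing: int
    q_values: tuple[float, ...] = ()

    @property
    def n_observed(self) -> int:
        return self.n_variants - self.n_missing


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Affected-birth proportion with 95% CI, on the prevalence scale."""

    population: Population
    point: float
    ci_low: float
    ci_high: float

    @property
    def per_million(self) -> float:
        return self.point * 1e6


@dataclass(frozen=True)
class CarrierEstimate:
    """Heterozygous-carrier proportion with 95% CI."""

    population: Population
    point: float
    ci_low: float
    ci_high: float

    @property
    def per_thousand(self) -> float:
        return self.point * 1e3


class AnStrategy:
    """How to choose the effective allele number when pooling variants.

    The per-variant AN_i differ (coverage varies across sites), but the
    pooled count is modelled as a single binomial; ``mean``, ``median`` and
    ``min`` summarise the observed AN_i, while ``fixed:N`` imposes a cohort
    size (``fixed:282912`` reproduces 2 x 141,456 gnomAD v2 individuals).
    """

    def __init__(self, spec: str = "mean"):
        self.spec = spec
        if spec.startswith("fixed:"):
            self.kind = "fixed"
            self.value = int(spec.split(":", 1)[1])
            if self.value < 1:
                raise ValueError(f"fixed AN must be positive, got {self.value}")
        elif spec in {"mean", "median", "min"}:
            self.kind = spec
            self.value = None
        else:
            raise ValueError(
                f"unknown an_strategy {spec!r}; expected mean, median, min or fixed:N"
            )

    def effective(self, an_values: list[int]) -> int | None:
        if self.kind == "fixed":
            return self.value
        if not an_values:
            return None
        if self.kind == "mean":
            return int(round(float(np.mean(an_values))))
        if self.kind == "median":
            return int(round(float(np.median(an_values))))
        return int(min(an_values))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AnStrategy({self.spec!r})"


def pool_allele_frequencies(
    records: list[VariantRecord],
    population: Population,
    an_strategy: AnStrategy | str = "mean",
) -> PooledAlleleFrequency:
    """Pool per-variant pathogenic allele frequencies for one population.

    q_sum is the sum of AC_i/AN_i over variants with data (published AF when
    counts are absent); variants with no data in the population contribute 0
    and are tallied in ``n_missing``.  ``ac_total`` falls back to
    ``round(q_sum * an_effective)`` for frequency-only sources.
    """
    if isinstance(an_strategy, str):
        an_strategy = AnStrategy(an_strategy)

    q_values: list[float] = []
    ac_seen: list[int] = []
    an_seen: list[int] = []
    n_missing = 0
    have_all_counts = True
    for rec in records:
        counts = rec.per_population.get(population)
        q = rec.frequency_in(population)
        if q is None:
            n_missing += 1
            continue
        q_values.append(q)
        if counts is not None and counts.ac is not None and counts.an is not None:
            ac_seen.append(counts.ac)
            an_seen.append(counts.an)
        else:
            have_all_counts = False

    q_sum = float(np.sum(q_values)) if q_values else 0.0
    an_effective = an_strategy.effective(an_seen)
    if have_all_counts and ac_seen:
        ac_total = int(np.sum(ac_seen))
    elif an_effective is not None:
        ac_total = int(round(q_sum * an_effective))
    else:
        ac_total = 0
    return PooledAlleleFrequency(
        population=population,
        q_sum=q_sum,
        ac_total=ac_total,
        an_effective=an_effective,
        n_variants=len(records),
        n_missing=n_missing,
        q_values=tuple(q_values),
    )


def _check_unit(q: float, name: str) -> None:
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {q}")


def genetic_prevalence(q_list, method: str = "exact") -> float:
    """Proportion of births with two pathogenic alleles.

    ``exact`` evaluates [1 - prod(1 - q_i)]^2; ``approx`` the rare-allele
    form (sum q_i)^2.
    """
    q = np.asarray(list(q_list), dtype=float)
    for qi in q:
        _check_unit(float(qi), "q")
    if q.size == 0:
        return 0.0
    if method == "exact":
        # 1 - prod(1 - q_i) via expm1/log1p: stable down to q ~ 1e-300,
        # where the naive product cancels to 0 in double precision
        p_hap = -np.expm1(np.sum(np.log1p(-q)))
        return float(p_hap**2)
    if method == "approx":
        return float(q.sum() ** 2)
    raise ValueError(f"unknown method {method!r}; expected 'exact' or 'approx'")


def carrier_frequency(q_sum: float, method: str = "exact") -> float:
    """Proportion of heterozygous carriers: 2(1 - sum q)(sum q), ~ 2 sum q."""
    _check_unit(q_sum, "q_sum")
    if method == "exact":
        return 2.0 * (1.0 - q_sum) * q_sum
    if method == "approx":
        return 2.0 * q_sum
    raise ValueError(f"unknown method {method!r}; expected 'exact' or 'approx'")


def wilson_interval(ac: int, an: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for the binomial proportion ac/an.

    Obtained by inverting the score test at the two-sided normal quantile for
    ``level``; always contains ac/an and respects [0, 1].
    """
    if an < 1:
        raise ValueError(f"an must be >= 1, got {an}")
    if not 0 <= ac <= an:
        raise ValueError(f"ac must satisfy 0 <= ac <= an, got ac={ac}, an={an}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    low, high = proportion_confint(ac, an, alpha=1.0 - level, method="wilson")
    # the score equation has exact roots 0 and 1 in the degenerate cases;
    # clear the ~1e-22 cancellation residue the closed form leaves
    if ac == 0:
        low = 0.0
    if ac == an:
        high = 1.0
    return float(min(max(low, 0.0), 1.0)), float(min(max(high, 0.0), 1.0))


def estimate_population(
    pooled: PooledAlleleFrequency,
    level: float = 0.95,
    method: str = "approx",
) -> tuple[PrevalenceEstimate, CarrierEstimate]:
    """Point estimates and CIs on the prevalence and carrier scales.

    The allele-scale Wilson interval for (ac_total, an_effective) is mapped
    through the prevalence and carrier transforms endpoint-by-endpoint; both
    are monotone increasing for q <= 1/2, so the mapped intervals retain the
    nominal level.
    """
    if pooled.an_effective is None:
        raise ValueError(
            f"population {pooled.population.value!r} has no effective allele "
            "number; supply an_strategy='fixed:N' or per-variant AN data"
        )
    q_low, q_high = wilson_interval(pooled.ac_total, pooled.an_effective, level)
    if method == "exact":
        prev_point = genetic_prevalence(pooled.q_values, "exact")
    else:
        prev_point = genetic_prevalence([pooled.q_sum], "approx")
    carrier_point = carrier_frequency(pooled.q_sum, method)
    prevalence = PrevalenceEstimate(
        population=pooled.population,
        point=prev_point,
        ci_low=genetic_prevalence([q_low], "approx" if method == "approx" else "exact"),
        ci_high=genetic_prevalence(
            [q_high], "approx" if method == "approx" else "exact"
        ),
    )
    carrier = CarrierEstimate(
        population=pooled.population,
        point=carrier_point,
        ci_low=carrier_frequency(q_low, method),
        ci_high=carrier_frequency(q_high, method),
    )
    return prevalence, carrier
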