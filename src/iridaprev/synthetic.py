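"""Synthetic gnomAD-like cohorts and genotype-level simulation.

The generator draws per-variant, per-population allele counts binomially at
stated true frequencies, so the whole estimation pipeline can be validated
against known truth without any download.  It emulates the sampling
structure of a reference cohort (independent binomial counts per site) but
none of its genealogy: no linkage, no relatedness, no sequencing error or
coverage gradients - see the methods note for what that implies.

Also provides two independent validation harnesses: a genotype-level
simulator that realises the two-haplotype probability model behind the
prevalence formula, and a Monte-Carlo coverage study for the Wilson
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimator import wilson_interval
from .variants import (
    Classification,
    Consequence,
    Population,
    PopulationCounts,
    VariantRecord,
)

__all__ = [
    "SyntheticCohortConfig",
    "default_config",
    "generate_cohort",
    "simulate_genotype_prevalence",
    "ci_coverage_study",
    "synthetic_ptv_complement",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """True frequency spectrum and sampling depths for a synthetic cohort.

    ``true_q[v][pop]`` is the true pathogenic allele frequency of variant
    ``v`` in population ``pop``; ``populations`` fixes the number of alleles
    sampled (AN) per population.  ``classification_mix`` and ``flagged_fraction``
    control how many decoy records (benign/VUS or quality-flagged) are added
    so that filter rules are exercised end to end.
    """

    populations: dict[Population, int]
    true_q: dict[str, dict[Population, float]]
    consequence_mix: dict[Consequence, float] = field(
        default_factory=lambda: {
            Consequence.MISSENSE: 40 / 86,
            Consequence.FRAMESHIFT: 20 / 86,
            Consequence.NONSENSE: 17 / 86,
            Consequence.SPLICE_ACCEPTOR: 5 / 86,
            Consequence.SPLICE_DONOR: 4 / 86,
        }
    )
    classification_mix: dict[Classification, float] = field(
        default_factory=lambda: {
            Classification.PATHOGENIC: 0.6,
            Classification.LIKELY_PATHOGENIC: 0.4,
        }
    )
    n_decoys: int = 0
    flagged_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, an in self.populations.items():
            if an < 2:
                raise ValueError(f"AN for {pop.value} must be >= 2, got {an}")
        for name, per_pop in self.true_q.items():
            for pop, q in per_pop.items():
                if not 0.0 <= q <= 1.0:
                    raise ValueError(
                        f"true q for {name}/{pop.value} must lie in [0, 1], got {q}"
                    )
        for mix, what in (
            (self.consequence_mix, "consequence_mix"),
            (self.classification_mix, "classification_mix"),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} proportions must sum to 1, got {total}")
        if not 0.0 <= self.flagged_fraction <= 1.0:
            raise ValueError("flagged_fraction must lie in [0, 1]")


def default_config(
    n_variants: int = 86,
    q_scale: float = 1.17e-5,
    an: int = 282_912,
    populations: tuple[Population, ...] = (Population.ALL,),
    n_decoys: int = 0,
    flagged_fraction: float = 0.0,
    seed: int = 0,
) -> SyntheticCohortConfig:
    """A cohort shaped like the TMPRSS6 study conditions.

    Defaults mirror the study: 86 pathogenic/likely pathogenic variants whose
    frequencies sum to ~1e-3 (the observed global pooled frequency) in a
    cohort of 282,912 alleles.  Individual q values follow the study's
    skewed spectrum: most sites are singletons-scale (a few 1e-6), a few
    carry most of the mass; here an exponential spread with mean ``q_scale``.
    """
    rng = np.random.default_rng(seed)
    q_draws = rng.exponential(q_scale, size=n_variants)
    true_q = {
        f"v{i + 1}": {pop: float(q_draws[i]) for pop in populations}
        for i in range(n_variants)
    }
    return SyntheticCohortConfig(
        populations={pop: an for pop in populations},
        true_q=true_q,
        n_decoys=n_decoys,
        flagged_fraction=flagged_fraction,
        seed=seed,
    )


_DECOY_CLASSES = (
    Classification.BENIGN,
    Classification.LIKELY_BENIGN,
    Classification.UNCERTAIN,
)


def generate_cohort(config: SyntheticCohortConfig) -> list[VariantRecord]:
    """Draw a gnomAD-like variant table with known truth.

    AC ~ Binomial(AN, true q) independently per variant and population;
    AF = AC/AN.  Deterministic for a fixed seed.  Decoy records (excluded
    classifications) and quality flags are appended per the config so the
    filter step is exercised; flagged records are drawn from the P/LP pool.
    """
    rng = np.random.default_rng(config.seed)
    consequences = list(config.consequence_mix)
    cons_p = np.array([config.consequence_mix[c] for c in consequences])
    classes = list(config.classification_mix)
    class_p = np.array([config.classification_mix[c] for c in classes])

    records: list[VariantRecord] = []
    pos = 37_000_000
    for name, per_pop_q in config.true_q.items():
        pos += rng.integers(1, 500)
        per_pop: dict[Population, PopulationCounts] = {}
        for pop, an in config.populations.items():
            q = per_pop_q.get(pop)
            if q is None:
                continue
            ac = int(rng.binomial(an, q))
            per_pop[pop] = PopulationCounts(ac=ac, an=an).resolved()
        cons = consequences[rng.choice(len(consequences), p=cons_p)]
        cls = classes[rng.choice(len(classes), p=class_p)]
        flags = (
            frozenset({"low_confidence_pLoF"})
            if rng.random() < config.flagged_fraction
            else frozenset()
        )
        counts_all = per_pop.get(Population.ALL)
        records.append(
            VariantRecord(
                chrom="22",
                pos=pos,
                ref="A",
                alt="G",
                hgvs_c=name,
                consequence=cons,
                classification=cls,
                flags=flags,
                per_population=per_pop,
                global_af=counts_all.frequency if counts_all else None,
            )
        )
    for i in range(config.n_decoys):
        pos += int(rng.integers(1, 500))
        per_pop = {}
        for pop, an in config.populations.items():
            ac = int(rng.binomial(an, 1e-5))
            per_pop[pop] = PopulationCounts(ac=ac, an=an).resolved()
        counts_all = per_pop.get(Population.ALL)
        records.append(
            VariantRecord(
                chrom="22",
                pos=pos,
                ref="C",
                alt="T",
                hgvs_c=f"decoy{i + 1}",
                consequence=Consequence.MISSENSE,
                classification=_DECOY_CLASSES[int(rng.choice(len(_DECOY_CLASSES)))],
                per_population=per_pop,
                global_af=counts_all.frequency if counts_all else None,
            )
        )
    return records


def simulate_genotype_prevalence(
    q_list, n_individuals: int, seed: int = 0, chunk: int = 1_000_000
) -> float:
    """Observed affected fraction under the two-haplotype genotype model.

    Each individual receives two independent haplotypes; a haplotype is
    pathogenic with probability 1 - prod(1 - q_i); an individual is affected
    iff both haplotypes are pathogenic.  Serves as the independent
    Monte-Carlo oracle for the closed-form prevalence.
    """
    q = np.asarray(list(q_list), dtype=float)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if np.any((q < 0) | (q > 1)) or q.sum() > 1.0:
        raise ValueError("q values must lie in [0, 1] with sum <= 1")
    if q.size == 0:
        return 0.0
    p_hap = float(-np.expm1(np.sum(np.log1p(-q))))
    rng = np.random.default_rng(seed)
    affected = 0
    remaining = n_individuals
    while remaining > 0:
        m = min(chunk, remaining)
        h1 = rng.random(m) < p_hap
        h2 = rng.random(m) < p_hap
        affected += int(np.count_nonzero(h1 & h2))
        remaining -= m
    return affected / n_individuals


def ci_coverage_study(
    true_q: float, an: int, reps: int = 2000, level: float = 0.95, seed: int = 0
) -> float:
    """Fraction of Wilson intervals covering the true allele frequency.

    Replicates AC ~ Binomial(an, true_q) and checks true_q against each
    Wilson interval.  Deterministic for a fixed seed.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful coverage estimate")
    rng = np.random.default_rng(seed)
    acs = rng.binomial(an, true_q, size=reps)
    covered = 0
    for ac in np.unique(acs):
        low, high = wilson_interval(int(ac), an, level)
        if low <= true_q <= high:
            covered += int(np.count_nonzero(acs == ac))
    return covered / reps


def synthetic_ptv_complement(seed: int = 0) -> list[VariantRecord]:
    """Synthetic stand-in for the 46 protein-truncating P/LP variants.

    The study's PTV list lives in an external repository; only its category
    counts (20 frameshift, 17 nonsense, 9 splice acceptor/donor) are printed.
    This builds 46 placeholder records with those exact counts and
    deterministic coordinates, for counting and filtering exercises - the
    allele frequencies are nominal, not the study's.
    """
    rng = np.random.default_rng(seed)
    cons = (
        [Consequence.FRAMESHIFT] * 20
        + [Consequence.NONSENSE] * 17
        + [Consequence.SPLICE_ACCEPTOR] * 5
        + [Consequence.SPLICE_DONOR] * 4
    )
    records = []
    pos = 37_461_000
    for i, c in enumerate(cons):
        pos += int(rng.integers(5, 300))
        records.append(
            VariantRecord(
                chrom="22",
                pos=pos,
                ref="G",
                alt="A",
                hgvs_c=f"synthetic_ptv_{i + 1}",
                consequence=c,
                classification=Classification.LIKELY_PATHOGENIC,
                global_af=float(rng.integers(1, 10)) * 1e-6,
            )
        )
    return records
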