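"""Published IRIDA estimates used as study inputs and cross-check anchors.

These are the headline numbers of the gnomAD v2.1.1 TMPRSS6 study this
package reimplements: the global prevalence/carrier pair and the
per-population table, in the study's reporting units (prevalence per
million births, carrier frequency per thousand individuals).  They serve as
inputs for desk-scale reconstruction - e.g. recovering the pooled allele
frequency as the square root of the global prevalence - never as outputs.
"""

from __future__ import annotations

from .variants import Population

#: Global genetic prevalence, per million births.
GLOBAL_PREVALENCE_PER_MILLION = 1.0228

#: Global carrier frequency, per thousand individuals.
GLOBAL_CARRIER_PER_THOUSAND = 2.02

#: Individuals in the reference cohort (gnomAD v2.1.1 exomes + genomes).
COHORT_INDIVIDUALS = 141_456

#: Published per-population table, in printed row order:
#: (prevalence per million, its 95% CI, carrier per thousand, its 95% CI).
POPULATION_TABLE: dict[Population, dict[str, object]] = {
    Population.NFE: {
        "prevalence_per_million": 1.54,
        "prevalence_ci": (0.87, 2.5),
        "carrier_per_thousand": 2.48,
        "carrier_ci": (2.11, 2.92),
    },
    Population.AMR: {
        "prevalence_per_million": 0.14,
        "prevalence_ci": (0.05, 0.41),
        "carrier_per_thousand": 0.75,
        "carrier_ci": (0.44, 1.29),
    },
    Population.AFR: {
        "prevalence_per_million": 3.55,
        "prevalence_ci": (1.76, 7.18),
        "carrier_per_thousand": 3.77,
        "carrier_ci": (2.65, 5.36),
    },
    Population.SAS: {
        "prevalence_per_million": 0.75,
        "prevalence_ci": (0.35, 1.6),
        "carrier_per_thousand": 1.73,
        "carrier_ci": (1.19, 2.53),
    },
    Population.EAS: {
        "prevalence_per_million": 1.51,
        "prevalence_ci": (0.67, 3.42),
        "carrier_per_thousand": 2.46,
        "carrier_ci": (0.69, 2.18),
    },
    Population.ALL: {
        "prevalence_per_million": 1.02,
        "prevalence_ci": (0.82, 1.28),
        "carrier_per_thousand": 2.02,
        "carrier_ci": (1.8, 2.28),
    },
}

#: Counts of curated pathogenic/likely pathogenic variants by class.
VARIANT_COUNTS = {
    "total": 86,
    "missense": 40,
    "ptv": 46,
    "frameshift": 20,
    "nonsense": 17,
    "splice": 9,
}


def global_q_sum() -> float:
    """Pooled pathogenic allele frequency implied by the global prevalence.

    Under the rare-allele approximation prevalence = (sum q)^2, so the
    printed per-million figure converts back to sum q by a square root.
    """
    return (GLOBAL_PREVALENCE_PER_MILLION * 1e-6) ** 0.5
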