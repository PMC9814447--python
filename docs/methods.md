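# Methods

## Estimand and model

For a monogenic autosomal-recessive disorder, two quantities are estimated
from a reference cohort: the *carrier frequency* (proportion of individuals
heterozygous for any pathogenic allele) and the *genetic prevalence*
(expected proportion of births with two pathogenic alleles). With
per-variant pathogenic allele frequencies qᵢ, treating sites as independent
biallelic loci under Hardy–Weinberg random mating, a haplotype is pathogenic
with probability p = 1 − ∏ᵢ(1 − qᵢ), giving prevalence p² and carrier
frequency 2p(1 − p) evaluated at p ≈ Σqᵢ. The package exposes both the
exact forms and the rare-allele approximations (Σqᵢ)² and 2Σqᵢ; the
*approximate* forms are the reporting default because the published
per-population tables satisfy the identity prevalence = (carrier/2)² exactly
at display precision, confirming they were produced that way. For
Σq ≤ 10⁻² the two differ by under 2% (first-order Taylor bound, verified by
property tests on randomised q grids).

Assumptions inherited from the model, and not relaxed here: random mating
(no consanguinity or assortative mating), no linkage between pathogenic
sites, complete penetrance of biallelic genotypes, autosomal inheritance,
and unbiased allele-frequency estimates ACᵢ/ANᵢ in the cohort. Variant
classification (ACMG/AMP five-tier labels) is an *input* produced by human
curation; no evidence-code engine is implemented.

## Inputs and filtering

The canonical interchange format is a TSV with fixed columns (`chrom`,
`pos`, `ref`, `alt`, `hgvs_c`, `hgvs_p`, `consequence`, `classification`,
`flags`, `counted_as`, `af_global`, plus `ac_<pop>`/`an_<pop>`/`af_<pop>`
triples); a VCF reader accepts the gnomAD v2 INFO dialect
(`AC`, `AN`, `AC_<pop>`, `AN_<pop>`), decomposing multi-allelic sites one
record per ALT and recording non-PASS FILTER values. Genomic coordinates
are 1-based GRCh37.

Estimation uses exactly the records classified pathogenic or likely
pathogenic and carrying none of the gnomAD quality flags
`low_confidence_pLoF`, `LCR`, `not_LoF` (this drops, for example, a
likely-pathogenic synonymous variant flagged low-confidence pLoF). Records
with no data in a population contribute q = 0 there and are tallied in a
per-population missing count rather than silently ignored.

The packaged table reproduces the 40 P/LP missense variants observed in
gnomAD v2.1.1 with global MAFs. Two design points: the two start-codon
substitutions (Met1Lys, Met1Ile) are typed `start_lost` but carry a
`counted_as=missense` override so category counts match the published
40-missense total without misstating the ontology; and their rows, printed
without a chromosome prefix in the source table, are normalised to
chromosome 22 (all *TMPRSS6* variants lie there). Protein positions use
the 802-aa MANE canonical matriptase-2 isoform; `map_isoform_position`
shifts by the 9-residue leader (MLLLFHSKRM) to the 811-aa literature
numbering, with residues 1–9 of the long isoform having no canonical image.

The 46 protein-truncating P/LP variants are published only as category
counts (20 frameshift, 17 nonsense, 9 splice acceptor/donor; the full list
sits in an external data repository). `synthetic_ptv_complement()` builds a
synthetic stand-in with those exact counts and nominal frequencies for
counting and filtering exercises; it is never used to estimate frequencies.

## Confidence intervals

The pooled pathogenic count is modelled as a single binomial: Σ ACᵢ
successes out of an *effective* allele number AN. The 95% interval is the
Wilson score interval (statsmodels implementation; z = 1.959964, the exact
two-sided normal quantile), which respects [0, 1] and always contains the
observed proportion; tests check it against an independent root-finder on
the score equation to 10⁻¹⁰, and a Monte-Carlo study at the study's scale
(q = 10⁻³, AN = 282,912, 2,000 replicates) confirms ~95% coverage.
Endpoints are mapped to the carrier scale by doubling and to the prevalence
scale by squaring — both monotone increasing for q ≤ ½, so the mapped
intervals keep the nominal level and are mutually consistent (a single
allele-scale interval underlies both, matching the published tables).

Choices the source leaves open, resolved as follows:

- **Effective allele number.** Per-variant ANᵢ differ across sites; the
  pooled binomial needs one AN. Strategies: `mean` (default when counts are
  available), `median`, `min`, or `fixed:N`. `fixed:282912`
  (2 × 141,456 individuals) reproduces the published global interval's
  lower bound to 2 significant figures; the published upper bound
  (2.28 per thousand) reconstructs as ≈2.27 from these inputs, so only the
  lower bound is treated as reproducible.
- **AC from frequency-only sources.** When a table prints frequencies but
  not counts, ac_total = round(q_sum × AN).
- **Sample-size gate.** Populations with effective AN below 10,000 alleles
  (configurable) are reported `not_analysed` with no numbers — the study
  excluded the Ashkenazi Jewish and Finnish strata on sample-size grounds
  without stating a threshold; 10,000 alleles caps the binomial SE of a
  10⁻³ frequency at ~√(10⁻³/10⁴) ≈ 3×10⁻⁴, a third of the estimate.
- **Display rounding.** Half-even to 2 decimals on the reporting scales
  (prevalence per million, carrier per thousand); full precision is kept
  internally and in JSON output.

## Synthetic cohorts

`generate_cohort` emulates the sampling structure of a gnomAD-style
dataset: for each variant and population, AC ~ Binomial(AN, true q)
independently, AF = AC/AN, all draws from one seeded generator
(bit-reproducible). Decoy records (benign/VUS classifications) and quality
flags are injected on request so the filter is exercised end to end.
Default study conditions mirror the worked case: 86 P/LP variants whose
true frequencies follow an exponential spectrum with mean 1.17×10⁻⁵ —
summing to ~10⁻³, the observed global pooled frequency, with most mass on a
few sites as in the real table — sampled at AN = 282,912.

What the generator does *not* emulate: linkage and haplotype structure,
relatedness, sequencing or annotation error, coverage-dependent per-site AN,
and ascertainment differences between exomes and genomes. Passing
recovery tests therefore show the estimator is correct *under the binomial
sampling model*, not that real-cohort biases are absent.

Two independent oracles validate the formulas rather than the sampler:
`simulate_genotype_prevalence` realises the probability model directly (two
independent haplotypes per individual, affected iff both pathogenic) and
converges on the exact closed form — distinguishably closer to exact than
to the approximation when q is large; `ci_coverage_study` measures Wilson
coverage by replicate binomial cohorts.

## Numerical notes

- 1 − ∏(1 − qᵢ) is computed as −expm1(Σ log1p(−qᵢ)), stable for q down to
  the smallest normal doubles where the naive product cancels to zero.
- Wilson bounds are clamped to exactly 0 (AC = 0) and 1 (AC = AN), where
  the closed form leaves ~10⁻²² cancellation residue.
- Degenerate populations (no observed variants, or AN under the gate)
  produce a `not_analysed` row, never a numeric estimate.

## Problem sizes

Validation runs use 2,000 replicate cohorts for the coverage study and 10⁶
individuals for the genotype-level simulation — sizes at which Monte-Carlo
error (binomial SE) is far below the tolerances being checked, while the
whole suite completes in seconds.

## Known limitations

Prevalence from reference-cohort allele frequencies is a *genetic*
prevalence: it counts genotypes, not diagnoses, and inherits the cohort's
ascertainment (gnomAD under-represents several ancestries, and the "other"
stratum is a residual category). Curation completeness bounds the estimate
from below — missed pathogenic variants deflate Σq. The single-binomial
treatment of the pooled count ignores between-variant sampling correlation
(negligible for rare, unlinked sites). No liftover, external HGVS
validation, or annotation retrieval is performed.
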