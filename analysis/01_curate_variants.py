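#!/usr/bin/env python
"""Assemble the curated TMPRSS6 P/LP variant table and count its classes.

Loads the packaged table of 40 missense variants observed in gnomAD v2.1.1
(global MAFs), appends the synthetic stand-in for the 46 protein-truncating
variants (their per-variant list lives in an external repository; only the
category counts 20 frameshift / 17 nonsense / 9 splice are published), and
writes the combined table plus its consequence breakdown.
"""

from pathlib import Path

import pandas as pd

from iridaprev import (
    categorize_consequences,
    filter_for_estimation,
    packaged_missense_table,
    synthetic_ptv_complement,
    write_variant_table,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

missense = packaged_missense_table()
curated = missense + synthetic_ptv_complement(seed=11)
write_variant_table(curated, RESULTS / "curated_variants.tsv")

counts = categorize_consequences(curated)
kept = filter_for_estimation(curated)
pd.Series(counts).to_csv(RESULTS / "variant_categories.csv", header=["count"])

print(f"curated table: {counts['total']} P/LP variants "
      f"({counts['missense']} missense, {counts['ptv']} protein-truncating; "
      f"frameshift {counts['frameshift']}, nonsense {counts['nonsense']}, "
      f"splice {counts['splice_acceptor'] + counts['splice_donor']})")
print(f"missense share: {100 * counts['missense'] / counts['total']:.1f}%")
print(f"{len(kept)} of {len(curated)} records pass the P/LP + flag filter")
print(f"tables written to {RESULTS}")
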