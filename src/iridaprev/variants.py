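"""Curated-variant data model, readers/writers and filtering rules.

A :class:`VariantRecord` is one curated disease-causing variant with
population-stratified allele counts in the gnomAD v2 dialect.  Records are
validated on construction; the estimation pipeline only ever sees records
that passed :func:`filter_for_estimation` (pathogenic / likely-pathogenic,
no quality flags).

Coordinates are 1-based GRCh37 (VCF convention).  Protein positions use the
802-aa MANE canonical isoform of matriptase-2; :func:`map_isoform_position`
converts to and from the 811-aa isoform numbering used in older literature.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Population",
    "Consequence",
    "Classification",
    "GNOMAD_FLAGS",
    "PopulationCounts",
    "VariantRecord",
    "VariantFormatError",
    "VariantValidationError",
    "read_variant_table",
    "write_variant_table",
    "packaged_missense_table",
    "filter_for_estimation",
    "categorize_consequences",
    "map_isoform_position",
    "ISOFORM_OFFSET",
]


class Population(str, Enum):
    """gnomAD v2 continental populations plus the pooled global cohort."""

    AFR = "afr"
    AMR = "amr"
    ASJ = "asj"
    EAS = "eas"
    FIN = "fin"
    NFE = "nfe"
    SAS = "sas"
    OTH = "oth"
    ALL = "all"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Consequence(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    START_LOST = "start_lost"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Consequence classes counted as protein-truncating.
PTV_CONSEQUENCES = frozenset(
    {
        Consequence.FRAMESHIFT,
        Consequence.NONSENSE,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
    }
)


class Classification(str, Enum):
    """ACMG/AMP five-tier classification (labels are curated inputs)."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: gnomAD quality flags that exclude a variant from estimation.
GNOMAD_FLAGS = frozenset({"low_confidence_pLoF", "LCR", "not_LoF"})

#: Classes retained for carrier-frequency / prevalence estimation.
INCLUDED_CLASSES = frozenset(
    {Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC}
)


class VariantFormatError(ValueError):
    """A table or VCF does not conform to the expected dialect."""


class VariantValidationError(ValueError):
    """A record violates an internal invariant (e.g. AC > AN)."""


@dataclass(frozen=True)
class PopulationCounts:
    """Allele count (AC), allele number (AN) and frequency for one population.

    ``af`` is AC/AN whenever both counts are known; a frequency-only source
    (a published table) may supply ``af`` with ``ac``/``an`` absent.
    """

    ac: int | None = None
    an: int | None = None
    af: float | None = None

    def __post_init__(self) -> None:
        if self.an is not None and self.an <= 0:
            raise VariantValidationError(f"AN must be positive, got {self.an}")
        if self.ac is not None:
            if self.ac < 0:
                raise VariantValidationError(f"AC must be non-negative, got {self.ac}")
            if self.an is not None and self.ac > self.an:
                raise VariantValidationError(
                    f"AC ({self.ac}) exceeds AN ({self.an})"
                )
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise VariantValidationError(f"AF must lie in [0, 1], got {self.af}")

    @property
    def frequency(self) -> float | None:
        """AF, computed from counts when not stored explicitly."""
        if self.ac is not None and self.an is not None:
            return self.ac / self.an
        return self.af

    def resolved(self) -> "PopulationCounts":
        """Return a copy with ``af`` filled in from AC/AN when derivable."""
        if self.af is None and self.ac is not None and self.an is not None:
            return replace(self, af=self.ac / self.an)
        return self


@dataclass(frozen=True)
class VariantRecord:
    """One curated variant with per-population allele counts.

    ``counted_as`` optionally overrides the consequence used for category
    counting (the start-codon substitutions are typed ``start_lost`` but are
    tallied with the missense class in the published table).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.MISSENSE
    classification: Classification = Classification.UNCERTAIN
    flags: frozenset[str] = frozenset()
    per_population: Mapping[Population, PopulationCounts] = field(
        default_factory=dict
    )
    global_af: float | None = None
    counted_as: Consequence | None = None
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        # accept plain strings for the enum-valued fields
        for attr, enum_cls in (
            ("consequence", Consequence),
            ("classification", Classification),
            ("counted_as", Consequence),
        ):
            val = getattr(self, attr)
            if val is not None and not isinstance(val, enum_cls):
                try:
                    object.__setattr__(self, attr, enum_cls(val))
                except ValueError:
                    allowed = ", ".join(m.value for m in enum_cls)
                    raise VariantValidationError(
                        f"unknown {attr} {val!r}; allowed values: {allowed}"
                    ) from None
        if not isinstance(self.flags, frozenset):
            object.__setattr__(self, "flags", frozenset(self.flags))
        if self.pos < 1:
            raise VariantValidationError(f"pos must be >= 1, got {self.pos}")
        unknown = set(self.flags) - GNOMAD_FLAGS
        if unknown:
            raise VariantValidationError(
                f"unknown flags {sorted(unknown)}; allowed: {sorted(GNOMAD_FLAGS)}"
            )
        if self.global_af is not None and not 0.0 <= self.global_af <= 1.0:
            raise VariantValidationError(
                f"global_af must lie in [0, 1], got {self.global_af}"
            )
        for pop, counts in self.per_population.items():
            f = counts.frequency
            if (
                counts.af is not None
                and counts.ac is not None
                and counts.an is not None
                and abs(counts.af - counts.ac / counts.an) > 1e-12
            ):
                raise VariantValidationError(
                    f"{self.label}: AF inconsistent with AC/AN for {pop.value}"
                )
            del f

    @property
    def label(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def category(self) -> Consequence:
        """Consequence class used for counting (override-aware)."""
        return self.counted_as if self.counted_as is not None else self.consequence

    def frequency_in(self, population: Population) -> float | None:
        """Pathogenic allele frequency in ``population`` (None if no data)."""
        counts = self.per_population.get(population)
        if counts is not None and counts.frequency is not None:
            return counts.frequency
        if population is Population.ALL:
            return self.global_af
        return None


_REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "consequence", "classification")
_SCALAR_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "classification",
    "flags",
    "counted_as",
    "af_global",
)


def _parse_enum(enum_cls, raw: str, what: str):
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise VariantValidationError(
            f"unknown {what} {raw!r}; allowed values: {allowed}"
        ) from None


def _row_to_record(row: Mapping[str, str]) -> VariantRecord:
    per_pop: dict[Population, PopulationCounts] = {}
    for pop in Population:
        ac_key, an_key, af_key = f"ac_{pop.value}", f"an_{pop.value}", f"af_{pop.value}"
        ac = row.get(ac_key, "").strip()
        an = row.get(an_key, "").strip()
        af = row.get(af_key, "").strip()
        if not (ac or an or af):
            continue
        per_pop[pop] = PopulationCounts(
            ac=int(ac) if ac else None,
            an=int(an) if an else None,
            af=float(af) if af else None,
        ).resolved()

    flags_raw = row.get("flags", "").strip()
    flags = frozenset(f.strip() for f in flags_raw.split(";") if f.strip())
    counted_raw = row.get("counted_as", "").strip()
    af_global_raw = row.get("af_global", "").strip()

    return VariantRecord(
        chrom=row["chrom"].strip(),
        pos=int(row["pos"]),
        ref=row["ref"].strip(),
        alt=row["alt"].strip(),
        hgvs_c=row.get("hgvs_c", "").strip(),
        hgvs_p=row.get("hgvs_p", "").strip(),
        consequence=_parse_enum(Consequence, row["consequence"].strip(), "consequence"),
        classification=_parse_enum(
            Classification, row["classification"].strip(), "classification"
        ),
        flags=flags,
        per_population=per_pop,
        global_af=float(af_global_raw) if af_global_raw else None,
        counted_as=(
            _parse_enum(Consequence, counted_raw, "consequence") if counted_raw else None
        ),
        filter_status=row.get("filter", "PASS").strip() or "PASS",
    )


def _read_tsv(text: str) -> list[VariantRecord]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise VariantFormatError("empty table: no header line found")
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise VariantFormatError(f"missing required column(s): {', '.join(missing)}")
    return [_row_to_record(row) for row in reader]


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    # gnomAD v2 INFO dialect: AC/AN plus AC_<pop>/AN_<pop>; multi-allelic
    # sites decompose into one record per ALT with per-allele AC.
    from cyvcf2 import VCF

    def _per_alt(value, idx: int, n_alt: int):
        if value is None:
            return None
        if isinstance(value, (tuple, list)):
            return value[idx] if idx < len(value) else None
        return value if n_alt == 1 or idx == 0 else None

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for site in vcf:
            n_alt = len(site.ALT)
            an_all = site.INFO.get("AN")
            for i, alt in enumerate(site.ALT):
                per_pop: dict[Population, PopulationCounts] = {}
                ac_all = _per_alt(site.INFO.get("AC"), i, n_alt)
                if ac_all is not None and an_all is not None:
                    per_pop[Population.ALL] = PopulationCounts(
                        ac=int(ac_all), an=int(an_all)
                    ).resolved()
                for pop in Population:
                    if pop is Population.ALL:
                        continue
                    ac = _per_alt(site.INFO.get(f"AC_{pop.value}"), i, n_alt)
                    an = site.INFO.get(f"AN_{pop.value}")
                    if ac is None or an is None or int(an) == 0:
                        continue
                    per_pop[pop] = PopulationCounts(ac=int(ac), an=int(an)).resolved()
                counts_all = per_pop.get(Population.ALL)
                filter_status = site.FILTER or "PASS"
                records.append(
                    VariantRecord(
                        chrom=site.CHROM,
                        pos=site.POS,
                        ref=site.REF,
                        alt=alt,
                        consequence=_parse_enum(
                            Consequence,
                            str(site.INFO.get("consequence", "missense")),
                            "consequence",
                        ),
                        classification=_parse_enum(
                            Classification,
                            str(site.INFO.get("classification", "uncertain")),
                            "classification",
                        ),
                        per_population=per_pop,
                        global_af=(
                            counts_all.frequency if counts_all is not None else None
                        ),
                        filter_status=filter_status,
                    )
                )
    finally:
        vcf.close()
    return records


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read a curated variant table.

    Parameters
    ----------
    path
        TSV file (UTF-8, tab-delimited, ``#`` comments allowed) or a VCF with
        gnomAD-style ``AC``/``AN``/``AC_<pop>``/``AN_<pop>`` INFO keys.
    dialect
        ``"tsv"`` or ``"vcf"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path.read_text(encoding="utf-8"))
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as a TSV in the canonical column dialect.

    Round-trips through :func:`read_variant_table` field-for-field.
    """
    records = list(records)
    pop_cols: list[str] = []
    for pop in Population:
        if any(pop in r.per_population for r in records):
            pop_cols += [f"ac_{pop.value}", f"an_{pop.value}", f"af_{pop.value}"]
    header = list(_SCALAR_COLUMNS) + ["filter"] + pop_cols
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in records:
            row = {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "hgvs_c": r.hgvs_c,
                "hgvs_p": r.hgvs_p,
                "consequence": r.consequence.value,
                "classification": r.classification.value,
                "flags": ";".join(sorted(r.flags)),
                "counted_as": r.counted_as.value if r.counted_as else "",
                "af_global": "" if r.global_af is None else repr(r.global_af),
                "filter": r.filter_status,
            }
            for pop, counts in r.per_population.items():
                row[f"ac_{pop.value}"] = "" if counts.ac is None else counts.ac
                row[f"an_{pop.value}"] = "" if counts.an is None else counts.an
                row[f"af_{pop.value}"] = "" if counts.af is None else repr(counts.af)
            writer.writerow([row.get(c, "") for c in header])


def packaged_missense_table() -> list[VariantRecord]:
    """The packaged table of the 40 P/LP TMPRSS6 missense variants in gnomAD."""
    ref = resources.files("iridaprev.data") / "tmprss6_plp_missense_gnomad.tsv"
    return _read_tsv(ref.read_text(encoding="utf-8"))


def filter_for_estimation(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep pathogenic / likely-pathogenic records with no gnomAD quality flag.

    Benign, likely-benign and uncertain-significance classes are dropped, as
    is anything flagged low-confidence pLoF, LCR or not-LoF.  Order is
    preserved and the input is not modified; the operation is idempotent.
    """
    return [
        r
        for r in records
        if r.classification in INCLUDED_CLASSES and not (r.flags & GNOMAD_FLAGS)
    ]


def categorize_consequences(records: Iterable[VariantRecord]) -> dict[str, int]:
    """Count records per consequence class, plus the aggregate PTV count.

    Uses the override-aware :attr:`VariantRecord.category`, so start-codon
    substitutions tallied with missense in the source table count as such.
    """
    counts = {c.value: 0 for c in Consequence}
    total = 0
    for r in records:
        counts[r.category.value] += 1
        total += 1
    counts["ptv"] = sum(counts[c.value] for c in PTV_CONSEQUENCES)
    counts["total"] = total
    return counts


#: Residue offset between the 811-aa literature isoform (alternate upstream
#: start codon, MLLLFHSKRM) and the 802-aa MANE canonical isoform.
ISOFORM_OFFSET = 811 - 802


def map_isoform_position(position: int, direction: str) -> int:
    """Convert a protein residue index between matriptase-2 isoform numberings.

    ``canonical_to_long`` maps 802-aa canonical numbering to the 811-aa
    isoform (adds 9); ``long_to_canonical`` subtracts 9.  Residues 1-9 of the
    long isoform precede the canonical start and have no canonical image.
    """
    if position < 1:
        raise ValueError(f"residue index must be >= 1, got {position}")
    if direction == "canonical_to_long":
        return position + ISOFORM_OFFSET
    if direction == "long_to_canonical":
        if position <= ISOFORM_OFFSET:
            raise ValueError(
                f"residue {position} of the long isoform has no canonical equivalent"
            )
        return position - ISOFORM_OFFSET
    raise ValueError(
        f"unknown direction {direction!r}; expected 'canonical_to_long' or "
        "'long_to_canonical'"
    )
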