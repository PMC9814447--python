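"""Variant data model, table IO, filtering and isoform coordinate mapping."""

import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from iridaprev import (
    Classification,
    Consequence,
    Population,
    PopulationCounts,
    VariantFormatError,
    VariantRecord,
    VariantValidationError,
    categorize_consequences,
    filter_for_estimation,
    map_isoform_position,
    read_variant_table,
    write_variant_table,
)

HEADER = "chrom\tpos\tref\talt\tconsequence\tclassification"


def _write(tmp_path, text, name="table.tsv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text), encoding="utf-8")
    return p


class TestTsvReading:
    def test_packaged_table_has_forty_missense(self, missense_records):
        assert len(missense_records) == 40
        counts = categorize_consequences(missense_records)
        assert counts["missense"] == 40
        # typed honestly: two start-codon substitutions counted with missense
        typed_start = sum(
            r.consequence is Consequence.START_LOST for r in missense_records
        )
        assert typed_start == 2

    def test_packaged_af_times_an_recovers_integer_counts(self, missense_records):
        # every printed MAF should correspond to a whole allele count in the
        # 282,912-allele cohort
        for rec in missense_records:
            implied = rec.global_af * 282_912
            assert abs(implied - round(implied)) < 0.5

    def test_empty_data_section_yields_empty_list(self, tmp_path):
        path = _write(tmp_path, HEADER + "\n")
        assert read_variant_table(path) == []

    def test_af_computed_from_counts_when_absent(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER + "\tac_all\tan_all\n"
            "22\t100\tA\tG\tmissense\tpathogenic\t5\t1000\n"
            "22\t200\tC\tT\tnonsense\tlikely_pathogenic\t5\t1000\n",
        )
        records = read_variant_table(path)
        assert len(records) == 2
        for rec in records:
            assert rec.per_population[Population.ALL].frequency == pytest.approx(0.005)

    def test_missing_required_column_names_the_column(self, tmp_path):
        path = _write(
            tmp_path,
            "chrom\tpos\tref\talt\tconsequence\n22\t1\tA\tG\tmissense\n",
        )
        with pytest.raises(VariantFormatError, match="classification"):
            read_variant_table(path)

    def test_ac_above_an_is_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER + "\tac_all\tan_all\n22\t100\tA\tG\tmissense\tpathogenic\t20\t10\n",
        )
        with pytest.raises(VariantValidationError, match="AC"):
            read_variant_table(path)

    @pytest.mark.parametrize(
        "column,value",
        [("consequence", "weird_effect"), ("classification", "pathogenicish")],
    )
    def test_unknown_enum_value_lists_allowed(self, tmp_path, column, value):
        row = {"consequence": "missense", "classification": "pathogenic"}
        row[column] = value
        path = _write(
            tmp_path,
            HEADER + f"\n22\t100\tA\tG\t{row['consequence']}\t{row['classification']}\n",
        )
        with pytest.raises(VariantValidationError, match="allowed"):
            read_variant_table(path)

    def test_comment_lines_are_skipped(self, tmp_path):
        path = _write(
            tmp_path,
            "# a comment\n" + HEADER + "\n# another\n22\t5\tA\tG\tmissense\tbenign\n",
        )
        assert len(read_variant_table(path)) == 1


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, curated_records):
        out = tmp_path / "roundtrip.tsv"
        write_variant_table(curated_records, out)
        back = read_variant_table(out)
        assert back == curated_records


def _vcf_text():
    return textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
        ##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
        ##INFO=<ID=AC_afr,Number=A,Type=Integer,Description="AC afr">
        ##INFO=<ID=AN_afr,Number=1,Type=Integer,Description="AN afr">
        ##INFO=<ID=AC_nfe,Number=A,Type=Integer,Description="AC nfe">
        ##INFO=<ID=AN_nfe,Number=1,Type=Integer,Description="AN nfe">
        ##contig=<ID=22>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        22\t37461000\t.\tG\tA\t.\tPASS\tAC=5;AN=1000;AC_afr=2;AN_afr=200;AC_nfe=3;AN_nfe=800
        22\t37462000\t.\tC\tT,G\t.\tPASS\tAC=4,6;AN=1000;AC_afr=1,2;AN_afr=200
        22\t37463000\t.\tA\tC\t.\tRF\tAC=1;AN=1000
        """
    )


class TestVcfReading:
    def test_multiallelic_sites_decompose_per_alt(self, tmp_path):
        path = _write(tmp_path, _vcf_text(), "slice.vcf")
        records = read_variant_table(path, dialect="vcf")
        assert len(records) == 4
        by_alt = {(r.pos, r.alt): r for r in records}
        assert by_alt[(37462000, "T")].per_population[Population.ALL].ac == 4
        assert by_alt[(37462000, "G")].per_population[Population.ALL].ac == 6
        assert by_alt[(37462000, "T")].per_population[Population.AFR].ac == 1
        assert by_alt[(37461000, "A")].global_af == pytest.approx(0.005)

    def test_non_pass_filter_recorded(self, tmp_path):
        path = _write(tmp_path, _vcf_text(), "slice.vcf")
        records = read_variant_table(path, dialect="vcf")
        status = {r.pos: r.filter_status for r in records}
        assert status[37463000] == "RF"
        assert status[37461000] == "PASS"


def _rec(classification=Classification.PATHOGENIC, flags=(), consequence=Consequence.MISSENSE):
    return VariantRecord(
        chrom="22",
        pos=1000,
        ref="A",
        alt="G",
        consequence=consequence,
        classification=classification,
        flags=frozenset(flags),
        global_af=1e-5,
    )


class TestFiltering:
    @pytest.mark.parametrize(
        "classification,kept",
        [
            (Classification.PATHOGENIC, True),
            (Classification.LIKELY_PATHOGENIC, True),
            (Classification.UNCERTAIN, False),
            (Classification.LIKELY_BENIGN, False),
            (Classification.BENIGN, False),
        ],
    )
    def test_classification_gate(self, classification, kept):
        out = filter_for_estimation([_rec(classification)])
        assert bool(out) is kept

    @pytest.mark.parametrize("flag", ["low_confidence_pLoF", "LCR", "not_LoF"])
    def test_quality_flag_excludes_even_pathogenic(self, flag):
        # e.g. the likely-pathogenic synonymous variant dropped for
        # low-confidence pLoF despite its classification
        assert filter_for_estimation([_rec(flags={flag})]) == []

    def test_empty_input(self):
        assert filter_for_estimation([]) == []

    def test_order_preserved_and_input_unmodified(self):
        records = [_rec(), _rec(Classification.BENIGN), _rec(Classification.LIKELY_PATHOGENIC)]
        snapshot = list(records)
        out = filter_for_estimation(records)
        assert out == [records[0], records[2]]
        assert records == snapshot

    @given(
        st.lists(
            st.builds(
                _rec,
                classification=st.sampled_from(list(Classification)),
                flags=st.sets(st.sampled_from(["low_confidence_pLoF", "LCR", "not_LoF"])),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_subset(self, records):
        once = filter_for_estimation(records)
        assert filter_for_estimation(once) == once
        assert all(r in records for r in once)


class TestCategorization:
    def test_curated_table_counts(self, curated_records):
        counts = categorize_consequences(curated_records)
        assert counts["missense"] == 40
        assert counts["ptv"] == 46
        assert counts["total"] == 86

    def test_ptv_breakdown(self):
        records = (
            [_rec(consequence=Consequence.FRAMESHIFT)] * 20
            + [_rec(consequence=Consequence.NONSENSE)] * 17
            + [_rec(consequence=Consequence.SPLICE_ACCEPTOR)] * 5
            + [_rec(consequence=Consequence.SPLICE_DONOR)] * 4
        )
        counts = categorize_consequences(records)
        assert counts["frameshift"] == 20
        assert counts["nonsense"] == 17
        assert counts["splice_acceptor"] + counts["splice_donor"] == 9
        assert counts["ptv"] == 46

    def test_empty_input_all_zero(self):
        counts = categorize_consequences([])
        assert counts["total"] == 0
        assert all(v == 0 for v in counts.values())

    def test_counts_sum_to_record_count(self, curated_records):
        counts = categorize_consequences(curated_records)
        per_class = sum(counts[c.value] for c in Consequence)
        assert per_class == counts["total"] == len(curated_records)


class TestIsoformMapping:
    @pytest.mark.parametrize(
        "pos,direction,expected",
        [
            (203, "canonical_to_long", 212),  # Ile203Thr == I212T in old numbering
            (1, "canonical_to_long", 10),
            (811, "long_to_canonical", 802),
        ],
    )
    def test_known_mappings(self, pos, direction, expected):
        assert map_isoform_position(pos, direction) == expected

    @pytest.mark.parametrize("pos", [1, 5, 9])
    def test_long_leader_residues_have_no_canonical_image(self, pos):
        with pytest.raises(ValueError, match="no canonical"):
            map_isoform_position(pos, "long_to_canonical")

    @given(st.integers(min_value=1, max_value=802))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, pos):
        there = map_isoform_position(pos, "canonical_to_long")
        assert map_isoform_position(there, "long_to_canonical") == pos


class TestValidation:
    def test_position_must_be_positive(self):
        with pytest.raises(VariantValidationError):
            VariantRecord(chrom="22", pos=0, ref="A", alt="G")

    def test_unknown_flag_rejected(self):
        with pytest.raises(VariantValidationError, match="unknown flags"):
            VariantRecord(chrom="22", pos=1, ref="A", alt="G", flags=frozenset({"odd"}))

    def test_counts_validate_bounds(self):
        with pytest.raises(VariantValidationError):
            PopulationCounts(ac=-1, an=10)
        with pytest.raises(VariantValidationError):
            PopulationCounts(ac=1, an=0)
        with pytest.raises(VariantValidationError):
            PopulationCounts(af=1.5)
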