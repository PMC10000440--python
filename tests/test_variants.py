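"""Variant ingestion, noncoding classification and annotation joining."""

import io

import pandas as pd
import pytest

from noncneo.errors import AnnotationFormatError, VcfFormatError
from noncneo.variants import (
    NONCODING_CATEGORIES,
    AnnotatedVariant,
    GenomicVariant,
    classify_noncoding,
    filter_noncoding,
    join_annotations,
    parse_somatic_vcf,
)

HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FILTER=<ID=PASS,Description="ok">\n'
    '##FILTER=<ID=germline,Description="x">\n'
    "##contig=<ID=chr1,length=1000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(tmp_path, body, name="test.vcf"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestParseSomaticVcf:
    def test_pass_snv_retained(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t100\t.\tC\tG\t.\tPASS\t.\n")
        (v,) = parse_somatic_vcf(p, sample_id="S1")
        assert (v.contig, v.pos, v.ref, v.alt) == ("chr1", 100, "C", "G")
        assert v.variant_class == "SNV"
        assert v.filter_status == "PASS"

    def test_non_pass_dropped_and_empty_body(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t100\t.\tC\tG\t.\tgermline\t.\n")
        assert parse_somatic_vcf(p, "S1") == []
        p2 = write_vcf(tmp_path, "", name="empty.vcf")
        assert parse_somatic_vcf(p2, "S1") == []

    def test_multiallelic_split_conserves_alleles(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\n")
        out = parse_somatic_vcf(p, "S1")
        assert [(v.ref, v.alt) for v in out] == [("A", "G"), ("A", "T")]
        assert all(v.variant_class == "SNV" for v in out)

    def test_indel_classes(self, tmp_path):
        body = "chr1\t100\t.\tC\tCTT\t.\tPASS\t.\nchr1\t200\t.\tCAA\tC\t.\tPASS\t.\n"
        ins, dele = parse_somatic_vcf(write_vcf(tmp_path, body), "S1")
        assert ins.variant_class == "insertion"
        assert dele.variant_class == "deletion"

    def test_missing_filter_column_is_format_error(self, tmp_path):
        p = tmp_path / "nofilter.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tINFO\n"
        )
        with pytest.raises(VcfFormatError):
            parse_somatic_vcf(p, "S1")

    def test_malformed_record_names_line(self, tmp_path):
        p = write_vcf(tmp_path, "chr1\tnotanumber\t.\tA\tG\t.\tPASS\t.\n")
        with pytest.raises(VcfFormatError, match="line"):
            parse_somatic_vcf(p, "S1")


class TestVariantInvariants:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            GenomicVariant("chr1", 1, "A", "A", "PASS", "SNV", "S1")

    def test_inconsistent_class_rejected(self):
        with pytest.raises(ValueError):
            GenomicVariant("chr1", 1, "A", "AT", "PASS", "SNV", "S1")


class TestClassifyNoncoding:
    @pytest.mark.parametrize("cat", sorted(NONCODING_CATEGORIES))
    def test_all_ten_categories_are_noncoding(self, cat):
        assert classify_noncoding(cat)
        assert classify_noncoding(f"  {cat} ")  # whitespace-trimmed

    @pytest.mark.parametrize("cat", ["exonic", "utr5", "UTR-5", "Intronic", "ncRNA", ""])
    def test_coding_unknown_and_case_variants_rejected(self, cat):
        assert not classify_noncoding(cat)


def make_variant(pos, ref="A", alt="G", contig="chr1"):
    from noncneo.variants import classify_allele_pair

    return GenomicVariant(
        contig, pos, ref, alt, "PASS", classify_allele_pair(ref, alt), "S1"
    )


ANNOT = "Chr\tStart\tEnd\tRef\tAlt\tFunc\tGene\n"


class TestJoinAnnotations:
    def test_exact_join(self):
        variants = [make_variant(10), make_variant(20), make_variant(30)]
        table = ANNOT + "".join(
            f"chr1\t{p}\t{p}\tA\tG\tintronic\tG{p}\n" for p in (10, 20, 30)
        )
        out = join_annotations(variants, pd.read_csv(io.StringIO(table), sep="\t"))
        assert [a.variant.pos for a in out] == [10, 20, 30]
        assert [a.gene for a in out] == ["G10", "G20", "G30"]

    def test_unmatched_variant_excluded(self):
        variants = [make_variant(10), make_variant(99)]
        table = ANNOT + "chr1\t10\t10\tA\tG\tUTR3\tX\n"
        out = join_annotations(variants, pd.read_csv(io.StringIO(table), sep="\t"))
        assert [a.variant.pos for a in out] == [10]

    def test_duplicate_rows_first_wins_with_warning(self):
        variants = [make_variant(10)]
        table = ANNOT + "chr1\t10\t10\tA\tG\tintronic\tFIRST\nchr1\t10\t10\tA\tG\tUTR5\tSECOND\n"
        with pytest.warns(UserWarning, match="duplicate"):
            out = join_annotations(variants, pd.read_csv(io.StringIO(table), sep="\t"))
        assert out[0].func_category == "intronic"
        assert out[0].gene == "FIRST"

    def test_missing_column_is_format_error(self):
        df = pd.DataFrame({"Chr": ["chr1"], "Start": [10]})
        with pytest.raises(AnnotationFormatError):
            join_annotations([make_variant(10)], df)


class TestFilterNoncoding:
    def test_mixed_categories(self):
        annotated = [
            AnnotatedVariant(make_variant(10), "intronic"),
            AnnotatedVariant(make_variant(20), "exonic"),
            AnnotatedVariant(make_variant(30), "UTR3"),
        ]
        out = filter_noncoding(annotated)
        assert [a.func_category for a in out] == ["intronic", "UTR3"]

    def test_empty_and_all_coding(self):
        assert filter_noncoding([]) == []
        allcoding = [AnnotatedVariant(make_variant(10), "exonic")]
        assert filter_noncoding(allcoding) == []

    def test_output_subset_with_noncoding_categories_only(self):
        annotated = [
            AnnotatedVariant(make_variant(p), cat)
            for p, cat in zip(
                range(10, 200, 10),
                sorted(NONCODING_CATEGORIES) + ["exonic", "splicing;exonic"],
            )
        ]
        out = filter_noncoding(annotated)
        assert set(out) <= set(annotated)
        assert all(a.func_category in NONCODING_CATEGORIES for a in out)

    def test_join_then_filter_commutes_with_category_prefilter(self):
        variants = [make_variant(p) for p in (10, 20, 30, 40)]
        cats = ["intronic", "exonic", "UTR5", "downstream"]
        table = ANNOT + "".join(
            f"chr1\t{v.pos}\t{v.pos}\tA\tG\t{c}\tg\n" for v, c in zip(variants, cats)
        )
        df = pd.read_csv(io.StringIO(table), sep="\t")
        route1 = filter_noncoding(join_annotations(variants, df))
        pre = df[df["Func"].isin(NONCODING_CATEGORIES)]
        route2 = join_annotations(variants, pre)
        assert [a.variant.variant_id for a in route1] == [
            a.variant.variant_id for a in route2
        ]
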