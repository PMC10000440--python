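"""Somatic variant ingestion and noncoding-region selection.

Somatic calls arrive as a VCF produced by a tumor/normal caller whose
FILTER column marks confident calls with ``PASS``; functional categories
arrive as a tab-separated annotation table (one row per variant) whose
category column assigns each variant to a genomic compartment.  This
module keeps the PASS calls, joins them to their annotations, and retains
the variants that fall in noncoding compartments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import pysam

from .errors import AnnotationFormatError, VcfFormatError

logger = logging.getLogger(__name__)

#: Annotation categories treated as noncoding.  Matching is exact
#: (after stripping surrounding whitespace) and case-sensitive.
NONCODING_CATEGORIES = frozenset(
    {
        "downstream",
        "intergenic",
        "intronic",
        "ncRNA_exonic",
        "ncRNA_intronic",
        "ncRNA_splicing",
        "splicing",
        "upstream",
        "UTR3",
        "UTR5",
    }
)

_DNA = frozenset("ACGT")

#: Default column names of the annotation table (Annovar multianno dialect).
DEFAULT_ANNOTATION_COLUMNS: Mapping[str, str] = {
    "contig": "Chr",
    "pos": "Start",
    "ref": "Ref",
    "alt": "Alt",
    "func": "Func",
    "gene": "Gene",
}


def classify_allele_pair(ref: str, alt: str) -> str:
    """Classify a REF/ALT pair as SNV, insertion, deletion or complex."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "complex"


@dataclass(frozen=True)
class GenomicVariant:
    """One somatic SNV/indel after per-ALT normalization.

    ``pos`` is the 1-based reference position of the first REF base
    (standard VCF convention, anchor-base style for indels).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    filter_status: str
    variant_class: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        expected = classify_allele_pair(self.ref, self.alt)
        if self.variant_class != expected:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with "
                f"allele lengths (expected {expected!r})"
            )

    @property
    def variant_id(self) -> str:
        """Stable identifier used throughout downstream provenance."""
        return f"{self.contig}_{self.pos}_{self.ref}_{self.alt}"

    @property
    def start0(self) -> int:
        """0-based start of the REF allele (half-open interval start)."""
        return self.pos - 1


@dataclass(frozen=True)
class AnnotatedVariant:
    """A PASS variant joined to its functional annotation."""

    variant: GenomicVariant
    func_category: str
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.func_category:
            raise ValueError("func_category must be non-empty")


def parse_somatic_vcf(vcf_path: Union[str, Path], sample_id: str) -> list[GenomicVariant]:
    """Read a somatic VCF and return the PASS calls, one record per ALT.

    Only records whose FILTER is exactly ``PASS`` are kept; multi-allelic
    sites are split into one :class:`GenomicVariant` per ALT allele, each
    inheriting the record's FILTER.  Records whose alleles are not plain
    A/C/G/T strings (symbolic alleles, breakends, N-containing alleles)
    are skipped with a warning.

    Raises
    ------
    VcfFormatError
        If the file cannot be parsed as VCF, or a record line is
        malformed (the error names the approximate line).
    """
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse {vcf_path} as VCF: {exc}") from exc

    n_header = str(vcf.header).count("\n")
    out: list[GenomicVariant] = []
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            filters = list(rec.filter.keys())
            status = ";".join(filters) if filters else "."
            if filters != ["PASS"]:
                continue
            if rec.ref is None or rec.alts is None:
                continue
            ref = rec.ref.upper()
            for alt in rec.alts:
                alt = alt.upper()
                if not (_DNA.issuperset(ref) and _DNA.issuperset(alt)):
                    warnings.warn(
                        f"skipping non-ACGT allele record at {rec.chrom}:{rec.pos} "
                        f"({ref}>{alt})",
                        stacklevel=2,
                    )
                    continue
                if ref == alt:
                    continue
                out.append(
                    GenomicVariant(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        filter_status=status,
                        variant_class=classify_allele_pair(ref, alt),
                        sample_id=sample_id,
                    )
                )
    except (ValueError, OSError) as exc:
        raise VcfFormatError(
            f"malformed VCF record near line {n_header + record_no + 1} "
            f"of {vcf_path}: {exc}"
        ) from exc
    finally:
        vcf.close()
    return out


def classify_noncoding(func_category: str) -> bool:
    """True iff the category is one of the ten noncoding compartments.

    Unknown or coding categories (e.g. ``exonic``) return False; matching
    is exact after trimming whitespace and is case-sensitive.
    """
    return func_category.strip() in NONCODING_CATEGORIES


def _load_annotation_table(
    table: Union[str, Path, pd.DataFrame], columns: Mapping[str, str]
) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t", dtype=str)
    required = [columns[k] for k in ("contig", "pos", "ref", "alt", "func")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationFormatError(
            f"annotation table is missing required column(s): {missing}"
        )
    return df


def join_annotations(
    variants: Sequence[GenomicVariant],
    annotation_table: Union[str, Path, pd.DataFrame],
    columns: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Attach functional categories to variants.

    The join key is ``(contig, 1-based pos, ref, alt)`` after per-ALT
    splitting; the annotation table's end coordinate (if any) is ignored.
    Unmatched variants are logged and excluded; duplicated key rows use
    the first occurrence (with a warning).  Output order follows the
    input variant order.
    """
    cols = dict(DEFAULT_ANNOTATION_COLUMNS)
    if columns:
        cols.update(columns)
    df = _load_annotation_table(annotation_table, cols)

    gene_col = cols.get("gene")
    have_gene = gene_col in df.columns

    lookup: dict[tuple[str, int, str, str], tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        key = (
            str(rowd[cols["contig"]]),
            int(rowd[cols["pos"]]),
            str(rowd[cols["ref"]]).upper(),
            str(rowd[cols["alt"]]).upper(),
        )
        if key in lookup:
            warnings.warn(
                f"duplicate annotation rows for {key}; keeping first occurrence",
                stacklevel=2,
            )
            continue
        gene = str(rowd[gene_col]) if have_gene and pd.notna(rowd[gene_col]) else ""
        lookup[key] = (str(rowd[cols["func"]]), gene)

    out: list[AnnotatedVariant] = []
    for v in variants:
        key = (v.contig, v.pos, v.ref, v.alt)
        hit = lookup.get(key)
        if hit is None:
            logger.warning("variant %s has no annotation row; excluded", v.variant_id)
            continue
        func, gene = hit
        out.append(AnnotatedVariant(variant=v, func_category=func, gene=gene))
    return out


def filter_noncoding(annotated: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep exactly the variants whose category is noncoding."""
    return [a for a in annotated if classify_noncoding(a.func_category)]


def write_variants_tsv(annotated: Sequence[AnnotatedVariant], path: Union[str, Path]) -> None:
    """Write retained variants as a TSV (one row per variant)."""
    rows = [
        {
            "variant_id": a.variant.variant_id,
            "sample_id": a.variant.sample_id,
            "contig": a.variant.contig,
            "pos": a.variant.pos,
            "ref": a.variant.ref,
            "alt": a.variant.alt,
            "variant_class": a.variant.variant_class,
            "func_category": a.func_category,
            "gene": a.gene,
        }
        for a in annotated
    ]
    pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "sample_id",
            "contig",
            "pos",
            "ref",
            "alt",
            "variant_class",
            "func_category",
            "gene",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: Union[str, Path]) -> list[AnnotatedVariant]:
    """Read back a TSV written by :func:`write_variants_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        v = GenomicVariant(
            contig=row.contig,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            filter_status="PASS",
            variant_class=row.variant_class,
            sample_id=row.sample_id,
        )
        out.append(AnnotatedVariant(variant=v, func_category=row.func_category, gene=row.gene))
    return out
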