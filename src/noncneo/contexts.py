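"""Mutant sequence context extraction.

For every retained noncoding variant a window of reference sequence is
extracted around the mutation site (``flank`` nucleotides on each side
of the REF allele, default 100), the REF bases are substituted by the
ALT bases, and the interval of mutation-derived bases inside the mutant
window is tracked so that later translation can tell which residues are
mutated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .errors import AlphabetError, ContigNotFoundError, ReferenceMismatchError
from .variants import AnnotatedVariant, GenomicVariant

_RC = str.maketrans("ACGTN", "TGCAN")
_NT = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    if not _NT.issuperset(seq):
        bad = sorted(set(seq) - _NT)
        raise AlphabetError(f"non-nucleotide characters in sequence: {bad}")
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class MutantContext:
    """A windowed mutant nucleotide sequence.

    ``mut_interval`` is a 0-based half-open interval within
    ``mut_window`` covering the mutation-derived bases.  ``window_start``
    is the 0-based genomic coordinate of the first window base.
    """

    variant_id: str
    contig: str
    window_start: int
    ref_window: str
    mut_window: str
    mut_interval: tuple[int, int]
    flank: int = 100
    gene: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        a, b = self.mut_interval
        if not (0 <= a < b <= len(self.mut_window)):
            raise ValueError(f"mut_interval {self.mut_interval} out of bounds")


def _fetch(genome, contig: str, start: int, end: int) -> str:
    try:
        seq = genome[contig]
    except KeyError as exc:
        raise ContigNotFoundError(f"contig {contig!r} not in genome") from exc
    return str(seq[start:end]).upper()


def _contig_length(genome, contig: str) -> int:
    try:
        return len(genome[contig])
    except KeyError as exc:
        raise ContigNotFoundError(f"contig {contig!r} not in genome") from exc


def extract_context(
    genome,
    variant: Union[GenomicVariant, AnnotatedVariant],
    flank: int = 100,
) -> MutantContext | None:
    """Extract the ±``flank`` nt window around a variant and apply REF→ALT.

    ``genome`` is any mapping from contig name to a sliceable sequence
    (a ``pyfaidx.Fasta`` or a plain ``dict`` of strings).  The window
    spans ``flank`` bases left of the first REF base through ``flank``
    bases right of the last REF base, clipped at contig bounds.  For a
    pure anchor-base deletion the mutated interval spans the junction
    (anchor base plus the first base past the junction, when present),
    because the novel sequence a deletion creates lives at the join.

    Returns ``None`` (with a warning) when the clipped mutant window is
    shorter than one codon.

    Raises
    ------
    ReferenceMismatchError
        If the genome bases at the variant position do not equal REF.
    ContigNotFoundError
        If the contig is absent from the genome.
    """
    gene = ""
    if isinstance(variant, AnnotatedVariant):
        gene = variant.gene
        variant = variant.variant
    v = variant

    clen = _contig_length(genome, v.contig)
    ref_start = v.start0
    ref_end = ref_start + len(v.ref)
    if ref_end > clen:
        raise ReferenceMismatchError(
            f"variant {v.variant_id} extends past end of contig {v.contig}"
        )
    genome_ref = _fetch(genome, v.contig, ref_start, ref_end)
    if genome_ref != v.ref.upper():
        raise ReferenceMismatchError(
            f"REF mismatch at {v.contig}:{v.pos}: genome has {genome_ref!r}, "
            f"variant says {v.ref!r}"
        )

    win_start = max(0, ref_start - flank)
    win_end = min(clen, ref_end + flank)
    left = _fetch(genome, v.contig, win_start, ref_start)
    right = _fetch(genome, v.contig, ref_end, win_end)
    ref_window = left + genome_ref + right
    mut_window = left + v.alt.upper() + right

    a = len(left)
    if v.variant_class == "deletion" and len(v.alt) == 1 and v.alt[0] == v.ref[0]:
        # pure anchor-base deletion: novel sequence sits at the junction
        b = min(a + 2, len(mut_window))
    else:
        b = a + len(v.alt)

    if len(mut_window) < 3:
        warnings.warn(
            f"context for {v.variant_id} shorter than one codon; dropped",
            stacklevel=2,
        )
        return None

    return MutantContext(
        variant_id=v.variant_id,
        contig=v.contig,
        window_start=win_start,
        ref_window=ref_window,
        mut_window=mut_window,
        mut_interval=(a, b),
        flank=flank,
        gene=gene,
        sample_id=v.sample_id,
    )


def extract_contexts(
    genome, variants: Sequence[Union[GenomicVariant, AnnotatedVariant]], flank: int = 100
) -> list[MutantContext]:
    """Extract contexts for many variants, dropping sub-codon windows."""
    out = []
    for v in variants:
        ctx = extract_context(genome, v, flank=flank)
        if ctx is not None:
            out.append(ctx)
    return out


def write_context_fasta(contexts: Sequence[MutantContext], path: Union[str, Path]) -> None:
    """Write mutant windows as FASTA with provenance-bearing headers."""
    with open(path, "w") as fh:
        for c in contexts:
            a, b = c.mut_interval
            fh.write(f">{c.variant_id}|{c.contig}:{c.window_start}|mut={a}-{b}\n")
            fh.write(c.mut_window + "\n")


def write_context_tsv(contexts: Sequence[MutantContext], path: Union[str, Path]) -> None:
    rows = [
        {
            "variant_id": c.variant_id,
            "sample_id": c.sample_id,
            "contig": c.contig,
            "window_start": c.window_start,
            "ref_window": c.ref_window,
            "mut_window": c.mut_window,
            "mut_start": c.mut_interval[0],
            "mut_end": c.mut_interval[1],
            "flank": c.flank,
            "gene": c.gene,
        }
        for c in contexts
    ]
    pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "sample_id",
            "contig",
            "window_start",
            "ref_window",
            "mut_window",
            "mut_start",
            "mut_end",
            "flank",
            "gene",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_context_tsv(path: Union[str, Path]) -> list[MutantContext]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        MutantContext(
            variant_id=r.variant_id,
            contig=r.contig,
            window_start=int(r.window_start),
            ref_window=r.ref_window,
            mut_window=r.mut_window,
            mut_interval=(int(r.mut_start), int(r.mut_end)),
            flank=int(r.flank),
            gene=r.gene,
            sample_id=r.sample_id,
        )
        for r in df.itertuples(index=False)
    ]
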