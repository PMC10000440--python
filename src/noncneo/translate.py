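"""Six-frame translation of mutant contexts into mutation-bearing peptides.

Noncoding sequence carries no reading-frame annotation, so each mutant
context is translated in all six frames under the standard genetic code.
Stop codons become ``*``; translations are fragmented on ``*``; mutated
nucleotide positions are mapped to residue positions; and only stop-free
fragments that contain at least one mutated residue and reach the
minimum searchable length survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio.Data import CodonTable

from .contexts import MutantContext, reverse_complement
from .errors import AlphabetError

#: Frame labels: +1/+2/+3 read the forward strand at offsets 0/1/2,
#: −1/−2/−3 read the reverse complement at offsets 0/1/2.
FRAMES = (1, 2, 3, -1, -2, -3)

_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE1.forward_table)
for _stop in _TABLE1.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a mutant context."""

    frame: int
    aa_seq: str
    mutated_residues: frozenset[int] = frozenset()


@dataclass(frozen=True)
class MutantPeptide:
    """A stop-free translated fragment containing ≥1 mutated residue.

    ``fragment_start`` is the 0-based residue offset of the fragment
    within its frame translation; ``mutated_offsets`` are 0-based indices
    within ``sequence``.  ``provenance`` lists every (variant_id, frame,
    fragment_start) that produced this sequence when duplicates from
    different frames are merged.
    """

    sequence: str
    variant_id: str
    frame: int
    fragment_start: int
    mutated_offsets: frozenset[int]
    gene: str = ""
    sample_id: str = ""
    provenance: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("peptide may not contain a stop")
        if not self.mutated_offsets:
            raise ValueError("peptide must contain >=1 mutated residue")
        if any(not 0 <= o < len(self.sequence) for o in self.mutated_offsets):
            raise ValueError("mutated offsets out of range")


def translate_frame(nt_seq: str, frame: int) -> FrameTranslation:
    """Translate one frame under the standard genetic code.

    Stop codons translate to ``*``; any codon containing N translates to
    ``X``; the trailing partial codon is ignored.  Minus frames translate
    the reverse complement at the corresponding offset.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame!r}; expected one of {FRAMES}")
    seq = nt_seq.upper()
    if not _NT.issuperset(seq):
        bad = sorted(set(seq) - _NT)
        raise AlphabetError(f"non-nucleotide characters in sequence: {bad}")
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    aa = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return FrameTranslation(frame=frame, aa_seq="".join(aa))


def map_mutated_residues(
    mut_interval: tuple[int, int], seq_len: int, frame: int
) -> frozenset[int]:
    """Map a mutated nucleotide interval to residue indices in a frame.

    For plus frames with offset ``s``, nucleotide offset ``o`` maps to
    residue ``(o − s) // 3`` when that residue lies within the frame's
    translation.  For minus frames the interval is first mapped into
    reverse-complement coordinates.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame!r}")
    a, b = mut_interval
    if not (0 <= a < b <= seq_len):
        raise ValueError(f"mut_interval {mut_interval} outside [0, {seq_len})")
    if frame < 0:
        a, b = seq_len - b, seq_len - a
    s = abs(frame) - 1
    frame_len = max(0, (seq_len - s)) // 3
    residues = set()
    for o in range(a, b):
        if o < s:
            continue
        r = (o - s) // 3
        if 0 <= r < frame_len:
            residues.add(r)
    return frozenset(residues)


def fragment_on_stops(
    ft: FrameTranslation,
) -> list[tuple[str, int, frozenset[int]]]:
    """Split a frame translation into maximal ``*``-free fragments.

    Each fragment carries the mutated residues that fall inside it,
    re-indexed to fragment coordinates, and its 0-based start within the
    frame translation.
    """
    out: list[tuple[str, int, frozenset[int]]] = []
    start = 0
    seq = ft.aa_seq
    for i, ch in enumerate(seq + "*"):
        if ch == "*":
            if i > start:
                frag = seq[start:i]
                muts = frozenset(
                    m - start for m in ft.mutated_residues if start <= m < i
                )
                out.append((frag, start, muts))
            start = i + 1
    return out


def generate_mutant_peptides(
    context: MutantContext, min_length: int = 7
) -> list[MutantPeptide]:
    """All mutation-bearing, stop-free peptides of a context, six frames.

    Fragments must contain at least one mutated residue and be at least
    ``min_length`` residues long (the minimum length an MS search will
    match).  Identical sequences arising from several frames are emitted
    once, with the provenance of every contributing frame retained.
    Peptides containing ``X`` (from N-containing codons) are retained
    here and excluded at database construction.
    """
    seq = context.mut_window
    by_seq: dict[str, MutantPeptide] = {}
    for frame in FRAMES:
        ft = translate_frame(seq, frame)
        muts = map_mutated_residues(context.mut_interval, len(seq), frame)
        ft = FrameTranslation(frame=frame, aa_seq=ft.aa_seq, mutated_residues=muts)
        for frag, frag_start, frag_muts in fragment_on_stops(ft):
            if not frag_muts or len(frag) < min_length:
                continue
            key = frag
            prov = (context.variant_id, frame, frag_start)
            if key in by_seq:
                prev = by_seq[key]
                by_seq[key] = MutantPeptide(
                    sequence=prev.sequence,
                    variant_id=prev.variant_id,
                    frame=prev.frame,
                    fragment_start=prev.fragment_start,
                    mutated_offsets=prev.mutated_offsets,
                    gene=prev.gene,
                    sample_id=prev.sample_id,
                    provenance=prev.provenance + (prov,),
                )
            else:
                by_seq[key] = MutantPeptide(
                    sequence=frag,
                    variant_id=context.variant_id,
                    frame=frame,
                    fragment_start=frag_start,
                    mutated_offsets=frag_muts,
                    gene=context.gene,
                    sample_id=context.sample_id,
                    provenance=(prov,),
                )
    return list(by_seq.values())


def generate_all_mutant_peptides(
    contexts: Iterable[MutantContext], min_length: int = 7
) -> list[MutantPeptide]:
    out: list[MutantPeptide] = []
    for ctx in contexts:
        out.extend(generate_mutant_peptides(ctx, min_length=min_length))
    return out


def write_peptide_fasta(peptides: Sequence[MutantPeptide], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            offs = ",".join(str(o) for o in sorted(p.mutated_offsets))
            fh.write(
                f">{p.variant_id}|F{p.frame:+d}|frag{p.fragment_start}|mut={offs}\n"
            )
            fh.write(p.sequence + "\n")


def write_peptide_tsv(peptides: Sequence[MutantPeptide], path: Union[str, Path]) -> None:
    rows = [
        {
            "sequence": p.sequence,
            "variant_id": p.variant_id,
            "sample_id": p.sample_id,
            "frame": p.frame,
            "fragment_start": p.fragment_start,
            "mutated_offsets": ",".join(str(o) for o in sorted(p.mutated_offsets)),
            "gene": p.gene,
        }
        for p in peptides
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "variant_id",
            "sample_id",
            "frame",
            "fragment_start",
            "mutated_offsets",
            "gene",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_peptide_tsv(path: Union[str, Path]) -> list[MutantPeptide]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        MutantPeptide(
            sequence=r.sequence,
            variant_id=r.variant_id,
            frame=int(r.frame),
            fragment_start=int(r.fragment_start),
            mutated_offsets=frozenset(
                int(x) for x in r.mutated_offsets.split(",") if x != ""
            ),
            gene=r.gene,
            sample_id=r.sample_id,
            provenance=((r.variant_id, int(r.frame), int(r.fragment_start)),),
        )
        for r in df.itertuples(index=False)
    ]
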