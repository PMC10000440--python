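"""Customized search database construction and MS identification handling.

The MS search engine is external; this module prepares what it consumes
(a per-sample FASTA of reference proteins, laboratory contaminants and
mutation-bearing peptides, optionally with pseudo-reversed tryptic
decoys) and consumes what it produces (a peptide-identification table in
the MaxQuant ``peptides.txt`` dialect), matching confident
identifications back to mutant entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationFormatError
from .translate import MutantPeptide

DECOY_PREFIX = "REV_"


@dataclass(frozen=True)
class DatabaseEntry:
    """One entry of the customized search database."""

    accession: str
    sequence: str
    origin: str  # reference | contaminant | mutant | decoy
    mutated_offsets: frozenset[int] = frozenset()
    variant_id: str = ""
    gene: str = ""
    sample_id: str = ""


@dataclass(frozen=True)
class IdentifiedPeptide:
    """One confidently identified peptide from the search engine table."""

    sequence: str
    protein_accessions: tuple[str, ...] = ()
    is_reverse: bool = False
    is_contaminant: bool = False
    scores: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class ValidatedMutantPeptide:
    """An identified peptide matched into a mutant database entry.

    ``covered_mutated_offsets`` are in identified-peptide coordinates
    (mutant-entry offsets shifted into the match window).
    """

    identified: IdentifiedPeptide
    mutant_entry: DatabaseEntry
    match_offset: int
    covered_mutated_offsets: frozenset[int]

    @property
    def sequence(self) -> str:
        return self.identified.sequence

    @property
    def mutated_offsets(self) -> frozenset[int]:
        return self.covered_mutated_offsets


def read_fasta_entries(path: Union[str, Path], origin: str) -> list[DatabaseEntry]:
    """Read a protein FASTA into tagged database entries."""
    return [
        DatabaseEntry(accession=rec.id, sequence=str(rec.seq).upper(), origin=origin)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def mutant_peptides_to_entries(peptides: Sequence[MutantPeptide]) -> list[DatabaseEntry]:
    """Deduplicate mutant peptides by sequence and assign accessions.

    Entries containing ``X`` or ``*`` are excluded with a warning (an MS
    search cannot match them).  The accession scheme is deterministic:
    the first-seen provenance of each unique sequence.
    """
    out: list[DatabaseEntry] = []
    seen: set[str] = set()
    for p in peptides:
        if "X" in p.sequence or "*" in p.sequence:
            warnings.warn(
                f"mutant peptide from {p.variant_id} contains X/*; excluded",
                stacklevel=2,
            )
            continue
        if p.sequence in seen:
            continue
        seen.add(p.sequence)
        acc = f"MUT|{p.variant_id}|F{p.frame:+d}|frag{p.fragment_start}"
        out.append(
            DatabaseEntry(
                accession=acc,
                sequence=p.sequence,
                origin="mutant",
                mutated_offsets=p.mutated_offsets,
                variant_id=p.variant_id,
                gene=p.gene,
                sample_id=p.sample_id,
            )
        )
    return out


def build_custom_database(
    reference_entries: Sequence[DatabaseEntry],
    contaminant_entries: Sequence[DatabaseEntry],
    mutant_peptides: Sequence[MutantPeptide],
) -> list[DatabaseEntry]:
    """Concatenate reference + contaminants + mutant peptides.

    Mutant peptides are deduplicated by sequence and written as
    standalone entries.  Duplicate accessions across sections are
    renamed with a numeric suffix (with a warning).
    """
    combined = (
        [DatabaseEntry(e.accession, e.sequence.upper(), "reference") for e in reference_entries]
        + [DatabaseEntry(e.accession, e.sequence.upper(), "contaminant") for e in contaminant_entries]
        + mutant_peptides_to_entries(mutant_peptides)
    )
    seen: dict[str, int] = {}
    out: list[DatabaseEntry] = []
    for e in combined:
        acc = e.accession
        if acc in seen:
            seen[acc] += 1
            new_acc = f"{acc}_{seen[acc]}"
            warnings.warn(
                f"duplicate accession {acc!r}; renamed to {new_acc!r}", stacklevel=2
            )
            e = DatabaseEntry(
                accession=new_acc,
                sequence=e.sequence,
                origin=e.origin,
                mutated_offsets=e.mutated_offsets,
                variant_id=e.variant_id,
                gene=e.gene,
                sample_id=e.sample_id,
            )
        else:
            seen[acc] = 0
        out.append(e)
    return out


class TrypticPeptide(NamedTuple):
    sequence: str
    start: int
    missed_cleavages: int


def _cleavage_boundaries(sequence: str) -> list[int]:
    """Positions where trypsin cuts: after K/R unless followed by P."""
    bounds = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            bounds.append(i + 1)
    bounds.append(len(sequence))
    return bounds


def digest_tryptic(
    sequence: str, max_missed: int = 2, min_length: int = 7
) -> list[TrypticPeptide]:
    """In-silico tryptic digestion (cleave after K/R, not before P).

    Returns every peptide with 0..``max_missed`` missed cleavages and
    length ≥ ``min_length``, with its 0-based start position, ordered by
    start then length.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bounds = _cleavage_boundaries(sequence)
    out: list[TrypticPeptide] = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for j in range(i + 1, min(i + max_missed + 2, n_seg + 1)):
            pep = sequence[bounds[i] : bounds[j]]
            if len(pep) >= min_length:
                out.append(TrypticPeptide(pep, bounds[i], j - i - 1))
    return out


def pseudo_reverse(sequence: str) -> str:
    """Reverse each tryptic segment in place, keeping C-terminal K/R.

    A segment ending in K/R has its preceding residues reversed with the
    terminal K/R left anchored; a terminal segment without K/R is fully
    reversed.  Segment boundaries, length and composition are preserved.
    """
    bounds = _cleavage_boundaries(sequence)
    parts = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = sequence[a:b]
        if seg and seg[-1] in "KR":
            parts.append(seg[:-1][::-1] + seg[-1])
        else:
            parts.append(seg[::-1])
    return "".join(parts)


def generate_reversed_tryptic_decoys(
    entries: Sequence[DatabaseEntry],
) -> list[DatabaseEntry]:
    """One pseudo-reversed decoy per target entry (``REV_`` accession)."""
    return [
        DatabaseEntry(
            accession=DECOY_PREFIX + e.accession,
            sequence=pseudo_reverse(e.sequence),
            origin="decoy",
        )
        for e in entries
    ]


def write_database_fasta(
    entries: Sequence[DatabaseEntry], path: Union[str, Path], with_decoys: bool = False
) -> None:
    """Write the database FASTA deterministically (input order)."""
    records = list(entries)
    if with_decoys:
        records = records + generate_reversed_tryptic_decoys(entries)
    SeqIO.write(
        (SeqRecord(Seq(e.sequence), id=e.accession, description="") for e in records),
        str(path),
        "fasta",
    )


def write_mutant_entry_tsv(entries: Sequence[DatabaseEntry], path: Union[str, Path]) -> None:
    rows = [
        {
            "accession": e.accession,
            "sequence": e.sequence,
            "mutated_offsets": ",".join(str(o) for o in sorted(e.mutated_offsets)),
            "variant_id": e.variant_id,
            "gene": e.gene,
            "sample_id": e.sample_id,
        }
        for e in entries
        if e.origin == "mutant"
    ]
    pd.DataFrame(
        rows,
        columns=["accession", "sequence", "mutated_offsets", "variant_id", "gene", "sample_id"],
    ).to_csv(path, sep="\t", index=False)


def read_mutant_entry_tsv(path: Union[str, Path]) -> list[DatabaseEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        DatabaseEntry(
            accession=r.accession,
            sequence=r.sequence,
            origin="mutant",
            mutated_offsets=frozenset(
                int(x) for x in r.mutated_offsets.split(",") if x != ""
            ),
            variant_id=r.variant_id,
            gene=r.gene,
            sample_id=r.sample_id,
        )
        for r in df.itertuples(index=False)
    ]


#: Default column names of the identification table (MaxQuant peptides.txt).
DEFAULT_PEPTIDE_COLUMNS: Mapping[str, str] = {
    "sequence": "Sequence",
    "proteins": "Proteins",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}


def parse_identified_peptides(
    table: Union[str, Path, pd.DataFrame],
    columns: Mapping[str, str] | None = None,
) -> list[IdentifiedPeptide]:
    """Parse a search-engine peptide table, dropping flagged rows.

    Rows whose reverse (decoy) or contaminant flag is set (any non-empty
    value, MaxQuant writes ``+``) are excluded; sequences are uppercased.

    Raises
    ------
    AnnotationFormatError
        If the sequence column is missing.
    """
    cols = dict(DEFAULT_PEPTIDE_COLUMNS)
    if columns:
        cols.update(columns)
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    if cols["sequence"] not in df.columns:
        raise AnnotationFormatError(
            f"identification table missing sequence column {cols['sequence']!r}"
        )

    def flag(row: Mapping[str, str], key: str) -> bool:
        col = cols[key]
        return col in df.columns and str(row.get(col, "")).strip() not in ("", "nan")

    score_cols = [c for c in ("Score", "PEP") if c in df.columns]
    out: list[IdentifiedPeptide] = []
    for _, row in df.iterrows():
        is_rev = flag(row, "reverse")
        is_con = flag(row, "contaminant")
        if is_rev or is_con:
            continue
        proteins = str(row.get(cols["proteins"], "") or "")
        scores = []
        for c in score_cols:
            try:
                scores.append((c, float(row[c])))
            except (TypeError, ValueError):
                pass
        out.append(
            IdentifiedPeptide(
                sequence=str(row[cols["sequence"]]).upper(),
                protein_accessions=tuple(p for p in proteins.split(";") if p),
                is_reverse=False,
                is_contaminant=False,
                scores=tuple(scores),
            )
        )
    return out


def match_identified_to_mutant(
    identified: Sequence[IdentifiedPeptide],
    mutant_entries: Sequence[DatabaseEntry],
    reference_entries: Sequence[DatabaseEntry] = (),
) -> list[ValidatedMutantPeptide]:
    """Match identified peptides back into mutant database entries.

    A peptide validates an entry iff it occurs as a substring whose
    window overlaps ≥1 mutated offset; every qualifying (peptide, entry)
    pair is reported once, at the first overlapping occurrence.
    Peptides present verbatim inside any reference protein are excluded:
    they are not cancer-specific.
    """
    reference_seqs = [e.sequence for e in reference_entries]
    out: list[ValidatedMutantPeptide] = []
    for ip in identified:
        seq = ip.sequence
        if any(seq in ref for ref in reference_seqs):
            continue
        for entry in mutant_entries:
            if entry.origin != "mutant":
                continue
            pos = entry.sequence.find(seq)
            matched = None
            while pos != -1:
                covered = frozenset(
                    m - pos
                    for m in entry.mutated_offsets
                    if pos <= m < pos + len(seq)
                )
                if covered:
                    matched = (pos, covered)
                    break
                pos = entry.sequence.find(seq, pos + 1)
            if matched is not None:
                out.append(
                    ValidatedMutantPeptide(
                        identified=ip,
                        mutant_entry=entry,
                        match_offset=matched[0],
                        covered_mutated_offsets=matched[1],
                    )
                )
    return out
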