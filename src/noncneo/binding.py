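"""MHC class-I binding candidate selection.

MS-validated mutant peptides are windowed into mutated 8–11-mers (the
lengths class-I molecules present), each (k-mer, allele) pair is scored
by a pluggable percentile-rank predictor, and pairs with %rank below the
candidate threshold (default 2) are retained.  Lower %rank means
stronger predicted binding: <0.5 strong binder (SB), <2 weak binder
(WB), otherwise non-binder (NB) under the conventional cutoffs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence, Union

from .errors import PredictorError
from .proteome import ValidatedMutantPeptide

logger = logging.getLogger(__name__)

#: (peptide, allele) -> percentile rank
Predictor = Callable[[str, str], float]

_HLA_PATTERN = re.compile(r"^HLA-[A-Z0-9]+\*\d{2,4}:\d{2,4}$")


@dataclass(frozen=True)
class KmerCandidate:
    """A mutated 8–11-mer windowed out of a validated peptide."""

    sequence: str
    parent: ValidatedMutantPeptide | None
    start: int
    mutated_offsets: frozenset[int]

    def __post_init__(self) -> None:
        if not self.mutated_offsets:
            raise ValueError("k-mer must contain >=1 mutated residue")
        if any(not 0 <= o < len(self.sequence) for o in self.mutated_offsets):
            raise ValueError("mutated offsets out of k-mer range")


@dataclass(frozen=True)
class HlaTyping:
    """Class-I alleles of one sample (``HLA-A*02:01`` nomenclature)."""

    sample_id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 6:
            raise ValueError("typing must list 1-6 class-I alleles")
        for a in self.alleles:
            if not _HLA_PATTERN.match(a):
                raise ValueError(f"allele {a!r} does not match HLA nomenclature")


@dataclass(frozen=True)
class BindingPrediction:
    """Percentile rank of one (k-mer, allele) pair."""

    kmer: KmerCandidate
    allele: str
    percentile_rank: float
    bind_level: str


def enumerate_kmers(
    parent: ValidatedMutantPeptide, kmin: int = 8, kmax: int = 11
) -> list[KmerCandidate]:
    """All k-mers (kmin ≤ k ≤ kmax) containing ≥1 mutated residue.

    Windows are enumerated over the validated peptide's sequence using
    its covered mutated offsets; parents shorter than ``kmin`` yield an
    empty list.  Order: increasing k, then increasing start.
    """
    seq = parent.sequence
    muts = parent.mutated_offsets
    out: list[KmerCandidate] = []
    for k in range(kmin, kmax + 1):
        for start in range(0, len(seq) - k + 1):
            local = frozenset(m - start for m in muts if start <= m < start + k)
            if local:
                out.append(
                    KmerCandidate(
                        sequence=seq[start : start + k],
                        parent=parent,
                        start=start,
                        mutated_offsets=local,
                    )
                )
    return out


def assign_bind_level(percentile_rank: float, sb: float = 0.5, wb: float = 2.0) -> str:
    """SB if rank < sb, WB if sb ≤ rank < wb, NB otherwise."""
    if percentile_rank < 0:
        raise ValueError(f"percentile rank must be >= 0, got {percentile_rank}")
    if percentile_rank < sb:
        return "SB"
    if percentile_rank < wb:
        return "WB"
    return "NB"


def predict_binding(
    kmers: Sequence[KmerCandidate],
    typing: HlaTyping,
    predictor: Predictor,
    sb: float = 0.5,
    wb: float = 2.0,
) -> list[BindingPrediction]:
    """Score every (k-mer, allele) pair with the predictor.

    Each unique (sequence, allele) pair is scored once and the result is
    fanned back out to every k-mer with that sequence.  Predictor
    failures for a pair are logged and that pair is skipped.
    """
    if predictor is None:
        raise PredictorError(
            "no predictor configured; supply a callable (peptide, allele) -> %rank, "
            "e.g. a parsed predictor output file or the fixtures mock"
        )
    cache: dict[tuple[str, str], float | None] = {}
    out: list[BindingPrediction] = []
    for kmer in kmers:
        for allele in typing.alleles:
            key = (kmer.sequence, allele)
            if key not in cache:
                try:
                    cache[key] = float(predictor(kmer.sequence, allele))
                except Exception as exc:  # noqa: BLE001 - contract: record and skip
                    logger.warning("predictor failed for %s/%s: %s", *key, exc)
                    cache[key] = None
            rank = cache[key]
            if rank is None:
                continue
            out.append(
                BindingPrediction(
                    kmer=kmer,
                    allele=allele,
                    percentile_rank=rank,
                    bind_level=assign_bind_level(rank, sb=sb, wb=wb),
                )
            )
    return out


def filter_candidates(
    predictions: Iterable[BindingPrediction], threshold: float = 2.0
) -> list[BindingPrediction]:
    """Keep predictions with %rank strictly below the threshold."""
    return [p for p in predictions if p.percentile_rank < threshold]


def read_allele_list(path: Union[str, Path], sample_id: str) -> HlaTyping:
    """Read a one-allele-per-line text file into a typing."""
    alleles = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                alleles.append(line)
    return HlaTyping(sample_id=sample_id, alleles=tuple(alleles))


class TablePredictor:
    """Predictor backed by a (peptide, allele) -> %rank table.

    Missing pairs raise ``KeyError``, which :func:`predict_binding`
    records and skips.
    """

    def __init__(self, table: dict[tuple[str, str], float]):
        self._table = dict(table)

    def __call__(self, peptide: str, allele: str) -> float:
        return self._table[(peptide, allele)]

    def __len__(self) -> int:
        return len(self._table)


def parse_netmhcpan_output(path: Union[str, Path]) -> TablePredictor:
    """Parse predictor output into a :class:`TablePredictor`.

    Two dialects are recognized:

    * a TSV with header columns including ``peptide``, ``allele`` and a
      rank column (``%rank``, ``rank`` or ``%Rank_EL``), case-insensitive;
    * the whitespace-separated long table printed by NetMHCpan 4.1,
      where data lines carry the allele in column 2 (``HLA-…``), the
      peptide in column 3 and the %Rank_EL score in the column the
      header labels ``%Rank_EL`` (falling back to column 13).
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PredictorError(f"predictor output {path} is empty")

    table: dict[tuple[str, str], float] = {}
    first = lines[0]
    if "\t" in first:
        header = [h.strip().lower() for h in first.split("\t")]
        try:
            pep_i = header.index("peptide")
            allele_i = header.index("allele")
        except ValueError as exc:
            raise PredictorError(
                f"TSV predictor output {path} lacks peptide/allele columns"
            ) from exc
        rank_i = None
        for cand in ("%rank", "rank", "%rank_el", "percentile_rank"):
            if cand in header:
                rank_i = header.index(cand)
                break
        if rank_i is None:
            raise PredictorError(f"TSV predictor output {path} lacks a rank column")
        for ln in lines[1:]:
            parts = ln.split("\t")
            table[(parts[pep_i].strip().upper(), parts[allele_i].strip())] = float(
                parts[rank_i]
            )
        return TablePredictor(table)

    rank_col = 12
    for ln in lines:
        toks = ln.split()
        if "%Rank_EL" in toks:
            rank_col = toks.index("%Rank_EL")
        if len(toks) > rank_col and toks[0].isdigit() and toks[1].startswith("HLA-"):
            allele = toks[1].replace("HLA-A", "HLA-A*").replace(
                "HLA-B", "HLA-B*"
            ).replace("HLA-C", "HLA-C*") if "*" not in toks[1] else toks[1]
            table[(toks[2].upper(), allele)] = float(toks[rank_col])
    if not table:
        raise PredictorError(f"no prediction rows recognized in {path}")
    return TablePredictor(table)
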