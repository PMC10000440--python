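"""Homology screening of candidate neoantigens.

Candidates that resemble experimentally validated immunogenic peptides
are more likely to be immunogenic themselves.  Each rank-filtered
candidate is locally aligned against a user-supplied reference set of
immunogenic peptides; candidates whose best hit exceeds 60% identical
matches are flagged high-confidence.  Because the queries are 8–11-mers,
an exact Smith–Waterman (BLOSUM62, affine gaps) replaces a heuristic
seeded search; an adapter for external BLASTp tabular output (with
E-values) is provided for parity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Mapping, Sequence, Union

import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .binding import BindingPrediction
from .errors import AlphabetError, ConfigurationError

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@lru_cache(maxsize=1)
def _blosum62() -> dict[tuple[str, str], int]:
    mat = substitution_matrices.load("BLOSUM62")
    return {
        (a, b): int(mat[a, b]) for a in mat.alphabet for b in mat.alphabet
    }


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment between a query and a target peptide."""

    query: str
    target: str
    score: float
    n_identical: int
    alignment_length: int
    percent_identity: float
    evalue: float | None = None


@dataclass(frozen=True)
class NeoantigenRecord:
    """A candidate with its homology-screen outcome and provenance."""

    candidate: BindingPrediction
    best_hit: AlignmentResult | None
    matched_reference: str | None
    high_confidence: bool
    variant_id: str = ""
    gene: str = ""
    sample_id: str = ""


def local_align(
    query: str,
    target: str,
    matrix: Mapping[tuple[str, str], int] | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Exact Smith–Waterman with affine gaps and identity statistics.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``.  Among
    equal-scoring optima the alignment with the most identical matches
    is reported, ties broken by smallest query start then target start.
    When no cell scores positive, an empty result (score 0, identity 0)
    is returned.
    """
    for seq in (query, target):
        if not seq:
            raise AlphabetError("peptides must be non-empty")
        bad = set(seq) - _AA
        if bad:
            raise AlphabetError(f"non-standard residues {sorted(bad)} in {seq!r}")
    sub = matrix if matrix is not None else _blosum62()

    n, m = len(query), len(target)
    NEG = float("-inf")
    # Gotoh: M ends in a substitution column, X consumes query (gap in
    # target), Y consumes target (gap in query).
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            s = sub[(query[i - 1], target[j - 1])]
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0),
            )
            if M[i][j] > best:
                best = M[i][j]

    if best <= 0:
        return AlignmentResult(query, target, 0.0, 0, 0, 0.0)

    # Enumerate optimal paths from every best-scoring end cell to apply
    # the deterministic tie-break; peptides are short, so this is cheap.
    best_stats: tuple[int, int, int, int] | None = None  # (-nid, qstart, tstart, alen)

    def walk(state: str, i: int, j: int, nid: int, alen: int) -> None:
        nonlocal best_stats
        if state == "M":
            s = sub[(query[i - 1], target[j - 1])]
            ident = 1 if query[i - 1] == target[j - 1] else 0
            prev = M[i][j] - s
            nid2, alen2 = nid + ident, alen + 1
            if prev == 0:
                # alignment may start here (fresh local start); prefer
                # most identities, then smallest starts, longest extent
                cand = (-nid2, i - 1, j - 1, -alen2)
                if best_stats is None or cand < best_stats:
                    best_stats = cand
            if M[i - 1][j - 1] == prev and M[i - 1][j - 1] > 0:
                walk("M", i - 1, j - 1, nid2, alen2)
            # gap states can tie prev even at 0 (net-zero prefix that
            # still carries identical columns)
            if X[i - 1][j - 1] == prev:
                walk("X", i - 1, j - 1, nid2, alen2)
            if Y[i - 1][j - 1] == prev:
                walk("Y", i - 1, j - 1, nid2, alen2)
        elif state == "X":
            if M[i - 1][j] - gap_open == X[i][j] and M[i - 1][j] > 0:
                walk("M", i - 1, j, nid, alen + 1)
            if X[i - 1][j] - gap_extend == X[i][j]:
                walk("X", i - 1, j, nid, alen + 1)
        else:
            if M[i][j - 1] - gap_open == Y[i][j] and M[i][j - 1] > 0:
                walk("M", i, j - 1, nid, alen + 1)
            if Y[i][j - 1] - gap_extend == Y[i][j]:
                walk("Y", i, j - 1, nid, alen + 1)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] == best:
                walk("M", i, j, 0, 0)

    assert best_stats is not None
    nid = -best_stats[0]
    alen = -best_stats[3]
    return AlignmentResult(
        query=query,
        target=target,
        score=best,
        n_identical=nid,
        alignment_length=alen,
        percent_identity=100.0 * nid / alen if alen else 0.0,
    )


def _normalize_reference(
    reference_set: Sequence[Union[str, tuple[str, str]]]
) -> list[tuple[str, str]]:
    out = []
    for i, item in enumerate(reference_set):
        if isinstance(item, str):
            out.append((f"ref{i + 1}", item.upper()))
        else:
            name, seq = item
            out.append((str(name), seq.upper()))
    return out


def best_reference_hit(
    sequence: str, reference: Sequence[tuple[str, str]]
) -> tuple[AlignmentResult | None, str | None]:
    """Best local alignment of a peptide against a reference set.

    Hits are ranked by score, then identical matches, then reference
    order; a peptide with no positive-scoring alignment has no hit.
    """
    best: AlignmentResult | None = None
    best_name: str | None = None
    for name, ref_seq in reference:
        res = local_align(sequence, ref_seq)
        if res.alignment_length == 0:
            continue
        if best is None or (res.score, res.n_identical) > (best.score, best.n_identical):
            best, best_name = res, name
    return best, best_name


def screen_candidates(
    candidates: Sequence[BindingPrediction],
    reference_set: Sequence[Union[str, tuple[str, str]]],
    identity_threshold: float = 60.0,
) -> list[NeoantigenRecord]:
    """Screen rank-filtered candidates against the immunogenic reference.

    ``high_confidence`` is set iff the best hit's percent identity
    strictly exceeds ``identity_threshold``.  Records are sorted by
    percentile rank, then descending identity.
    """
    if not reference_set:
        raise ConfigurationError("reference peptide set must be non-empty")
    reference = _normalize_reference(reference_set)
    records = []
    align_cache: dict[str, tuple[AlignmentResult | None, str | None]] = {}
    for cand in candidates:
        seq = cand.kmer.sequence
        if seq not in align_cache:
            align_cache[seq] = best_reference_hit(seq, reference)
        hit, name = align_cache[seq]
        high = hit is not None and hit.percent_identity > identity_threshold
        entry = cand.kmer.parent.mutant_entry if cand.kmer.parent else None
        records.append(
            NeoantigenRecord(
                candidate=cand,
                best_hit=hit,
                matched_reference=name if hit else None,
                high_confidence=high,
                variant_id=entry.variant_id if entry else "",
                gene=entry.gene if entry else "",
                sample_id=entry.sample_id if entry else "",
            )
        )
    records.sort(
        key=lambda r: (
            r.candidate.percentile_rank,
            -(r.best_hit.percent_identity if r.best_hit else 0.0),
            r.candidate.kmer.sequence,
            r.candidate.allele,
        )
    )
    return records


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact null distribution when both groups have ≤ 10 observations and
    no cross-group ties; normal approximation with tie correction
    otherwise.  Returns (U statistic, p-value).
    """
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must contain at least one observation")
    pooled = list(x) + list(y)
    has_ties = len(set(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class EvaluationSummary:
    """Positive-vs-random similarity evaluation of candidate groups."""

    positive_proportions: tuple[float, ...]
    random_proportions: tuple[float, ...]
    group_ids: tuple[str, ...]
    statistic: float
    p_value: float


def evaluate_positive_vs_random(
    grouped_candidates: Mapping[str, Sequence[str]],
    positive_set: Sequence[Union[str, tuple[str, str]]],
    random_set: Sequence[Union[str, tuple[str, str]]],
    identity_threshold: float = 60.0,
    evalue_max: float = 0.5,
    similar: Callable[[str, Sequence[tuple[str, str]]], bool] | None = None,
) -> EvaluationSummary:
    """Compare candidate similarity to immunogenic vs random peptides.

    For each group (typically one sample) the proportion of candidates
    similar to the positive set and to the random set is computed; the
    two proportion vectors are compared with a two-sided Wilcoxon
    rank-sum test.  With the native aligner "similar" means best-hit
    identity strictly above ``identity_threshold``; ``evalue_max``
    applies only when a caller supplies a ``similar`` function backed by
    an external search that reports E-values.
    """
    if not positive_set or not random_set:
        raise ConfigurationError("positive and random sets must be non-empty")
    if not grouped_candidates:
        raise ConfigurationError("at least one candidate group is required")

    pos = _normalize_reference(positive_set)
    rnd = _normalize_reference(random_set)

    if similar is None:

        def similar(seq: str, refs: Sequence[tuple[str, str]]) -> bool:
            hit, _ = best_reference_hit(seq, refs)
            return hit is not None and hit.percent_identity > identity_threshold

    group_ids = tuple(grouped_candidates)
    pos_props, rnd_props = [], []
    for gid in group_ids:
        seqs = [s.upper() for s in grouped_candidates[gid]]
        if not seqs:
            raise ConfigurationError(f"group {gid!r} has no candidates")
        pos_props.append(sum(similar(s, pos) for s in seqs) / len(seqs))
        rnd_props.append(sum(similar(s, rnd) for s in seqs) / len(seqs))

    stat, p = rank_sum_test(pos_props, rnd_props)
    return EvaluationSummary(
        positive_proportions=tuple(pos_props),
        random_proportions=tuple(rnd_props),
        group_ids=group_ids,
        statistic=stat,
        p_value=p,
    )


BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def parse_blast_outfmt6(path: Union[str, Path]) -> pd.DataFrame:
    """Parse BLASTp ``-outfmt 6`` tabular output (12 standard columns)."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")


def blast_similarity(
    path: Union[str, Path],
    identity_threshold: float = 60.0,
    evalue_max: float = 0.5,
) -> dict[str, bool]:
    """Per-query similarity verdicts from external BLASTp output.

    A query is similar when any hit has identity strictly above the
    threshold and an E-value strictly below ``evalue_max``.
    """
    df = parse_blast_outfmt6(path)
    ok = df[(df["pident"] > identity_threshold) & (df["evalue"] < evalue_max)]
    verdicts = {q: False for q in df["qseqid"].astype(str)}
    for q in ok["qseqid"].astype(str):
        verdicts[q] = True
    return verdicts
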