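"""Independent brute-force oracles used to pin down expected values.

These deliberately re-derive each operation from first principles (and
through Biopython where possible) so they share no code with the package
implementations they check.
"""

from Bio.Align import substitution_matrices
from Bio.Seq import Seq


def sixframe_peptides_bruteforce(mut_window, mut_interval, min_length=7):
    """All stop-free, mutation-containing fragments of all six frames.

    Returns a set of (frame, fragment_start, sequence, mutated_offsets).
    """
    seq = mut_window.upper()
    L = len(seq)
    a, b = mut_interval
    mutated_nt = set(range(a, b))
    rc = str(Seq(seq).reverse_complement())

    out = set()
    for frame in (1, 2, 3, -1, -2, -3):
        s = abs(frame) - 1
        src = seq if frame > 0 else rc
        coding = src[s : s + (L - s) // 3 * 3]
        aa = str(Seq(coding).translate(table=1))
        # residue r reads source positions s+3r .. s+3r+2; a minus-frame
        # source position p sits at original coordinate L-1-p
        mutated_res = set()
        for r in range(len(aa)):
            positions = {s + 3 * r + j for j in range(3)}
            if frame < 0:
                positions = {L - 1 - p for p in positions}
            if positions & mutated_nt:
                mutated_res.add(r)
        # fragment on stops
        start = 0
        for i, ch in enumerate(aa + "*"):
            if ch == "*":
                frag = aa[start:i]
                offsets = frozenset(m - start for m in mutated_res if start <= m < i)
                if frag and offsets and len(frag) >= min_length:
                    out.add((frame, start, frag, offsets))
                start = i + 1
    return out


def digest_bruteforce(sequence, max_missed=2, min_length=7):
    """All substrings whose boundaries satisfy the tryptic cleavage rule.

    Returns a set of (start, peptide).
    """

    def cut_after(k):  # cleavage between k and k+1
        return sequence[k] in "KR" and (
            k + 1 == len(sequence) or sequence[k + 1] != "P"
        )

    L = len(sequence)
    out = set()
    for i in range(L):
        if not (i == 0 or cut_after(i - 1)):
            continue
        for j in range(i + 1, L + 1):
            if not (j == L or cut_after(j - 1)):
                continue
            missed = sum(1 for k in range(i, j - 1) if cut_after(k))
            if missed <= max_missed and j - i >= min_length:
                out.add((i, sequence[i:j]))
    return out


def kmer_windows_bruteforce(length, mutated_positions, kmin=8, kmax=11):
    """All (k, start) windows containing a mutated position."""
    out = set()
    for k in range(kmin, kmax + 1):
        for start in range(0, length - k + 1):
            if any(start <= m < start + k for m in mutated_positions):
                out.add((k, start))
    return out


def sw_bruteforce(query, target, gap_open=11, gap_extend=1):
    """Reference Gotoh local-alignment DP: (score, max identities).

    Forward dynamic program tracking, for every optimal decomposition,
    the maximum number of identical aligned pairs; gap of length L costs
    gap_open + (L-1) * gap_extend.
    """
    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(query), len(target)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    IM = [[0] * (m + 1) for _ in range(n + 1)]
    IX = [[0] * (m + 1) for _ in range(n + 1)]
    IY = [[0] * (m + 1) for _ in range(n + 1)]

    def argbest(cands):
        score = max(c[0] for c in cands)
        ident = max(c[1] for c in cands if c[0] == score)
        return score, ident

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j], IX[i][j] = argbest(
                [
                    (M[i - 1][j] - gap_open, IM[i - 1][j]),
                    (X[i - 1][j] - gap_extend, IX[i - 1][j]),
                ]
            )
            Y[i][j], IY[i][j] = argbest(
                [
                    (M[i][j - 1] - gap_open, IM[i][j - 1]),
                    (Y[i][j - 1] - gap_extend, IY[i][j - 1]),
                ]
            )
            s = float(mat[query[i - 1], target[j - 1]])
            ident = 1 if query[i - 1] == target[j - 1] else 0
            cands = [(0.0, 0)]
            if M[i - 1][j - 1] > 0:
                cands.append((M[i - 1][j - 1], IM[i - 1][j - 1]))
            if X[i - 1][j - 1] > NEG / 2:
                cands.append((X[i - 1][j - 1], IX[i - 1][j - 1]))
            if Y[i - 1][j - 1] > NEG / 2:
                cands.append((Y[i - 1][j - 1], IY[i - 1][j - 1]))
            prev, prev_id = argbest(cands)
            if s + prev > 0:
                M[i][j] = s + prev
                IM[i][j] = ident + prev_id
            else:
                M[i][j] = 0.0
                IM[i][j] = 0

    best = max(M[i][j] for i in range(n + 1) for j in range(m + 1))
    if best <= 0:
        return 0.0, 0
    nid = max(
        IM[i][j]
        for i in range(n + 1)
        for j in range(m + 1)
        if M[i][j] == best
    )
    return best, nid
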