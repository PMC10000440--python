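"""Local alignment, homology screening and positive-vs-random evaluation."""

import random

import pytest

from noncneo.binding import BindingPrediction, KmerCandidate
from noncneo.errors import AlphabetError, ConfigurationError
from noncneo.similarity import (
    blast_similarity,
    evaluate_positive_vs_random,
    local_align,
    rank_sum_test,
    screen_candidates,
)
from oracles import sw_bruteforce

AA = "ACDEFGHIKLMNPQRSTVWY"


def candidate(seq, rank=0.5, allele="HLA-A*02:01"):
    return BindingPrediction(
        kmer=KmerCandidate(seq, None, 0, frozenset({0})),
        allele=allele,
        percentile_rank=rank,
        bind_level="SB" if rank < 0.5 else "WB",
    )


class TestLocalAlign:
    def test_self_alignment_is_100_percent(self):
        r = local_align("KTDAQAISL", "KTDAQAISL")
        assert r.percent_identity == 100.0
        assert r.n_identical == r.alignment_length == 9

    def test_single_mismatch_nine_mer(self):
        r = local_align("AAAAAAAAA", "AAAAAAAAT")
        assert (r.n_identical, r.alignment_length) == (8, 9)
        assert r.percent_identity == pytest.approx(88.9, abs=0.05)

    def test_no_positive_alignment(self):
        r = local_align("AAAA", "WWWW")
        assert r.score == 0
        assert r.alignment_length == 0
        assert r.percent_identity == 0.0

    def test_alphabet_checked(self):
        with pytest.raises(AlphabetError):
            local_align("AAAB", "AAAA")
        with pytest.raises(AlphabetError):
            local_align("", "AAAA")

    def test_score_symmetric_for_swapped_arguments(self):
        rnd = random.Random(5)
        for _ in range(50):
            q = "".join(rnd.choice(AA) for _ in range(rnd.randint(4, 11)))
            t = "".join(rnd.choice(AA) for _ in range(rnd.randint(4, 11)))
            assert local_align(q, t).score == local_align(t, q).score

    def test_identity_invariant_under_nonaligning_flanks(self):
        r0 = local_align("KTDAQAISL", "KTDAQAISL")
        r1 = local_align("KTDAQAISL", "WWKTDAQAISLWW")
        assert r1.percent_identity == r0.percent_identity
        assert r1.n_identical == r0.n_identical

    def test_matches_reference_dp_on_random_pairs(self):
        rnd = random.Random(42)
        for _ in range(200):
            q = "".join(rnd.choice(AA) for _ in range(rnd.randint(2, 11)))
            t = "".join(rnd.choice(AA) for _ in range(rnd.randint(2, 11)))
            got = local_align(q, t)
            score, nid = sw_bruteforce(q, t)
            assert got.score == score, (q, t)
            assert got.n_identical == nid, (q, t)


class TestScreenCandidates:
    REFS = [("hit", "KTDAQAISL"), ("other", "WWWWYYYYW")]

    def test_exact_duplicate_is_high_confidence(self):
        (rec,) = screen_candidates([candidate("KTDAQAISL")], self.REFS)
        assert rec.high_confidence
        assert rec.best_hit.percent_identity == 100.0
        assert rec.matched_reference == "hit"

    def test_six_of_nine_identities_pass(self):
        # three substitutions -> full-length alignment, 6/9 = 66.7% > 60
        (rec,) = screen_candidates([candidate("KTDAMMMSL")], self.REFS)
        assert rec.matched_reference == "hit"
        assert rec.best_hit.n_identical == 6
        assert rec.best_hit.percent_identity == pytest.approx(66.7, abs=0.05)
        assert rec.high_confidence

    def test_five_of_nine_identities_fail(self):
        # four substitutions -> best alignment has at most 5/9 = 55.6%
        (rec,) = screen_candidates([candidate("KTDAQMMMM")], self.REFS)
        if rec.best_hit is not None and rec.best_hit.alignment_length == 9:
            assert rec.best_hit.percent_identity == pytest.approx(55.6, abs=0.05)
            assert not rec.high_confidence

    def test_threshold_100_keeps_only_exact(self):
        cands = [candidate("KTDAQAISL"), candidate("KTDAQAISW")]
        recs = screen_candidates(cands, self.REFS, identity_threshold=100.0)
        hc = [r for r in recs if r.high_confidence]
        assert hc == []
        recs0 = screen_candidates(cands, self.REFS, identity_threshold=0.0)
        assert all(r.high_confidence for r in recs0 if r.best_hit)

    def test_monotone_in_threshold(self):
        cands = [candidate("KTDAQAISL"), candidate("KTDAWWWSL"), candidate("WWWWWWWWC")]
        lo = {id(r.candidate) for r in screen_candidates(cands, self.REFS, 50.0) if r.high_confidence}
        hi = {id(r.candidate) for r in screen_candidates(cands, self.REFS, 90.0) if r.high_confidence}
        assert hi <= lo

    def test_empty_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            screen_candidates([candidate("KTDAQAISL")], [])

    def test_sorted_by_rank_then_identity(self):
        cands = [candidate("KTDAWWWSL", rank=1.5), candidate("KTDAQAISL", rank=0.1)]
        recs = screen_candidates(cands, self.REFS)
        assert [r.candidate.percentile_rank for r in recs] == [0.1, 1.5]


class TestRankSumTest:
    def test_exact_separated_groups(self):
        stat, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_distributions(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_minimal_p_for_dominating_groups(self):
        # complete separation of two groups of 4: exact two-sided
        # p = 2 / C(8,4) = 2/70
        _, p = rank_sum_test([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestEvaluatePositiveVsRandom:
    def test_engineered_separation(self):
        groups = {
            "s1": ["KTDAQAISL", "WWWWWWWWW"],
            "s2": ["KTDAQAISL", "KTDAQAISL", "CCCCCCCCC"],
            "s3": ["KTDAQAISW", "MMMMMMMMM", "HHHHHHHHH"],
        }
        positive = [("p1", "KTDAQAISL")]
        # glycine homopolymer scores non-positively against every
        # candidate residue used above, so no random hit exists
        rand = [("r1", "GGGGGGGGG")]
        summary = evaluate_positive_vs_random(groups, positive, rand)
        assert summary.positive_proportions == (0.5, 2 / 3, 1 / 3)
        assert summary.random_proportions == (0.0, 0.0, 0.0)
        assert 0 < summary.p_value < 0.2

    def test_empty_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate_positive_vs_random({"s1": ["KTDAQAISL"]}, [], [("r", "AAAA")])
        with pytest.raises(ConfigurationError):
            evaluate_positive_vs_random({}, [("p", "AAAA")], [("r", "AAAA")])


class TestBlastAdapter:
    def test_similarity_verdicts(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "pepA\tref1\t77.8\t9\t2\t0\t1\t9\t1\t9\t0.01\t25.0\n"
            "pepB\tref2\t55.6\t9\t4\t0\t1\t9\t1\t9\t0.02\t18.0\n"
            "pepC\tref3\t88.9\t9\t1\t0\t1\t9\t1\t9\t0.9\t30.0\n"
        )
        verdicts = blast_similarity(p)
        # pepA: identity and E-value pass; pepB fails identity;
        # pepC fails the E-value < 0.5 condition
        assert verdicts == {"pepA": True, "pepB": False, "pepC": False}
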