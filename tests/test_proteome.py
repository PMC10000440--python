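"""Database construction, tryptic digestion, decoys and MS matching."""

import io
import random
from collections import Counter

import pandas as pd
import pytest

from noncneo.errors import AnnotationFormatError
from noncneo.proteome import (
    DatabaseEntry,
    IdentifiedPeptide,
    build_custom_database,
    digest_tryptic,
    generate_reversed_tryptic_decoys,
    match_identified_to_mutant,
    parse_identified_peptides,
    pseudo_reverse,
)
from noncneo.translate import MutantPeptide
from oracles import digest_bruteforce


def mutant(seq, vid="v1", frame=1, start=0, offsets=(0,)):
    return MutantPeptide(
        sequence=seq,
        variant_id=vid,
        frame=frame,
        fragment_start=start,
        mutated_offsets=frozenset(offsets),
    )


REF = [DatabaseEntry("sp|REF001", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "reference")]
CON = [DatabaseEntry("CON|cRAP001", "KWVTFISLLFLFSSAYS", "contaminant")]


class TestBuildCustomDatabase:
    def test_section_counts(self):
        db = build_custom_database(
            REF * 1 + [DatabaseEntry("sp|REF002", "AAAAAAA", "reference")],
            CON,
            [mutant("LLLLLLK"), mutant("WWWWWWW", vid="v2"), mutant("YYYYYYY", vid="v3")],
        )
        assert len(db) == 6
        assert Counter(e.origin for e in db) == {
            "reference": 2,
            "contaminant": 1,
            "mutant": 3,
        }

    def test_mutant_dedup_by_sequence(self):
        db = build_custom_database(
            REF,
            CON,
            [
                mutant("LLLLLLK"),
                mutant("LLLLLLK", vid="v2"),
                mutant("YYYYYYY", start=9),
            ],
        )
        assert len(db) == 4

    def test_empty_mutant_set(self):
        db = build_custom_database(REF, CON, [])
        assert [e.origin for e in db] == ["reference", "contaminant"]

    def test_x_containing_peptides_excluded(self):
        with pytest.warns(UserWarning, match="X"):
            db = build_custom_database(REF, CON, [mutant("LLXLLLL")])
        assert all(e.origin != "mutant" for e in db)

    def test_duplicate_accessions_renamed(self):
        ref2 = REF + [DatabaseEntry("sp|REF001", "CCCCCCC", "reference")]
        with pytest.warns(UserWarning, match="duplicate accession"):
            db = build_custom_database(ref2, [], [])
        assert len({e.accession for e in db}) == 2

    def test_deterministic(self):
        args = (REF, CON, [mutant("LLLLLLK"), mutant("YYYYYYY", vid="v2")])
        assert build_custom_database(*args) == build_custom_database(*args)


class TestDigestTryptic:
    def test_enumerated_example(self):
        got = {p.sequence for p in digest_tryptic("AAAKBBBRCCC", 2, 3)}
        assert got == {"AAAK", "BBBR", "CCC", "AAAKBBBR", "BBBRCCC", "AAAKBBBRCCC"}

    def test_kp_rule_blocks_cleavage(self):
        got = {p.sequence for p in digest_tryptic("AAKPBBR", 2, 1)}
        assert got == {"AAKPBBR"}

    def test_single_residue_peptides(self):
        got = [p.sequence for p in digest_tryptic("KRK", 0, 1)]
        assert got == ["K", "R", "K"]

    def test_missed_cleavage_counts(self):
        peps = digest_tryptic("AAAKBBBRCCC", 2, 3)
        missed = {p.sequence: p.missed_cleavages for p in peps}
        assert missed["AAAKBBBR"] == 1
        assert missed["AAAKBBBRCCC"] == 2

    def test_matches_bruteforce_on_random_sequences(self):
        rnd = random.Random(3)
        alphabet = "ACDEFGHIKLMNPQRSTVWYKRP"  # K/R/P enriched
        for _ in range(100):
            seq = "".join(rnd.choice(alphabet) for _ in range(rnd.randint(1, 30)))
            mm = rnd.randint(0, 3)
            ml = rnd.randint(1, 8)
            got = {(p.start, p.sequence) for p in digest_tryptic(seq, mm, ml)}
            assert got == digest_bruteforce(seq, mm, ml)


class TestDecoys:
    def test_pseudo_reverse_segments(self):
        assert pseudo_reverse("MABCKDEFR") == "CBAMKFEDR"
        assert pseudo_reverse("AAAA") == "AAAA"
        assert pseudo_reverse("MABCKDEF") == "CBAMKFED"  # last segment no K/R

    def test_decoy_bijection_and_composition(self):
        targets = [
            DatabaseEntry("a", "MKTAYIAKQRQISFVK", "reference"),
            DatabaseEntry("b", "SHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK", "reference"),
        ]
        decoys = generate_reversed_tryptic_decoys(targets)
        assert len(decoys) == len(targets)
        for t, d in zip(targets, decoys):
            assert d.accession == "REV_" + t.accession
            assert len(d.sequence) == len(t.sequence)
            assert Counter(d.sequence) == Counter(t.sequence)
            assert d.origin == "decoy"

    def test_decoys_preserve_cleavage_sites(self):
        seq = "MABCKDEFRGH"
        decoy = pseudo_reverse(seq)
        assert [i for i, c in enumerate(seq) if c in "KR"] == [
            i for i, c in enumerate(decoy) if c in "KR"
        ]


MSTABLE = (
    "Sequence\tProteins\tScore\tReverse\tPotential contaminant\n"
    "LLLLLLK\tMUT|v1\t80.1\t\t\n"
    "aaaawaaak\tMUT|v2\t70.0\t\t\n"
    "KLLLLLL\tREV_x\t30.0\t+\t\n"
    "WWWWWWW\tCON_1\t55.0\t\t+\n"
    "YYYYYYY\tMUT|v3\t60.0\t\t\n"
)


class TestParseIdentifiedPeptides:
    def test_flagged_rows_dropped_and_uppercased(self):
        out = parse_identified_peptides(
            pd.read_csv(io.StringIO(MSTABLE), sep="\t", dtype=str, keep_default_na=False)
        )
        assert [p.sequence for p in out] == ["LLLLLLK", "AAAAWAAAK", "YYYYYYY"]
        assert all(not p.is_reverse and not p.is_contaminant for p in out)

    def test_empty_table(self):
        df = pd.DataFrame(columns=["Sequence", "Proteins", "Reverse", "Potential contaminant"])
        assert parse_identified_peptides(df) == []

    def test_missing_sequence_column(self):
        with pytest.raises(AnnotationFormatError):
            parse_identified_peptides(pd.DataFrame({"Proteins": ["x"]}))


def entry(seq, offsets, acc="MUT|v1"):
    return DatabaseEntry(
        accession=acc, sequence=seq, origin="mutant",
        mutated_offsets=frozenset(offsets), variant_id="v1",
    )


class TestMatchIdentifiedToMutant:
    def test_full_length_match(self):
        (v,) = match_identified_to_mutant(
            [IdentifiedPeptide("LLLLLLK")], [entry("LLLLLLK", {2})]
        )
        assert v.match_offset == 0
        assert v.covered_mutated_offsets == {2}
        assert v.sequence in v.mutant_entry.sequence

    def test_match_window_must_overlap_mutation(self):
        out = match_identified_to_mutant(
            [IdentifiedPeptide("AAAK")], [entry("AAAAAWAAAK", {5})]
        )
        assert out == []  # match at offset 6 misses offset 5

    def test_reference_substring_excluded(self):
        ref = [DatabaseEntry("r", "XXXLLLLLLKZZZ".replace("X", "G").replace("Z", "A"), "reference")]
        out = match_identified_to_mutant(
            [IdentifiedPeptide("LLLLLLK")], [entry("LLLLLLK", {2})], reference_entries=ref
        )
        assert out == []

    def test_first_overlapping_occurrence_used(self):
        e = entry("AAAKZZAAAK".replace("Z", "W"), {7})
        (v,) = match_identified_to_mutant([IdentifiedPeptide("AAAK")], [e])
        assert v.match_offset == 6
        assert v.covered_mutated_offsets == {1}
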