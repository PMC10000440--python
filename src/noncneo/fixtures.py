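"""Deterministic synthetic inputs with known ground truth.

Every external input of the pipeline — reference genome, somatic VCF,
annotation table, reference proteome, contaminants, MS identification
table, HLA typings, binding-rank table and immunogenic reference
peptides — can be generated here from a seed, with the planted truth
(which variants survive filtering, which (k-mer, allele) pairs are
strong binders, which candidates must come out high-confidence)
recorded alongside.  This makes every stage and the end-to-end pipeline
testable offline.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np

from .binding import HlaTyping, enumerate_kmers
from .contexts import extract_contexts
from .errors import NoncneoError
from .proteome import (
    DatabaseEntry,
    digest_tryptic,
    match_identified_to_mutant,
    mutant_peptides_to_entries,
    parse_identified_peptides,
    pseudo_reverse,
)
from .translate import generate_all_mutant_peptides
from .variants import NONCODING_CATEGORIES, AnnotatedVariant, GenomicVariant

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Common class-I alleles used for synthetic typings.
HLA_POOL = (
    "HLA-A*02:01",
    "HLA-A*24:02",
    "HLA-A*33:03",
    "HLA-B*07:02",
    "HLA-B*15:01",
    "HLA-B*58:01",
    "HLA-C*03:04",
    "HLA-C*07:02",
)

_NONPASS_FILTERS = ("germline", "weak_evidence", "strand_bias")


def _rng(seed: int, salt: str) -> np.random.Generator:
    # independent stream per fixture component, stable across runs
    return np.random.default_rng([seed % 2**31, zlib.crc32(salt.encode())])


def make_toy_genome(seed: int, n_contigs: int = 2, length: int = 5000) -> dict[str, str]:
    """Seeded uniform A/C/G/T contigs named chr1..chrN."""
    if length < 300:
        raise ValueError("contig length must be >= 300")
    rng = _rng(seed, "genome")
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(rng.choice(bases, size=length))
        for i in range(n_contigs)
    }


def genome_fasta_text(genome: dict[str, str], width: int = 70) -> str:
    lines = []
    for name, seq in genome.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded while building a synthetic run."""

    variants: tuple[tuple[GenomicVariant, str], ...]  # (variant, func_category)
    expected_surviving: frozenset[str]  # variant_ids entering context extraction
    expected_peptides: frozenset[str] = frozenset()
    planted_binders: frozenset[tuple[str, str]] = frozenset()
    expected_high_confidence: frozenset[str] = frozenset()


def plant_variants(
    genome: dict[str, str],
    n_snv: int = 10,
    n_indel: int = 0,
    seed: int = 0,
    n_nonpass: int = 3,
    n_coding: int = 2,
    spacing: int = 250,
    sample_id: str = "S1",
) -> tuple[str, str, PlantedTruth]:
    """Plant variants into the genome; return VCF text, annotation TSV, truth.

    ``n_nonpass`` of the SNVs get a non-PASS FILTER and ``n_coding`` get
    an ``exonic`` (coding) category, so exactly
    ``n_snv - n_nonpass - n_coding + n_indel`` variants survive variant
    filtering.  Variants are spaced ≥ ``spacing`` nt apart so their
    contexts never overlap; REF is read from the genome so reference
    mismatches cannot occur.
    """
    if n_nonpass + n_coding > n_snv:
        raise ValueError("n_nonpass + n_coding cannot exceed n_snv")
    rng = _rng(seed, "variants")
    total = n_snv + n_indel

    slots: list[tuple[str, int]] = []  # (contig, 1-based pos)
    margin = 150
    for contig in sorted(genome):
        pos = margin
        while pos + margin < len(genome[contig]):
            slots.append((contig, pos + 1))
            pos += spacing
    if len(slots) < total:
        raise NoncneoError(
            f"genome too short: {len(slots)} variant slots for {total} variants"
        )
    chosen_idx = sorted(rng.choice(len(slots), size=total, replace=False))
    chosen = [slots[i] for i in chosen_idx]

    roles = ["nonpass"] * n_nonpass + ["coding"] * n_coding + [
        "noncoding"
    ] * (n_snv - n_nonpass - n_coding)
    rng.shuffle(roles)
    roles += ["indel"] * n_indel

    categories = sorted(NONCODING_CATEGORIES)
    bases = "ACGT"
    planted: list[tuple[GenomicVariant, str]] = []
    for i, ((contig, pos), role) in enumerate(zip(chosen, roles)):
        ref_base = genome[contig][pos - 1]
        if role == "indel":
            if i % 2 == 0:  # insertion
                ins = "".join(rng.choice(list(bases), size=2))
                ref, alt = ref_base, ref_base + ins
            else:  # anchor-base deletion of 2 nt
                ref = genome[contig][pos - 1 : pos + 2]
                alt = ref_base
        else:
            alt = bases[(bases.index(ref_base) + 1 + int(rng.integers(3))) % 4]
            ref = ref_base
        filt = (
            _NONPASS_FILTERS[i % len(_NONPASS_FILTERS)] if role == "nonpass" else "PASS"
        )
        category = (
            "exonic" if role == "coding" else categories[i % len(categories)]
        )
        from .variants import classify_allele_pair

        v = GenomicVariant(
            contig=contig,
            pos=pos,
            ref=ref,
            alt=alt,
            filter_status=filt,
            variant_class=classify_allele_pair(ref, alt),
            sample_id=sample_id,
        )
        planted.append((v, category))

    surviving = frozenset(
        v.variant_id
        for v, cat in planted
        if v.filter_status == "PASS" and cat in NONCODING_CATEGORIES
    )

    header = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
    ]
    header += [
        f'##FILTER=<ID={f},Description="synthetic non-PASS filter">'
        for f in _NONPASS_FILTERS
    ]
    header += [
        f"##contig=<ID={name},length={len(seq)}>" for name, seq in sorted(genome.items())
    ]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    body = [
        f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter_status}\t."
        for v, _ in sorted(planted, key=lambda p: (p[0].contig, p[0].pos))
    ]
    vcf_text = "\n".join(header + body) + "\n"

    ann_lines = ["Chr\tStart\tEnd\tRef\tAlt\tFunc\tGene"]
    for i, (v, cat) in enumerate(planted):
        end = v.pos + len(v.ref) - 1
        ann_lines.append(
            f"{v.contig}\t{v.pos}\t{end}\t{v.ref}\t{v.alt}\t{cat}\tGENE{i + 1}"
        )
    annotation_text = "\n".join(ann_lines) + "\n"

    truth = PlantedTruth(
        variants=tuple(planted), expected_surviving=surviving
    )
    return vcf_text, annotation_text, truth


def make_protein_entries(
    seed: int, n: int, length: int, prefix: str, origin: str, salt: str
) -> list[DatabaseEntry]:
    """Random protein entries (uniform over the 20 standard residues)."""
    rng = _rng(seed, salt)
    aa = np.array(list(_AA20))
    return [
        DatabaseEntry(
            accession=f"{prefix}{i + 1:03d}",
            sequence="".join(rng.choice(aa, size=length)),
            origin=origin,
        )
        for i in range(n)
    ]


def simulate_ms_table(
    mutant_entries: Sequence[DatabaseEntry],
    recall: float,
    seed: int,
    n_decoy_rows: int = 2,
    n_contaminant_rows: int = 2,
) -> str:
    """Simulate a search-engine peptide table (MaxQuant dialect).

    A fraction ``recall`` of the unique tryptic peptides (≤2 missed
    cleavages, length ≥7) that overlap a mutated position is emitted as
    identified rows; decoy rows (``Reverse='+'``) and contaminant rows
    are appended and must be dropped by downstream parsing.
    """
    if not 0 <= recall <= 1:
        raise ValueError("recall must be in [0, 1]")
    rng = _rng(seed, "ms")

    qualifying: dict[str, list[str]] = {}
    for e in mutant_entries:
        if e.origin != "mutant":
            continue
        for pep in digest_tryptic(e.sequence, max_missed=2, min_length=7):
            window = range(pep.start, pep.start + len(pep.sequence))
            if any(m in window for m in e.mutated_offsets):
                qualifying.setdefault(pep.sequence, []).append(e.accession)

    seqs = sorted(qualifying)
    k = round(recall * len(seqs))
    order = rng.permutation(len(seqs))
    chosen = sorted(seqs[i] for i in order[:k])

    lines = ["Sequence\tProteins\tScore\tReverse\tPotential contaminant"]
    for s in chosen:
        score = 40 + 60 * float(rng.random())
        lines.append(f"{s}\t{';'.join(sorted(set(qualifying[s])))}\t{score:.2f}\t\t")
    for s in chosen[:n_decoy_rows]:
        lines.append(f"{pseudo_reverse(s)}\tREV_decoy\t35.00\t+\t")
    aa = np.array(list(_AA20))
    for i in range(n_contaminant_rows):
        pep = "".join(rng.choice(aa, size=9))
        lines.append(f"{pep}\tCON_{i + 1}\t50.00\t\t+")
    return "\n".join(lines) + "\n"


def make_hla_typing(sample_id: str = "S1", n_alleles: int = 4, seed: int = 0) -> HlaTyping:
    rng = _rng(seed, "hla")
    idx = sorted(rng.choice(len(HLA_POOL), size=n_alleles, replace=False))
    return HlaTyping(sample_id=sample_id, alleles=tuple(HLA_POOL[i] for i in idx))


def mock_predictor(
    planted_binders: frozenset[tuple[str, str]], seed: int
) -> Callable[[str, str], float]:
    """Deterministic seeded %rank predictor.

    Planted (peptide, allele) pairs receive ranks in [0, 0.5) and all
    other pairs ranks ≥ 10, so planted pairs are strong binders and
    everything else is filtered out at the candidate threshold.
    """

    def rank(peptide: str, allele: str) -> float:
        h = zlib.crc32(f"{seed}|{peptide}|{allele}".encode()) / 2**32
        if (peptide, allele) in planted_binders:
            return 0.499 * h
        return 10.0 + 90.0 * h

    return rank


def engineer_reference_peptides(
    planted_kmers: Sequence[str], seed: int, n_unrelated: int = 20
) -> list[tuple[str, str]]:
    """Immunogenic reference set guaranteeing the planted screen outcome.

    Each planted k-mer gets a partner differing at two positions (so
    identity to its partner is at least (k−2)/k ≥ 75% > 60%), plus
    unrelated random 9-mers exercising the sub-threshold path.
    """
    rng = _rng(seed, "refset")
    out: list[tuple[str, str]] = []
    for i, kmer in enumerate(sorted(set(planted_kmers))):
        k = len(kmer)
        mutated = list(kmer)
        for pos in (k // 3, (2 * k) // 3):
            orig = mutated[pos]
            mutated[pos] = _AA20[(_AA20.index(orig) + 1 + int(rng.integers(18))) % 20]
        out.append((f"immuno_{i + 1:03d}", "".join(mutated)))
    aa = np.array(list(_AA20))
    for i in range(n_unrelated):
        out.append((f"unrelated_{i + 1:03d}", "".join(rng.choice(aa, size=9))))
    return out


@dataclass
class PlantedRun:
    """A complete synthetic run: all inputs plus the planted truth."""

    seed: int
    sample_id: str
    flank: int
    genome: dict[str, str]
    vcf_text: str
    annotation_text: str
    reference_entries: list[DatabaseEntry]
    contaminant_entries: list[DatabaseEntry]
    ms_table_text: str
    typing: HlaTyping
    reference_peptides: list[tuple[str, str]]
    predictor: Callable[[str, str], float]
    predictor_table: dict[tuple[str, str], float] = field(default_factory=dict)
    truth: PlantedTruth = None  # type: ignore[assignment]


def build_planted_run(
    seed: int,
    n_snv: int = 10,
    n_indel: int = 0,
    n_nonpass: int = 3,
    n_coding: int = 2,
    recall: float = 1.0,
    flank: int = 100,
    n_alleles: int = 4,
    sample_id: str = "S1",
) -> PlantedRun:
    """Assemble a full synthetic run with planted truth.

    The defaults plant ten SNVs of which three are non-PASS and two are
    coding decoys, so five variants enter context extraction.  With
    ``recall=1`` every qualifying tryptic peptide is identified; one
    (k-mer, allele) binder is planted per validated peptide, and the
    immunogenic reference set is engineered so that exactly the planted
    k-mers come out high-confidence.
    """
    genome = make_toy_genome(seed)
    vcf_text, annotation_text, truth = plant_variants(
        genome,
        n_snv=n_snv,
        n_indel=n_indel,
        seed=seed,
        n_nonpass=n_nonpass,
        n_coding=n_coding,
        sample_id=sample_id,
    )

    surviving = [
        AnnotatedVariant(variant=v, func_category=cat, gene=f"GENE{i + 1}")
        for i, (v, cat) in enumerate(truth.variants)
        if v.variant_id in truth.expected_surviving
    ]
    contexts = extract_contexts(genome, surviving, flank=flank)
    peptides = generate_all_mutant_peptides(contexts, min_length=7)
    mutant_entries = mutant_peptides_to_entries(peptides)

    # regenerate any reference/contaminant protein that collides with a
    # mutant peptide (would wrongly void its cancer specificity)
    mutant_seqs = [e.sequence for e in mutant_entries]

    def no_collision(entries: list[DatabaseEntry]) -> bool:
        return not any(
            pep in e.sequence for e in entries for pep in mutant_seqs
        )

    for attempt in range(5):
        reference_entries = make_protein_entries(
            seed + attempt, n=5, length=200, prefix="sp|REF", origin="reference",
            salt="refproteome",
        )
        if no_collision(reference_entries):
            break
    contaminant_entries = make_protein_entries(
        seed, n=2, length=120, prefix="CON|cRAP", origin="contaminant", salt="crap"
    )

    ms_table_text = simulate_ms_table(mutant_entries, recall=recall, seed=seed)
    typing = make_hla_typing(sample_id=sample_id, n_alleles=n_alleles, seed=seed)

    import io

    import pandas as pd

    identified = parse_identified_peptides(
        pd.read_csv(io.StringIO(ms_table_text), sep="\t", dtype=str, keep_default_na=False)
    )
    validated = match_identified_to_mutant(
        identified, mutant_entries, reference_entries=reference_entries
    )

    rng = _rng(seed, "binders")
    planted: set[tuple[str, str]] = set()
    for vp in validated:
        kmers = enumerate_kmers(vp)
        if not kmers:
            continue
        kmer = kmers[int(rng.integers(len(kmers)))]
        allele = typing.alleles[int(rng.integers(len(typing.alleles)))]
        planted.add((kmer.sequence, allele))

    planted_frozen = frozenset(planted)
    predictor = mock_predictor(planted_frozen, seed)
    reference_peptides = engineer_reference_peptides(
        [s for s, _ in planted_frozen], seed
    )

    # full rank table so a file-backed predictor can replay the run
    predictor_table: dict[tuple[str, str], float] = {}
    for vp in validated:
        for kmer in enumerate_kmers(vp):
            for allele in typing.alleles:
                key = (kmer.sequence, allele)
                predictor_table[key] = predictor(*key)

    truth = PlantedTruth(
        variants=truth.variants,
        expected_surviving=truth.expected_surviving,
        expected_peptides=frozenset(e.sequence for e in mutant_entries),
        planted_binders=planted_frozen,
        expected_high_confidence=frozenset(s for s, _ in planted_frozen),
    )
    return PlantedRun(
        seed=seed,
        sample_id=sample_id,
        flank=flank,
        genome=genome,
        vcf_text=vcf_text,
        annotation_text=annotation_text,
        reference_entries=reference_entries,
        contaminant_entries=contaminant_entries,
        ms_table_text=ms_table_text,
        typing=typing,
        reference_peptides=reference_peptides,
        predictor=predictor,
        predictor_table=predictor_table,
        truth=truth,
    )


def write_run(run: PlantedRun, outdir: Union[str, Path]) -> Path:
    """Write every input of a planted run as standard-format files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "genome.fa").write_text(genome_fasta_text(run.genome))
    (outdir / "variants.vcf").write_text(run.vcf_text)
    (outdir / "annotation.tsv").write_text(run.annotation_text)
    with open(outdir / "reference_proteome.fasta", "w") as fh:
        for e in run.reference_entries:
            fh.write(f">{e.accession}\n{e.sequence}\n")
    with open(outdir / "contaminants.fasta", "w") as fh:
        for e in run.contaminant_entries:
            fh.write(f">{e.accession}\n{e.sequence}\n")
    (outdir / "ms_peptides.tsv").write_text(run.ms_table_text)
    (outdir / "alleles.txt").write_text("\n".join(run.typing.alleles) + "\n")
    with open(outdir / "reference_peptides.fasta", "w") as fh:
        for name, seq in run.reference_peptides:
            fh.write(f">{name}\n{seq}\n")
    with open(outdir / "predictor_ranks.tsv", "w") as fh:
        fh.write("peptide\tallele\t%rank\n")
        for (pep, allele), rank in sorted(run.predictor_table.items()):
            fh.write(f"{pep}\t{allele}\t{rank:.6f}\n")
    truth_json = {
        "sample_id": run.sample_id,
        "seed": run.seed,
        "expected_surviving": sorted(run.truth.expected_surviving),
        "expected_peptides": sorted(run.truth.expected_peptides),
        "planted_binders": sorted(map(list, run.truth.planted_binders)),
        "expected_high_confidence": sorted(run.truth.expected_high_confidence),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
    return outdir
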