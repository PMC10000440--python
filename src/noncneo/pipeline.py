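"""End-to-end orchestration: variants → contexts → peptides → database →
MS validation → binding selection → homology screen → report."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import pandas as pd

from .binding import (
    BindingPrediction,
    HlaTyping,
    enumerate_kmers,
    filter_candidates,
    predict_binding,
)
from .contexts import MutantContext, extract_contexts
from .proteome import (
    DatabaseEntry,
    IdentifiedPeptide,
    ValidatedMutantPeptide,
    build_custom_database,
    match_identified_to_mutant,
    parse_identified_peptides,
)
from .similarity import NeoantigenRecord, screen_candidates
from .translate import MutantPeptide, generate_all_mutant_peptides
from .variants import AnnotatedVariant, filter_noncoding


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the pipeline (defaults are the standard run)."""

    flank: int = 100
    min_peptide_length: int = 7
    kmin: int = 8
    kmax: int = 11
    rank_threshold: float = 2.0
    sb_threshold: float = 0.5
    wb_threshold: float = 2.0
    identity_threshold: float = 60.0


@dataclass
class SampleRunResult:
    """Everything one sample's run produced, stage by stage."""

    sample_id: str
    noncoding: list[AnnotatedVariant]
    contexts: list[MutantContext]
    peptides: list[MutantPeptide]
    database: list[DatabaseEntry]
    identified: list[IdentifiedPeptide]
    validated: list[ValidatedMutantPeptide]
    predictions: list[BindingPrediction]
    candidates: list[BindingPrediction]
    records: list[NeoantigenRecord]
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def mutant_entries(self) -> list[DatabaseEntry]:
        return [e for e in self.database if e.origin == "mutant"]

    @property
    def high_confidence(self) -> list[NeoantigenRecord]:
        return [r for r in self.records if r.high_confidence]

    def counts(self) -> dict[str, int]:
        return {
            "noncoding_variants": len(self.noncoding),
            "mutant_peptides": len(self.mutant_entries),
            "validated_peptides": len(self.validated),
            "candidate_predictions": len(self.candidates),
            "high_confidence_neoantigens": len(self.high_confidence),
        }


def run_sample(
    genome,
    annotated_variants: Sequence[AnnotatedVariant],
    reference_entries: Sequence[DatabaseEntry],
    contaminant_entries: Sequence[DatabaseEntry],
    ms_table,
    typing: HlaTyping,
    predictor: Callable[[str, str], float],
    reference_peptides: Sequence,
    config: PipelineConfig | None = None,
) -> SampleRunResult:
    """Run the complete post-calling pipeline for one sample."""
    cfg = config or PipelineConfig()
    noncoding = filter_noncoding(annotated_variants)
    contexts = extract_contexts(genome, noncoding, flank=cfg.flank)
    peptides = generate_all_mutant_peptides(contexts, min_length=cfg.min_peptide_length)
    database = build_custom_database(reference_entries, contaminant_entries, peptides)
    mutant_entries = [e for e in database if e.origin == "mutant"]
    reference_db = [e for e in database if e.origin == "reference"]
    identified = parse_identified_peptides(ms_table)
    validated = match_identified_to_mutant(
        identified, mutant_entries, reference_entries=reference_db
    )
    kmers = [
        kmer
        for vp in validated
        for kmer in enumerate_kmers(vp, kmin=cfg.kmin, kmax=cfg.kmax)
    ]
    predictions = predict_binding(
        kmers, typing, predictor, sb=cfg.sb_threshold, wb=cfg.wb_threshold
    )
    candidates = filter_candidates(predictions, threshold=cfg.rank_threshold)
    records = screen_candidates(
        candidates, reference_peptides, identity_threshold=cfg.identity_threshold
    )
    return SampleRunResult(
        sample_id=typing.sample_id,
        noncoding=noncoding,
        contexts=contexts,
        peptides=peptides,
        database=database,
        identified=identified,
        validated=validated,
        predictions=predictions,
        candidates=candidates,
        records=records,
        config=cfg,
    )


def run_from_files(
    genome_fasta: Union[str, Path],
    vcf_path: Union[str, Path],
    annotation_path: Union[str, Path],
    reference_fasta: Union[str, Path],
    contaminant_fasta: Union[str, Path],
    ms_table_path: Union[str, Path],
    allele_list_path: Union[str, Path],
    reference_peptides_path: Union[str, Path],
    predictor: Union[Callable[[str, str], float], str, Path],
    sample_id: str,
    config: PipelineConfig | None = None,
) -> SampleRunResult:
    """File-based entry point mirroring :func:`run_sample`.

    ``predictor`` may be a callable or the path of a predictor output
    file (parsed with :func:`noncneo.binding.parse_netmhcpan_output`).
    """
    import pyfaidx

    from .binding import parse_netmhcpan_output, read_allele_list
    from .proteome import read_fasta_entries
    from .variants import join_annotations, parse_somatic_vcf

    genome = pyfaidx.Fasta(str(genome_fasta))
    variants = parse_somatic_vcf(vcf_path, sample_id=sample_id)
    annotated = join_annotations(variants, annotation_path)
    reference_entries = read_fasta_entries(reference_fasta, origin="reference")
    contaminant_entries = read_fasta_entries(contaminant_fasta, origin="contaminant")
    typing = read_allele_list(allele_list_path, sample_id=sample_id)
    reference_peptides = read_reference_peptides(reference_peptides_path)
    if not callable(predictor):
        predictor = parse_netmhcpan_output(predictor)
    return run_sample(
        genome,
        annotated,
        reference_entries,
        contaminant_entries,
        ms_table_path,
        typing,
        predictor,
        reference_peptides,
        config=config,
    )


def read_reference_peptides(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a reference peptide set (FASTA or one sequence per line)."""
    text = Path(path).read_text()
    out: list[tuple[str, str]] = []
    if text.lstrip().startswith(">"):
        name = None
        seq_parts: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(seq_parts).upper()))
                name = line[1:].split()[0]
                seq_parts = []
            elif line:
                seq_parts.append(line)
        if name is not None:
            out.append((name, "".join(seq_parts).upper()))
    else:
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if line and not line.startswith("#"):
                out.append((f"ref{i + 1}", line.upper()))
    return out


REPORT_COLUMNS = [
    "peptide",
    "allele",
    "percent_rank",
    "bind_level",
    "best_hit_reference",
    "percent_identity",
    "high_confidence",
    "gene",
    "variant_id",
    "sample_id",
]


def report_frame(records: Sequence[NeoantigenRecord]) -> pd.DataFrame:
    rows = [
        {
            "peptide": r.candidate.kmer.sequence,
            "allele": r.candidate.allele,
            "percent_rank": round(r.candidate.percentile_rank, 6),
            "bind_level": r.candidate.bind_level,
            "best_hit_reference": r.matched_reference or "",
            "percent_identity": round(r.best_hit.percent_identity, 3) if r.best_hit else 0.0,
            "high_confidence": r.high_confidence,
            "gene": r.gene,
            "variant_id": r.variant_id,
            "sample_id": r.sample_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(records: Sequence[NeoantigenRecord], path: Union[str, Path]) -> None:
    report_frame(records).to_csv(path, sep="\t", index=False)
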