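"""Per-sample and cohort summaries.

HLA allele frequencies over the sample population, candidate counts
normalized by the number of samples carrying each allele, items (peptide
sequences, genes) shared between samples, and per-sample counts at each
filtering stage of the pipeline.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .binding import BindingPrediction, HlaTyping
from .errors import ConfigurationError


@dataclass(frozen=True)
class AlleleSummary:
    allele: str
    carrier_count: int
    frequency: float
    candidate_count: int = 0
    normalized_count: float = 0.0


def _carriers(typings: Sequence[HlaTyping]) -> dict[str, set[str]]:
    carriers: dict[str, set[str]] = defaultdict(set)
    for t in typings:
        for a in t.alleles:
            carriers[a].add(t.sample_id)
    return carriers


def allele_frequencies(typings: Sequence[HlaTyping]) -> list[AlleleSummary]:
    """Allele frequencies over 2n chromosomes.

    Each sample contributes two chromosomes per locus; an allele listed
    twice in one typing (homozygote) counts twice.  Only observed
    alleles are reported, sorted by descending frequency then name.
    """
    if not typings:
        raise ConfigurationError("at least one sample typing is required")
    n = len(typings)
    occurrences: Counter[str] = Counter()
    for t in typings:
        occurrences.update(t.alleles)
    carriers = _carriers(typings)
    out = [
        AlleleSummary(
            allele=a,
            carrier_count=len(carriers[a]),
            frequency=occurrences[a] / (2 * n),
        )
        for a in occurrences
    ]
    out.sort(key=lambda s: (-s.frequency, s.allele))
    return out


def normalized_neoantigen_counts(
    candidates: Sequence[BindingPrediction],
    typings: Sequence[HlaTyping],
    per: str = "carriers",
) -> list[AlleleSummary]:
    """Candidate (peptide, allele) records per allele, carrier-normalized.

    ``normalized_count`` divides the allele's total candidate records by
    the number of samples carrying it (``per="carriers"``, default) or
    by its allele-copy count over the population (``per="copies"``).
    Output is sorted by descending normalized count, ties by allele name
    (the construction behind a top-10 most-bound-allele ranking).

    Raises
    ------
    ConfigurationError
        If a candidate's allele is carried by no sample.
    """
    if per not in ("carriers", "copies"):
        raise ValueError(f"per must be 'carriers' or 'copies', got {per!r}")
    carriers = _carriers(typings)
    copies: Counter[str] = Counter()
    for t in typings:
        copies.update(t.alleles)
    freqs = {s.allele: s for s in allele_frequencies(typings)}

    counts: Counter[str] = Counter(p.allele for p in candidates)
    for allele in counts:
        if allele not in carriers:
            raise ConfigurationError(
                f"candidate allele {allele} is carried by no typed sample"
            )
    out = []
    for allele, summ in freqs.items():
        denom = summ.carrier_count if per == "carriers" else copies[allele]
        out.append(
            AlleleSummary(
                allele=allele,
                carrier_count=summ.carrier_count,
                frequency=summ.frequency,
                candidate_count=counts.get(allele, 0),
                normalized_count=counts.get(allele, 0) / denom,
            )
        )
    out.sort(key=lambda s: (-s.normalized_count, s.allele))
    return out


def shared_items(
    per_sample_sets: Mapping[str, Iterable[str]], min_samples: int = 2
) -> dict[str, list[str]]:
    """Items present in at least ``min_samples`` samples, with carriers."""
    carriers: dict[str, list[str]] = defaultdict(list)
    for sample, items in per_sample_sets.items():
        for item in set(items):
            carriers[item].append(sample)
    return {
        item: sorted(samples)
        for item, samples in sorted(carriers.items())
        if len(samples) >= min_samples
    }


#: Pipeline stage names in filtering order.
STAGES = (
    "noncoding_variants",
    "mutant_peptides",
    "validated_peptides",
    "candidate_predictions",
    "high_confidence_neoantigens",
)


def stage_counts(run_states: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Per-sample counts at each pipeline stage as a tidy table.

    ``run_states`` maps sample_id to a mapping with the :data:`STAGES`
    keys (missing stages count as zero).
    """
    rows = []
    for sample_id in sorted(run_states):
        counts = run_states[sample_id]
        row = {"sample_id": sample_id}
        row.update({stage: int(counts.get(stage, 0)) for stage in STAGES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *STAGES])


def allele_summary_frame(summaries: Sequence[AlleleSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "allele": s.allele,
                "carrier_count": s.carrier_count,
                "frequency": s.frequency,
                "candidate_count": s.candidate_count,
                "normalized_count": s.normalized_count,
            }
            for s in summaries
        ],
        columns=["allele", "carrier_count", "frequency", "candidate_count", "normalized_count"],
    )
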