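# Methods

## Scope and model

`noncneo` implements the computational core of a proteogenomics workflow for
neoantigens from noncoding somatic variants. The working model is:

* A somatic variant in noncoding sequence can be transcribed and translated
  even without annotation; because no reading frame is known, all six frames
  of the ±100 nt mutant context are candidate protein products.
* A translated fragment is only of interest if (i) it contains at least one
  mutation-derived residue (otherwise it is not tumor-specific), (ii) it is
  free of stop codons, and (iii) it is long enough (≥ 7 aa) to be matched by
  an MS search engine.
* Protein-level evidence comes from an external search of tumor MS data
  against a customized database (reference proteome + contaminants + mutant
  peptides); this package builds that database and consumes the search's
  peptide table, trusting the engine's 1% FDR control and re-applying only
  flag-based decoy/contaminant exclusion.
* Immunogenicity is approximated in two stages: MHC class-I presentation
  (percentile rank of mutated 8–11-mers from a pluggable predictor,
  candidates at %rank < 2) and sequence similarity to experimentally
  validated immunogenic peptides (> 60% identical matches to a reference
  set; similar sequences are likelier to share structure and T-cell
  cross-reactivity).

External engines — read trimming, alignment, somatic calling, HLA typing,
annotation, the MS search itself, and the MHC predictor's neural network —
are out of scope by design; the package speaks their file formats instead.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `flank` | 100 nt | reference sequence taken on each side of the REF allele; covers every peptide of ≤ 33 aa containing the mutation in any frame |
| `min_peptide_length` | 7 aa | matches the MS search's minimum; shorter entries could never be confirmed |
| missed cleavages | ≤ 2 | standard tryptic search setting, mirrored by the in-silico digest |
| `kmin..kmax` | 8–11 | peptide lengths presented by MHC class I |
| `rank_threshold` | 2.0 | candidate cut on percentile rank, strict `<` |
| `sb`/`wb` | 0.5 / 2.0 | strong/weak binder labels, the conventional predictor cutoffs |
| `identity_threshold` | 60.0% | homology-screen cut, strict `>` , denominator = alignment length |
| gap open / extend | 11 / 1 | BLOSUM62 affine gap costs; a gap of length L costs 11 + (L−1) |

All are keyword/CLI-configurable; defaults are the standard run.

## Coordinate and substitution conventions

VCF input is 1-based with anchor-base indels; internally coordinates are
0-based half-open. Multi-allelic records are split per ALT, each inheriting
the record FILTER. The context window spans `flank` bases left of the first
REF base through `flank` bases right of the last REF base, clipped (not
padded) at contig ends; soft-masked genome bases are uppercased. The mutated
interval covers the ALT bases; for a pure anchor-base deletion it spans the
junction (anchor + first base past the join, when present), because that is
where a deletion creates novel sequence. Contexts shorter than one codon are
dropped with a warning. Each variant yields an independent context; nearby
variants are not phased together.

## Translation and fragmentation

Translation uses the standard genetic code. Stop codons become `*` and
fragments are the maximal `*`-free substrings. Codons containing N translate
to `X`; `X` is kept as an ordinary residue during generation but any peptide
containing `X` is excluded at database construction, since search engines
cannot match it. Identical peptide sequences arising from several frames are
emitted once with merged provenance; across variants, the database builder
deduplicates by sequence (first-seen provenance names the entry) so the
search database carries no redundant entries.

## Decoys and digestion

Decoy generation is pseudo-reversal: the sequence is cut into tryptic
segments (after K/R unless before P), each segment is reversed with its
C-terminal K/R left anchored, and a terminal segment without K/R is fully
reversed. This preserves length, composition and cleavage-site positions —
the properties FDR estimation relies on. The digestion routine is written
in-package (the cleavage rule here is exactly after-K/R-not-before-P, with
no further exceptions) and is checked against a substring brute-force oracle
in the tests.

## MS matching and cancer specificity

An identified peptide validates a mutant entry iff it occurs as a substring
whose window overlaps ≥ 1 mutated offset; the first overlapping occurrence
is reported per (peptide, entry) pair. Peptides that also occur verbatim
inside any reference protein are excluded: presence in the normal proteome
voids the cancer-specific claim.

## Binding selection

Unique (sequence, allele) pairs are scored once and fanned back out to every
k-mer occurrence, so a peptide arising from several parents is predicted
once but traced to each. Predictor failures for a pair are logged and the
pair is skipped. Two predictor backends ship with the package: a parser for
predictor output tables (a peptide/allele/%rank TSV or the NetMHCpan 4.1
long text format) and a seeded mock for offline testing whose planted pairs
score < 0.5 and all others ≥ 10.

## Homology screen

Because queries are 8–11-mers, heuristic seeded search (BLAST) is
unnecessary; an exact Smith–Waterman with BLOSUM62 and affine gaps decides
the identity rule, removing an external dependency from the decision path.
Among equal-scoring optima the alignment with the most identical matches is
reported, ties broken by smallest query/target start and then by longest
extent (so a terminal mismatch column that costs nothing is included — a
9-mer differing at one position reports 8/9 = 88.9%, not a trimmed 8/8).
The native aligner computes no E-value: Karlin–Altschul calibration for
short peptides is deliberately out of scope, so the native decision uses
identity alone, while the adapter for external BLASTp tabular output
(`-outfmt 6`) applies both the identity and the E-value < 0.5 condition.
One consequence of score-ranked best hits worth knowing: two peptides
sharing even a single residue admit a one-column alignment at 100% identity,
so the native screen against an arbitrary reference set is permissive for
unrelated sequences; with curated immunogenic sets the intended long
alignments dominate by score, and the external-BLAST route's E-value filter
removes such trivial hits entirely.

The positive-vs-random evaluation computes, per sample group, the proportion
of candidates similar to an immunogenic ("positive") set and to a random
background set, and compares the two proportion vectors with a two-sided
Wilcoxon rank-sum test — exact null distribution when both groups have ≤ 10
observations without cross-group ties, normal approximation with tie
correction otherwise.

## Reporting conventions

Allele frequencies are computed per locus over 2n chromosomes (a homozygote
counts twice). Neoantigen counts per allele are normalized by the number of
**carrier samples** by default; dividing by allele copies instead is
available via a flag, since either reading of "normalizing by the allele
count" is defensible. Ties in ranked outputs break by allele name, making
every table deterministic.

## Synthetic data: what it emulates and what it does not

The fixtures module emulates the *shape* of every input: uniform-composition
contigs, planted SNVs/indels spaced ≥ 250 nt apart (so contexts never
overlap), a mix of `PASS`/non-`PASS` filters and noncoding/coding categories
with known counts, a MaxQuant-style peptide table at a chosen recall with
flagged decoy and contaminant rows, class-I typings drawn from common
alleles, a deterministic rank table with planted strong binders, and an
immunogenic reference set engineered so that each planted k-mer has a
partner at ≥ 75% identity while unrelated entries stay below threshold by
score. The standard conditions plant ten SNVs (three non-`PASS`, two coding
decoys → five survivors) at full MS recall.

It does **not** emulate realistic mutation signatures, read-level noise,
spectra, search-engine scoring, or true MHC binding physics. Passing tests
therefore demonstrate the correctness of the bookkeeping, filtering rules,
and decision thresholds — not the biological accuracy of predictions on
real cohorts, which depends entirely on the external engines plugged in.

## Determinism

Every generator consumes a seed through independent named streams, all
outputs are written in deterministic order, and repeated runs with the same
seed are byte-identical — verified end to end in the test suite.

## Known limitations

* One variant per context: co-occurring nearby somatic variants are not
  combined into a single mutant haplotype.
* The native screen reports no E-value (see above); use the BLASTp adapter
  when E-value control matters.
* The `splicing` category is treated like every other noncoding category;
  no transcript-aware handling of splice-affecting variants is attempted.
* Modification-aware search settings (fixed/variable modifications) concern
  the external engine only and have no counterpart here.
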