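# noncneo

Proteogenomics discovery of candidate neoantigens arising from **noncoding**
somatic variants.

Most neoantigen prediction pipelines look only at protein-coding exons, yet
the overwhelming majority of somatic mutations in tumors fall in noncoding
sequence — introns, UTRs, ncRNA exons, intergenic and up/downstream regions —
and peptides translated from such regions are known to be presented by MHC
class I. For tumor types with a low coding mutational burden (e.g.
hepatocellular carcinoma) noncoding variants may be the main source of
targetable tumor-specific antigens. `noncneo` implements the bespoke
computational stages of such a proteogenomics workflow; the heavyweight
external engines (aligner, variant caller, MS search engine, MHC binding
predictor) stay external and are abstracted behind standard file formats and
pluggable interfaces.

## What the pipeline computes

Starting from somatic calls (VCF, `PASS`-filtered), a functional annotation
table and an indexed reference genome:

1. **Variant selection** — keep `PASS` somatic SNVs/indels whose annotation
   category is one of the ten noncoding compartments (`downstream`,
   `intergenic`, `intronic`, `ncRNA_exonic`, `ncRNA_intronic`,
   `ncRNA_splicing`, `splicing`, `upstream`, `UTR3`, `UTR5`).
2. **Context extraction** — take 100 nt of reference sequence on each side of
   the mutation, substitute REF → ALT, and track the mutated interval.
3. **Peptide generation** — translate each mutant context in all six reading
   frames (noncoding sequence has no annotated frame), replace stops with
   `*`, split on `*`, map mutated nucleotides to residues, and keep stop-free
   fragments that contain a mutated residue and are ≥ 7 aa (the minimum an MS
   search will match).
4. **Custom search database** — reference proteome + laboratory contaminants
   (cRAP) + the mutant peptides, optionally with pseudo-reversed tryptic
   decoys (per-segment reversal keeping C-terminal K/R anchored). In-silico
   tryptic digestion follows cleave-after-K/R-not-before-P with up to two
   missed cleavages.
5. **MS validation** — parse the search engine's peptide table (MaxQuant
   `peptides.txt` dialect, decoy/contaminant rows dropped), and match
   identifications back into mutant entries; a match must overlap a mutated
   residue and must not occur verbatim in the reference proteome
   (cancer-specific evidence at the protein level).
6. **Binding selection** — enumerate mutated 8–11-mers, score each
   (peptide, allele) pair with a pluggable percentile-rank predictor, and
   keep pairs with %rank < 2 (SB < 0.5 ≤ WB < 2 ≤ NB).
7. **Homology screen** — align each candidate against a user-supplied set of
   experimentally immunogenic peptides with an exact Smith–Waterman
   (BLOSUM62, gap open 11 / extend 1); candidates whose best hit exceeds 60%
   identical matches are reported **high-confidence**.
8. **Reporting** — HLA allele frequencies over 2n chromosomes,
   carrier-normalized neoantigen counts per allele, shared
   neoantigens/genes between samples, and per-stage counts.

A fixtures module generates every input synthetically (seeded, with planted
ground truth), so the entire pipeline runs and is tested offline.

## Worked example

Generate a synthetic run and execute the pipeline end to end:

```bash
noncneo fixtures --seed 1 --outdir runs/demo
noncneo run --dir runs/demo --out runs/demo/report.tsv --counts-out runs/demo/counts.json
```

which prints

```
synthetic run (seed 1) -> runs/demo
282 candidates, 282 high-confidence -> runs/demo/report.tsv
```

and `counts.json` contains

```json
{
  "noncoding_variants": 5,
  "mutant_peptides": 27,
  "validated_peptides": 89,
  "candidate_predictions": 282,
  "high_confidence_neoantigens": 282
}
```

Ten SNVs were planted; three carry a non-`PASS` filter and two are coding
(`exonic`) decoys, so **5** variants enter context extraction. Six-frame
translation of their mutant contexts yields **27** unique mutation-bearing
peptide database entries, **89** (identified peptide, entry) pairs are
validated by the simulated MS table at full recall, and the planted
(8–11-mer, allele) strong binders fan out to **282** candidate records —
every one of which matches its engineered immunogenic partner above 60%
identity, hence 282 high-confidence records and zero false positives
(`report.tsv` lists peptide, allele, %rank, bind level, best reference hit,
identity, and the full variant provenance per row).

The stages are also available individually (`noncneo variants`,
`noncneo peptides extract-context`, `noncneo peptides translate`,
`noncneo builddb`, `noncneo msfilter`, `noncneo predict`, `noncneo screen`,
`noncneo evaluate`, `noncneo report`), reading and writing TSV/FASTA/VCF so
real search-engine or predictor output can be substituted at any point.

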