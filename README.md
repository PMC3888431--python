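# txconsolidate

Two-tiered consolidation of hybrid transcriptome assemblies, with
reference-proteome completeness metrics.

## The problem

RNA-seq assemblies of a non-model organism are usually produced several
ways at once: reference-guided transcript models on a (draft) genome, and
de novo contigs from one or more assemblers at many k-mer settings. No
single assembly covers the transcriptome — each contributes transcripts
the others miss — but naively pooling them yields millions of sequences
riddled with duplicates, truncations and chimeras. `txconsolidate`
implements the two-branch consolidation workflow that turns such a pool
into one compact, quality-filtered transcript set, together with the
evaluation statistics needed to show the result is better than any input:

* **Reference branch** — transcript models mapped to the genome pass
  three filters: mapping coverage ≥ 90% of the source transcript,
  canonical GT..AG splice sites on every intron, and a locus rule that
  drops models whose longest ORF is under 75% of the longest ORF at their
  gene locus (loci = connected components of same-strand exonic overlap).
* **De novo branch** — unoriented contigs are reduced to longest-ORF CDS
  regions (≥ 200 nt), deduplicated by ungapped containment (removed if a
  longer sequence covers ≥ 90% of them at ≥ 95% identity), clustered by
  shared canonical k-mer fraction (single linkage), and re-assembled per
  cluster by a forward-only, gap-free greedy overlap-consensus assembler
  — the orientation and gap restrictions prevent chimeric joins and new
  frameshifts.
* **Merge** — a de novo transcript is dropped when a reference-branch
  transcript covers ≥ 95% of it; a reference transcript is dropped only
  when a de novo transcript covers it completely without gaps.

Any transcript set can then be scored against a reference proteome:

* **Classification** — each transcript's ORFs are aligned to the
  proteome; the best significant hit (identity ≥ 90%, e-value ≤ 1e-20 or
  an internal matches proxy) classifies it as *correct* (protein ≥ 90%
  covered, ≤ 1% gaps), *incomplete* (protein < 90% but ORF ≥ 90% covered,
  ≤ 1% gaps) or *false* (any other significant hit).
* **u80 metric** — the number of reference proteins with at least one
  *ungapped* alignment covering ≥ 80% of the protein, plus a gap-class
  table (0% / ≤ 5% / > 5% gaps / uncovered).
* **Presence test** — a protein counts as retained by consolidation if it
  keeps a significant hit whose identity drops no more than 5 percentage
  points versus the combined pre-merge pool.
* **Paralog table** — a 2×3 cross-tabulation of sequence clusters against
  gene loci (unique/shared cluster × single/multiple/no locus).

A seeded synthetic-data module generates toy genomes (multi-exon genes,
exon-skipping isoforms, canonical introns), proteomes, and corrupted
transcript sets with oracle-computed truth labels, so the entire workflow
is testable without any downloads.

## Worked example

```bash
txconsolidate simulate --n-genes 15 --seed 3 --out-dir sim
txconsolidate pipeline \
    --genome sim/genome.fasta --ref-models sim/ref_models.gtf \
    --denovo-fasta sim/denovo.fasta --proteins sim/proteome.fasta \
    --out-dir run --seed 3
```

prints

```
reference branch: 50 models -> 20 transcripts
de novo branch: 30 -> 15 contigs
merged final set: 20 transcripts
correct: 75.0%
incomplete: 10.0%
false: 15.0%
u80: 15 of 15 proteins
```

The simulated reference branch holds 50 models: the 20 true isoform
models of 15 genes plus 30 planted decoys; the per-stage report
(`run/report.tsv`) shows each filter removing exactly its 10 planted
defects (low mapping coverage, non-canonical splice site, short locus
ORF). The de novo branch holds each gene's CDS plus 15 planted contained
fragments, which die in containment dedup. After merging, every one of
the 15 reference proteins retains an ungapped alignment covering ≥ 80%
(`u80: 15 of 15`); the classification fractions refer to the final set's
transcripts, where exon-skipping isoforms aligned to their gene's primary
protein legitimately land in the *incomplete*/*false* classes (internal
deletions > 1% gaps).

Other outputs in `run/`: `final.fasta` (the consolidated set),
`clusters.tsv`, `paralogs.tsv` (2×3 table), `classes.tsv`, `u80.tsv`,
`merge_log.tsv` and `report.tsv`, each with a provenance header (version,
seed, config hash).

The same functionality is available as a library
(`txconsolidate.run_refpipe`, `run_denovo_pipe`, `merge_sets`,
`classify_set`, `u80_metric`, ...); see `docs/methods.md` for the model
and its assumptions.

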