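# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `txconsolidate`, in the order data flows through the
toolkit.

## Coordinate and record conventions

All in-memory coordinates are 0-based half-open. GTF input/output
converts to/from 1-based inclusive at the boundary; PSL is natively
0-based half-open; BLAST tabular (1-based inclusive) is converted on
ingest. Alignment records carry explicit match/mismatch/gap-column
accounting from which every derived quantity is defined once:
`alignment_length = matches + mismatches + gap_columns`,
`percent_identity = 100·matches/(matches+mismatches)`,
`query_coverage = (matches+mismatches)/query_len` (target analogous),
`gap_fraction = gap_columns/alignment_length`. An alignment is *ungapped*
iff it is a single block with zero gap columns. BLAST tabular rows lack
block structure; they are flagged `blockless`, with gap columns inferred
from the span/length accounting (`gaps = 2·length − q_span − s_span`),
and are accepted only by operations that need no block chain.

## ORF model

CDS detection is the longest-ORF rule: ATG-initiated reading frames
scanned in all six frames (both strands by default, since de novo contigs
are unoriented; a flag restricts to forward). One ORF is reported per
stop-bounded frame segment — from its 5'-most ATG — because nested
ATG-initiated ORFs are strict sub-intervals that can never win a
longest-ORF contest. ORFs open at the 3' end are allowed by default
(assembled transcripts are frequently truncated; the *incomplete*
evaluation class exists precisely for them). ORF length includes the stop
codon when present. Ties in `longest_orf` break deterministically: '+'
strand, then leftmost. Codons containing N translate to X; frameshift
recovery and non-ATG starts are out of scope.

## Aligners

Two internal aligners cover every filter and metric. Scoring is unit
match/mismatch with no substitution matrix: every downstream rule
consumes only coverage, identity and gap-fraction thresholds, so a
BLOSUM-weighted score would change nothing but the tie-breaks.

**Ungapped nucleotide containment** (`ungapped_align_nt`): both query
orientations are tried; every diagonal sharing an exact k-mer (default
k=8 — at the 90% identity floor, exact seed runs average ~10 nt, so
larger words routinely miss genuine alignments) is extended to its
maximal-scoring run (+1/−1, N never matches, Kadane with deterministic
ties: longest then leftmost). The best single-block record by aligned
columns among those with identity ≥ the floor and at least `min_aligned`
(20) columns is returned; shorter runs are random-level noise (the best
exact run between unrelated sequences of this size is ~6–8 nt) and carry
no containment evidence.

**Protein chain alignment** (`translated_align` / `protein_align`): the
target transcript is translated in six frames (or the target is itself a
protein); exact word seeds (default 5 aa vs translations, 4 aa
protein–protein) define diagonals, each extended to its maximal-scoring
run; blocks are then chained by dynamic programming, monotone on both
axes, with inter-block offsets of at most `max_join_gap` (30 aa) on
either axis counted as gap columns. A successor block may be head-trimmed
when a coincidental boundary match extended its run into the
predecessor's span. The chain maximizing matches wins (ties: fewer gaps,
then leftmost); gap columns are accounted in amino-acid units on both
axes, so a 3-nt in-frame deletion in the transcript counts as one gap
column.

*Known limitation*: an insertion that exactly cancels a deletion folds
the alignment back onto one diagonal, where the gap-free run absorbs the
interval as mismatch columns rather than gaps; a full DP aligner may
report the same optimal score with a different coverage/gap split.
Oracle-equivalence tests therefore use indel fixtures whose cumulative
diagonal shifts are distinct.

**Significance without e-values.** E-values are never computed
internally. Rules stated as e-value cutoffs apply them only when records
come from BLAST tabular input; internal alignments use a minimum-matches
proxy instead — 33 aa of match for the strict (1e-20-tier)
classification significance, 20 aa for the looser (1e-5-tier) presence
test — roughly the information content of such hits at unit scoring.
Both are parameters at every call site.

## Reference-branch filters

Order: mapping coverage → canonical splice → locus ORF fraction. All
thresholds are inclusive on the keep side (the removal rules are strict
"less than"). Mapping coverage is spliced exon length over source
transcript length (soft-clipping is not modelled; the source length
travels with the model, serialized as a `source_length` GTF attribute).
The canonical splice set defaults to GT–AG only — the strictest
defensible reading of "non-canonical"; GC–AG/AT–AC can be added via
configuration. Loci are connected components of same-contig, same-strand,
≥ 1 bp exonic overlap, computed by a sweep with union–find; locus ids are
the lexicographically smallest member id. Within a locus, models whose
longest ORF is below 75% of the locus maximum are dropped; ORF-less
models are dropped whenever any locus member has an ORF. Each filter is a
partition of its input, idempotent, and order-insensitive.

## De novo branch

Stage 1 replaces a trained coding-region HMM with longest-ORF CDS
extraction (the toolkit's one declared methodological simplification;
consequently there is no frameshift correction) and orients every
sequence on its coding strand, which is what makes the later forward-only
rule meaningful. Stage 2 removes containments: descending length order,
a transcript dies to the first kept longer transcript whose ungapped
alignment covers ≥ 90% of the *shorter* sequence (cd-hit-est semantics;
the alternative "90% of the longer" reading is a parameter) at ≥ 95%
identity. Stage 3 clusters by shared canonical k-mer fraction
(|shared| / min(|A|,|B|) ≥ 0.30 at k=14, single linkage), a simpler,
exactly testable stand-in for word-count distance clustering with the
same connected-component semantics. Stage 4 assembles each cluster by
greedy overlap consensus: only forward-orientation, gap-free
suffix–prefix overlaps or containments of ≥ 40 columns at ≥ 98% identity
qualify; the highest score (overlap × identity) merges first; disagreeing
columns take the longer parent's base; the merged contig keeps the longer
parent's id. Taking the "large gap penalty" idea to its limit — no gaps
at all — is deliberate: a gapped join is exactly how frameshifts enter a
consensus. The price is that diverged isoforms do not merge, which is the
intended behavior (they remain separate contigs in one cluster).

## Merging and evaluation

The de novo-removal rule (≥ 95% coverage by any reference transcript,
gaps permitted in principle, identity floor 90) is evaluated against the
full reference set first; the reference-removal rule (complete ungapped
cover by a surviving de novo transcript) second. This order prefers
reference-based structures: an exact duplicate pair resolves in favor of
the reference copy. Both rules re-verify as a post-condition on the final
set.

Classification runs in the BLASTp direction: translated ORFs are queries,
reference proteins targets. The pooled hits of all ORFs of a transcript
compete; the best significant hit (highest score, ties by target id)
decides the class. "Covering the transcript ≥ 90%" is interpreted as
coverage of the translated ORF query (a parameter switches to full
transcript length). Fractions are reported over transcripts with a
significant hit; an empty denominator reports None rather than zero.

The u80 metric demands a *single* ungapped alignment covering ≥ 80% of a
protein at ≥ 70% identity — multiple transcripts may not jointly cover
it. The gap-class table assigns each protein its best class among
coverage-qualified alignments (ungapped > ≤ 5% > > 5% gaps > uncovered).
The presence test compares, per protein, the maximum identity over
significant hits in the final set against the combined pre-merge set
(max over hits, rather than the single best-scoring hit's identity, so
the statistic is stable under hit reordering); a drop of more than 5
percentage points counts the protein as lost.

The paralog table cross-tabulates clusters against loci: columns by the
number of distinct loci a cluster's members map to (1 / >1 / 0), rows by
whether the cluster shares a locus with another cluster. In the
end-to-end pipeline, transcripts surviving from the reference branch
carry their locus; de novo contigs are unplaced and populate the
`no_locus` column.

## Synthetic data

The generator emulates the structural features the pipeline's decisions
depend on, not read-level noise. Genes have 3–8 exons of 120–350 nt
(codon-multiple lengths, so exon skipping preserves frame), introns of
60–800 nt beginning GT and ending AG on the coding strand, a CDS of at
least 240 nt spanning 60–85% of the mature transcript (so every protein
clears the significance proxies with margin, including chimera halves),
1–3 isoforms per gene built by skipping a CDS-internal exon no longer
than 20% of the CDS (so genuine isoforms survive the 75% locus-ORF
filter), and both strands. 5' UTRs are generated ATG-free and each gene
is rejection-sampled until the longest ORF of every isoform is exactly
the planted CDS — making longest-ORF truth exact by construction, which
every generation audits (spliced models reproduce matures; all introns
canonical; proteome = CDS translations).

Corruptions model assembler failure modes: 3' truncation (default to 70%
length), in-frame chimera of two genes' CDS halves, in-frame internal
deletion (30 nt), point mutations (rate 0.2 — far enough below the 90%
identity floor that classification decisively loses the hit), and strand
flips (a no-op for a both-strand ORF scan). Expected classes are never
hand-asserted: each corrupted transcript's ORFs are aligned to its source
(and chimera partner) protein by an independent dynamic-programming
aligner (Biopython `PairwiseAligner`, local, unit scores, linear gaps)
and pushed through the real classification rules, so labels stay correct
if thresholds change. What passing label-recovery shows is therefore that
the seed-and-chain aligner and the classifier reproduce DP-oracle
decisions on clean-to-moderately-damaged data; it does not certify
behavior on sequencing-error-dominated or repeat-rich real data, which
the generator does not emulate (no read-level error model, no repeats,
no paralogous gene families beyond chimeras, no expression levels).

Planted decoys for the filter tests are constructed to fail exactly one
filter each: inflated source length (coverage ≈ 0.7), an intron boundary
shifted until a splice dinucleotide goes non-canonical (coverage intact),
a transcript-order prefix retaining ~40% of the CDS (coverage and splice
sites intact), and exact CDS substrings of 40–60% length for containment.

## Numerical and determinism choices

No floating tolerance enters any rule: thresholds compare exact rational
quantities (counts and their ratios). Every ordering in the toolkit is
total — descending length then id, '+' before '−', lower frame first,
smaller start — so all outputs are byte-reproducible without a seed; the
only randomness anywhere is the synthetic generator's single
`numpy.random.default_rng(seed)` stream per operation. Output tables
carry a provenance line (version, seed, config hash) and no timestamps.

## Problem sizes

The bundled studies run at desk scale by design: genomes of 10–60 genes
(tens of kilobases), transcript sets of 30–150, proteomes of 10–60
proteins, 500/300/200-instance oracle-equivalence sweeps. All algorithms
are quadratic or better in set size with k-mer prefiltering and were
chosen for exact testability rather than throughput; scaling to millions
of contigs would require batched indexing, which is out of scope.
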