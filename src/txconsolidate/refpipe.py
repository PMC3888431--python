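"""Reference-based re-assembly filters.

Transcript models mapped to a (draft) genome pass three filters in order:

1. mapping coverage — a model must place at least 90% of its source
   transcript's nucleotides on the genome;
2. canonical splice sites — every intron must read a canonical
   donor..acceptor pair (GT..AG by default) on the transcript's strand;
3. locus ORF fraction — within a gene locus (connected component of
   same-contig, same-strand exonic overlap), models whose longest ORF is
   shorter than 75% of the locus' longest ORF are dropped.

All thresholds are inclusive on the "keep" side (the removal rules are
phrased as strict "less than").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .orf import longest_orf, revcomp, spliced_sequence
from .records import LocusAssignment, Transcript, TranscriptModel, ValidationError

__all__ = [
    "filter_mapping_coverage",
    "filter_canonical_splice",
    "group_loci",
    "filter_orf_fraction",
    "run_refpipe",
    "StageReport",
]

CANONICAL_PAIRS = frozenset({("GT", "AG")})


def filter_mapping_coverage(
    models: Sequence[TranscriptModel], min_cov: float = 0.90
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition models by spliced-length / source-length coverage >= ``min_cov``."""
    kept, removed = [], []
    for m in models:
        if m.source_length is None:
            raise ValidationError(
                f"model {m.transcript_id!r}: source_length required for coverage filter"
            )
        (kept if m.spliced_length / m.source_length >= min_cov else removed).append(m)
    return kept, removed


def _intron_dinucleotides(m: TranscriptModel, contig: str) -> Iterable[tuple[str, str]]:
    """Donor/acceptor dinucleotide pairs of each intron, on the model's strand."""
    for s, e in m.introns:
        if e - s < 4:
            raise ValidationError(
                f"model {m.transcript_id!r}: intron [{s},{e}) shorter than 4 nt"
            )
        left = contig[s : s + 2]
        right = contig[e - 2 : e]
        if m.strand == "+":
            yield left, right
        else:
            yield revcomp(right), revcomp(left)


def filter_canonical_splice(
    models: Sequence[TranscriptModel],
    genome: dict[str, str],
    canonical_pairs: frozenset[tuple[str, str]] = CANONICAL_PAIRS,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Keep models whose every intron matches a canonical donor..acceptor pair.

    Single-exon models are always kept.
    """
    kept, removed = [], []
    for m in models:
        if m.contig_id not in genome:
            raise ValidationError(
                f"model {m.transcript_id!r}: contig {m.contig_id!r} not in genome"
            )
        contig = genome[m.contig_id]
        ok = all(
            pair in canonical_pairs for pair in _intron_dinucleotides(m, contig)
        )
        (kept if ok else removed).append(m)
    return kept, removed


def group_loci(models: Sequence[TranscriptModel]) -> LocusAssignment:
    """Gene loci as connected components of exonic overlap.

    Two models are linked iff they share a contig and strand and at least
    one base pair of exonic overlap. The locus id is the lexicographically
    smallest member transcript_id.
    """
    parent = list(range(len(models)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, m in enumerate(models):
        for s, e in m.exons:
            by_key.setdefault((m.contig_id, m.strand), []).append((s, e, idx))
    for intervals in by_key.values():
        intervals.sort()
        group_rep = None
        group_max_end = -1
        for s, e, idx in intervals:
            if group_rep is None or s >= group_max_end:
                group_rep = idx
                group_max_end = e
            else:
                union(group_rep, idx)
                group_max_end = max(group_max_end, e)
    comp: dict[int, list[int]] = {}
    for idx in range(len(models)):
        comp.setdefault(find(idx), []).append(idx)
    mapping: dict[str, Optional[str]] = {}
    for members in comp.values():
        lid = min(models[i].transcript_id for i in members)
        for i in members:
            mapping[models[i].transcript_id] = lid
    return LocusAssignment(mapping=mapping)


def filter_orf_fraction(
    models: Sequence[TranscriptModel],
    genome: dict[str, str],
    min_fraction: float = 0.75,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Keep models whose longest ORF reaches ``min_fraction`` of the locus maximum.

    Models with no ORF are removed whenever any locus member has one; loci
    without any ORF keep all members.
    """
    loci = group_loci(models)
    orf_len: dict[str, int] = {}
    for m in models:
        seq = spliced_sequence(m, genome)
        o = longest_orf(Transcript(id=m.transcript_id, seq=seq))
        orf_len[m.transcript_id] = o.length_nt if o is not None else 0
    locus_max: dict[str, int] = {}
    for tid, lid in loci.mapping.items():
        locus_max[lid] = max(locus_max.get(lid, 0), orf_len[tid])
    kept, removed = [], []
    for m in models:
        lmax = locus_max[loci.mapping[m.transcript_id]]
        ok = orf_len[m.transcript_id] >= min_fraction * lmax
        (kept if ok else removed).append(m)
    return kept, removed


@dataclass
class StageReport:
    """Per-stage input/kept/removed accounting of a pipeline run."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, kept: Sequence, removed: Sequence) -> None:
        self.stages.append(
            {
                "stage": name,
                "n_in": n_in,
                "n_kept": len(kept),
                "n_removed": len(removed),
                "removed_ids": sorted(
                    getattr(x, "transcript_id", None) or x.id for x in removed
                ),
            }
        )

    def as_rows(self) -> list[tuple]:
        return [
            (s["stage"], s["n_in"], s["n_kept"], s["n_removed"]) for s in self.stages
        ]


def run_refpipe(
    models: Sequence[TranscriptModel],
    genome: dict[str, str],
    min_cov: float = 0.90,
    canonical_pairs: frozenset[tuple[str, str]] = CANONICAL_PAIRS,
    min_orf_fraction: float = 0.75,
) -> tuple[list[TranscriptModel], LocusAssignment, StageReport]:
    """Run the three reference-branch filters in their stated order."""
    report = StageReport()
    kept, removed = filter_mapping_coverage(models, min_cov=min_cov)
    report.add("mapping_coverage", len(models), kept, removed)
    stage2_in = kept
    kept, removed = filter_canonical_splice(stage2_in, genome, canonical_pairs)
    report.add("canonical_splice", len(stage2_in), kept, removed)
    stage3_in = kept
    kept, removed = filter_orf_fraction(stage3_in, genome, min_fraction=min_orf_fraction)
    report.add("orf_fraction", len(stage3_in), kept, removed)
    loci = group_loci(kept)
    return kept, loci, report
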