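"""Domain records shared by every stage of the toolkit.

All coordinates held in these records are 0-based half-open. Readers and
writers in :mod:`txconsolidate.io_formats` convert at the boundary (GTF is
1-based inclusive on disk; PSL is already 0-based half-open).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "ToolkitError",
    "FormatError",
    "ValidationError",
    "Transcript",
    "ProteinRecord",
    "TranscriptModel",
    "Orf",
    "AlnRecord",
    "ClusterSet",
    "LocusAssignment",
    "HitClass",
    "GapClassTable",
    "ParalogTable",
    "TruthRecord",
]


class ToolkitError(Exception):
    """Base class for all errors raised by the toolkit."""


class FormatError(ToolkitError):
    """A file does not conform to its declared format.

    ``line`` carries the 1-based offending line number when known.
    """

    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(ToolkitError):
    """A record violates a domain invariant."""


_NT_RE = re.compile(r"[ACGTN]+")
_AA_RE = re.compile(r"[ACDEFGHIKLMNPQRSTVWYX*]+")


@dataclass(frozen=True)
class Transcript:
    """A nucleotide sequence with an identifier; the atomic unit of the toolkit."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValidationError(f"transcript {self.id!r}: empty sequence")
        if not _NT_RE.fullmatch(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValidationError(
                f"transcript {self.id!r}: invalid nucleotide characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence (20 standard letters plus X and *)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        if not _AA_RE.fullmatch(self.seq):
            bad = sorted(set(self.seq) - set("ACDEFGHIKLMNPQRSTVWYX*"))
            raise ValidationError(
                f"protein {self.id!r}: invalid amino-acid characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    """An exon chain placing a transcript on a genome contig.

    ``exons`` are 0-based half-open genomic intervals, sorted ascending and
    pairwise non-overlapping. ``source_length`` is the nucleotide length of
    the originating transcript sequence (needed by the mapping-coverage
    filter) and may be absent.
    """

    transcript_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    source_length: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"model {self.transcript_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        if not self.exons:
            raise ValidationError(f"model {self.transcript_id!r}: no exons")
        for s, e in self.exons:
            if e - s < 1 or s < 0:
                raise ValidationError(
                    f"model {self.transcript_id!r}: invalid exon interval [{s},{e})"
                )
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < s1 and e0 <= s1):
                raise ValidationError(
                    f"model {self.transcript_id!r}: exons not sorted/non-overlapping "
                    f"([{s0},{e0}) then [{s1},{e1}))"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic gaps between consecutive exons, 0-based half-open."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Orf:
    """A candidate coding region on a transcript.

    ``start``/``end`` are 0-based half-open coordinates on the *forward*
    transcript sequence regardless of ``strand``; ``frame`` is relative to
    the 5' end of the (possibly reverse-complemented) reading strand.
    ``aa_seq`` excludes the terminal stop symbol.
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    has_stop: bool
    aa_seq: str

    def __post_init__(self):
        n = self.end - self.start
        if n < 3 or n % 3 != 0:
            raise ValidationError(
                f"ORF on {self.transcript_id!r}: span {n} nt not a positive codon multiple"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class AlnRecord:
    """A block-chain pairwise alignment with match/mismatch/gap accounting.

    Units: ``blocks`` entries are ``(q_start, t_start, length)`` where the
    query axis is in the query's own residues (aa for protein queries) and
    the target axis in the target's residues. ``gap_columns`` counts
    unaligned residues between consecutive blocks summed over both axes, in
    query units for protein-vs-nucleotide chains. For minus-orientation
    nucleotide alignments the query coordinates refer to the
    reverse-complemented query.
    """

    query_id: str
    target_id: str
    query_len: int
    target_len: int
    strand_or_frame: str
    blocks: list[tuple[int, int, int]]
    matches: int
    mismatches: int
    gap_columns: int
    score: float
    evalue: Optional[float] = None
    blockless: bool = False

    def __post_init__(self):
        if not self.blockless:
            total = sum(l for _, _, l in self.blocks)
            if total != self.matches + self.mismatches:
                raise ValidationError(
                    f"alignment {self.query_id}->{self.target_id}: block lengths "
                    f"({total}) != matches+mismatches ({self.matches + self.mismatches})"
                )
            for (q0, t0, l0), (q1, t1, _) in zip(self.blocks, self.blocks[1:]):
                if q1 < q0 + l0 or t1 < t0 + l0:
                    raise ValidationError(
                        f"alignment {self.query_id}->{self.target_id}: blocks not "
                        "monotone on both axes"
                    )

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches

    @property
    def alignment_length(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def percent_identity(self) -> float:
        cols = self.aligned_columns
        return 100.0 * self.matches / cols if cols else 0.0

    @property
    def query_coverage(self) -> float:
        return self.aligned_columns / self.query_len if self.query_len else 0.0

    @property
    def target_coverage(self) -> float:
        return self.aligned_columns / self.target_len if self.target_len else 0.0

    @property
    def gap_fraction(self) -> float:
        n = self.alignment_length
        return self.gap_columns / n if n else 0.0

    @property
    def ungapped(self) -> bool:
        return self.gap_columns == 0 and (self.blockless or len(self.blocks) == 1)


@dataclass
class ClusterSet:
    """A partition of transcript ids into named clusters."""

    clusters: dict[str, list[str]]

    def __post_init__(self):
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if not members:
                raise ValidationError(f"cluster {cid!r} is empty")
            for m in members:
                if m in seen:
                    raise ValidationError(f"transcript {m!r} in more than one cluster")
                seen.add(m)

    @property
    def transcript_to_cluster(self) -> dict[str, str]:
        return {m: cid for cid, members in self.clusters.items() for m in members}

    @property
    def member_ids(self) -> set[str]:
        return {m for members in self.clusters.values() for m in members}

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class LocusAssignment:
    """transcript_id -> locus_id (or None for unplaced transcripts)."""

    mapping: dict[str, Optional[str]]

    @property
    def loci(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tid, lid in self.mapping.items():
            if lid is not None:
                out.setdefault(lid, []).append(tid)
        for members in out.values():
            members.sort()
        return out

    def __len__(self) -> int:
        return len({l for l in self.mapping.values() if l is not None})


class HitClass(str, Enum):
    """Assembly-quality class of a transcript from its best significant protein hit."""

    CORRECT = "correct"
    INCOMPLETE = "incomplete"
    FALSE = "false"
    NO_HIT = "no_hit"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GAP_CLASSES = ("ungapped", "gap_le_5pct", "gap_gt_5pct", "uncovered")


@dataclass
class GapClassTable:
    """Per-reference-protein best alignment gap class (0%, <=5%, >5% or uncovered)."""

    per_protein: dict[str, str]

    def __post_init__(self):
        for pid, cls in self.per_protein.items():
            if cls not in GAP_CLASSES:
                raise ValidationError(f"protein {pid!r}: unknown gap class {cls!r}")

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.per_protein.values())
        return {cls: c.get(cls, 0) for cls in GAP_CLASSES}


PARALOG_ROWS = ("unique_cluster", "multiple_cluster")
PARALOG_COLS = ("single_locus", "multiple_loci", "no_locus")


@dataclass
class ParalogTable:
    """2x3 cross-tabulation of clusters against the gene loci they map to."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        full = {}
        for row in PARALOG_ROWS:
            for col in PARALOG_COLS:
                full[(row, col)] = int(self.counts.get((row, col), 0))
        self.counts = full

    @property
    def n_clusters(self) -> int:
        return sum(self.counts.values())

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [[self.counts[(r, c)] for c in PARALOG_COLS] for r in PARALOG_ROWS],
            index=list(PARALOG_ROWS),
            columns=list(PARALOG_COLS),
        )


@dataclass
class TruthRecord:
    """Ground-truth label for one synthetic transcript."""

    transcript_id: str
    source_gene: str
    source_isoform: str
    corruption: str
    params: dict = field(default_factory=dict)
    expected_class: HitClass = HitClass.CORRECT
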