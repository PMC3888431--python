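"""Cross-pipeline merging and reference-proteome evaluation statistics.

This module carries the evaluation vocabulary of the toolkit:

* the correct / incomplete / false transcript classification from the
  best significant protein hit (reference >=90% covered with <=1% gaps ->
  correct; gaps <=1%, reference <90% but query >=90% covered ->
  incomplete; any other significant hit -> false);
* the u80 metric: the number of reference proteins with at least one
  *ungapped* alignment covering >=80% of the protein, plus the gap-class
  table (0% / <=5% / >5% gaps / uncovered) over coverage-qualified
  alignments;
* the cross-branch merge rules (a de novo transcript dies to a >=95%
  coverage alignment from the reference branch; a reference transcript
  dies only to a complete ungapped cover by a de novo transcript);
* the presence test (a protein is retained in the final set if it keeps a
  significant hit whose identity drops <=5 percentage points against the
  combined pre-merge set);
* the 2x3 paralog contingency table of clusters against gene loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .align import (
    MIN_MATCHES_E5,
    MIN_MATCHES_E20,
    kmer_index,
    protein_align,
    six_frames,
    translated_align,
    ungapped_align_nt,
)
from .orf import find_orfs
from .records import (
    AlnRecord,
    ClusterSet,
    GapClassTable,
    HitClass,
    LocusAssignment,
    ParalogTable,
    ProteinRecord,
    Transcript,
    ValidationError,
)

__all__ = [
    "merge_sets",
    "classify_transcript",
    "classify_set",
    "u80_metric",
    "unique_u80",
    "presence_test",
    "paralog_table",
    "RemovalLogEntry",
]


@dataclass(frozen=True)
class RemovalLogEntry:
    removed_id: str
    by_id: str
    rule: str
    coverage: float
    identity: float


def merge_sets(
    ref_ts: Sequence[Transcript],
    denovo_ts: Sequence[Transcript],
    denovo_removal_cov: float = 0.95,
    min_identity_pct: float = 90,
    k: int = 8,
) -> tuple[list[Transcript], list[RemovalLogEntry]]:
    """Merge the reference-branch and de novo-branch transcript sets.

    A de novo transcript is removed iff some reference transcript's
    alignment covers at least ``denovo_removal_cov`` of it; a reference
    transcript is removed iff some *surviving* de novo transcript covers
    100% of it with an ungapped alignment. The de novo rule is evaluated
    first (so exact duplicates resolve in favor of the reference copy).
    """
    ids = [t.id for t in ref_ts] + [t.id for t in denovo_ts]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"id collision across branch sets: {dupes}")
    log: list[RemovalLogEntry] = []
    ref_index = [kmer_index(r.seq, k) for r in ref_ts]
    denovo_kept: list[Transcript] = []
    for d in denovo_ts:
        hit = None
        for r, idx in zip(ref_ts, ref_index):
            aln = ungapped_align_nt(
                d, r, k=k, min_identity_pct=min_identity_pct, target_index=idx
            )
            if aln is not None and aln.query_coverage >= denovo_removal_cov:
                hit = (r, aln)
                break
        if hit is None:
            denovo_kept.append(d)
        else:
            r, aln = hit
            log.append(
                RemovalLogEntry(
                    removed_id=d.id,
                    by_id=r.id,
                    rule="denovo_covered_by_ref",
                    coverage=aln.query_coverage,
                    identity=aln.percent_identity,
                )
            )
    denovo_index = [kmer_index(d.seq, k) for d in denovo_kept]
    ref_kept: list[Transcript] = []
    for r in ref_ts:
        hit = None
        for d, idx in zip(denovo_kept, denovo_index):
            aln = ungapped_align_nt(
                r, d, k=k, min_identity_pct=min_identity_pct, target_index=idx
            )
            if aln is not None and aln.ungapped and aln.query_coverage >= 1.0:
                hit = (d, aln)
                break
        if hit is None:
            ref_kept.append(r)
        else:
            d, aln = hit
            log.append(
                RemovalLogEntry(
                    removed_id=r.id,
                    by_id=d.id,
                    rule="ref_fully_covered_by_denovo",
                    coverage=aln.query_coverage,
                    identity=aln.percent_identity,
                )
            )
    return ref_kept + denovo_kept, log


def _significant(
    hits: Sequence[AlnRecord],
    min_identity_pct: float,
    max_evalue: float,
    min_matches: int,
) -> list[AlnRecord]:
    out = []
    for h in hits:
        if h.percent_identity < min_identity_pct:
            continue
        if h.evalue is not None:
            if h.evalue <= max_evalue:
                out.append(h)
        elif h.matches >= min_matches:
            out.append(h)
    return out


def classify_transcript(
    t: Transcript,
    hits: Sequence[AlnRecord],
    ref_cov: float = 0.90,
    query_cov: float = 0.90,
    max_gap_fraction: float = 0.01,
    min_identity_pct: float = 90,
    max_evalue: float = 1e-20,
    min_matches: int = MIN_MATCHES_E20,
) -> HitClass:
    """Classify a transcript from its protein hits (query = translated ORF,
    target = reference protein)."""
    sig = _significant(hits, min_identity_pct, max_evalue, min_matches)
    if not sig:
        return HitClass.NO_HIT
    best = sorted(sig, key=lambda h: (-h.score, h.target_id))[0]
    if best.target_coverage >= ref_cov and best.gap_fraction <= max_gap_fraction:
        return HitClass.CORRECT
    if (
        best.gap_fraction <= max_gap_fraction
        and best.target_coverage < ref_cov
        and best.query_coverage >= query_cov
    ):
        return HitClass.INCOMPLETE
    return HitClass.FALSE


def classify_set(
    transcripts: Sequence[Transcript],
    proteins: Sequence[ProteinRecord],
    min_orf_nt: int = 200,
    hits_by_transcript: Optional[dict[str, list[AlnRecord]]] = None,
    **thresholds,
) -> tuple[dict[str, Optional[float]], pd.DataFrame]:
    """Classify every transcript against a reference proteome.

    ORFs >= ``min_orf_nt`` are translated and aligned to every reference
    protein (BLASTp direction: ORF translation is the query); the pooled
    hits of all ORFs of a transcript feed :func:`classify_transcript`.
    Precomputed hits (e.g. from BLAST tabular input) may be supplied via
    ``hits_by_transcript``. Fractions use transcripts with a significant
    hit as the denominator; with an empty denominator they are None.
    """
    word = 4
    indexes = [(p, kmer_index(p.seq, word, skip="X*")) for p in proteins]
    rows = []
    counts = {c: 0 for c in HitClass}
    for t in transcripts:
        if hits_by_transcript is not None:
            hits = hits_by_transcript.get(t.id, [])
        else:
            hits = []
            for o in find_orfs(t, min_len_nt=min_orf_nt):
                aa = o.aa_seq
                if not aa:
                    continue
                q = ProteinRecord(id=f"{t.id}|{o.strand}{o.frame}:{o.start}", seq=aa)
                for p, idx in indexes:
                    aln = protein_align(q, p, word=word, target_index=idx)
                    if aln is not None:
                        hits.append(aln)
        cls = classify_transcript(t, hits, **thresholds)
        counts[cls] += 1
        best = None
        sig = _significant(
            hits,
            thresholds.get("min_identity_pct", 90),
            thresholds.get("max_evalue", 1e-20),
            thresholds.get("min_matches", MIN_MATCHES_E20),
        )
        if sig:
            best = sorted(sig, key=lambda h: (-h.score, h.target_id))[0]
        rows.append(
            {
                "transcript_id": t.id,
                "hit_class": cls.value,
                "best_target": best.target_id if best else None,
                "target_coverage": best.target_coverage if best else None,
                "query_coverage": best.query_coverage if best else None,
                "gap_fraction": best.gap_fraction if best else None,
                "percent_identity": best.percent_identity if best else None,
            }
        )
    denom = len(transcripts) - counts[HitClass.NO_HIT]
    fractions: dict[str, Optional[float]] = {}
    for cls in (HitClass.CORRECT, HitClass.INCOMPLETE, HitClass.FALSE):
        fractions[cls.value] = counts[cls] / denom if denom else None
    return fractions, pd.DataFrame(rows)


def _qualifying_alignments(
    protein: ProteinRecord,
    transcripts: Sequence[Transcript],
    min_cov: float,
    min_identity_pct: float,
    frames_cache: Optional[dict[str, list]] = None,
) -> list[AlnRecord]:
    out = []
    for t in transcripts:
        frames = None
        if frames_cache is not None:
            frames = frames_cache.get(t.id)
            if frames is None:
                frames = six_frames(t)
                frames_cache[t.id] = frames
        aln = translated_align(
            protein, t, min_identity_pct=min_identity_pct, frames=frames
        )
        if aln is not None and aln.query_coverage >= min_cov:
            out.append(aln)
    return out


def u80_metric(
    proteins: Sequence[ProteinRecord],
    transcripts: Optional[Sequence[Transcript]] = None,
    min_cov: float = 0.80,
    min_identity_pct: float = 70,
    alignments: Optional[Sequence[AlnRecord]] = None,
    frames_cache: Optional[dict[str, list]] = None,
) -> tuple[int, GapClassTable]:
    """Count reference proteins with an ungapped alignment covering >= ``min_cov``.

    Every protein is additionally assigned its best gap class (ungapped >
    <=5% > >5% > uncovered) among coverage-qualified alignments. The u80
    requirement is a SINGLE ungapped alignment; several transcripts may
    not jointly cover a protein. Precomputed alignments (e.g. PSL input;
    query must be the protein) can be supplied instead of ``transcripts``.
    """
    per_protein: dict[str, str] = {}
    count = 0
    by_query: dict[str, list[AlnRecord]] = {}
    if alignments is not None:
        for a in alignments:
            by_query.setdefault(a.query_id, []).append(a)
    for p in proteins:
        if alignments is not None:
            quals = [
                a
                for a in by_query.get(p.id, [])
                if a.query_coverage >= min_cov
                and a.percent_identity >= min_identity_pct
            ]
        else:
            if transcripts is None:
                raise ValueError("u80_metric needs transcripts or alignments")
            quals = _qualifying_alignments(
                p, transcripts, min_cov, min_identity_pct, frames_cache
            )
        if not quals:
            per_protein[p.id] = "uncovered"
        elif any(a.ungapped for a in quals):
            per_protein[p.id] = "ungapped"
            count += 1
        elif any(a.gap_fraction <= 0.05 for a in quals):
            per_protein[p.id] = "gap_le_5pct"
        else:
            per_protein[p.id] = "gap_gt_5pct"
    return count, GapClassTable(per_protein=per_protein)


def unique_u80(
    proteins: Sequence[ProteinRecord],
    transcript_sets: Sequence[Sequence[Transcript]],
    min_cov: float = 0.80,
    min_identity_pct: float = 70,
) -> list[int]:
    """Per-set count of proteins in that set's u80 and in no other set's."""
    if len(transcript_sets) < 2:
        raise ValueError("unique_u80 requires at least 2 transcript sets")
    frames_cache: dict[str, list] = {}
    u80_sets = []
    for ts in transcript_sets:
        _, table = u80_metric(
            proteins, ts, min_cov=min_cov, min_identity_pct=min_identity_pct,
            frames_cache=frames_cache,
        )
        u80_sets.append({p for p, c in table.per_protein.items() if c == "ungapped"})
    out = []
    for i, s in enumerate(u80_sets):
        others = set().union(*(u80_sets[j] for j in range(len(u80_sets)) if j != i))
        out.append(len(s - others))
    return out


def _best_identity(
    protein: ProteinRecord,
    transcripts: Sequence[Transcript],
    min_matches: int,
    frames_cache: Optional[dict[str, list]] = None,
) -> Optional[float]:
    """Max percent identity among significant hits of a protein, or None."""
    best = None
    for t in transcripts:
        frames = None
        if frames_cache is not None:
            frames = frames_cache.get(t.id)
            if frames is None:
                frames = six_frames(t)
                frames_cache[t.id] = frames
        aln = translated_align(protein, t, min_identity_pct=0, frames=frames)
        if aln is None or aln.matches < min_matches:
            continue
        if best is None or aln.percent_identity > best:
            best = aln.percent_identity
    return best


def presence_test(
    proteins: Sequence[ProteinRecord],
    combined_set: Sequence[Transcript],
    final_set: Sequence[Transcript],
    max_identity_drop_points: float = 5,
    min_matches: int = MIN_MATCHES_E5,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Which reference proteins survive the consolidation?

    A protein is present in the combined set iff it has a significant hit
    there; present in the final set iff it has a significant hit whose
    identity is no more than ``max_identity_drop_points`` percentage
    points below its combined-set identity. Returns (present_in_combined,
    missing_in_final, per-protein table).
    """
    frames_cache: dict[str, list] = {}
    rows = []
    present: set[str] = set()
    missing: set[str] = set()
    for p in proteins:
        ci = _best_identity(p, combined_set, min_matches, frames_cache)
        fi = _best_identity(p, final_set, min_matches, frames_cache)
        in_combined = ci is not None
        in_final = (
            fi is not None
            and in_combined
            and fi >= ci - max_identity_drop_points
        )
        if in_combined:
            present.add(p.id)
            if not in_final:
                missing.add(p.id)
        rows.append(
            {
                "protein_id": p.id,
                "combined_identity": ci,
                "final_identity": fi,
                "present_in_combined": in_combined,
                "present_in_final": in_final,
            }
        )
    return present, missing, pd.DataFrame(rows)


def paralog_table(clusters: ClusterSet, loci: LocusAssignment) -> ParalogTable:
    """Cross-tabulate clusters against the gene loci their members map to.

    Columns: a cluster maps to exactly one locus, to several, or to none.
    Rows: a cluster is ``multiple_cluster`` iff it shares at least one
    locus with a different cluster, else ``unique_cluster``.
    """
    missing = clusters.member_ids - set(loci.mapping)
    if missing:
        raise ValidationError(
            f"clustered transcripts absent from locus assignment: {sorted(missing)[:5]}"
        )
    cluster_loci: dict[str, set[str]] = {}
    locus_users: dict[str, set[str]] = {}
    for cid, members in clusters.clusters.items():
        ls = {loci.mapping[m] for m in members if loci.mapping[m] is not None}
        cluster_loci[cid] = ls
        for l in ls:
            locus_users.setdefault(l, set()).add(cid)
    counts: dict[tuple[str, str], int] = {}
    for cid, ls in cluster_loci.items():
        if not ls:
            col = "no_locus"
        elif len(ls) == 1:
            col = "single_locus"
        else:
            col = "multiple_loci"
        shared = any(len(locus_users[l]) > 1 for l in ls)
        row = "multiple_cluster" if shared else "unique_cluster"
        counts[(row, col)] = counts.get((row, col), 0) + 1
    return ParalogTable(counts=counts)
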