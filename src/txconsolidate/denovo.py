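"""Non-reference re-assembly: containment dedup, clustering, consensus assembly.

The branch reduces an unoriented de novo transcript soup to a compact CDS
set in four stages: longest-ORF CDS extraction (orienting every sequence
on its coding strand), removal of transcripts ungapped-contained in a
longer one, single-linkage clustering by shared canonical k-mer fraction,
and per-cluster forward-only gap-free greedy overlap-consensus assembly.
The forward-only and gap-free restrictions deliberately forgo sensitivity
to avoid chimeric joins and the introduction of frameshifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import kmer_index, ungapped_align_nt
from .orf import longest_orf, orf_sequence, revcomp
from .records import ClusterSet, Transcript
from .refpipe import StageReport

__all__ = [
    "dedupe_containment",
    "cluster_kmer",
    "assemble_cluster",
    "run_denovo_pipe",
    "ContainmentEvidence",
]


@dataclass(frozen=True)
class ContainmentEvidence:
    removed_id: str
    kept_id: str
    coverage: float
    identity: float


def dedupe_containment(
    transcripts: Sequence[Transcript],
    min_cov: float = 0.90,
    min_identity_pct: float = 95,
    k: int = 8,
) -> tuple[list[Transcript], list[Transcript], list[ContainmentEvidence]]:
    """Remove transcripts ungapped-contained in an already-kept longer one.

    Transcripts are visited by descending length (ties: id order); one is
    removed iff an ungapped alignment against some kept longer transcript
    covers at least ``min_cov`` of the *shorter* sequence (cd-hit-est
    semantics) at ``min_identity_pct`` or better.
    """
    order = sorted(transcripts, key=lambda t: (-len(t.seq), t.id))
    kept: list[Transcript] = []
    kept_index: list[dict] = []
    removed: list[Transcript] = []
    evidence: list[ContainmentEvidence] = []
    for t in order:
        hit = None
        for other, idx in zip(kept, kept_index):
            aln = ungapped_align_nt(
                t, other, k=k, min_identity_pct=min_identity_pct, target_index=idx
            )
            if aln is not None and aln.query_coverage >= min_cov:
                hit = (other, aln)
                break
        if hit is None:
            kept.append(t)
            kept_index.append(kmer_index(t.seq, k))
        else:
            other, aln = hit
            removed.append(t)
            evidence.append(
                ContainmentEvidence(
                    removed_id=t.id,
                    kept_id=other.id,
                    coverage=aln.query_coverage,
                    identity=aln.percent_identity,
                )
            )
    return kept, removed, evidence


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        out.add(min(w, revcomp(w)))
    return out


def cluster_kmer(
    transcripts: Sequence[Transcript],
    k: int = 14,
    min_shared_fraction: float = 0.30,
) -> ClusterSet:
    """Single-linkage clustering by shared canonical k-mer fraction.

    Two transcripts are linked iff shared canonical k-mers divided by the
    smaller of the two k-mer sets reaches ``min_shared_fraction`` (both
    orientations considered via canonical k-mers). Cluster id = smallest
    member transcript id.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    n = len(transcripts)
    sets = [_canonical_kmers(t.seq, k) for t in transcripts]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    inv: dict[str, list[int]] = {}
    for i, s in enumerate(sets):
        for w in s:
            inv.setdefault(w, []).append(i)
    candidate_pairs: set[tuple[int, int]] = set()
    for members in inv.values():
        if len(members) > 1:
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    candidate_pairs.add((members[a], members[b]))
    for i, j in candidate_pairs:
        denom = min(len(sets[i]), len(sets[j]))
        if denom == 0:
            continue
        if len(sets[i] & sets[j]) / denom >= min_shared_fraction:
            union(i, j)
    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)
    clusters: dict[str, list[str]] = {}
    for members in comp.values():
        ids = sorted(transcripts[i].id for i in members)
        clusters[ids[0]] = ids
    return ClusterSet(clusters=clusters)


def _overlap_candidates(a: str, b: str, min_overlap: int, seed_k: int = 12):
    """Forward gap-free overlap placements of b relative to a.

    Yields (offset, overlap_len, matches): b starts at ``offset`` in a's
    coordinates (negative = b sticks out to the left). Only seeded
    diagonals are examined; the overlap extent is fixed by geometry.
    """
    idx = kmer_index(a, seed_k)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    ba = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")
    offsets = set()
    for i in range(len(b) - seed_k + 1):
        w = b[i : i + seed_k]
        if "N" in w:
            continue
        for ap in idx.get(w, ()):
            offsets.add(ap - i)
    for d in sorted(offsets):
        lo_a = max(0, d)
        hi_a = min(len(a), d + len(b))
        ovl = hi_a - lo_a
        if ovl < min_overlap:
            continue
        seg_a = aa[lo_a:hi_a]
        seg_b = ba[lo_a - d : hi_a - d]
        matches = int(np.count_nonzero((seg_a == seg_b) & (seg_a != n_code)))
        yield d, ovl, matches


def assemble_cluster(
    members: Sequence[Transcript],
    min_overlap_nt: int = 40,
    min_identity_pct: float = 98,
) -> list[Transcript]:
    """Greedy forward-only gap-free overlap-consensus assembly of one cluster.

    All pairwise forward-orientation suffix-prefix overlaps and
    containments of at least ``min_overlap_nt`` columns at
    ``min_identity_pct`` identity are scored as overlap length x identity;
    the best pair is merged into a consensus (disagreeing columns take the
    longer parent's base) until no overlap qualifies. Reverse-complement
    placements are never considered, so an inverted fragment is left as
    its own contig.
    """
    if not members:
        raise ValueError("assemble_cluster requires at least one member")
    contigs: dict[str, str] = {t.id: t.seq for t in members}
    while True:
        ids = sorted(contigs, key=lambda i: (-len(contigs[i]), i))
        best = None  # (score, id_a, id_b, offset)
        for ia in range(len(ids)):
            for ib in range(ia + 1, len(ids)):
                a_id, b_id = ids[ia], ids[ib]
                a, b = contigs[a_id], contigs[b_id]
                for d, ovl, m in _overlap_candidates(a, b, min_overlap_nt):
                    identity = 100.0 * m / ovl
                    if identity < min_identity_pct:
                        continue
                    score = ovl * (identity / 100.0)
                    key = (score, -ia, -ib, -abs(d))
                    if best is None or key > best[0]:
                        best = (key, a_id, b_id, d)
        if best is None:
            break
        _, a_id, b_id, d = best
        a, b = contigs[a_id], contigs[b_id]
        # consensus: a keeps its coordinates, b placed at offset d
        lo = min(0, d)
        hi = max(len(a), d + len(b))
        out = []
        a_longer = (len(a), b_id) > (len(b), a_id)  # ties -> lexicographic id
        for pos in range(lo, hi):
            ca = a[pos] if 0 <= pos < len(a) else None
            cb = b[pos - d] if 0 <= pos - d < len(b) else None
            if ca is None:
                out.append(cb)
            elif cb is None or ca == cb:
                out.append(ca)
            else:
                out.append(ca if a_longer else cb)
        keep_id = a_id if (len(a), b_id) > (len(b), a_id) else b_id
        del contigs[a_id], contigs[b_id]
        contigs[keep_id] = "".join(out)
    result = [
        Transcript(id=i, seq=s)
        for i, s in sorted(contigs.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    return result


def run_denovo_pipe(
    transcripts: Sequence[Transcript],
    min_orf_nt: int = 200,
    dedupe_cov: float = 0.90,
    dedupe_identity_pct: float = 95,
    cluster_k: int = 14,
    min_shared_fraction: float = 0.30,
    min_overlap_nt: int = 40,
    assemble_identity_pct: float = 98,
) -> tuple[list[Transcript], ClusterSet, StageReport]:
    """CDS extraction -> containment dedup -> clustering -> per-cluster assembly."""
    report = StageReport()
    cds: list[Transcript] = []
    dropped: list[Transcript] = []
    for t in transcripts:
        o = longest_orf(t)
        if o is None or o.length_nt < min_orf_nt:
            dropped.append(t)
        else:
            cds.append(Transcript(id=t.id, seq=orf_sequence(t, o)))
    report.add("cds_extraction", len(transcripts), cds, dropped)
    kept, removed, _evidence = dedupe_containment(
        cds, min_cov=dedupe_cov, min_identity_pct=dedupe_identity_pct
    )
    report.add("containment_dedupe", len(cds), kept, removed)
    clusters = cluster_kmer(kept, k=cluster_k, min_shared_fraction=min_shared_fraction)
    by_id = {t.id: t for t in kept}
    final: list[Transcript] = []
    for cid in sorted(clusters.clusters):
        members = [by_id[m] for m in clusters.clusters[cid]]
        final.extend(
            assemble_cluster(
                members,
                min_overlap_nt=min_overlap_nt,
                min_identity_pct=assemble_identity_pct,
            )
        )
    report.add("cluster_assembly", len(kept), final, [])
    return final, clusters, report
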