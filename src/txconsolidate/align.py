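"""Internal pairwise aligners behind every filter and metric.

Two aligners are provided:

* :func:`ungapped_align_nt` — seed-and-extend ungapped nucleotide
  containment alignment (the substrate of containment dedup and of the
  cross-pipeline merge rules);
* :func:`translated_align` / :func:`protein_align` — protein versus
  six-frame-translated nucleotide (or protein versus protein) chain
  alignment: exact word seeds, ungapped extension to the maximal-scoring
  run per diagonal, then monotone chaining of co-frame blocks with bounded
  inter-block offsets counted as gap columns.

Scoring is unit match/mismatch (no substitution matrix): every downstream
rule consumes only coverage, identity and gap-fraction thresholds, never
raw scores. E-values are not computed internally; rules stated as e-value
cutoffs fall back to a minimum-matches proxy (defaults below) when
alignments were produced internally rather than read from BLAST output.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .orf import revcomp, translate
from .records import AlnRecord, ProteinRecord, Transcript

__all__ = [
    "ungapped_align_nt",
    "translated_align",
    "protein_align",
    "six_frames",
    "kmer_index",
    "MIN_MATCHES_E20",
    "MIN_MATCHES_E5",
]

# Minimum aligned matches accepted as "significant" for internal (e-value-free)
# alignments, standing in for BLAST-style e-value cutoffs at unit scoring:
# ~33 aa of exact match carries the information content of a 1e-20 protein hit,
# ~20 aa that of a 1e-5 hit. Both are configurable at every call site.
MIN_MATCHES_E20 = 33
MIN_MATCHES_E5 = 20


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def kmer_index(seq: str, k: int, skip: str = "N") -> dict[str, list[int]]:
    """Exact k-mer/word index of ``seq``; words containing ``skip`` chars are omitted."""
    index: dict[str, list[int]] = {}
    skipset = set(skip)
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if skipset & set(w):
            continue
        index.setdefault(w, []).append(i)
    return index


def _best_run(pm: np.ndarray) -> Optional[tuple[int, int, int]]:
    """Maximal-scoring contiguous run of a +1/-1 array.

    Returns ``(score, start, end)`` (end exclusive). Ties resolved
    deterministically: highest score, then longest run, then leftmost.
    Returns None when no positive-scoring run exists.
    """
    pre = np.concatenate(([0], np.cumsum(pm, dtype=np.int64)))
    min_acc = np.minimum.accumulate(pre)
    scores = pre[1:] - min_acc[:-1]
    best_score = int(scores.max())
    if best_score <= 0:
        return None
    ends = np.flatnonzero(scores == best_score) + 1
    best = None
    for j in (int(x) for x in ends):
        i = int(np.argmin(pre[:j]))  # leftmost minimum -> longest run for this end
        cand = (j - i, -i)  # prefer longer, then leftmost
        if best is None or cand > best[0]:
            best = (cand, i, j)
    _, i, j = best
    return best_score, i, j


def _diagonals(q: str, t_index: dict[str, list[int]], k: int) -> list[int]:
    diags: set[int] = set()
    skipset = set("N")
    for i in range(len(q) - k + 1):
        w = q[i : i + k]
        if skipset & set(w):
            continue
        for tp in t_index.get(w, ()):
            diags.add(tp - i)
    return sorted(diags)


def ungapped_align_nt(
    query: Transcript,
    target: Transcript,
    k: int = 8,
    min_identity_pct: float = 90,
    min_aligned: int = 20,
    target_index: Optional[dict[str, list[int]]] = None,
) -> Optional[AlnRecord]:
    """Best single-block ungapped alignment of ``query`` against ``target``.

    Both orientations of the query are considered; each shared-k-mer
    diagonal is extended without gaps to its maximal-scoring run (match +1,
    mismatch -1, N never matches). The single-block record with maximal
    aligned columns among those at or above ``min_identity_pct`` and at
    least ``min_aligned`` columns long is returned, ties broken by higher
    identity, then '+' orientation, then smaller target start; runs below
    the floor are random-level noise that carries no containment evidence.
    For '-' records the query coordinates refer to the reverse-complemented
    query (PSL convention).
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if target_index is None:
        target_index = kmer_index(target.seq, k)
    ta = _encode(target.seq)
    n_code = ord("N")
    best = None
    best_key = None
    for strand in ("+", "-"):
        q = query.seq if strand == "+" else revcomp(query.seq)
        qa = _encode(q)
        for d in _diagonals(q, target_index, k):
            lo = max(0, -d)
            hi = min(len(q), len(target.seq) - d)
            if hi - lo < 1:
                continue
            qseg = qa[lo:hi]
            tseg = ta[lo + d : hi + d]
            pm = np.where((qseg == tseg) & (qseg != n_code), 1, -1).astype(np.int64)
            run = _best_run(pm)
            if run is None:
                continue
            score, i, j = run
            length = j - i
            if length < min_aligned:
                continue
            m = (length + score) // 2
            mm = length - m
            identity = 100.0 * m / length
            if identity < min_identity_pct:
                continue
            q_start = lo + i
            t_start = q_start + d
            key = (length, identity, strand == "+", -t_start)
            if best_key is None or key > best_key:
                best_key = key
                best = AlnRecord(
                    query_id=query.id,
                    target_id=target.id,
                    query_len=len(query.seq),
                    target_len=len(target.seq),
                    strand_or_frame=strand,
                    blocks=[(q_start, t_start, length)],
                    matches=m,
                    mismatches=mm,
                    gap_columns=0,
                    score=float(score),
                )
    return best


def six_frames(target: Transcript) -> list[tuple[str, int, str]]:
    """All six frame translations of a transcript as (strand, frame, protein)."""
    out = []
    for strand in ("+", "-"):
        seq = target.seq if strand == "+" else revcomp(target.seq)
        for frame in range(3):
            out.append((strand, frame, translate(seq, frame)))
    return out


def _chain_align(
    q: str,
    t: str,
    word: int,
    max_join_gap: int,
    t_index: Optional[dict[str, list[int]]] = None,
):
    """Seed/extend/chain two same-alphabet strings; returns the best chain.

    Blocks are the maximal-scoring ungapped run of each seeded diagonal;
    chaining is a DP over blocks monotone on both axes with inter-block
    offsets bounded by ``max_join_gap`` on either axis, the offsets counted
    as gap columns. The chain maximizing total matches wins (ties: fewer
    gap columns, then leftmost). Returns (blocks, matches, mismatches,
    gap_columns) or None.
    """
    if t_index is None:
        t_index = kmer_index(t, word, skip="X*")
    qa = _encode(q)
    ta = _encode(t)
    never = np.isin(qa, np.frombuffer(b"X*", dtype=np.uint8))
    blocks = []  # (q_start, t_start, length, match_prefix: np.ndarray)
    diags: set[int] = set()
    skipset = set("X*")
    for i in range(len(q) - word + 1):
        w = q[i : i + word]
        if skipset & set(w):
            continue
        for tp in t_index.get(w, ()):
            diags.add(tp - i)
    for d in sorted(diags):
        lo = max(0, -d)
        hi = min(len(q), len(t) - d)
        if hi - lo < 1:
            continue
        qseg = qa[lo:hi]
        tseg = ta[lo + d : hi + d]
        ok = (qseg == tseg) & ~never[lo:hi] & ~np.isin(
            tseg, np.frombuffer(b"X*", dtype=np.uint8)
        )
        pm = np.where(ok, 1, -1).astype(np.int64)
        run = _best_run(pm)
        if run is None:
            continue
        _score, i, j = run
        # prefix match counts allow head-trimming when chained blocks overlap
        # (a coincidental boundary match extends a run into its predecessor)
        pref = np.concatenate(([0], np.cumsum((pm[i:j] == 1).astype(np.int64))))
        blocks.append((lo + i, lo + i + d, j - i, pref))
    if not blocks:
        return None
    blocks.sort(key=lambda b: (b[0], b[1]))
    n = len(blocks)
    # DP over blocks monotone on both axes; a successor may be head-trimmed to
    # resolve small overlaps with its predecessor.
    # best[i] = (total_matches, -total_gaps, -total_mismatches)
    best_val = []
    prev: list[tuple[int, int]] = []  # (predecessor index, trim of block i)
    for i, (qs, ts, ln, pref) in enumerate(blocks):
        m_full = int(pref[ln])
        cur = (m_full, 0, -(ln - m_full))
        cur_prev = (-1, 0)
        for j in range(i):
            qj, tj, lj, _pj = blocks[j]
            trim = max(0, (qj + lj) - qs, (tj + lj) - ts)
            if trim >= ln:
                continue
            q_off = qs + trim - (qj + lj)
            t_off = ts + trim - (tj + lj)
            if q_off > max_join_gap or t_off > max_join_gap:
                continue
            m_eff = int(pref[ln] - pref[trim])
            mm_eff = (ln - trim) - m_eff
            vm, vg, vmm = best_val[j]
            cand = (vm + m_eff, vg - (q_off + t_off), vmm - mm_eff)
            if cand > cur:
                cur = cand
                cur_prev = (j, trim)
        best_val.append(cur)
        prev.append(cur_prev)
    end = max(range(n), key=lambda i: (best_val[i], -blocks[i][0]))
    chain = []
    i = end
    trim = 0
    while i != -1:
        qs, ts, ln, pref = blocks[i]
        j, trim = prev[i]
        # the recorded trim applies to block i itself
        chain.append((qs + trim, ts + trim, ln - trim,
                      int(pref[ln] - pref[trim])))
        i = j
    chain.reverse()
    matches = sum(b[3] for b in chain)
    mismatches = sum(b[2] - b[3] for b in chain)
    gaps = 0
    for (qj, tj, lj, _), (qs, ts, _, _) in zip(chain, chain[1:]):
        gaps += (qs - (qj + lj)) + (ts - (tj + lj))
    return [(qs, ts, ln) for qs, ts, ln, _ in chain], matches, mismatches, gaps


def translated_align(
    query: ProteinRecord,
    target: Transcript,
    word: int = 5,
    max_join_gap: int = 30,
    min_identity_pct: float = 70,
    frames: Optional[Sequence[tuple[str, int, str]]] = None,
) -> Optional[AlnRecord]:
    """Best chained alignment of a protein against the six frames of a transcript.

    Per frame the protein is aligned to the frame translation by exact-word
    seeding, ungapped extension and bounded chaining; the frame chain with
    maximal matches subject to ``min_identity_pct`` wins (ties: higher
    identity, '+' strand, lower frame). Both alignment axes are in amino
    acids; target positions refer to the frame translation (nucleotide
    position = frame + 3*aa on the reading strand). ``frames`` may carry a
    precomputed :func:`six_frames` result to amortize translation across
    many queries.
    """
    if frames is None:
        frames = six_frames(target)
    best = None
    best_key = None
    for strand, frame, prot in frames:
        if len(prot) < word:
            continue
        res = _chain_align(query.seq, prot, word, max_join_gap)
        if res is None:
            continue
        blocks, m, mm, gaps = res
        identity = 100.0 * m / (m + mm) if (m + mm) else 0.0
        if identity < min_identity_pct:
            continue
        key = (m, identity, strand == "+", -frame, -blocks[0][1])
        if best_key is None or key > best_key:
            best_key = key
            best = AlnRecord(
                query_id=query.id,
                target_id=target.id,
                query_len=len(query.seq),
                target_len=len(prot),
                strand_or_frame=f"{strand}{frame}",
                blocks=blocks,
                matches=m,
                mismatches=mm,
                gap_columns=gaps,
                score=float(m - mm - gaps),
            )
    return best


def protein_align(
    query: ProteinRecord,
    target: ProteinRecord,
    word: int = 4,
    max_join_gap: int = 30,
    min_identity_pct: float = 0,
    target_index: Optional[dict[str, list[int]]] = None,
) -> Optional[AlnRecord]:
    """Best chained protein-protein alignment (both axes in amino acids).

    Used where a practitioner would run BLASTp (translated ORFs against a
    reference proteome). ``target_index`` may carry a precomputed
    :func:`kmer_index` of the target (skip="X*") for reuse across queries.
    """
    res = _chain_align(query.seq, target.seq, word, max_join_gap, t_index=target_index)
    if res is None:
        return None
    blocks, m, mm, gaps = res
    identity = 100.0 * m / (m + mm) if (m + mm) else 0.0
    if identity < min_identity_pct:
        return None
    return AlnRecord(
        query_id=query.id,
        target_id=target.id,
        query_len=len(query.seq),
        target_len=len(target.seq),
        strand_or_frame="+",
        blocks=blocks,
        matches=m,
        mismatches=mm,
        gap_columns=gaps,
        score=float(m - mm - gaps),
    )
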