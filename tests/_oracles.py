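"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct route available
(exhaustive enumeration, all-pairs graphs, dynamic programming) so they
share no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

_RC = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_orfs(seq: str, min_len: int, both_strands: bool = True,
               allow_open: bool = True):
    """Enumerate every ATG, scan to the next in-frame stop; keep the 5'-most
    ATG per (strand, frame, stop). Returns a set of (strand, start, end,
    has_stop) on forward-transcript coordinates."""
    out = {}
    strands = ["+", "-"] if both_strands else ["+"]
    n = len(seq)
    for strand in strands:
        s = seq if strand == "+" else rc(seq)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            stop = None
            while j + 3 <= n:
                if s[j : j + 3] in _STOPS:
                    stop = j + 3
                    break
                j += 3
            if stop is not None:
                span = (i, stop, True)
            elif allow_open:
                end = i + 3 * ((n - i) // 3)
                span = (i, end, False)
            else:
                continue
            start, end, has_stop = span
            if end - start < min_len:
                continue
            key = (strand, i % 3, end)  # one ORF per stop-bounded frame segment
            if key not in out or start < out[key][0]:
                out[key] = (start, end, has_stop)
    result = set()
    for (strand, _frame, _end), (start, end, has_stop) in out.items():
        if strand == "+":
            result.add((strand, start, end, has_stop))
        else:
            result.add((strand, n - end, n - start, has_stop))
    return result


def _best_run_naive(pm):
    """Max-sum run of a +/-1 list; ties: longer, then leftmost. Plain loops."""
    best = None  # (score, length, -start)
    n = len(pm)
    for i in range(n):
        acc = 0
        for j in range(i, n):
            acc += pm[j]
            cand = (acc, j + 1 - i, -i)
            if best is None or cand > best:
                best = cand
    if best is None or best[0] <= 0:
        return None
    return best[0], -best[2], -best[2] + best[1]


def all_diagonal_best_nt(q: str, t: str, min_identity_pct: float = 90,
                         min_aligned: int = 20):
    """Score every diagonal of both orientations; return the best
    (aligned_columns, identity, strand, q_start, t_start) or None.

    Vectorized per diagonal but with the same stated tie rules as the
    brute definition: per diagonal the maximal-scoring run (longer, then
    leftmost); across diagonals maximal aligned columns among runs at or
    above the identity floor, then higher identity, '+' orientation,
    smaller target start."""
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    n_code = ord("N")
    best = None
    best_key = None
    for strand in ("+", "-"):
        qs = q if strand == "+" else rc(q)
        qa = np.frombuffer(qs.encode(), dtype=np.uint8)
        for d in range(-(len(qs) - 1), len(t)):
            lo = max(0, -d)
            hi = min(len(qs), len(t) - d)
            if hi <= lo:
                continue
            qseg = qa[lo:hi]
            tseg = ta[lo + d : hi + d]
            pm = np.where((qseg == tseg) & (qseg != n_code), 1, -1).astype(np.int64)
            pre = np.concatenate(([0], np.cumsum(pm)))
            min_acc = np.minimum.accumulate(pre)
            scores = pre[1:] - min_acc[:-1]
            sc = int(scores.max())
            if sc <= 0:
                continue
            ends = np.flatnonzero(scores == sc) + 1
            run = None
            for j in (int(x) for x in ends):
                i = int(np.argmin(pre[:j]))
                cand = (j - i, -i)
                if run is None or cand > run[0]:
                    run = (cand, i, j)
            _, i, j = run
            length = j - i
            if length < min_aligned:
                continue
            m = (length + sc) // 2
            identity = 100.0 * m / length
            if identity < min_identity_pct:
                continue
            q_start = lo + i
            t_start = q_start + d
            key = (length, identity, strand == "+", -t_start)
            if best_key is None or key > best_key:
                best_key = key
                best = (length, identity, strand, q_start, t_start)
    return best


_DP = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-1,
    extend_gap_score=-1,
)

_AA_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = {}


def _translate_frame(dna: str, frame: int) -> str:
    from Bio.Seq import Seq

    sub = dna[frame : frame + 3 * ((len(dna) - frame) // 3)]
    return str(Seq(sub).translate())


def dp_translated_best(prot: str, transcript: str):
    """DP oracle: align the protein to each of the six frame translations
    (local, unit scores, linear gaps); return (coverage, gap_columns) of
    the frame alignment with maximal matches (ties: fewer gaps)."""
    best = None
    for strand in ("+", "-"):
        s = transcript if strand == "+" else rc(transcript)
        for frame in range(3):
            t = _translate_frame(s, frame)
            if not t:
                continue
            alns = _DP.align(prot, t)
            if len(alns) == 0 or alns.score <= 0:
                continue
            # the chain aligner maximizes matches; among equal-score optimal
            # DP alignments pick the one with max matches, then fewest gaps
            for idx, a in enumerate(alns):
                if idx >= 64:
                    break
                qb, tb = a.aligned
                m = mm = 0
                for (qs, qe), (ts, te) in zip(qb, tb):
                    for x, y in zip(prot[qs:qe], t[ts:te]):
                        if x == y and x not in "X*":
                            m += 1
                        else:
                            mm += 1
                gaps = 0
                for k in range(1, len(qb)):
                    gaps += (qb[k][0] - qb[k - 1][1]) + (tb[k][0] - tb[k - 1][1])
                cand = (m, -gaps)
                if best is None or cand > best[0]:
                    best = (cand, (m + mm) / len(prot), gaps)
    if best is None:
        return None
    return best[1], best[2]


def overlap_components(items, linked) -> list[frozenset]:
    """Connected components of an explicit all-pairs predicate via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(items)))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if linked(items[i], items[j]):
                g.add_edge(i, j)
    return [frozenset(c) for c in nx.connected_components(g)]


def models_overlap(a, b) -> bool:
    """Same contig, same strand, >=1 bp exonic overlap (brute force)."""
    if a.contig_id != b.contig_id or a.strand != b.strand:
        return False
    for s0, e0 in a.exons:
        for s1, e1 in b.exons:
            if max(s0, s1) < min(e0, e1):
                return True
    return False


def canonical_kmer_fraction(a: str, b: str, k: int) -> float:
    def km(s):
        out = set()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" not in w:
                out.add(min(w, rc(w)))
        return out

    ka, kb = km(a), km(b)
    denom = min(len(ka), len(kb))
    return len(ka & kb) / denom if denom else 0.0
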