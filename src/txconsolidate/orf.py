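"""ORF discovery, translation, and longest-ORF CDS prediction.

CDS detection throughout the toolkit is the "longest ORF" approach: the
longest ATG-initiated reading frame (optionally open at the 3' end, since
assembled transcripts are frequently truncated) is taken as the coding
region. One ORF is reported per stop-bounded frame segment — the one
starting at the 5'-most ATG — because nested ATG-initiated sub-ORFs are
strict sub-intervals and can never win a longest-ORF contest.
"""

from __future__ import annotations

from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .records import Orf, Transcript, ValidationError

__all__ = ["revcomp", "translate", "find_orfs", "longest_orf", "spliced_sequence"]

_STANDARD = unambiguous_dna_by_id[1]
_CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TABLE[_stop] = "*"

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_RC)[::-1]


def translate(dna: str, frame: int = 0) -> str:
    """Translate ``dna`` from ``frame`` with the standard genetic code.

    Codons containing N translate to ``X``; stop codons to ``*``; the
    trailing 1-2 nt that do not fill a codon are ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise ValidationError(f"invalid nucleotide characters {sorted(bad)}")
    out = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(_CODON_TABLE[codon])
    return "".join(out)


def find_orfs(
    t: Transcript,
    min_len_nt: int = 200,
    both_strands: bool = True,
    allow_open_3prime: bool = True,
) -> list[Orf]:
    """Find ATG-initiated ORFs of at least ``min_len_nt`` nucleotides.

    Per frame and strand, each stop-bounded segment contributes at most one
    ORF, from its 5'-most ATG to the stop (span includes the stop codon) or
    — when ``allow_open_3prime`` — to the last complete codon of a
    stop-less terminal segment. Coordinates are reported on the forward
    transcript sequence; results are sorted by descending nucleotide
    length, ties broken by strand ('+' first) then smaller start.
    """
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")
    strands = ["+", "-"] if both_strands else ["+"]
    n = len(t.seq)
    orfs: list[Orf] = []
    for strand in strands:
        seq = t.seq if strand == "+" else revcomp(t.seq)
        for frame in range(3):
            aa = translate(seq, frame)
            atg_codon: Optional[int] = None
            for ci, res in enumerate(aa):
                codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
                if atg_codon is None and codon == "ATG":
                    atg_codon = ci
                if res == "*":
                    if atg_codon is not None:
                        _emit(orfs, t.id, strand, frame, seq, n, aa,
                              atg_codon, ci, True, min_len_nt)
                    atg_codon = None
            if allow_open_3prime and atg_codon is not None:
                _emit(orfs, t.id, strand, frame, seq, n, aa,
                      atg_codon, len(aa) - 1, False, min_len_nt)
    orfs.sort(key=lambda o: (-(o.length_nt), o.strand != "+", o.start, o.frame))
    return orfs


def _emit(orfs, tid, strand, frame, seq, n, aa, atg_codon, last_codon, has_stop, min_len):
    """Append one ORF spanning codons [atg_codon, last_codon] of ``frame``."""
    s = frame + 3 * atg_codon
    e = frame + 3 * (last_codon + 1)
    if e - s < min_len:
        return
    aa_seq = aa[atg_codon : last_codon + 1]
    if has_stop:
        aa_seq = aa_seq[:-1]
        if not aa_seq:
            return  # bare ATG-stop below any sensible min_len, guarded anyway
    if strand == "+":
        start, end = s, e
    else:
        start, end = n - e, n - s
    orfs.append(
        Orf(
            transcript_id=tid,
            strand=strand,
            frame=frame,
            start=start,
            end=end,
            has_stop=has_stop,
            aa_seq=aa_seq,
        )
    )


def longest_orf(t: Transcript, both_strands: bool = True) -> Optional[Orf]:
    """The single longest ORF of ``t`` (ties: '+' strand, then leftmost), or None."""
    orfs = find_orfs(t, min_len_nt=3, both_strands=both_strands)
    return orfs[0] if orfs else None


def orf_sequence(t: Transcript, o: Orf) -> str:
    """Nucleotide sequence of an ORF on its reading strand (starts with ATG)."""
    region = t.seq[o.start : o.end]
    return region if o.strand == "+" else revcomp(region)


def spliced_sequence(m, genome: dict[str, str]) -> str:
    """Materialize the mature transcript of a model from a genome.

    Exon substrings are concatenated in genomic order and the result is
    reverse-complemented as a whole for minus-strand models.
    """
    if m.contig_id not in genome:
        raise ValidationError(
            f"model {m.transcript_id!r}: contig {m.contig_id!r} not in genome"
        )
    contig = genome[m.contig_id]
    parts = []
    for s, e in m.exons:
        if s < 0 or e > len(contig):
            raise ValidationError(
                f"model {m.transcript_id!r}: exon [{s},{e}) outside contig "
                f"{m.contig_id!r} (length {len(contig)})"
            )
        parts.append(contig[s:e])
    seq = "".join(parts)
    return revcomp(seq) if m.strand == "-" else seq
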