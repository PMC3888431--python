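"""Readers and writers for the standard formats the toolkit touches.

Everything is normalized to one internal coordinate convention: 0-based
half-open. GTF (1-based inclusive) is converted on ingest and on output;
PSL is already 0-based half-open; BLAST tabular (1-based inclusive) is
converted on ingest.
"""

from __future__ import annotations

import os
import re
from typing import Optional, Sequence, Union

from Bio import SeqIO

from .records import (
    AlnRecord,
    FormatError,
    ProteinRecord,
    Transcript,
    TranscriptModel,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_alignments",
    "write_psl",
]

FastaRecord = Union[Transcript, ProteinRecord]


def read_fasta(path, kind: str = "nucleotide") -> list[FastaRecord]:
    """Read a FASTA file into :class:`Transcript` or :class:`ProteinRecord` objects.

    Sequences are uppercased; record order is preserved. ``kind`` selects the
    record type ("nucleotide" or "protein"). Duplicate ids raise, naming the id.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"unknown FASTA kind {kind!r}")
    cls = Transcript if kind == "nucleotide" else ProteinRecord
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"malformed FASTA: expected '>' header, got {line.strip()[:40]!r}",
                        line=lineno,
                    )
                break
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(cls(id=rec.id, seq=str(rec.seq), description=desc))
    return records


def write_fasta(records: Sequence[FastaRecord], path, line_width: int = 60) -> None:
    """Write records as FASTA; re-reading yields identical records."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Read GTF exon lines into :class:`TranscriptModel` objects.

    Only ``exon`` features are considered; exons are grouped by their
    ``transcript_id`` attribute, converted from 1-based inclusive to 0-based
    half-open, and sorted. All exons of one transcript must share a contig
    and a strand. A ``source_length`` attribute, when present, is parsed
    back into the model (it is emitted by :func:`write_gtf`).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"GTF file not found: {path}")
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, Optional[int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"GTF line has {len(fields)} tab-separated fields, expected >= 8",
                    line=lineno,
                )
            contig, _source, feature, start, end, _score, strand, _frame = fields[:8]
            if feature != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8])) if len(fields) > 8 else {}
            tid = attrs.get("transcript_id")
            if not tid:
                raise FormatError("exon line lacks a transcript_id attribute", line=lineno)
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"non-integer coordinates {start!r}..{end!r}", line=lineno)
            if strand not in ("+", "-"):
                raise FormatError(f"invalid strand {strand!r}", line=lineno)
            src_len = attrs.get("source_length")
            src_len_i = int(src_len) if src_len is not None else None
            if tid not in meta:
                meta[tid] = (contig, strand, src_len_i)
                order.append(tid)
            else:
                c0, s0, l0 = meta[tid]
                if c0 != contig:
                    raise FormatError(
                        f"transcript {tid!r} has exons on contigs {c0!r} and {contig!r}",
                        line=lineno,
                    )
                if s0 != strand:
                    raise FormatError(
                        f"transcript {tid!r} has exons on strands {s0!r} and {strand!r}",
                        line=lineno,
                    )
                if src_len_i is not None and l0 is None:
                    meta[tid] = (c0, s0, src_len_i)
            # GTF 1-based inclusive -> 0-based half-open
            exons.setdefault(tid, []).append((start_i - 1, end_i))
    models = []
    for tid in order:
        contig, strand, src_len = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                contig_id=contig,
                strand=strand,
                exons=sorted(exons[tid]),
                source_length=src_len,
            )
        )
    return models


def write_gtf(models: Sequence[TranscriptModel], path, source: str = "txconsolidate") -> None:
    """Write models as GTF exon lines (0-based half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.transcript_id}"; transcript_id "{m.transcript_id}";'
            if m.source_length is not None:
                attrs += f' source_length "{m.source_length}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.contig_id}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


_PSL_HEADER_TOKENS = ("psLayout", "match", "-----")


def _read_psl(path) -> list[AlnRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or any(line.startswith(t) for t in _PSL_HEADER_TOKENS):
                continue
            fields = line.split("\t")
            if len(fields) != 21:
                raise FormatError(
                    f"PSL line has {len(fields)} fields, expected 21", line=lineno
                )
            try:
                (matches, mismatches, rep_matches, _n_count,
                 _q_num_ins, q_base_ins, _t_num_ins, t_base_ins,
                 strand, q_name, q_size, _q_start, _q_end,
                 t_name, t_size, _t_start, _t_end, block_count) = (
                    int(fields[0]), int(fields[1]), int(fields[2]), int(fields[3]),
                    int(fields[4]), int(fields[5]), int(fields[6]), int(fields[7]),
                    fields[8], fields[9], int(fields[10]), int(fields[11]), int(fields[12]),
                    fields[13], int(fields[14]), int(fields[15]), int(fields[16]),
                    int(fields[17]),
                )
                sizes = [int(x) for x in fields[18].rstrip(",").split(",") if x]
                q_starts = [int(x) for x in fields[19].rstrip(",").split(",") if x]
                t_starts = [int(x) for x in fields[20].rstrip(",").split(",") if x]
            except ValueError:
                raise FormatError("non-numeric field in PSL line", line=lineno)
            if not (len(sizes) == len(q_starts) == len(t_starts) == block_count):
                raise FormatError("PSL block list lengths disagree", line=lineno)
            m = matches + rep_matches
            records.append(
                AlnRecord(
                    query_id=q_name,
                    target_id=t_name,
                    query_len=q_size,
                    target_len=t_size,
                    strand_or_frame=strand,
                    blocks=list(zip(q_starts, t_starts, sizes)),
                    matches=m,
                    mismatches=mismatches,
                    gap_columns=q_base_ins + t_base_ins,
                    score=float(m - mismatches - (q_base_ins + t_base_ins)),
                )
            )
    return records


def _read_blast_tab(path) -> list[AlnRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"BLAST tabular line has {len(fields)} fields, expected 12",
                    line=lineno,
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                mismatches = int(fields[4])
                _gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise FormatError("non-numeric field in BLAST tabular line", line=lineno)
            strand = "+"
            if sstart > send:
                strand = "-"
                sstart, send = send, sstart
            q0, s0 = qstart - 1, sstart - 1
            q_span = qend - qstart + 1
            s_span = send - sstart + 1
            # alignment length includes gap columns on both axes:
            #   length = q_span + gaps_in_query = s_span + gaps_in_subject
            gap_columns = max(0, 2 * length - q_span - s_span)
            matches = length - mismatches - gap_columns
            if matches < 0:
                raise FormatError("inconsistent BLAST gap/length accounting", line=lineno)
            records.append(
                AlnRecord(
                    query_id=qid,
                    target_id=sid,
                    query_len=0,  # unknown from the 12-column dialect
                    target_len=0,
                    strand_or_frame=strand,
                    blocks=[(q0, s0, matches + mismatches)],
                    matches=matches,
                    mismatches=mismatches,
                    gap_columns=gap_columns,
                    score=bitscore,
                    evalue=evalue,
                    blockless=True,
                )
            )
    return records


def read_alignments(path, dialect: str) -> list[AlnRecord]:
    """Read precomputed alignments in ``psl`` or ``blast-tab`` dialect.

    blast-tab records lack block structure; they are flagged ``blockless``
    (with gap columns inferred from span/length accounting) and carry
    ``query_len``/``target_len`` of 0, so only operations consuming
    coverage-free quantities (identity, gaps, e-value) accept them.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"alignment file not found: {path}")
    if dialect == "psl":
        return _read_psl(path)
    if dialect == "blast-tab":
        return _read_blast_tab(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_psl(records: Sequence[AlnRecord], path) -> None:
    """Write block-chain alignments as headerless PSL (bit-exact round trip)."""
    with open(path, "w") as fh:
        for r in records:
            if r.blockless:
                raise ValueError(
                    f"alignment {r.query_id}->{r.target_id} is blockless; cannot emit PSL"
                )
            q_gaps = 0
            t_gaps = 0
            q_ins = 0
            t_ins = 0
            for (q0, t0, l0), (q1, t1, _) in zip(r.blocks, r.blocks[1:]):
                dq = q1 - (q0 + l0)
                dt = t1 - (t0 + l0)
                if dq:
                    q_ins += 1
                    q_gaps += dq
                if dt:
                    t_ins += 1
                    t_gaps += dt
            q_start = r.blocks[0][0]
            q_end = r.blocks[-1][0] + r.blocks[-1][2]
            t_start = r.blocks[0][1]
            t_end = r.blocks[-1][1] + r.blocks[-1][2]
            sizes = ",".join(str(l) for _, _, l in r.blocks) + ","
            q_starts = ",".join(str(q) for q, _, _ in r.blocks) + ","
            t_starts = ",".join(str(t) for _, t, _ in r.blocks) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.matches, r.mismatches, 0, 0,
                        q_ins, q_gaps, t_ins, t_gaps,
                        r.strand_or_frame, r.query_id, r.query_len, q_start, q_end,
                        r.target_id, r.target_len, t_start, t_end,
                        len(r.blocks), sizes, q_starts, t_starts,
                    )
                )
                + "\n"
            )
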