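"""Seeded generator of toy genomes, gene models, isoforms and corrupted
transcript sets with machine-readable truth labels.

The generator emulates the situation the consolidation pipeline is built
for: multi-exon genes with canonical GT..AG introns on a genome, mature
transcripts whose longest ORF is the annotated CDS, exon-skipping
isoforms, and transcript sets damaged the way real assemblers damage them
(truncations, chimeras, internal deletions, point-mutation noise, strand
flips). Expected classification labels are not hand-asserted: they are
computed at generation time by an independent dynamic-programming aligner
(Biopython's PairwiseAligner) pushed through the real classification
rules, so labels stay correct if thresholds change.

Every operation is a pure function of its seed; identical inputs yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .merge_eval import classify_transcript
from .orf import find_orfs, longest_orf, revcomp, spliced_sequence, translate
from .records import (
    AlnRecord,
    HitClass,
    ProteinRecord,
    Transcript,
    TranscriptModel,
    TruthRecord,
)
from .refpipe import CANONICAL_PAIRS, _intron_dinucleotides

__all__ = [
    "GenomeParams",
    "GenomeBundle",
    "TwoBranchInputs",
    "make_genome",
    "corrupt_transcripts",
    "make_two_branch_inputs",
    "tile_sequence",
    "dp_protein_align",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class GenomeParams:
    """Bounds for the toy genome generator.

    Exon lengths are drawn as codon multiples so exon skipping preserves
    the reading frame; CDS length is forced to at least ``min_cds_nt`` so
    every protein clears the significance proxies with margin. Skippable
    exons are restricted to CDS-internal exons no longer than
    ``max_skip_fraction`` of the CDS, so true isoforms survive the
    75%-locus-ORF filter.
    """

    n_exons: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (120, 351)
    intron_len: tuple[int, int] = (60, 800)
    isoforms: tuple[int, int] = (1, 3)
    cds_frac: tuple[float, float] = (0.60, 0.85)
    min_cds_nt: int = 240
    max_skip_fraction: float = 0.20
    intergenic: tuple[int, int] = (200, 600)
    contig_id: str = "chr1"


@dataclass
class IsoformTruth:
    transcript_id: str
    gene_id: str
    utr5: int
    cds_len: int
    mature_len: int


@dataclass
class GeneTruth:
    gene_id: str
    protein_id: str
    strand: str
    primary: str
    cds_seq: str
    isoforms: list[IsoformTruth] = field(default_factory=list)


@dataclass
class GenomeBundle:
    """Everything :func:`make_genome` produced, with truth bookkeeping."""

    genome: dict[str, str]
    models: list[TranscriptModel]
    transcripts: list[Transcript]
    proteome: list[ProteinRecord]
    genes: dict[str, GeneTruth]
    seed: int
    params: GenomeParams

    @property
    def transcripts_by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}

    @property
    def proteins_by_id(self) -> dict[str, ProteinRecord]:
        return {p.id: p for p in self.proteome}


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_utr(rng: np.random.Generator, n: int) -> str:
    """Random nucleotides free of ATG (keeps the planted CDS the longest ORF)."""
    if n == 0:
        return ""
    s = _random_nt(rng, n)
    while "ATG" in s:
        s = s.replace("ATG", "ATC")
    return s


def _random_cds(rng: np.random.Generator, cds_len: int) -> str:
    n_body = cds_len // 3 - 2
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_body)
    body = "".join(_NONSTOP_CODONS[int(i)] for i in idx)
    stop = _STOPS[int(rng.integers(0, 3))]
    return "ATG" + body + stop


def _make_gene(rng: np.random.Generator, gene_id: str, params: GenomeParams):
    """One accepted gene: exon/intron layout, mature isoforms, CDS, protein.

    Rejection-samples the random pieces until the longest ORF of every
    isoform's mature transcript is exactly the planted CDS.
    """
    p = params
    for _attempt in range(50):
        n_ex = int(rng.integers(p.n_exons[0], p.n_exons[1] + 1))
        exon_lens = [
            3 * int(rng.integers(p.exon_len[0] // 3, p.exon_len[1] // 3 + 1))
            for _ in range(n_ex)
        ]
        total = sum(exon_lens)
        frac = rng.uniform(*p.cds_frac)
        cds_len = max(p.min_cds_nt, 3 * int(frac * total / 3))
        cds_len = min(cds_len, 3 * ((total - 6) // 3))
        utr_total = total - cds_len
        utr5 = 3 * int(utr_total * rng.uniform(0.3, 0.7) / 3)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        cds = _random_cds(rng, cds_len)
        mature = (
            _random_utr(rng, utr5) + cds + _random_nt(rng, total - cds_len - utr5)
        )
        # transcript-order exon spans
        spans = []
        pos = 0
        for L in exon_lens:
            spans.append((pos, pos + L))
            pos += L
        # skippable: internal exons fully inside the CDS body, short enough
        # that skipping keeps the isoform above the locus-ORF threshold
        skippable = [
            i
            for i, (s, e) in enumerate(spans)
            if 0 < i < n_ex - 1
            and s >= utr5 + 3
            and e <= utr5 + cds_len - 3
            and (e - s) <= p.max_skip_fraction * cds_len
        ]
        n_iso = int(rng.integers(p.isoforms[0], p.isoforms[1] + 1))
        skips = list(rng.permutation(len(skippable))[: max(0, n_iso - 1)])
        isoform_skips: list[Optional[int]] = [None] + [skippable[i] for i in skips]
        matures = []
        ok = True
        for skip in isoform_skips:
            if skip is None:
                iso_mature = mature
                iso_cds = cds_len
            else:
                s, e = spans[skip]
                iso_mature = mature[:s] + mature[e:]
                iso_cds = cds_len - (e - s)
            o = longest_orf(Transcript(id="x", seq=iso_mature))
            if (
                o is None
                or o.strand != "+"
                or o.start != utr5
                or o.length_nt != iso_cds
                or iso_cds < 0.6 * len(iso_mature)  # CDS-dominant isoforms only
            ):
                ok = False
                break
            matures.append((skip, iso_mature, iso_cds))
        if ok:
            introns = [
                "GT" + _random_nt(rng, int(rng.integers(*p.intron_len)) - 4) + "AG"
                for _ in range(n_ex - 1)
            ]
            return {
                "gene_id": gene_id,
                "strand": strand,
                "exon_lens": exon_lens,
                "spans": spans,
                "utr5": utr5,
                "cds_len": cds_len,
                "cds": cds,
                "mature": mature,
                "introns": introns,
                "matures": matures,
            }
    raise RuntimeError(f"gene generation failed to converge for {gene_id}")


def make_genome(
    n_genes: int,
    seed: int,
    params: Optional[GenomeParams] = None,
) -> GenomeBundle:
    """Generate a toy genome with multi-exon genes, isoforms and a proteome.

    All introns read GT..AG on the coding strand; every mature
    transcript's longest ORF is its annotated CDS (ATG..stop) spanning at
    least 60% of the transcript; the proteome holds one protein per gene
    (the primary isoform's translation). Fully deterministic given
    ``(n_genes, seed, params)``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    p = params or GenomeParams()
    if p.exon_len[0] < 100 // 3 * 3 or p.intron_len[0] < 10:
        raise ValueError("contradictory generator bounds")
    rng = np.random.default_rng(seed)
    contig_parts: list[str] = []
    offset = 0
    models: list[TranscriptModel] = []
    transcripts: list[Transcript] = []
    proteome: list[ProteinRecord] = []
    genes: dict[str, GeneTruth] = {}
    for g in range(n_genes):
        gid = f"g{g:03d}"
        spec = _make_gene(rng, gid, p)
        spacer = _random_nt(rng, int(rng.integers(*p.intergenic)))
        contig_parts.append(spacer)
        offset += len(spacer)
        # genomic layout of the full (primary) exon chain, transcript order
        region_parts = []
        exon_genomic_tx_order = []  # per full-model exon, in transcript order
        pos = 0
        for i, L in enumerate(spec["exon_lens"]):
            exon_genomic_tx_order.append((pos, pos + L))
            region_parts.append(spec["mature"][spec["spans"][i][0] : spec["spans"][i][1]])
            pos += L
            if i < len(spec["introns"]):
                region_parts.append(spec["introns"][i])
                pos += len(spec["introns"][i])
        region = "".join(region_parts)
        if spec["strand"] == "-":
            region_seq = revcomp(region)
            exon_genomic = [
                (len(region) - e, len(region) - s) for s, e in exon_genomic_tx_order
            ]
        else:
            region_seq = region
            exon_genomic = list(exon_genomic_tx_order)
        contig_parts.append(region_seq)
        gene_protein = ProteinRecord(
            id=f"{gid}_p",
            seq=translate(spec["cds"], 0)[:-1],
            description=f"gene={gid} seed={seed}",
        )
        proteome.append(gene_protein)
        truth = GeneTruth(
            gene_id=gid,
            protein_id=gene_protein.id,
            strand=spec["strand"],
            primary=f"{gid}.i0",
            cds_seq=spec["cds"],
        )
        for j, (skip, iso_mature, iso_cds) in enumerate(spec["matures"]):
            tid = f"{gid}.i{j}"
            keep = [i for i in range(len(spec["exon_lens"])) if i != skip]
            exons = sorted(
                (offset + exon_genomic[i][0], offset + exon_genomic[i][1])
                for i in keep
            )
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    contig_id=p.contig_id,
                    strand=spec["strand"],
                    exons=exons,
                    source_length=len(iso_mature),
                )
            )
            transcripts.append(
                Transcript(
                    id=tid, seq=iso_mature, description=f"gene={gid} seed={seed}"
                )
            )
            truth.isoforms.append(
                IsoformTruth(
                    transcript_id=tid,
                    gene_id=gid,
                    utr5=spec["utr5"],
                    cds_len=iso_cds,
                    mature_len=len(iso_mature),
                )
            )
        genes[gid] = truth
        offset += len(region_seq)
    contig_parts.append(_random_nt(rng, int(rng.integers(*p.intergenic))))
    genome = {p.contig_id: "".join(contig_parts)}
    bundle = GenomeBundle(
        genome=genome,
        models=models,
        transcripts=transcripts,
        proteome=proteome,
        genes=genes,
        seed=seed,
        params=p,
    )
    _audit_bundle(bundle)
    return bundle


def _audit_bundle(bundle: GenomeBundle) -> None:
    """Internal-consistency audit run on every generated bundle."""
    by_id = bundle.transcripts_by_id
    for m in bundle.models:
        if spliced_sequence(m, bundle.genome) != by_id[m.transcript_id].seq:
            raise AssertionError(
                f"generator inconsistency: model {m.transcript_id} does not "
                "reproduce its mature transcript"
            )
        for pair in _intron_dinucleotides(m, bundle.genome[m.contig_id]):
            if pair not in CANONICAL_PAIRS:
                raise AssertionError(
                    f"generator inconsistency: non-canonical intron in {m.transcript_id}"
                )


_DP = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def dp_protein_align(
    query_id: str, q: str, target_id: str, t: str
) -> Optional[AlnRecord]:
    """Optimal local protein alignment by dynamic programming (linear gaps).

    Independent of the seed-and-chain aligner; used to compute expected
    classification labels at generation time (and reusable as an oracle).
    """
    if not q or not t:
        return None
    alns = _DP.align(q, t)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    q_blocks, t_blocks = aln.aligned
    blocks = []
    matches = mismatches = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        seg_q = q[qs:qe]
        seg_t = t[ts:te]
        m = sum(1 for a, b in zip(seg_q, seg_t) if a == b and a not in "X*")
        matches += m
        mismatches += (qe - qs) - m
        blocks.append((int(qs), int(ts), int(qe - qs)))
    gaps = 0
    for (q0, t0, l0), (q1, t1, _) in zip(blocks, blocks[1:]):
        gaps += (q1 - (q0 + l0)) + (t1 - (t0 + l0))
    return AlnRecord(
        query_id=query_id,
        target_id=target_id,
        query_len=len(q),
        target_len=len(t),
        strand_or_frame="+",
        blocks=blocks,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        score=float(matches - mismatches - gaps),
    )


def _expected_class(
    t: Transcript,
    candidates: Sequence[ProteinRecord],
    min_orf_nt: int,
    **thresholds,
) -> HitClass:
    hits = []
    for o in find_orfs(t, min_len_nt=min_orf_nt):
        for p in candidates:
            aln = dp_protein_align(f"{t.id}|orf", o.aa_seq, p.id, p.seq)
            if aln is not None:
                hits.append(aln)
    return classify_transcript(t, hits, **thresholds)


DEFAULT_CORRUPTION_PARAMS = {
    "truncation": {"fraction": 0.7},
    "internal_deletion": {"span": 30},
    "point_mutations": {"rate": 0.2},
}


def corrupt_transcripts(
    bundle: GenomeBundle,
    corruption_spec: dict[str, float],
    seed: int,
    n: Optional[int] = None,
    min_orf_nt: int = 200,
    corruption_params: Optional[dict] = None,
    **thresholds,
) -> tuple[list[Transcript], list[TruthRecord]]:
    """Produce a damaged transcript set with oracle-computed truth labels.

    ``corruption_spec`` maps corruption names (none, truncation, chimera,
    internal_deletion, point_mutations, strand_flip) to fractions summing
    to <= 1 (the remainder is 'none'). ``n`` transcripts are drawn by
    cycling the bundle's mature transcript pool. Each TruthRecord's
    ``expected_class`` is computed by the DP alignment oracle pushed
    through the real classification rules.
    """
    total = sum(corruption_spec.values())
    if total > 1 + 1e-9:
        raise ValueError("corruption fractions sum to more than 1")
    known = {"none", "truncation", "chimera", "internal_deletion",
             "point_mutations", "strand_flip"}
    unknown = set(corruption_spec) - known
    if unknown:
        raise ValueError(f"unknown corruption kinds: {sorted(unknown)}")
    cp = dict(DEFAULT_CORRUPTION_PARAMS)
    if corruption_params:
        for k, v in corruption_params.items():
            cp[k] = {**cp.get(k, {}), **v}
    pool = bundle.transcripts
    if n is None:
        n = len(pool)
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for name, frac in corruption_spec.items():
        labels.extend([name] * int(round(frac * n)))
    labels = labels[:n]
    labels.extend(["none"] * (n - len(labels)))
    order = rng.permutation(n)
    assigned = [""] * n
    for slot, lab in zip(order, labels):
        assigned[int(slot)] = lab
    iso_by_tid = {
        iso.transcript_id: (g, iso)
        for g in bundle.genes.values()
        for iso in g.isoforms
    }
    out_ts: list[Transcript] = []
    truth: list[TruthRecord] = []
    use_count: dict[str, int] = {}
    gene_ids = sorted(bundle.genes)
    for i in range(n):
        src = pool[i % len(pool)]
        k = use_count.get(src.id, 0)
        use_count[src.id] = k + 1
        tid = src.id if k == 0 else f"{src.id}.{k}"
        gene, iso = iso_by_tid[src.id]
        label = assigned[i]
        params: dict = {}
        candidates = [bundle.proteins_by_id[gene.protein_id]]
        seq = src.seq
        if label == "truncation":
            frac = cp["truncation"]["fraction"]
            seq = seq[: max(3, int(frac * len(seq)))]
            params = {"fraction": frac}
        elif label == "chimera":
            others = [g for g in gene_ids if g != gene.gene_id]
            partner = bundle.genes[others[int(rng.integers(0, len(others)))]]
            p_iso = next(
                x for x in partner.isoforms if x.transcript_id == partner.primary
            )
            p_seq = bundle.transcripts_by_id[partner.primary].seq
            ha = 3 * (iso.cds_len // 6)
            hb = 3 * (p_iso.cds_len // 6)
            seq = seq[: iso.utr5 + ha] + p_seq[p_iso.utr5 + hb :]
            params = {"partner_gene": partner.gene_id}
            candidates.append(bundle.proteins_by_id[partner.protein_id])
        elif label == "internal_deletion":
            span = cp["internal_deletion"]["span"]
            pos = iso.utr5 + 3 * ((iso.cds_len // 2) // 3)
            seq = seq[:pos] + seq[pos + span :]
            params = {"span": span}
        elif label == "point_mutations":
            rate = cp["point_mutations"]["rate"]
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = rng.random(len(arr)) < rate
            shifts = rng.integers(1, 4, size=len(arr))
            base_idx = np.searchsorted(_BASES, arr)
            arr[mask] = _BASES[(base_idx[mask] + shifts[mask]) % 4]
            seq = arr.tobytes().decode()
            params = {"rate": rate}
        elif label == "strand_flip":
            seq = revcomp(seq)
        t = Transcript(
            id=tid, seq=seq,
            description=f"source={src.id} corruption={label} seed={seed}",
        )
        out_ts.append(t)
        truth.append(
            TruthRecord(
                transcript_id=tid,
                source_gene=gene.gene_id,
                source_isoform=src.id,
                corruption=label,
                params=params,
                expected_class=_expected_class(
                    t, candidates, min_orf_nt, **thresholds
                ),
            )
        )
    return out_ts, truth


@dataclass
class TwoBranchInputs:
    """Reference-branch models and de novo-branch transcripts with plants."""

    ref_models: list[TranscriptModel]
    denovo_transcripts: list[Transcript]
    planted_low_coverage: list[str]
    planted_noncanonical: list[str]
    planted_short_orf: list[str]
    planted_containment: list[str]


def _noncanonical_decoy(
    model: TranscriptModel, genome: dict[str, str], decoy_id: str
) -> Optional[TranscriptModel]:
    """Shift an intron boundary of ``model`` until a splice pair goes non-canonical."""
    contig = genome[model.contig_id]
    for which in ("left", "right"):
        for delta in range(1, 13):
            exons = list(model.exons)
            s0, e0 = exons[0]
            s1, e1 = exons[1]
            if which == "left":
                if e0 - delta <= s0:
                    continue
                exons[0] = (s0, e0 - delta)
            else:
                if s1 + delta >= e1:
                    continue
                exons[1] = (s1 + delta, e1)
            cand = TranscriptModel(
                transcript_id=decoy_id,
                contig_id=model.contig_id,
                strand=model.strand,
                exons=exons,
            )
            cand.source_length = cand.spliced_length
            pairs = list(_intron_dinucleotides(cand, contig))
            if any(p not in CANONICAL_PAIRS for p in pairs):
                return cand
    return None


def _short_orf_decoy(
    bundle: GenomeBundle, gene: GeneTruth, decoy_id: str
) -> Optional[TranscriptModel]:
    """Transcript-order prefix of a gene's primary model retaining ~40% of the CDS."""
    model = next(m for m in bundle.models if m.transcript_id == gene.primary)
    iso = next(x for x in gene.isoforms if x.transcript_id == gene.primary)
    for frac in (0.4, 0.3):
        target = iso.utr5 + int(frac * iso.cds_len)
        tx_order = model.exons if model.strand == "+" else list(reversed(model.exons))
        kept = []
        cum = 0
        for s, e in tx_order:
            L = e - s
            if cum + L >= target:
                need = target - cum
                if need > 0:
                    if model.strand == "+":
                        kept.append((s, s + need))
                    else:
                        kept.append((e - need, e))
                break
            kept.append((s, e))
            cum += L
        cand = TranscriptModel(
            transcript_id=decoy_id,
            contig_id=model.contig_id,
            strand=model.strand,
            exons=sorted(kept),
        )
        cand.source_length = cand.spliced_length
        o = longest_orf(Transcript(id=decoy_id, seq=spliced_sequence(cand, bundle.genome)))
        olen = o.length_nt if o is not None else 0
        if olen < 0.75 * iso.cds_len:
            return cand
    return None


def make_two_branch_inputs(
    bundle: GenomeBundle,
    seed: int,
    n_low_coverage: int = 10,
    n_noncanonical: int = 10,
    n_short_orf: int = 10,
    n_containment: int = 15,
) -> TwoBranchInputs:
    """Build the two pipeline input branches with planted, logged defects.

    The reference branch carries the truth models plus low-coverage,
    non-canonical-splice and short-ORF decoys (one per sampled gene); the
    de novo branch carries each gene's primary CDS plus planted contained
    fragments. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    gene_ids = sorted(bundle.genes)
    models_by_tid = {m.transcript_id: m for m in bundle.models}

    def pick_gene(i: int) -> GeneTruth:
        return bundle.genes[gene_ids[int(rng.integers(0, len(gene_ids)))]]

    ref_models = list(bundle.models)
    low_cov: list[str] = []
    for i in range(n_low_coverage):
        g = pick_gene(i)
        base = models_by_tid[g.primary]
        decoy = TranscriptModel(
            transcript_id=f"decoy_lowcov{i:02d}",
            contig_id=base.contig_id,
            strand=base.strand,
            exons=list(base.exons),
            source_length=int(base.spliced_length / 0.7) + 1,
        )
        ref_models.append(decoy)
        low_cov.append(decoy.transcript_id)
    noncanon: list[str] = []
    i = 0
    while len(noncanon) < n_noncanonical:
        g = pick_gene(i)
        base = models_by_tid[g.primary]
        decoy = _noncanonical_decoy(
            base, bundle.genome, f"decoy_splice{len(noncanon):02d}"
        )
        i += 1
        if decoy is None:
            continue
        ref_models.append(decoy)
        noncanon.append(decoy.transcript_id)
    short_orf: list[str] = []
    i = 0
    while len(short_orf) < n_short_orf:
        g = pick_gene(i)
        decoy = _short_orf_decoy(bundle, g, f"decoy_orf{len(short_orf):02d}")
        i += 1
        if decoy is None:
            continue
        ref_models.append(decoy)
        short_orf.append(decoy.transcript_id)
    denovo: list[Transcript] = [
        Transcript(
            id=f"{g}.cds",
            seq=bundle.genes[g].cds_seq,
            description=f"gene={g} seed={seed}",
        )
        for g in gene_ids
    ]
    containment: list[str] = []
    for i in range(n_containment):
        g = pick_gene(i)
        cds = g.cds_seq
        L = max(100, int(rng.uniform(0.4, 0.6) * len(cds)))
        a = int(rng.integers(0, len(cds) - L + 1))
        tid = f"plant_contain{i:02d}"
        denovo.append(
            Transcript(
                id=tid, seq=cds[a : a + L],
                description=f"contained_in={g.gene_id}.cds seed={seed}",
            )
        )
        containment.append(tid)
    return TwoBranchInputs(
        ref_models=ref_models,
        denovo_transcripts=denovo,
        planted_low_coverage=low_cov,
        planted_noncanonical=noncanon,
        planted_short_orf=short_orf,
        planted_containment=containment,
    )


def tile_sequence(
    seq: str,
    n_fragments: int,
    rng: np.random.Generator,
    min_overlap: int = 60,
    max_overlap: int = 120,
) -> list[tuple[int, int]]:
    """Forward tiling of ``seq`` into overlapping fragments.

    Consecutive fragments overlap by [min_overlap, max_overlap] nt;
    non-consecutive fragments are disjoint, so greedy overlap-consensus
    assembly reconstructs ``seq`` exactly from error-free fragments.
    """
    L = len(seq)
    if n_fragments < 2 or L < n_fragments * (min_overlap + 40):
        raise ValueError("sequence too short for the requested tiling")
    bounds = [0]
    base = L // n_fragments
    for i in range(1, n_fragments):
        jitter = int(rng.integers(-base // 8, base // 8 + 1))
        bounds.append(min(L - 1, max(bounds[-1] + min_overlap + 10, i * base + jitter)))
    bounds.append(L)
    frags = []
    for i in range(n_fragments):
        start = bounds[i]
        end = bounds[i + 1]
        if i > 0:
            seg = bounds[i] - bounds[i - 1]
            ovl = int(rng.integers(min_overlap, min(max_overlap, seg - 5) + 1))
            start = bounds[i] - ovl
        frags.append((start, end))
    return frags
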