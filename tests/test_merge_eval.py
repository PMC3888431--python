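import numpy as np
import pytest

from txconsolidate import (
    AlnRecord,
    ClusterSet,
    HitClass,
    LocusAssignment,
    ProteinRecord,
    Transcript,
    classify_set,
    classify_transcript,
    merge_sets,
    paralog_table,
    presence_test,
    u80_metric,
    unique_u80,
)
from txconsolidate.records import ValidationError

from conftest import random_nt
from test_align import _CODON, encode, random_aa


def hit(target_cov=0.95, query_cov=0.95, gap_fraction=0.0, identity=100.0,
        matches=None, target_id="p", score=None):
    """Construct an AlnRecord with the requested derived quantities."""
    q_len = 1000
    aligned = int(round(query_cov * q_len))
    t_len = int(round(aligned / target_cov))
    m = int(round(identity / 100.0 * aligned)) if matches is None else matches
    mm = aligned - m
    gaps = int(round(gap_fraction * aligned / (1 - gap_fraction)))
    blocks = (
        [(0, 0, aligned)]
        if gaps == 0
        else [(0, 0, aligned // 2), (aligned // 2 + gaps, aligned // 2 + gaps,
                                     aligned - aligned // 2)]
    )
    return AlnRecord(
        query_id="q", target_id=target_id, query_len=q_len, target_len=t_len,
        strand_or_frame="+", blocks=blocks, matches=m, mismatches=mm,
        gap_columns=gaps, score=float(m - mm - gaps) if score is None else score,
    )


class TestClassifyTranscript:
    t = Transcript(id="t", seq="ATGAAA")

    def test_correct(self):
        assert classify_transcript(
            self.t, [hit(target_cov=0.95, gap_fraction=0.005)]
        ) == HitClass.CORRECT

    def test_incomplete(self):
        assert classify_transcript(
            self.t, [hit(target_cov=0.60, query_cov=0.95, gap_fraction=0.0)]
        ) == HitClass.INCOMPLETE

    def test_false(self):
        assert classify_transcript(
            self.t, [hit(target_cov=0.60, query_cov=0.60, gap_fraction=0.0)]
        ) == HitClass.FALSE

    def test_no_hit_low_identity(self):
        assert classify_transcript(
            self.t, [hit(identity=85.0)]
        ) == HitClass.NO_HIT

    def test_no_hit_insignificant_matches(self):
        assert classify_transcript(
            self.t, [hit(matches=10, query_cov=0.02)]
        ) == HitClass.NO_HIT

    def test_evalue_gate_when_available(self):
        h = hit()
        h.evalue = 1e-10  # above the 1e-20 cutoff
        assert classify_transcript(self.t, [h]) == HitClass.NO_HIT
        h.evalue = 1e-30
        assert classify_transcript(self.t, [h]) == HitClass.CORRECT

    def test_best_hit_by_score_then_target_id(self):
        good = hit(target_cov=0.95, score=500.0, target_id="b")
        other = hit(target_cov=0.60, query_cov=0.60, score=500.0, target_id="a")
        # equal scores: target id 'a' wins -> false
        assert classify_transcript(self.t, [good, other]) == HitClass.FALSE

    def test_classes_partition_input(self, rng):
        classes = [
            classify_transcript(self.t, [hit(
                target_cov=float(rng.uniform(0.3, 1.0)),
                query_cov=float(rng.uniform(0.3, 1.0)),
                gap_fraction=float(rng.choice([0.0, 0.005, 0.05])),
                identity=float(rng.uniform(80, 100)),
            )])
            for _ in range(100)
        ]
        assert all(isinstance(c, HitClass) for c in classes)


class TestClassifySet:
    def test_exact_cds_copies_all_correct(self, single_isoform_bundle):
        b = single_isoform_bundle
        ts = [Transcript(id=f"{g}.cds", seq=b.genes[g].cds_seq) for g in sorted(b.genes)]
        fractions, table = classify_set(ts, b.proteome)
        assert fractions["correct"] == 1.0
        assert set(table.hit_class) == {"correct"}

    def test_empty_set_fractions_undefined(self, single_isoform_bundle):
        fractions, table = classify_set([], single_isoform_bundle.proteome)
        assert all(v is None for v in fractions.values())
        assert len(table) == 0


class TestMergeSets:
    def test_denovo_covered_removed(self, rng):
        ref = Transcript(id="r", seq=random_nt(rng, 1000))
        dn = Transcript(id="d", seq=ref.seq[10:980])  # coverage 1.0 > 0.95
        final, log = merge_sets([ref], [dn])
        assert [t.id for t in final] == ["r"]
        assert log[0].rule == "denovo_covered_by_ref"

    def test_identical_pair_reference_survives(self, rng):
        s = random_nt(rng, 800)
        final, log = merge_sets([Transcript(id="r", seq=s)], [Transcript(id="d", seq=s)])
        assert [t.id for t in final] == ["r"]
        assert [e.removed_id for e in log] == ["d"]

    def test_ref_removed_only_when_fully_covered_ungapped(self, rng):
        dn = Transcript(id="d", seq=random_nt(rng, 1200))
        ref = Transcript(id="r", seq=dn.seq[100:700])  # ref wholly inside denovo
        final, log = merge_sets([ref], [dn])
        assert [t.id for t in final] == ["d"]
        assert log[0].rule == "ref_fully_covered_by_denovo"

    def test_partial_cover_keeps_both(self, rng):
        ref = Transcript(id="r", seq=random_nt(rng, 1000))
        dn = Transcript(id="d", seq=ref.seq[:500] + random_nt(rng, 500))  # cov 0.5
        final, log = merge_sets([ref], [dn])
        assert {t.id for t in final} == {"r", "d"} and log == []

    def test_id_collision_rejected(self, rng):
        s = random_nt(rng, 100)
        with pytest.raises(ValidationError, match="collision"):
            merge_sets([Transcript(id="x", seq=s)], [Transcript(id="x", seq=s)])

    def test_postcondition_audit(self, small_bundle, rng):
        # after merging, no surviving de novo transcript may still satisfy
        # the removal predicate against a surviving reference transcript
        genes = sorted(small_bundle.genes)
        ref = [
            Transcript(id=f"r_{g}", seq=small_bundle.transcripts_by_id[
                small_bundle.genes[g].primary].seq)
            for g in genes[:8]
        ]
        dn = [
            Transcript(id=f"d_{g}", seq=small_bundle.genes[g].cds_seq)
            for g in genes
        ]
        final, log = merge_sets(ref, dn)
        final_ref = [t for t in final if t.id.startswith("r_")]
        final_dn = [t for t in final if t.id.startswith("d_")]
        from txconsolidate import ungapped_align_nt

        for d in final_dn:
            for r in final_ref:
                a = ungapped_align_nt(d, r)
                assert a is None or a.query_coverage < 0.95


def _u80_fixture(rng, covered_aa, gap_layout=None):
    """One 100-aa protein and a transcript encoding a chosen slice of it.

    Flanks encode W runs (absent from the protein alphabet used) so the
    alignment cannot extend past the intended span.
    """
    aa = random_aa(rng, 100)
    prot = ProteinRecord(id="p", seq=aa)
    flank = _CODON["W"] * 10
    if gap_layout is None:
        core = encode(aa[10 : 10 + covered_aa])
    else:
        a, skip, b = gap_layout
        core = encode(aa[a[0] : a[1]]) + encode(aa[b[0] : b[1]])
    t = Transcript(id="t", seq=flank + core + flank)
    return prot, t


class TestU80:
    def test_exact_full_length_counts(self, rng):
        aa = random_aa(rng, 120)
        prot = ProteinRecord(id="p", seq=aa)
        t = Transcript(id="t", seq=encode(aa))
        count, table = u80_metric([prot], [t])
        assert count == 1 and table.per_protein["p"] == "ungapped"

    def test_coverage_boundary_inclusive_at_080(self, rng):
        prot, t = _u80_fixture(rng, covered_aa=80)
        count, table = u80_metric([prot], [t])
        assert count == 1 and table.per_protein["p"] == "ungapped"

    def test_coverage_079_does_not_count(self, rng):
        prot, t = _u80_fixture(rng, covered_aa=79)
        count, table = u80_metric([prot], [t])
        assert count == 0 and table.per_protein["p"] == "uncovered"

    def test_gapped_chain_lands_in_le5_class(self, rng):
        # 90 aligned aa in two blocks, 3 query-side gap columns:
        # coverage 0.90, gap fraction 3/93 ~ 3.2%
        prot, t = _u80_fixture(rng, 0, gap_layout=((0, 45), 3, (48, 93)))
        count, table = u80_metric([prot], [t])
        assert count == 0 and table.per_protein["p"] == "gap_le_5pct"

    def test_large_gap_lands_in_gt5_class(self, rng):
        prot, t = _u80_fixture(rng, 0, gap_layout=((0, 45), 10, (55, 100)))
        count, table = u80_metric([prot], [t])
        assert count == 0 and table.per_protein["p"] == "gap_gt_5pct"

    def test_class_counts_sum_to_protein_count(self, single_isoform_bundle):
        b = single_isoform_bundle
        count, table = u80_metric(b.proteome, b.transcripts[:5])
        assert sum(table.counts.values()) == len(b.proteome)

    def test_monotone_under_superset(self, single_isoform_bundle):
        b = single_isoform_bundle
        u_small, _ = u80_metric(b.proteome, b.transcripts[:4])
        u_big, _ = u80_metric(b.proteome, b.transcripts)
        assert u_small <= u_big


class TestUniqueU80:
    def test_identical_sets_no_unique(self, single_isoform_bundle):
        b = single_isoform_bundle
        ts = b.transcripts[:4]
        assert unique_u80(b.proteome, [ts, list(ts)]) == [0, 0]

    def test_disjoint_single_gene_sets(self, single_isoform_bundle):
        b = single_isoform_bundle
        sets = [[t] for t in b.transcripts[:3]]
        assert unique_u80(b.proteome, sets) == [1, 1, 1]

    def test_requires_two_sets(self, single_isoform_bundle):
        with pytest.raises(ValueError):
            unique_u80(single_isoform_bundle.proteome, [[]])


class TestPresenceTest:
    def _mutant(self, aa, n_bad):
        """Encode aa with n_bad scattered interior residues swapped to W.

        Scattering keeps the maximal-scoring run spanning the full protein,
        so the alignment identity is exactly (100 - n_bad)%.
        """
        mutated = list(aa)
        for i in np.linspace(8, 92, n_bad).astype(int):
            mutated[int(i)] = "W"
        return encode("".join(mutated))

    def test_five_point_rule_boundary(self, rng):
        aa = random_aa(rng, 100)
        prot = ProteinRecord(id="p", seq=aa)
        combined = [Transcript(id="c", seq=self._mutant(aa, 5))]  # identity 95
        final_ok = [Transcript(id="f", seq=self._mutant(aa, 9))]  # identity 91
        final_bad = [Transcript(id="g", seq=self._mutant(aa, 11))]  # identity 89
        present, missing, _ = presence_test([prot], combined, final_ok)
        assert present == {"p"} and missing == set()
        present, missing, _ = presence_test([prot], combined, final_bad)
        assert present == {"p"} and missing == {"p"}

    def test_absent_from_combined_not_counted(self, rng):
        prot = ProteinRecord(id="p", seq=random_aa(rng, 100))
        junk = [Transcript(id="j", seq=random_nt(rng, 300))]
        present, missing, _ = presence_test([prot], junk, junk)
        assert present == set() and missing == set()


class TestParalogTable:
    def test_unique_single_locus(self):
        table = paralog_table(
            ClusterSet(clusters={"c1": ["a", "b"]}),
            LocusAssignment(mapping={"a": "L1", "b": "L1"}),
        )
        assert table.counts[("unique_cluster", "single_locus")] == 1
        assert table.n_clusters == 1

    def test_shared_locus_marks_both_multiple(self):
        table = paralog_table(
            ClusterSet(clusters={"c1": ["a"], "c2": ["b"]}),
            LocusAssignment(mapping={"a": "L1", "b": "L1"}),
        )
        assert table.counts[("multiple_cluster", "single_locus")] == 2

    def test_no_locus_column(self):
        table = paralog_table(
            ClusterSet(clusters={"c1": ["a"]}),
            LocusAssignment(mapping={"a": None}),
        )
        assert table.counts[("unique_cluster", "no_locus")] == 1

    def test_membership_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paralog_table(
                ClusterSet(clusters={"c1": ["a"]}), LocusAssignment(mapping={})
            )

    def test_matches_tabulation_oracle(self, rng):
        for _ in range(50):
            n_t = int(rng.integers(4, 20))
            tids = [f"t{i:02d}" for i in range(n_t)]
            n_c = int(rng.integers(1, 5))
            n_l = int(rng.integers(1, 5))
            clusters: dict = {}
            for i, tid in enumerate(tids):
                clusters.setdefault(f"c{int(rng.integers(0, n_c))}", []).append(tid)
            mapping = {
                tid: (None if rng.random() < 0.2 else f"L{int(rng.integers(0, n_l))}")
                for tid in tids
            }
            cs = ClusterSet(clusters=clusters)
            got = paralog_table(cs, LocusAssignment(mapping=mapping))
            # direct tabulation
            cl = {c: {mapping[t] for t in ms if mapping[t]} for c, ms in clusters.items()}
            exp = {}
            for c, ls in cl.items():
                col = "no_locus" if not ls else (
                    "single_locus" if len(ls) == 1 else "multiple_loci")
                row = "multiple_cluster" if any(
                    ls & cl[o] for o in cl if o != c) else "unique_cluster"
                exp[(row, col)] = exp.get((row, col), 0) + 1
            for key, v in exp.items():
                assert got.counts[key] == v
            assert got.n_clusters == len(clusters)
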