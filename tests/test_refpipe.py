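import numpy as np
import pytest

from txconsolidate import (
    Transcript,
    TranscriptModel,
    filter_canonical_splice,
    filter_mapping_coverage,
    filter_orf_fraction,
    group_loci,
    run_refpipe,
)
from txconsolidate.orf import revcomp
from txconsolidate.records import ValidationError

from _oracles import models_overlap, overlap_components
from conftest import random_nt


def model(tid, exons, strand="+", contig="c", source_length=None):
    return TranscriptModel(
        transcript_id=tid, contig_id=contig, strand=strand, exons=exons,
        source_length=source_length,
    )


class TestMappingCoverage:
    def test_boundary_inclusive(self):
        kept, removed = filter_mapping_coverage(
            [model("a", [(0, 900)], source_length=1000)]
        )
        assert [m.transcript_id for m in kept] == ["a"] and removed == []

    def test_below_boundary_removed(self):
        kept, removed = filter_mapping_coverage(
            [model("a", [(0, 899)], source_length=1000)]
        )
        assert kept == [] and [m.transcript_id for m in removed] == ["a"]

    def test_missing_source_length_names_transcript(self):
        with pytest.raises(ValidationError, match="'a'"):
            filter_mapping_coverage([model("a", [(0, 100)])])

    def test_matches_predicate_oracle(self, rng):
        models = []
        for i in range(300):
            spliced = int(rng.integers(100, 1000))
            src = int(rng.integers(spliced, int(spliced / 0.75)))
            models.append(model(f"m{i}", [(0, spliced)], source_length=src))
        kept, removed = filter_mapping_coverage(models)
        for m in models:
            expected_kept = m.spliced_length / m.source_length >= 0.90
            assert (m in kept) == expected_kept
            assert (m in removed) != expected_kept


def _two_exon_genome(intron_seq, strand="+"):
    """A genome where t has exons [0,30) and [30+len(intron),60+len(intron))."""
    e1, e2 = random_nt(np.random.default_rng(0), 30), random_nt(
        np.random.default_rng(1), 30
    )
    contig = e1 + intron_seq + e2
    m = model(
        "t", [(0, 30), (30 + len(intron_seq), 60 + len(intron_seq))], strand=strand
    )
    m.source_length = 60
    return m, {"c": contig}


class TestCanonicalSplice:
    def test_gt_ag_kept(self):
        m, genome = _two_exon_genome("GT" + "C" * 50 + "AG")
        kept, removed = filter_canonical_splice([m], genome)
        assert kept == [m]

    def test_gt_ac_removed(self):
        m, genome = _two_exon_genome("GT" + "C" * 50 + "AC")
        kept, removed = filter_canonical_splice([m], genome)
        assert removed == [m]

    def test_minus_strand_reads_on_transcript_strand(self):
        # genomic forward shows CT..AC = revcomp of GT..AG read on '-'
        m, genome = _two_exon_genome("CT" + "C" * 50 + "AC", strand="-")
        kept, removed = filter_canonical_splice([m], genome)
        assert kept == [m]

    def test_single_exon_always_kept(self):
        m = model("s", [(0, 50)])
        kept, _ = filter_canonical_splice([m], {"c": "A" * 50})
        assert kept == [m]

    def test_short_intron_rejected(self):
        m = model("t", [(0, 10), (12, 20)])
        with pytest.raises(ValidationError, match="intron"):
            filter_canonical_splice([m], {"c": "A" * 20})

    def test_generator_decoys_recovered(self, small_bundle):
        from txconsolidate.synthetic import make_two_branch_inputs

        tb = make_two_branch_inputs(small_bundle, seed=3, n_low_coverage=0,
                                    n_short_orf=0, n_containment=0)
        kept, removed = filter_canonical_splice(tb.ref_models, small_bundle.genome)
        assert sorted(m.transcript_id for m in removed) == sorted(tb.planted_noncanonical)


class TestGroupLoci:
    def test_shared_exon_same_locus(self):
        la = group_loci([model("a", [(0, 100)]), model("b", [(50, 150)])])
        assert la.mapping["a"] == la.mapping["b"] == "a"

    def test_opposite_strands_different_loci(self):
        la = group_loci(
            [model("a", [(0, 100)], strand="+"), model("b", [(0, 100)], strand="-")]
        )
        assert la.mapping["a"] != la.mapping["b"]

    def test_abutting_intervals_do_not_overlap(self):
        la = group_loci([model("a", [(0, 100)]), model("b", [(100, 200)])])
        assert la.mapping["a"] != la.mapping["b"]

    def test_chained_overlap_links_transitively(self):
        la = group_loci(
            [model("a", [(0, 100)]), model("b", [(90, 200)]), model("c", [(190, 300)])]
        )
        assert len({la.mapping["a"], la.mapping["b"], la.mapping["c"]}) == 1

    def test_matches_connected_component_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 16))
            models = []
            for i in range(n):
                start = int(rng.integers(0, 500))
                n_ex = int(rng.integers(1, 4))
                exons = []
                pos = start
                for _e in range(n_ex):
                    ln = int(rng.integers(10, 60))
                    exons.append((pos, pos + ln))
                    pos += ln + int(rng.integers(5, 50))
                models.append(
                    model(
                        f"m{i:02d}", exons,
                        strand="+" if rng.random() < 0.7 else "-",
                        contig="c1" if rng.random() < 0.8 else "c2",
                    )
                )
            got = group_loci(models)
            comps = overlap_components(models, models_overlap)
            exp_partition = {
                frozenset(models[i].transcript_id for i in c) for c in comps
            }
            got_partition = {
                frozenset(tids) for tids in got.loci.values()
            }
            assert got_partition == exp_partition


def _cds_of_len(rng, n):
    """An ORF of exactly n nt (ATG + body + stop) with no internal stops."""
    codons = [c for c in
              ("GCT", "TGC", "GAC", "GAA", "TTC", "GGA", "CAC", "ATC", "AAA")
              ]
    body = "".join(codons[int(i)] for i in rng.integers(0, len(codons), n // 3 - 2))
    return "ATG" + body + "TAA"


class TestOrfFraction:
    def test_locus_rule_boundary(self, rng):
        # shared first exon links the models into one locus; ORFs 900 vs 600
        a_cds = _cds_of_len(rng, 900)
        b_cds = _cds_of_len(rng, 600)
        contig = "TTTTT" + a_cds + b_cds + "C" * 10
        a = model("a", [(0, 5), (5, 905)])
        b = model("b", [(0, 5), (905, 1505)])
        kept, removed = filter_orf_fraction([a, b], {"c": contig})
        assert [m.transcript_id for m in removed] == ["b"]  # 600 < 675

    def test_boundary_inclusive_at_75(self, rng):
        a_cds = _cds_of_len(rng, 900)
        b_cds = _cds_of_len(rng, 675)
        contig = "TTTTT" + a_cds + b_cds + "C" * 10
        a = model("a", [(0, 5), (5, 905)])
        b = model("b", [(0, 5), (905, 1580)])
        kept, removed = filter_orf_fraction([a, b], {"c": contig})
        assert removed == [] and len(kept) == 2

    def test_no_orf_removed_when_locus_has_one(self, rng):
        a_cds = _cds_of_len(rng, 300)
        contig = "TTTTT" + a_cds + "CCCCCCCCCC" * 5
        a = model("a", [(0, 5), (5, 305)])
        b = model("b", [(0, 5)])  # 5 nt, no ORF
        kept, removed = filter_orf_fraction([a, b], {"c": contig})
        assert [m.transcript_id for m in removed] == ["b"]


class TestRunRefpipe:
    def test_empty_input(self):
        final, loci, report = run_refpipe([], {})
        assert final == [] and loci.mapping == {}
        assert all(s["n_in"] == 0 for s in report.stages)

    def test_clean_truth_all_kept(self, small_bundle):
        final, loci, report = run_refpipe(small_bundle.models, small_bundle.genome)
        assert len(final) == len(small_bundle.models)
        assert sum(s["n_removed"] for s in report.stages) == 0

    def test_partition_and_idempotence(self, small_bundle):
        from txconsolidate.synthetic import make_two_branch_inputs

        tb = make_two_branch_inputs(small_bundle, seed=5)
        final, _loci, report = run_refpipe(tb.ref_models, small_bundle.genome)
        for s in report.stages:
            assert s["n_kept"] + s["n_removed"] == s["n_in"]
        final2, _l2, report2 = run_refpipe(final, small_bundle.genome)
        assert [m.transcript_id for m in final2] == [m.transcript_id for m in final]
        assert sum(s["n_removed"] for s in report2.stages) == 0

    def test_input_order_invariance(self, small_bundle):
        from txconsolidate.synthetic import make_two_branch_inputs

        tb = make_two_branch_inputs(small_bundle, seed=5)
        final1, _, _ = run_refpipe(tb.ref_models, small_bundle.genome)
        final2, _, _ = run_refpipe(list(reversed(tb.ref_models)), small_bundle.genome)
        assert {m.transcript_id for m in final1} == {m.transcript_id for m in final2}
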