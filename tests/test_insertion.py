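"""Insertion-candidate pipeline: classification, localization, filters."""

import pytest

from kinspector import insertion as ins
from kinspector import simulate as sim
from conftest import random_seq
from oracles import best_local_score, rc


@pytest.fixture(scope="module")
def cassette():
    return random_seq(777, 1200)


class TestCassetteClassify:
    def test_exact_substring_is_strongly_positive(self, cassette):
        reads = {"r1": cassette[200:300]}
        pos, neg = ins.cassette_classify(reads, cassette)
        assert neg == []
        hit = pos[0]
        assert hit.evalue < 1e-40  # perfect 100-nt match, closed-form tiny
        assert hit.cassette_span == (200, 300)
        # cross-check the score against full Smith-Waterman
        assert hit.score == best_local_score(cassette[200:300], cassette)

    def test_unrelated_read_is_negative(self, cassette):
        read = random_seq(123, 150)
        # independent check that no significant local similarity exists
        assert best_local_score(read, cassette) < 40
        pos, neg = ins.cassette_classify({"r1": read}, cassette)
        assert pos == [] and neg == ["r1"]

    def test_chimeric_read_span_recovered(self, cassette):
        genome_part = random_seq(31, 75)
        read = cassette[100:175] + genome_part
        pos, _ = ins.cassette_classify({"c": read}, cassette)
        (hit,) = pos
        qs, qe = hit.read_span
        assert qe - qs == pytest.approx(75, abs=3)
        assert qs <= 2

    def test_reverse_orientation_detected(self, cassette):
        pos, _ = ins.cassette_classify({"r": rc(cassette[400:520])}, cassette)
        assert pos[0].orientation == "-"
        assert pos[0].cassette_span == (400, 520)

    def test_partition_is_exhaustive(self, cassette):
        reads = {f"r{i}": random_seq(i, 150) for i in range(20)}
        reads["hit"] = cassette[:120]
        pos, neg = ins.cassette_classify(reads, cassette)
        assert len(pos) + len(neg) == len(reads)
        assert {h.read_id for h in pos}.isdisjoint(neg)

    def test_cassette_shorter_than_word_raises(self):
        with pytest.raises(ValueError):
            ins.cassette_classify({"r": "ACGTACGTACGT"}, "ACGT")


class TestLocalize:
    def make_chimeric(self, genome_seq, cassette, pos, n, flank=90, tag=""):
        """n reads: cassette prefix + genome starting at pos."""
        reads = {}
        for i in range(n):
            reads[f"chim{tag}{pos}_{i}"] = cassette[:60] + genome_seq[pos : pos + flank]
        return reads

    def test_six_reads_one_cluster(self, toy, cassette):
        genome = toy.genome
        reads = self.make_chimeric(genome["chr1"], cassette, 20_000, 6)
        hits, _ = ins.cassette_classify(reads, cassette)
        clusters = ins.localize_ics(hits, reads, genome, guide_used="left")
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.read_count == 6
        assert cl.chrom == "chr1"
        assert cl.start <= 20_000 <= cl.end + 1

    def test_two_chromosomes_two_clusters(self, toy, cassette):
        genome = toy.genome
        reads = {
            **self.make_chimeric(genome["chr1"], cassette, 15_000, 3, tag="a"),
            **self.make_chimeric(genome["chr2"], cassette, 15_000, 3, tag="b"),
        }
        hits, _ = ins.cassette_classify(reads, cassette)
        clusters = ins.localize_ics(hits, reads, genome)
        assert len(clusters) == 2
        assert {c.chrom for c in clusters} == {"chr1", "chr2"}

    def test_short_genomic_segment_not_localized(self, toy, cassette):
        reads = {"short": cassette[:140] + toy.genome["chr1"][5000:5010]}
        hits, _ = ins.cassette_classify(reads, cassette)
        clusters = ins.localize_ics(hits, reads, toy.genome)
        assert clusters == []


class TestFilterICS:
    def make_cluster(self, n_reads, chrom="chr1", start=100):
        return ins.GenomicCluster(
            chrom, start, start + 100, [f"r{i}" for i in range(n_reads)], "left"
        )

    @pytest.mark.parametrize("n,kept", [(3, 0), (4, 0), (5, 1), (6, 1)])
    def test_read_support_boundary(self, n, kept):
        assert len(ins.filter_ics([self.make_cluster(n)])) == kept

    def test_numbered_by_descending_support(self):
        clusters = [
            self.make_cluster(5, start=100),
            self.make_cluster(9, start=5000),
            self.make_cluster(7, start=9000),
        ]
        recs = ins.filter_ics(clusters)
        assert [r.read_count for r in recs] == [9, 7, 5]
        assert [r.id for r in recs] == [1, 2, 3]

    def test_monotone_in_min_reads(self):
        clusters = [self.make_cluster(n, start=1000 * n) for n in range(1, 10)]
        prev = None
        for m in range(1, 10):
            recs = ins.filter_ics(clusters, ins.ICSParams(min_reads=m))
            keys = {(r.chrom, r.start) for r in recs}
            if prev is not None:
                assert keys <= prev
            prev = keys


class TestFlagAndMerge:
    def rec(self, chrom, start, end, guide="left", rid=1, reads=10):
        return ins.ICSRecord(rid, guide, reads, chrom, start, end)

    def test_inside_locus_flagged(self):
        recs = ins.flag_on_target([self.rec("chr1", 1000, 1100)], ("chr1", 900, 1200))
        assert recs[0].on_target

    def test_distant_record_not_flagged(self):
        recs = ins.flag_on_target(
            [self.rec("chr1", 1_000_000, 1_000_100)], ("chr1", 900, 1200)
        )
        assert not recs[0].on_target

    def test_nearby_guides_merge(self):
        left = [self.rec("chr1", 1000, 1100, "left", 1)]
        right = [self.rec("chr1", 1200, 1300, "right", 1)]
        merged = ins.merge_equivalent_ics(left, right)
        assert len(merged) == 1
        m = merged[0]
        assert m.read_count == 20
        assert set(m.merged_from) == {"left:1", "right:1"}

    def test_different_chromosomes_never_merge(self):
        left = [self.rec("chr1", 1000, 1100, "left")]
        right = [self.rec("chr2", 1000, 1100, "right")]
        assert len(ins.merge_equivalent_ics(left, right)) == 2

    def test_merge_idempotent(self):
        left = [self.rec("chr1", 1000, 1100, "left", 1),
                self.rec("chr2", 5000, 5100, "left", 2, reads=6)]
        right = [self.rec("chr1", 1300, 1400, "right", 1)]
        once = ins.merge_equivalent_ics(left, right)
        twice = ins.merge_equivalent_ics(once, [])
        assert [(r.chrom, r.start, r.end, r.read_count) for r in once] == [
            (r.chrom, r.start, r.end, r.read_count) for r in twice
        ]


class TestOcsOverlap:
    def test_disjoint_and_coincident(self):
        recs = [
            ins.ICSRecord(1, "left", 8, "chr1", 1000, 1100),
            ins.ICSRecord(2, "left", 8, "chr1", 50_000, 50_100),
        ]
        from kinspector.sitecall import CleavageSite

        ocs = [CleavageSite("chr1", 1000, 1100, 10, 1, 1)]
        df = ins.ics_vs_ocs_overlap(recs, ocs)
        assert len(df) == len(recs)
        assert bool(df.iloc[0]["overlaps_ocs"]) is True
        assert bool(df.iloc[1]["overlaps_ocs"]) is False
        assert df.iloc[1]["nearest_ocs_distance"] > 40_000


class TestEndToEnd:
    def test_all_six_event_kinds_recovered(self, toy, sim_config):
        """Each archetype yields exactly one candidate within the cluster
        gap of its true breakpoint; on-target kinds are flagged."""
        cassette, guide_l, guide_r = sim.make_cassette(7)
        events = [
            sim.InsertionEvent("precise_on_target", "chr1", 40_000),
            sim.InsertionEvent(
                "on_target_deletion", "chr1", 42_000, deletion_len=4000
            ),
            sim.InsertionEvent("ri_clean", "chr1", 12_000),
            sim.InsertionEvent(
                "ri_flank_duplication", "chr1", 30_000, duplication_len=1700
            ),
            sim.InsertionEvent("ri_repeat_gap", "chr2", 12_000, gap_len=62),
            sim.InsertionEvent(
                "ri_ltr_coinsert", "chr2", 20_000, coinsert_len=623
            ),
            sim.InsertionEvent("ri_inverted", "chr2", 30_000),
        ]
        modified = sim.apply_insertion_events(toy.genome, cassette, events)
        lib_l = sim.simulate_circle_library(
            modified, [guide_l], sim_config, min_pairs_per_site=6
        )
        lib_r = sim.simulate_circle_library(
            modified, [guide_r], sim_config, min_pairs_per_site=6
        )
        params = ins.ICSParams()
        records = ins.ics_pipeline(
            {"left": lib_l.pairs, "right": lib_r.pairs},
            cassette,
            toy.genome,
            params,
            target_locus=("chr1", 40_000, 42_000),
        )
        for ev in events:
            near = [
                r
                for r in records
                if r.chrom == ev.chrom
                and r.start - params.cluster_gap <= ev.pos <= r.end + params.cluster_gap
            ]
            assert len(near) == 1, f"{ev.kind}: {near}"
            expect_on_target = ev.kind in ("precise_on_target", "on_target_deletion")
            assert near[0].on_target is expect_on_target, ev.kind
        for r in records:
            assert r.read_count >= params.min_reads
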