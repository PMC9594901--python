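"""Site-calling thresholds, planted-truth recovery, junction clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinspector import simulate as sim
from kinspector import sitecall as sc
from conftest import random_seq
from oracles import rc


def pileup(n_fwd, n_rev, pos=1000, chrom="chr1", mapq=60):
    """n forward 5' ends at pos and n reverse 5' ends at pos-1 — the
    signature of a blunt cut at pos."""
    reads = []
    for i in range(n_fwd):
        reads.append(sc.AlignedRead(f"f{i}", chrom, pos, pos + 150, "+", mapq))
    for i in range(n_rev):
        reads.append(sc.AlignedRead(f"r{i}", chrom, pos - 150, pos, "-", mapq))
    return reads


class TestReadThresholds:
    def test_four_reads_two_per_strand_emit_one_site(self):
        sites = sc.call_cleavage_sites(pileup(2, 2))
        assert len(sites) == 1
        assert sites[0].read_count == 4
        assert sites[0].window_start <= 1000 <= sites[0].window_end

    def test_three_reads_below_threshold(self):
        assert sc.call_cleavage_sites(pileup(2, 1)) == []

    def test_low_mapq_pileup_rejected(self):
        assert sc.call_cleavage_sites(pileup(2, 2, mapq=30)) == []

    def test_single_strand_pileup_never_called(self):
        assert sc.call_cleavage_sites(pileup(8, 0)) == []

    def test_five_reads_pass(self):
        sites = sc.call_cleavage_sites(pileup(3, 2))
        assert len(sites) == 1 and sites[0].read_count == 5

    def test_empty_input(self):
        assert sc.call_cleavage_sites([]) == []

    def test_control_subtraction_removes_shared_positions(self):
        sites = sc.call_cleavage_sites(pileup(3, 3), control=pileup(1, 1))
        assert sites == []


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 4), st.integers(0, 40)),
        min_size=1,
        max_size=6,
    ),
    thresholds=st.tuples(st.integers(1, 8), st.integers(1, 8)),
)
def test_raising_read_threshold_never_adds_sites(counts, thresholds):
    reads = []
    for f, r, bucket in counts:
        reads += pileup(f, r, pos=1000 + 100 * bucket)
    lo, hi = sorted(thresholds)
    lo_sites = sc.call_cleavage_sites(reads, sc.SiteCallParams(read_threshold=lo))
    hi_sites = sc.call_cleavage_sites(reads, sc.SiteCallParams(read_threshold=hi))
    lo_keys = {(s.chrom, s.window_start) for s in lo_sites}
    hi_keys = {(s.chrom, s.window_start) for s in hi_sites}
    assert hi_keys <= lo_keys
    for s in lo_sites + hi_sites:
        assert s.read_count >= lo


def test_recovers_all_planted_sites_within_window(planted_library):
    genome, guide, truth, lib = planted_library
    aligned = sc.exact_map(lib.pairs, genome)
    params = sc.SiteCallParams()
    called = sc.call_cleavage_sites(aligned, params, genome=genome, guide=guide)
    for site in truth:
        near = [
            s
            for s in called
            if s.chrom == site.chrom
            and abs(s.midpoint - site.pos) <= params.window_size
        ]
        assert len(near) == 1, f"planted site {site} not recovered exactly once"
    # no guide-matched calls away from planted loci (background rate 0)
    planted_pos = {(s.chrom, s.pos) for s in truth}
    for s in called:
        if s.guide_match is not None:
            assert any(
                s.chrom == c and abs(s.midpoint - p) <= params.window_size
                for c, p in planted_pos
            )


def test_site_seq_extraction_unknown_chromosome_raises(toy):
    site = sc.CleavageSite("chrZZ", 10, 11, 4, 1, 1)
    with pytest.raises(KeyError):
        sc.extract_site_window(toy.genome, site)


class TestReferenceFree:
    def make_pairs(self, n, seed=0, name="p"):
        s1, s2 = random_seq(seed, 150), random_seq(seed + 1, 150)
        return [sim.ReadPair(f"{name}{i}", s1, s2) for i in range(n)]

    def test_identical_prefixes_one_cluster(self):
        clusters = sc.reference_free_identify(self.make_pairs(10))
        assert len(clusters) == 1
        assert clusters[0].support == 10

    def test_two_junctions_two_clusters(self):
        pairs = self.make_pairs(5, seed=10) + self.make_pairs(3, seed=20, name="q")
        clusters = sc.reference_free_identify(pairs)
        assert [c.support for c in clusters] == [5, 3]

    def test_pair_conservation(self):
        pairs = (
            self.make_pairs(4, seed=1)
            + self.make_pairs(7, seed=2, name="q")
            + [sim.ReadPair("orphan", random_seq(3, 150), "")]
        )
        clusters = sc.reference_free_identify(pairs)
        assert sum(c.support for c in clusters) == 11  # orphan excluded

    def test_signature_canonical_under_mate_swap_and_strand(self):
        a, b = random_seq(5, 150), random_seq(6, 150)
        k = 25
        base = sc.junction_signature(a, b, k)
        # either end may be labelled read 1
        assert sc.junction_signature(b, a, k) == base
        # and the prefixes may be read on the opposite strand
        assert sc.junction_signature(rc(a[:k]), rc(b[:k]), k) == base

    def test_cluster_signature_matches_genomic_flanks(self, planted_library):
        genome, _, truth, lib = planted_library
        k = 25
        clusters = sc.reference_free_identify(lib.pairs, k=k)
        site = truth[0]
        expected = min(
            genome[site.chrom][site.pos : site.pos + k]
            + rc(genome[site.chrom][site.pos - k : site.pos]),
            genome[site.chrom][site.pos - k : site.pos]
            + rc(genome[site.chrom][site.pos : site.pos + k]),
        )
        assert any(c.signature == expected for c in clusters)


class TestConsensusPWM:
    def make_sites(self, seqs, counts=None):
        counts = counts or [4] * len(seqs)
        return [
            sc.CleavageSite("chr1", i * 100, i * 100 + 1, n, 1, 1, site_seq=q)
            for i, (q, n) in enumerate(zip(seqs, counts))
        ]

    def test_identical_sequences(self):
        seq = "AAGAAGGAGCCCTAGTTCAAGGG"
        pwm = sc.consensus_pwm(self.make_sites([seq] * 5))
        assert pwm.consensus == seq
        assert np.allclose(pwm.matrix.max(axis=0), 1.0)

    def test_columns_sum_to_one(self):
        seqs = ["ACGTA" * 4 + "GGG", "TGCAT" * 4 + "AGG"]
        pwm = sc.consensus_pwm(self.make_sites(seqs))
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sc.consensus_pwm([])

    def test_tie_break_fixed_base_order(self):
        pwm = sc.consensus_pwm(self.make_sites(["A", "C"]))
        assert pwm.consensus == "A"  # A < C in the fixed order

    def test_consensus_recovers_guide_target_from_low_mm_sites(
        self, toy, cassette_and_guides, sim_config
    ):
        """Majority vote over sites planted at <= 2 mismatches equals the
        guide target sequence (independent per-column vote oracle)."""
        _, guide_l, _ = cassette_and_guides
        sites = [
            sim.PlantedSite("chr1", 3000 + 1500 * i, "+", i % 3) for i in range(12)
        ]
        genome, truth = sim.plant_guide_sites(toy.genome, guide_l, sites, seed=4)
        planted_23mers = [
            genome[s.chrom][s.pos - 17 : s.pos + 6] for s in truth
        ]
        # independent oracle: per-column majority with A<C<G<T ties
        expect = "".join(
            min(sorted(set(col)), key=lambda b: (-col.count(b), b))
            for col in map(list, zip(*planted_23mers))
        )
        lib = sim.simulate_circle_library(
            genome, [guide_l], sim_config, min_pairs_per_site=5,
            cuts=sim.cuts_from_planted(sites),
        )
        called = sc.call_cleavage_sites(
            sc.exact_map(lib.pairs, genome), genome=genome, guide=guide_l
        )
        matched = [
            s
            for s in called
            if s.guide_match is not None and s.guide_match.bulge_kind == "none"
        ]
        pwm = sc.consensus_pwm(matched)
        assert pwm.consensus == expect == guide_l.protospacer + "AGG"


class TestRankReport:
    def test_on_target_ranks_first_when_read_count_max(self, planted_library):
        genome, guide, truth, lib = planted_library
        called = sc.call_cleavage_sites(
            sc.exact_map(lib.pairs, genome), genome=genome, guide=guide
        )
        # boost the 0-mm site's support artificially via target flagging
        on_target = max(called, key=lambda s: s.read_count)
        df = sc.rank_report(
            called, target_locus=(on_target.chrom, on_target.window_start,
                                  on_target.window_end)
        )
        assert bool(df.iloc[0]["on_target"]) is True
        assert df.iloc[0]["rank"] == 1

    def test_empty_input_yields_header_only(self):
        df = sc.rank_report([])
        assert len(df) == 0
        assert list(df.columns)[:3] == ["rank", "chrom", "pos"]

    def test_row_count_conserved(self, planted_library):
        genome, guide, _, lib = planted_library
        called = sc.call_cleavage_sites(sc.exact_map(lib.pairs, genome))
        assert len(sc.rank_report(called)) == len(called)
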