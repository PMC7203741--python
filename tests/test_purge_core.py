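"""Anchor filtering, collinear chaining, and haplotig/overlap calling."""

import numpy as np
import pytest
from helpers import best_chain_score_bruteforce, random_anchor_instance

from haplopurge.assembly_prep import split_at_gaps
from haplopurge.coverage import DepthProfile
from haplopurge.cutoffs import Cutoffs
from haplopurge.io_formats import BedInterval, ContigSeq, PafRecord
from haplopurge.purge_core import (
    Anchor,
    ChainParams,
    PurgeParams,
    build_purge_plan,
    call_haplotigs,
    call_overlaps,
    chain_anchors,
    classify_depth_extremes,
    filter_self_alignments,
)

CUT = Cutoffs(5, 28, 95, peaks=[20, 40], mode="diploid-dominant")


def paf(qname, tname, qs, qe, ts, te, nmatch=None, qlen=100_000, tlen=100_000, strand="+"):
    nm = nmatch if nmatch is not None else qe - qs
    return PafRecord(qname, qlen, qs, qe, strand, tname, tlen, ts, te,
                     nm, max(qe - qs, te - ts), 60)


def anchor(qs, qe, ts, te, nmatch, strand="+", qname="a", tname="b",
           qlen=1_000_000, tlen=1_000_000):
    return Anchor(qname, tname, qlen, tlen, qs, qe, ts, te, strand, nmatch)


def uniform_profile(spec):
    """spec: name -> (length, depth) or (length, array)."""
    depths = {}
    for name, (length, d) in spec.items():
        depths[name] = np.asarray(d, dtype=np.int32) if np.ndim(d) else np.full(length, d, dtype=np.int32)
    return DepthProfile(depths)


class TestFilter:
    def test_self_hit_dropped(self):
        assert filter_self_alignments([paf("c1", "c1", 0, 2000, 0, 2000)]) == []

    def test_symmetric_pair_deduplicated(self):
        fwd = paf("c1", "c2", 0, 2000, 500, 2500)
        mirror = paf("c2", "c1", 500, 2500, 0, 2000)
        anchors = filter_self_alignments([fwd, mirror])
        assert len(anchors) == 1
        assert anchors[0].qname == "c1" and anchors[0].tname == "c2"

    def test_min_match_threshold_edge(self):
        rec = paf("c1", "c2", 0, 1500, 0, 1500, nmatch=499)
        assert filter_self_alignments([rec], min_match=500) == []
        rec2 = paf("c1", "c2", 0, 1500, 0, 1500, nmatch=500)
        assert len(filter_self_alignments([rec2], min_match=500)) == 1

    def test_short_alignment_dropped(self):
        rec = paf("c1", "c2", 0, 900, 0, 900, nmatch=900)
        assert filter_self_alignments([rec], min_aln_len=1000) == []


class TestChaining:
    def test_two_collinear_anchors_one_chain(self):
        params = ChainParams(gap_open=0, gap_scale=0.01, min_chain_score=0)
        anchors = [anchor(0, 100, 0, 100, 100), anchor(200, 300, 200, 300, 100)]
        chains = chain_anchors(anchors, params)
        assert len(chains) == 1
        assert chains[0].score == pytest.approx(200.0)  # |qgap - tgap| = 0
        assert len(chains[0].anchors) == 2

    def test_strand_consistency_splits_chains(self):
        params = ChainParams(gap_open=0, gap_scale=0.01, min_chain_score=0)
        anchors = [anchor(0, 100, 0, 100, 100, "+"), anchor(200, 300, 200, 300, 100, "-")]
        chains = chain_anchors(anchors, params)
        assert len(chains) == 2
        assert all(len(c.anchors) == 1 for c in chains)

    def test_minus_strand_requires_decreasing_target(self):
        params = ChainParams(gap_open=0, gap_scale=0.01, min_chain_score=0)
        good = [anchor(0, 100, 900, 1000, 100, "-"), anchor(200, 300, 600, 700, 100, "-")]
        assert len(chain_anchors(good, params)) == 1
        bad = [anchor(0, 100, 600, 700, 100, "-"), anchor(200, 300, 900, 1000, 100, "-")]
        assert len(chain_anchors(bad, params)) == 2

    def test_max_gap_forbids_transition(self):
        params = ChainParams(gap_open=0, gap_scale=0.0, max_gap=1000, min_chain_score=0)
        anchors = [anchor(0, 100, 0, 100, 100), anchor(2000, 2100, 2000, 2100, 100)]
        assert len(chain_anchors(anchors, params)) == 2

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError, match="one segment pair"):
            chain_anchors([anchor(0, 100, 0, 100, 50),
                           anchor(0, 100, 0, 100, 50, qname="x", tname="y")])

    @pytest.mark.parametrize("seed", range(40))
    def test_best_score_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        params = ChainParams(gap_open=50, gap_scale=0.05, max_gap=50_000,
                             max_overlap=100, min_chain_score=0)
        anchors = random_anchor_instance(rng, max_anchors=10)
        chains = chain_anchors(anchors, params)
        oracle = best_chain_score_bruteforce(anchors, params)
        assert chains[0].score == pytest.approx(oracle)

    def test_anchor_order_invariance(self):
        rng = np.random.default_rng(123)
        anchors = random_anchor_instance(rng, max_anchors=12)
        params = ChainParams(min_chain_score=0)
        ref = chain_anchors(anchors, params)
        for _ in range(5):
            perm = list(anchors)
            rng.shuffle(perm)
            got = chain_anchors(perm, params)
            assert [(c.score, c.qspan, c.tspan, c.strand) for c in got] == [
                (c.score, c.qspan, c.tspan, c.strand) for c in ref]

    def test_raising_min_score_never_adds_chains(self):
        rng = np.random.default_rng(77)
        anchors = random_anchor_instance(rng, max_anchors=12)
        counts = [len(chain_anchors(anchors, ChainParams(min_chain_score=s)))
                  for s in (0, 500, 1000, 2000, 4000)]
        assert counts == sorted(counts, reverse=True)


class TestDepthExtremes:
    def test_uniform_low_is_junk(self):
        prof = uniform_profile({"s": (100, 1)})
        assert classify_depth_extremes(prof, CUT, "s") == "JUNK"

    def test_below_transition_is_none(self):
        prof = uniform_profile({"s": (100, CUT.transition - 1)})
        assert classify_depth_extremes(prof, CUT, "s") == "NONE"

    def test_threshold_edge_79_percent(self):
        d = np.full(100, 40)
        d[:79] = 1  # 79% below L: not enough at frac=0.8
        assert classify_depth_extremes(uniform_profile({"s": (100, d)}), CUT, "s", frac=0.8) == "NONE"
        d[79] = 1  # exactly 80% below L: flagged
        assert classify_depth_extremes(uniform_profile({"s": (100, d)}), CUT, "s", frac=0.8) == "JUNK"

    def test_high_coverage_flagged(self):
        prof = uniform_profile({"s": (100, CUT.high + 10)})
        assert classify_depth_extremes(prof, CUT, "s") == "HIGHCOV"


def containment_chain(qname, tname, qlen, tlen, tstart, nmatch_frac=0.99):
    """One chain covering all of qname against a window of tname."""
    a = anchor(0, qlen, tstart, tstart + qlen, int(qlen * nmatch_frac),
               qname=qname, tname=tname, qlen=qlen, tlen=tlen)
    return chain_anchors([a], ChainParams(min_chain_score=0))[0]


class TestCallHaplotigs:
    def test_contained_low_depth_segment_called(self):
        prof = uniform_profile({"S": (10_000, 20), "Big": (100_000, 40)})
        chain = containment_chain("S", "Big", 10_000, 100_000, 30_000)
        haps, remaining = call_haplotigs([chain], prof, CUT)
        assert haps == ["S"] and remaining == []

    def test_diploid_depth_blocks_call(self):
        prof = uniform_profile({"S": (10_000, 40), "Big": (100_000, 40)})
        chain = containment_chain("S", "Big", 10_000, 100_000, 30_000)
        haps, remaining = call_haplotigs([chain], prof, CUT)
        assert haps == [] and len(remaining) == 1

    def test_partial_coverage_blocks_call(self):
        prof = uniform_profile({"S": (10_000, 20), "Big": (100_000, 40)})
        a = anchor(0, 5000, 30_000, 35_000, 4950, qname="S", tname="Big",
                   qlen=10_000, tlen=100_000)
        chain = chain_anchors([a], ChainParams(min_chain_score=0))[0]
        haps, _ = call_haplotigs([chain], prof, CUT, cov_frac=0.8)
        assert haps == []

    def test_excluded_segments_skipped(self):
        prof = uniform_profile({"S": (10_000, 20), "Big": (100_000, 40)})
        chain = containment_chain("S", "Big", 10_000, 100_000, 30_000)
        haps, remaining = call_haplotigs([chain], prof, CUT, excluded=["S"])
        assert haps == [] and remaining == []

    def test_synthetic_haplotigs_recovered(self, small_sim):
        from haplopurge.coverage import compute_depth
        from haplopurge.purge_core import chain_all

        sim = small_sim
        lengths = {c.name: len(c.seq) for c in sim.draft}
        prof = compute_depth(sim.alignments.read_paf, lengths)
        hist_cut = Cutoffs(5, 28, 95, peaks=[20, 40], mode="diploid-dominant")
        anchors = filter_self_alignments(sim.alignments.self_paf)
        chains = chain_all(anchors, ChainParams(min_chain_score=2000))
        junk = [n for n in lengths if n.startswith("junk")]
        haps, _ = call_haplotigs(chains, prof, hist_cut, excluded=junk)
        expected = sorted(n for n, k in sim.truth.origin.items() if k == "haplotig")
        assert sorted(haps) == expected


def dovetail_chain(qname, tname, qlen, tlen, ov, strand="+"):
    """Suffix of qname overlaps prefix of tname by ov bases."""
    a = anchor(qlen - ov, qlen, 0, ov, int(ov * 0.99), strand,
               qname=qname, tname=tname, qlen=qlen, tlen=tlen)
    return chain_anchors([a], ChainParams(min_chain_score=0))[0]


class TestCallOverlaps:
    P = PurgeParams(end_tolerance_bp=3000)

    def test_heterozygous_dovetail_trims_shorter(self):
        prof = uniform_profile({"A": (200_000, 20), "B": (150_000, 20)})
        chain = dovetail_chain("A", "B", 200_000, 150_000, 50_000)
        calls = call_overlaps([chain], prof, CUT, self.P)
        assert len(calls) == 1
        iv = calls[0]
        assert iv.contig == "B" and (iv.start, iv.end) == (0, 50_000)

    def test_high_depth_on_one_side_blocks_call(self):
        d = np.full(200_000, 20, dtype=np.int32)
        d[150_000:] = 40  # the matched suffix of A sits at diploid depth
        prof = DepthProfile({"A": d, "B": np.full(150_000, 20, dtype=np.int32)})
        chain = dovetail_chain("A", "B", 200_000, 150_000, 50_000)
        assert call_overlaps([chain], prof, CUT, self.P) == []

    def test_ambiguous_end_blocks_both(self):
        prof = uniform_profile({"A": (200_000, 20), "B": (150_000, 20), "C": (180_000, 20)})
        c1 = dovetail_chain("A", "B", 200_000, 150_000, 50_000)
        c2 = dovetail_chain("C", "B", 180_000, 150_000, 40_000)
        assert call_overlaps([c1, c2], prof, CUT, self.P) == []

    def test_containment_is_not_a_dovetail(self):
        prof = uniform_profile({"S": (10_000, 20), "Big": (100_000, 20)})
        chain = containment_chain("S", "Big", 10_000, 100_000, 30_000)
        assert call_overlaps([chain], prof, CUT, self.P) == []

    def test_interval_extended_to_segment_end(self):
        prof = uniform_profile({"A": (200_000, 20), "B": (150_000, 20)})
        # overlap stops 2 kb short of B's start: residual < tolerance, extend
        a = anchor(150_000, 198_000, 2000, 50_000, 47_000,
                   qname="A", tname="B", qlen=200_000, tlen=150_000)
        chain = chain_anchors([a], ChainParams(min_chain_score=0))[0]
        calls = call_overlaps([chain], prof, CUT, self.P)
        assert len(calls) == 1 and (calls[0].start, calls[0].end) == (0, 50_000)

    def test_raising_transition_never_loses_calls(self):
        prof = uniform_profile({"A": (200_000, 25), "B": (150_000, 25)})
        chain = dovetail_chain("A", "B", 200_000, 150_000, 50_000)
        low_t = Cutoffs(5, 24, 95)
        high_t = Cutoffs(5, 40, 95)
        assert call_overlaps([chain], prof, low_t, self.P) == []
        assert len(call_overlaps([chain], prof, high_t, self.P)) == 1


class TestBuildPlan:
    def _smap(self):
        contigs = [ContigSeq("c", "A" * 6000)]
        _, smap = split_at_gaps(contigs)
        return smap

    def test_haplotig_lifted_to_original(self):
        contigs = [ContigSeq("c", "N" * 100 + "A" * 5000 + "N" * 100)]
        _, smap = split_at_gaps(contigs)
        plan = build_purge_plan({}, ["c:100-5100"], [], smap)
        assert plan.intervals == [BedInterval("c", 100, 5100, "HAPLOTIG")]

    def test_priority_merge_nested(self):
        smap = self._smap()
        plan = build_purge_plan(
            {}, [], [BedInterval("c", 0, 1000, "OVLP")], smap)
        # nested OVLP under a HAPLOTIG collapses into the haplotig interval
        plan2 = build_purge_plan({}, ["c"], [BedInterval("c", 0, 1000, "OVLP")], smap)
        assert plan2.intervals == [BedInterval("c", 0, 6000, "HAPLOTIG")]
        assert plan.intervals == [BedInterval("c", 0, 1000, "OVLP")]

    def test_partial_overlap_clips_lower_priority(self):
        smap = self._smap()
        plan = build_purge_plan(
            {"c": "JUNK"}, [], [BedInterval("c", 5000, 6000, "OVLP")], smap)
        assert plan.intervals == [BedInterval("c", 0, 6000, "JUNK")]

    def test_empty_inputs_empty_plan(self):
        plan = build_purge_plan({}, [], [], self._smap())
        assert plan.intervals == []

    def test_intervals_disjoint_and_bounded(self):
        rng = np.random.default_rng(4)
        smap = self._smap()
        ivs = [BedInterval("c", int(s), int(s) + int(l), lab)
               for s, l, lab in zip(rng.integers(0, 5000, 30),
                                    rng.integers(1, 1000, 30),
                                    rng.choice(["OVLP", "HAPLOTIG"], 30))]
        ivs = [iv for iv in ivs if iv.end <= 6000]
        plan = build_purge_plan({}, [], [iv for iv in ivs if iv.label == "OVLP"], smap)
        prev_end = 0
        for iv in plan.intervals:
            assert iv.start >= prev_end and iv.end <= 6000
            prev_end = iv.end
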