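"""The synthetic diploid scenario generator: determinism, rates, truth accounting."""

import numpy as np
import pytest

from haplopurge.coverage import compute_depth
from haplopurge.io_formats import ContigSeq
from haplopurge.synthetic import (
    SimConfig,
    build_draft,
    read_sequences,
    revcomp,
    simulate,
    simulate_alignments,
    simulate_diploid,
)

from conftest import SMALL


class TestConfig:
    def test_invalid_heterozygosity(self):
        with pytest.raises(ValueError):
            SimConfig(heterozygosity=0.5)

    def test_features_exceeding_contigs(self):
        with pytest.raises(ValueError, match="exceed"):
            SimConfig(n_contigs=4, n_overlaps=2, n_haplotigs=2)

    def test_overlap_too_large(self):
        with pytest.raises(ValueError, match="overlap_len"):
            SimConfig(genome_length=100_000, n_contigs=10, overlap_len=6_000)


class TestDiploid:
    CFG = SimConfig(genome_length=100_000, n_contigs=2, n_haplotigs=0,
                    n_overlaps=0, n_junk=0, n_repeat=0, overlap_len=1000)

    def test_zero_heterozygosity_identical(self):
        cfg = SimConfig(genome_length=50_000, heterozygosity=0.0, n_contigs=2,
                        n_haplotigs=0, n_overlaps=0, n_junk=0, n_repeat=0, overlap_len=100)
        dip = simulate_diploid(cfg)
        assert dip.seq_a == dip.seq_b

    def test_substitution_rate_binomial(self):
        cfg = SimConfig(genome_length=1_000_000, heterozygosity=0.01, n_contigs=2,
                        n_haplotigs=0, n_overlaps=0, n_junk=0, n_repeat=0, overlap_len=100)
        dip = simulate_diploid(cfg)
        # compare in indel-free coordinate blocks via the map
        cm = dip.coord_map
        diffs = total = 0
        for a0, b0, ln in zip(cm.a_starts.tolist(), cm.b_starts.tolist(), cm.block_lens.tolist()):
            a = np.frombuffer(dip.seq_a[a0 : a0 + ln].encode(), np.uint8)
            b = np.frombuffer(dip.seq_b[b0 : b0 + ln].encode(), np.uint8)
            diffs += int((a != b).sum())
            total += ln
        expect = total * 0.01
        sigma = np.sqrt(expect * 0.99)
        assert abs(diffs - expect) < 3 * sigma

    def test_seed_determinism(self):
        d1 = simulate_diploid(self.CFG)
        d2 = simulate_diploid(self.CFG)
        assert d1.seq_a == d2.seq_a and d1.seq_b == d2.seq_b

    def test_coord_map_roundtrip(self):
        dip = simulate_diploid(self.CFG)
        cm = dip.coord_map
        rng = np.random.default_rng(1)
        for a in rng.integers(0, len(dip.seq_a), 200).tolist():
            b = cm.a_to_b(a)
            assert abs(cm.b_to_a(b) - a) <= 10  # exact except inside an indel run


class TestDraft:
    def test_clean_config_partitions_hap_a(self):
        cfg = SimConfig(genome_length=100_000, n_contigs=4, n_haplotigs=0,
                        n_overlaps=0, n_junk=0, n_repeat=0, overlap_len=1000)
        dip = simulate_diploid(cfg)
        draft, truth = build_draft(dip, cfg)
        assert truth.intervals == []
        assert "".join(c.seq for c in draft) == dip.seq_a

    def test_single_overlap_truth(self):
        cfg = SimConfig(genome_length=200_000, n_contigs=4, n_haplotigs=0,
                        n_overlaps=1, overlap_len=8_000, n_junk=0, n_repeat=0)
        dip = simulate_diploid(cfg)
        draft, truth = build_draft(dip, cfg)
        ovl = [iv for iv in truth.intervals if iv.label == "OVLP"]
        assert len(ovl) == 1 and len(ovl[0]) == 8_000
        # the pair-second contig begins with the B-version of that window
        second = next(c for c in draft if c.name == "ctg01")
        prefix_block = truth.blocks["ctg01"][0]
        assert prefix_block.hap == "B"
        assert second.seq.startswith(dip.seq_b[prefix_block.start : prefix_block.start + 100])

    def test_truth_base_totals_match_construction(self, small_sim):
        truth = small_sim.truth
        cfg = small_sim.config
        assert truth.bases("OVLP") == cfg.n_overlaps * cfg.overlap_len
        assert truth.bases("JUNK") == cfg.n_junk * cfg.junk_len
        hap_lens = [len(c.seq) for c in small_sim.draft if c.name.startswith("hap")]
        assert truth.bases("HAPLOTIG") == sum(hap_lens)

    def test_reverse_complement_haplotig_planted(self, small_sim):
        strands = [b.strand for n, bl in small_sim.truth.blocks.items()
                   if n.startswith("hap") for b in bl]
        assert "-" in strands and "+" in strands


class TestAlignments:
    def test_depth_matches_expectation_within_3_sigma(self, small_sim):
        sim = small_sim
        lengths = {c.name: len(c.seq) for c in sim.draft}
        prof = compute_depth(sim.alignments.read_paf, lengths)
        for name, exp in sim.alignments.expected_depth.items():
            rate = float(exp.mean())
            got = float(prof.depths[name].mean())
            # effective independent draws ~ length * rate / read_len
            n_eff = max(lengths[name] * rate / sim.config.read_len, 1.0)
            sigma = rate / np.sqrt(n_eff)
            assert abs(got - rate) < 3 * max(sigma, 0.5), name

    def test_haplotig_depth_half_of_diploid(self, small_sim):
        sim = small_sim
        lengths = {c.name: len(c.seq) for c in sim.draft}
        prof = compute_depth(sim.alignments.read_paf, lengths)
        hap_means = [prof.depths[n].mean() for n in lengths if n.startswith("hap")]
        bulk = prof.depths["ctg08"].mean()
        for m in hap_means:
            assert m == pytest.approx(bulk / 2, rel=0.25)

    def test_paf_byte_determinism(self):
        import io

        from haplopurge.io_formats import write_paf

        s1 = simulate(SMALL)
        s2 = simulate(SMALL)

        def paf_bytes(sim):
            import tempfile, os
            fd, p = tempfile.mkstemp()
            os.close(fd)
            write_paf(sim.alignments.read_paf, p)
            data = open(p, "rb").read()
            os.unlink(p)
            return data

        assert paf_bytes(s1) == paf_bytes(s2)

    def test_generated_records_pass_validation(self, small_sim):
        # PafRecord/ContigSeq validate on construction; re-validate bounds here
        lengths = {c.name: len(c.seq) for c in small_sim.draft}
        for rec in small_sim.alignments.read_paf + small_sim.alignments.self_paf:
            assert rec.tend <= lengths[rec.tname]
            assert rec.qend <= rec.qlen

    def test_self_anchors_reflect_divergence(self, small_sim):
        # planted anchors carry ~(1 - heterozygosity) identity; the low-score
        # noise records (mapq 20) are excluded
        planted = [r for r in small_sim.alignments.self_paf if r.mapq == 60]
        assert planted
        for rec in planted:
            if rec.qname.startswith("hap"):
                ident = rec.nmatch / (rec.qend - rec.qstart)
                assert 0.9 <= ident <= 1.0

    def test_read_sequences_match_draft(self, small_sim):
        draft = small_sim.draft_dict
        recs = small_sim.alignments.read_paf[:50]
        for rec, seq in zip(recs, read_sequences(draft, recs)):
            if rec.strand == "+":
                assert seq == draft[rec.tname][rec.tstart : rec.tend]
            else:
                assert revcomp(seq) == draft[rec.tname][rec.tstart : rec.tend]
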