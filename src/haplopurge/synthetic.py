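"""Synthetic diploid genomes and draft assemblies with planted purge targets.

The generator emulates the situation the purging pipeline is built for: a
diploid genome at configurable heterozygosity (SNPs plus small 1-10 bp
indels), assembled into a draft whose primary contigs tile haplotype A but
which additionally contains

* *haplotigs* — extra contigs copied from haplotype B over regions already
  represented (contained duplication; one planted copy is
  reverse-complemented),
* *heterozygous overlaps* — adjacent contig pairs where the second contig
  begins with the haplotype-B version of the first contig's terminal
  ``overlap_len`` bases (dovetail duplication),
* *junk* — random low-coverage decoy contigs,
* *collapsed repeats* — contigs whose sequence also occurs inside a
  primary contig and which receive reads at twice diploid depth (they are
  planted as things purging must NOT remove).

Reads are placed by construction rather than aligned: each read is sampled
uniformly from one haplotype and emitted as PAF records at its true draft
location, with haplotype-B reads diverted to the planted B-copies of their
region, so duplicated regions sit at haploid depth, junk at ~1x and
collapsed repeats at ~2x diploid depth.  The self-alignment PAF contains
anchors for every planted duplication relationship, broken into gapped
pieces with match counts reflecting the planted divergence, plus a few
sub-threshold noise records.  Everything is byte-deterministic given the
seed.

What this does NOT emulate: sequencing error, structural variants,
low-complexity sequence or realistic repeat families; see the methods
note for what that implies about test coverage.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .coverage import DepthProfile
from .io_formats import BedInterval, ContigSeq, PafRecord

__all__ = [
    "SimConfig",
    "DiploidGenome",
    "TruthSet",
    "SimAlignments",
    "SimResult",
    "simulate_diploid",
    "build_draft",
    "simulate_alignments",
    "simulate",
    "read_sequences",
    "revcomp",
    "gaussian_mixture_histogram",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = str.maketrans("ACGTN", "TGCAN")

JUNK_MARGIN = 20_000  # clearance kept around planted repeat windows


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe a 2 Mb diploid genome at 1% heterozygosity (within
    the 0.6-1.6% range typical of outbred species this class of pipeline
    targets), drafted into 10 contigs with 4 haplotigs, 3 heterozygous
    overlaps of 50 kb, 2 junk contigs and 1 collapsed repeat, read at 40x
    total long-read coverage with 10 kb reads.
    """

    genome_length: int = 2_000_000
    heterozygosity: float = 0.01
    n_contigs: int = 10
    n_haplotigs: int = 4
    n_overlaps: int = 3
    overlap_len: int = 50_000
    n_junk: int = 2
    n_repeat: int = 1
    read_len: int = 10_000
    depth: float = 40.0
    seed: int = 42
    junk_depth: float = 1.0
    repeat_depth_factor: float = 2.0
    junk_len: int = 20_000

    def __post_init__(self) -> None:
        if min(self.n_contigs, self.n_haplotigs, self.n_overlaps, self.n_junk, self.n_repeat) < 0:
            raise ValueError("feature counts must be >= 0")
        if not (0.0 <= self.heterozygosity <= 0.1):
            raise ValueError("heterozygosity must be in [0, 0.1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_contigs < 1 or self.genome_length < self.n_contigs:
            raise ValueError("need at least one contig of positive length")
        if 2 * self.n_overlaps + self.n_haplotigs > self.n_contigs:
            raise ValueError(
                "planted features exceed genome: need "
                f"{2 * self.n_overlaps + self.n_haplotigs} contigs, have {self.n_contigs}"
            )
        tile = self.genome_length // self.n_contigs
        if self.n_overlaps and self.overlap_len >= tile // 2:
            raise ValueError("overlap_len too large for the contig tile size")

    @property
    def tile(self) -> int:
        return self.genome_length // self.n_contigs

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class CoordMap:
    """Piecewise-exact coordinate map between the two haplotypes."""

    a_starts: np.ndarray
    b_starts: np.ndarray
    block_lens: np.ndarray

    def a_to_b(self, pos: int) -> int:
        i = int(np.searchsorted(self.a_starts, pos, side="right")) - 1
        off = min(pos - int(self.a_starts[i]), int(self.block_lens[i]))
        return int(self.b_starts[i]) + off

    def b_to_a(self, pos: int) -> int:
        i = int(np.searchsorted(self.b_starts, pos, side="right")) - 1
        off = min(pos - int(self.b_starts[i]), int(self.block_lens[i]))
        return int(self.a_starts[i]) + off


@dataclass
class DiploidGenome:
    hap_a: List[ContigSeq]
    hap_b: List[ContigSeq]
    coord_map: CoordMap

    @property
    def seq_a(self) -> str:
        return self.hap_a[0].seq

    @property
    def seq_b(self) -> str:
        return self.hap_b[0].seq


@dataclass(frozen=True)
class Block:
    """One source block of a draft contig.

    ``hap`` is "A"/"B" (coordinates into that haplotype), "R" (repeat copy,
    coordinates into haplotype A) or "J" (junk, private sequence).
    """

    hap: str
    start: int
    end: int
    strand: str
    draft_start: int


@dataclass
class TruthSet:
    intervals: List[BedInterval]
    origin: Dict[str, str]
    blocks: Dict[str, List[Block]]

    def bases(self, label: str) -> int:
        return sum(len(iv) for iv in self.intervals if iv.label == label)


@dataclass
class SimAlignments:
    read_paf: List[PafRecord]
    self_paf: List[PafRecord]
    expected_depth: Dict[str, np.ndarray]


@dataclass
class SimResult:
    config: SimConfig
    diploid: DiploidGenome
    draft: List[ContigSeq]
    truth: TruthSet
    alignments: SimAlignments

    @property
    def draft_dict(self) -> Dict[str, str]:
        return {c.name: c.seq for c in self.draft}


# ---------------------------------------------------------------------------
# diploid genome

def simulate_diploid(config: SimConfig) -> DiploidGenome:
    """Generate haplotype A and its diverged counterpart B.

    B carries i.i.d. substitutions at rate ``heterozygosity`` and 1-10 bp
    indels at a tenth of that rate; the exact A<->B coordinate map is
    retained for planting and read placement.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    het = config.heterozygosity
    a_arr = rng.integers(0, 4, L, dtype=np.uint8)

    sub_mask = rng.random(L) < het
    shifts = rng.integers(1, 4, L, dtype=np.uint8)
    b_pre = np.where(sub_mask, (a_arr + shifts) % 4, a_arr).astype(np.uint8)

    ev_pos = np.flatnonzero(rng.random(L) < het / 10.0)
    ev_ins = rng.random(ev_pos.size) < 0.5
    ev_len = rng.integers(1, 11, ev_pos.size)

    pieces: List[np.ndarray] = []
    a_starts, b_starts, block_lens = [0], [0], []
    a_cur = b_cur = 0
    for pos, is_ins, ln in zip(ev_pos.tolist(), ev_ins.tolist(), ev_len.tolist()):
        if pos < a_cur:
            continue  # swallowed by an earlier deletion
        block = b_pre[a_cur:pos]
        pieces.append(block)
        block_lens.append(pos - a_cur)
        b_cur += pos - a_cur
        if is_ins:
            ins = rng.integers(0, 4, ln, dtype=np.uint8)
            pieces.append(ins)
            b_cur += int(ln)
            a_cur = pos
        else:
            a_cur = min(pos + int(ln), L)
        a_starts.append(a_cur)
        b_starts.append(b_cur)
    pieces.append(b_pre[a_cur:L])
    block_lens.append(L - a_cur)

    b_arr = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    cmap = CoordMap(
        np.asarray(a_starts, dtype=np.int64),
        np.asarray(b_starts, dtype=np.int64),
        np.asarray(block_lens, dtype=np.int64),
    )
    return DiploidGenome(
        hap_a=[ContigSeq("chr1_hapA", _decode(a_arr))],
        hap_b=[ContigSeq("chr1_hapB", _decode(b_arr))],
        coord_map=cmap,
    )


# ---------------------------------------------------------------------------
# draft assembly with planted artifacts

def _ctg(i: int) -> str:
    return f"ctg{i:02d}"


def build_draft(diploid: DiploidGenome, config: SimConfig) -> Tuple[List[ContigSeq], TruthSet]:
    """Tile haplotype A into primary contigs and plant purgeable artifacts.

    Layout: contigs ``2i``/``2i+1`` (i < n_overlaps) form overlap pairs
    (the second begins with the B-version of the first's terminal
    ``overlap_len`` bases, so the truth OVLP sits on the shorter, first
    member); the next ``n_haplotigs`` contigs donate interior windows for
    haplotig copies; repeat windows are placed in remaining clear space;
    junk contigs are pure random sequence.
    """
    rng = np.random.default_rng(config.seed + 1)
    L, t, ov = config.genome_length, config.tile, config.overlap_len
    cmap = diploid.coord_map
    seq_a, seq_b = diploid.seq_a, diploid.seq_b

    tile_start = [i * t for i in range(config.n_contigs)]
    tile_end = [(i + 1) * t for i in range(config.n_contigs)]
    tile_end[-1] = L

    reserved: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(config.n_contigs)}
    draft: List[ContigSeq] = []
    truth = TruthSet(intervals=[], origin={}, blocks={})

    # overlap pairs first: they change pair-second contigs' prefixes
    prefix_blocks: Dict[int, Block] = {}
    for i in range(config.n_overlaps):
        first, second = 2 * i, 2 * i + 1
        s = tile_start[second]
        bs, be = cmap.a_to_b(s - ov), cmap.a_to_b(s)
        prefix_blocks[second] = Block("B", bs, be, "+", 0)
        reserved[first].append((t - ov, t))
        truth.intervals.append(BedInterval(_ctg(first), t - ov, t, "OVLP"))

    for i in range(config.n_contigs):
        name = _ctg(i)
        blocks: List[Block] = []
        seq_parts: List[str] = []
        offset = 0
        if i in prefix_blocks:
            pb = prefix_blocks[i]
            seq_parts.append(seq_b[pb.start : pb.end])
            offset = pb.end - pb.start
            blocks.append(pb)
        blocks.append(Block("A", tile_start[i], tile_end[i], "+", offset))
        seq_parts.append(seq_a[tile_start[i] : tile_end[i]])
        draft.append(ContigSeq(name, "".join(seq_parts)))
        truth.origin[name] = "primary"
        truth.blocks[name] = blocks

    # contained haplotigs from interior windows of dedicated source contigs
    for m in range(config.n_haplotigs):
        src = 2 * config.n_overlaps + m
        hlen = int(t * (0.25 + 0.05 * m))
        w_lo = tile_start[src] + t // 4
        w_hi = w_lo + hlen
        if w_hi > tile_end[src]:
            raise ValueError("planted haplotig exceeds its source contig")
        reserved[src].append((w_lo - tile_start[src], w_hi - tile_start[src]))
        bs, be = cmap.a_to_b(w_lo), cmap.a_to_b(w_hi)
        strand = "-" if (config.n_haplotigs >= 2 and m == 1) else "+"
        seq = seq_b[bs:be]
        if strand == "-":
            seq = revcomp(seq)
        name = f"hap{m:02d}"
        draft.append(ContigSeq(name, seq))
        truth.origin[name] = "haplotig"
        truth.blocks[name] = [Block("B", bs, be, strand, 0)]
        truth.intervals.append(BedInterval(name, 0, len(seq), "HAPLOTIG"))

    # collapsed repeats: exact second copies of interior primary windows
    rep_len = max(5000, t // 5)
    margin = max(1000, min(JUNK_MARGIN, t // 8))
    for r in range(config.n_repeat):
        src = (2 * config.n_overlaps + config.n_haplotigs + r) % config.n_contigs
        lo = _find_clear_window(reserved[src], tile_end[src] - tile_start[src], rep_len, margin)
        if lo is None:
            raise ValueError("no clear window for planted repeat")
        reserved[src].append((lo, lo + rep_len))
        w_lo, w_hi = tile_start[src] + lo, tile_start[src] + lo + rep_len
        name = f"rep{r:02d}"
        draft.append(ContigSeq(name, seq_a[w_lo:w_hi]))
        truth.origin[name] = "repeat"
        truth.blocks[name] = [Block("R", w_lo, w_hi, "+", 0)]
        truth.intervals.append(BedInterval(name, 0, rep_len, "HIGHCOV"))

    # junk decoys
    for j in range(config.n_junk):
        name = f"junk{j:02d}"
        seq = _decode(rng.integers(0, 4, config.junk_len, dtype=np.uint8))
        draft.append(ContigSeq(name, seq))
        truth.origin[name] = "junk"
        truth.blocks[name] = [Block("J", 0, config.junk_len, "+", 0)]
        truth.intervals.append(BedInterval(name, 0, config.junk_len, "JUNK"))

    return draft, truth


def _find_clear_window(
    reserved: List[Tuple[int, int]], contig_len: int, want: int, margin: int = JUNK_MARGIN
) -> Optional[int]:
    """First local offset whose [lo, lo+want) keeps ``margin`` clearance."""
    lo = margin
    taken = sorted(reserved)
    while lo + want + margin <= contig_len:
        clash = next(
            (hi for (s, e) in taken if not (lo + want + margin <= s or lo >= e + margin)),
            None,
        )
        if clash is None:
            return lo
        lo = clash + margin
        taken = [iv for iv in taken if iv[1] + margin > lo]
    return None


# ---------------------------------------------------------------------------
# reads and self-alignment

def _sample_starts(rng: np.random.Generator, length: int, rate: float, read_len: int) -> np.ndarray:
    """Uniform read starts allowing end overhang, so coverage is flat ~= rate."""
    span = length + read_len - 1
    n = int(round(rate * span / read_len))
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    return rng.integers(1 - read_len, length, n)


def simulate_alignments(
    draft: List[ContigSeq],
    diploid: DiploidGenome,
    truth: TruthSet,
    config: SimConfig,
) -> SimAlignments:
    """Place reads and planted-duplication anchors on the draft.

    Reads are drawn uniformly from each haplotype at ``depth/2`` fold each;
    haplotype-B reads falling in a planted B-copy window are diverted to
    that copy, everything else maps to the primary tiling through the
    coordinate map.  Junk and repeat contigs get their own read streams at
    ``junk_depth`` and ``depth * repeat_depth_factor``.
    """
    rng = np.random.default_rng(config.seed + 2)
    t, rl, het = config.tile, config.read_len, config.heterozygosity
    cmap = diploid.coord_map
    n_ctg = config.n_contigs
    L = config.genome_length
    lengths = {c.name: len(c.seq) for c in draft}

    tile_start = [i * t for i in range(n_ctg)]
    tile_end = [(i + 1) * t for i in range(n_ctg)]
    tile_end[-1] = L
    prefix = [0] * n_ctg
    for i in range(n_ctg):
        blocks = truth.blocks[_ctg(i)]
        if blocks[0].hap == "B":
            prefix[i] = blocks[0].end - blocks[0].start

    # diversion windows: every B block placed in the draft
    divs = []  # (b_lo, b_hi, contig, draft_off, strand)
    for name, blocks in truth.blocks.items():
        for b in blocks:
            if b.hap == "B":
                divs.append((b.start, b.end, name, b.draft_start, b.strand))
    divs.sort()
    div_lo = [d[0] for d in divs]

    read_paf: List[PafRecord] = []

    def _emit_primary(qname: str, qlen: int, q0: int, q1: int, a0: int, a1: int) -> None:
        """Split an A-coordinate interval at tile boundaries and emit pieces.

        Indels make the A-range length differ slightly from the read piece
        [q0, q1); query coordinates are clamped into that window.
        """
        p = a0
        while p < a1:
            idx = min(p // t, n_ctg - 1)
            pe = min(a1, tile_end[idx])
            if pe > p:
                qs = min(q0 + (p - a0), q1 - 1)
                qe = min(q0 + (pe - a0), q1)
                read_paf.append(PafRecord(
                    qname, qlen, qs, max(qe, qs + 1), "+",
                    _ctg(idx), lengths[_ctg(idx)],
                    p - tile_start[idx] + prefix[idx], pe - tile_start[idx] + prefix[idx],
                    min(pe - p, max(qe, qs + 1) - qs), max(pe - p, max(qe, qs + 1) - qs), 60,
                ))
            p = pe

    # haplotype A reads
    la = len(diploid.seq_a)
    for i, s in enumerate(_sample_starts(rng, la, config.depth / 2, rl).tolist()):
        s0, e0 = max(s, 0), min(s + rl, la)
        if e0 - s0 < 100:
            continue
        _emit_primary(f"rA{i:07d}", e0 - s0, 0, e0 - s0, s0, e0)

    # haplotype B reads, with diversion into planted B copies
    lb = len(diploid.seq_b)
    for i, s in enumerate(_sample_starts(rng, lb, config.depth / 2, rl).tolist()):
        s0, e0 = max(s, 0), min(s + rl, lb)
        if e0 - s0 < 100:
            continue
        qname, qlen = f"rB{i:07d}", e0 - s0
        p = s0
        while p < e0:
            j = bisect_right(div_lo, p) - 1
            if j >= 0 and p < divs[j][1]:
                lo, hi, contig, off, strand = divs[j]
                pe = min(e0, hi)
                if strand == "+":
                    ts, te = off + (p - lo), off + (pe - lo)
                else:
                    ts, te = off + (hi - pe), off + (hi - p)
                if te > ts:
                    read_paf.append(PafRecord(
                        qname, qlen, p - s0, pe - s0, strand,
                        contig, lengths[contig], ts, te, te - ts, te - ts, 60,
                    ))
            else:
                nxt = bisect_right(div_lo, p)
                pe = min(e0, divs[nxt][0]) if nxt < len(divs) else e0
                a0, a1 = cmap.b_to_a(p), cmap.b_to_a(pe)
                if a1 > a0:
                    _emit_primary(qname, qlen, p - s0, pe - s0, a0, a1)
            p = pe

    # junk and repeat streams
    for name in sorted(truth.origin):
        kind = truth.origin[name]
        if kind == "junk":
            rate = config.junk_depth
        elif kind == "repeat":
            rate = config.depth * config.repeat_depth_factor
        else:
            continue
        clen = lengths[name]
        for i, s in enumerate(_sample_starts(rng, clen, rate, rl).tolist()):
            s0, e0 = max(s, 0), min(s + rl, clen)
            if e0 - s0 < 100:
                continue
            read_paf.append(PafRecord(
                f"r{name}_{i:05d}", e0 - s0, 0, e0 - s0, "+",
                name, clen, s0, e0, e0 - s0, e0 - s0, 60,
            ))

    self_paf = _planted_anchors(truth, lengths, cmap, config, tile_start, prefix, rng)
    expected = _expected_depth(draft, truth, config, cmap, tile_start, tile_end, prefix)
    return SimAlignments(read_paf, self_paf, expected)


def _planted_anchors(
    truth: TruthSet,
    lengths: Dict[str, int],
    cmap: CoordMap,
    config: SimConfig,
    tile_start: List[int],
    prefix: List[int],
    rng: np.random.Generator,
    n_pieces: int = 5,
    gap: int = 200,
) -> List[PafRecord]:
    """Self-alignment anchors for every planted duplication relationship."""
    t = config.tile
    het = config.heterozygosity
    out: List[PafRecord] = []

    def a_to_target(a: int) -> Tuple[str, int]:
        idx = min(a // t, config.n_contigs - 1)
        return _ctg(idx), a - tile_start[idx] + prefix[idx]

    def emit_b_block(qname: str, block: Block) -> None:
        qlen_block = block.end - block.start
        plen = max(1, (qlen_block - (n_pieces - 1) * gap) // n_pieces)
        for p in range(n_pieces):
            q0 = block.draft_start + p * (plen + gap)
            q1 = min(q0 + plen, block.draft_start + qlen_block)
            if q1 <= q0:
                continue
            if block.strand == "+":
                b0, b1 = block.start + (q0 - block.draft_start), block.start + (q1 - block.draft_start)
            else:
                b0, b1 = block.end - (q1 - block.draft_start), block.end - (q0 - block.draft_start)
            a0, a1 = cmap.b_to_a(b0), cmap.b_to_a(b1)
            if a1 <= a0:
                continue
            tname, t0 = a_to_target(a0)
            tname2, t1 = a_to_target(a1 - 1)
            if tname != tname2:
                continue  # piece crosses a tile boundary; drop it
            t1 += 1
            nmatch = max(1, round((q1 - q0) * (1 - het)))
            out.append(PafRecord(
                qname, lengths[qname], q0, q1, block.strand,
                tname, lengths[tname], t0, t1,
                min(nmatch, max(q1 - q0, t1 - t0)), max(q1 - q0, t1 - t0), 60,
            ))

    for name in sorted(truth.blocks):
        for block in truth.blocks[name]:
            if block.hap == "B":
                emit_b_block(name, block)
            elif block.hap == "R":
                # exact-copy anchors repeat -> embedded window
                qlen_block = block.end - block.start
                plen = max(1, (qlen_block - (n_pieces - 1) * gap) // n_pieces)
                for p in range(n_pieces):
                    q0 = p * (plen + gap)
                    q1 = min(q0 + plen, qlen_block)
                    if q1 <= q0:
                        continue
                    tname, t0 = a_to_target(block.start + q0)
                    out.append(PafRecord(
                        name, lengths[name], q0, q1, "+",
                        tname, lengths[tname], t0, t0 + (q1 - q0),
                        q1 - q0, q1 - q0, 60,
                    ))

    # mirrored duplicates of overlap-pair anchors (exercises symmetric dedup)
    mirrors = [
        PafRecord(r.tname, r.tlen, r.tstart, r.tend, r.strand,
                  r.qname, r.qlen, r.qstart, r.qend, r.nmatch, r.alnlen, r.mapq)
        for r in out
        if r.qname.startswith("ctg") and r.tname.startswith("ctg")
    ]
    out.extend(mirrors)

    # sub-threshold noise records
    names = sorted(n for n in lengths if lengths[n] >= 2000)
    for _ in range(8):
        qn, tn = rng.choice(len(names), 2, replace=False).tolist()
        q0 = int(rng.integers(0, lengths[names[qn]] - 900))
        t0 = int(rng.integers(0, lengths[names[tn]] - 900))
        out.append(PafRecord(
            names[qn], lengths[names[qn]], q0, q0 + 800, "+",
            names[tn], lengths[names[tn]], t0, t0 + 800, 300, 800, 20,
        ))
    return out


def _expected_depth(
    draft: List[ContigSeq],
    truth: TruthSet,
    config: SimConfig,
    cmap: CoordMap,
    tile_start: List[int],
    tile_end: List[int],
    prefix: List[int],
) -> Dict[str, np.ndarray]:
    """Idealized per-base depth implied by the planted layout.

    Primary contigs sit at full (diploid) depth except where a haplotype-B
    copy was planted elsewhere: there the B reads are diverted, leaving
    haploid depth on both copies.
    """
    t = config.tile
    hap = config.depth / 2
    expected: Dict[str, np.ndarray] = {}
    for c in draft:
        kind = truth.origin[c.name]
        if kind == "junk":
            expected[c.name] = np.full(len(c.seq), config.junk_depth)
        elif kind == "repeat":
            expected[c.name] = np.full(len(c.seq), config.depth * config.repeat_depth_factor)
        elif kind == "haplotig":
            expected[c.name] = np.full(len(c.seq), hap)
        else:
            expected[c.name] = np.full(len(c.seq), float(config.depth))
    for name, blocks in truth.blocks.items():
        for b in blocks:
            if b.hap != "B":
                continue
            if truth.origin[name] == "primary":  # the planted B prefix itself
                expected[name][b.draft_start : b.draft_start + (b.end - b.start)] = hap
            # the homologous primary window loses its diverted B reads
            a_lo, a_hi = cmap.b_to_a(b.start), cmap.b_to_a(b.end)
            p = a_lo
            while p < a_hi:
                idx = min(p // t, config.n_contigs - 1)
                pe = min(a_hi, tile_end[idx])
                lo = p - tile_start[idx] + prefix[idx]
                expected[_ctg(idx)][lo : lo + (pe - p)] = hap
                p = pe
    return expected


# ---------------------------------------------------------------------------
# one-call scenario

def simulate(config: SimConfig | None = None) -> SimResult:
    """Run the full generator: genome, draft, truth, reads, self-alignment."""
    config = config or SimConfig()
    diploid = simulate_diploid(config)
    draft, truth = build_draft(diploid, config)
    aln = simulate_alignments(draft, diploid, truth, config)
    return SimResult(config, diploid, draft, truth, aln)


def read_sequences(draft: Dict[str, str], read_paf: List[PafRecord]) -> Iterator[str]:
    """Sequences of the placed reads (error-free draft substrings)."""
    for rec in read_paf:
        seq = draft[rec.tname][rec.tstart : rec.tend]
        yield revcomp(seq) if rec.strand == "-" else seq


# ---------------------------------------------------------------------------
# shaped histograms for cutoff testing

def gaussian_mixture_histogram(
    peaks: List[Tuple[float, float]],
    total: float = 1_000_000,
    d_max: int = 200,
    sigma_frac: float = 0.125,
):
    """Depth histogram with Gaussian-shaped peaks at given (depth, weight).

    Peak standard deviation scales with depth (``sigma_frac`` of it,
    floor 1.5), mimicking the widening of coverage peaks with depth.
    """
    from .coverage import DepthHistogram

    d = np.arange(d_max + 1, dtype=np.float64)
    counts = np.zeros(d_max + 1)
    for mu, w in peaks:
        sigma = max(1.5, sigma_frac * mu)
        counts += w * np.exp(-0.5 * ((d - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    counts *= total / counts.sum()
    return DepthHistogram(counts, d_max)
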