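"""Haplotig and heterozygous-overlap calling from assembly self-alignments.

The algorithm takes the all-by-all self-alignment of the (N-split)
assembly, read-depth per base and the depth cutoffs, and produces a purge
plan:

1. self-alignment records are filtered to cross-segment anchors;
2. anchors between each segment pair are chained per strand with a
   collinear dynamic program (score = matched bases minus affine gap
   costs);
3. segments dominated by sub-``low`` depth are flagged JUNK and segments
   dominated by super-``high`` depth HIGHCOV (collapsed repeats; reported
   but not removed), and both are excluded from further calling;
4. a segment mostly covered by chains to longer segments, at haploid mean
   depth, is a haplotig (the contained-duplication case) and all its
   matches are discarded;
5. remaining chains that form unambiguous dovetails are heterozygous
   overlaps when the matched interval sits below the haploid/diploid
   transition depth on *both* segments; the matched interval on the
   shorter segment is trimmed.

The depth gate in steps 4-5 is what distinguishes haplotypic duplication
(reads split between two copies, so each copy sits at haploid depth) from
repeat duplication (both copies at diploid depth or above), and is the
reason collapsed repeats survive purging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .assembly_prep import SegmentMap, lift_interval
from .coverage import DepthProfile, mean_depth
from .cutoffs import Cutoffs
from .io_formats import BedInterval, PafRecord

__all__ = [
    "Anchor",
    "Chain",
    "ChainParams",
    "PurgeParams",
    "PurgePlan",
    "filter_self_alignments",
    "chain_anchors",
    "classify_depth_extremes",
    "call_haplotigs",
    "call_overlaps",
    "build_purge_plan",
]

JUNK = "JUNK"
HAPLOTIG = "HAPLOTIG"
OVLP = "OVLP"
HIGHCOV = "HIGHCOV"
NONE = "NONE"

# merge priority when lifted intervals overlap (highest wins)
_PRIORITY = {JUNK: 3, HAPLOTIG: 2, OVLP: 1, HIGHCOV: 0}


@dataclass(frozen=True)
class Anchor:
    """One self-alignment match between two distinct segments."""

    qname: str
    tname: str
    qlen: int
    tlen: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    nmatch: int


@dataclass
class Chain:
    """A collinear, strand-consistent set of anchors between two segments."""

    qname: str
    tname: str
    qlen: int
    tlen: int
    strand: str
    anchors: List[Anchor]
    score: float

    @property
    def qspan(self) -> Tuple[int, int]:
        return (min(a.qstart for a in self.anchors), max(a.qend for a in self.anchors))

    @property
    def tspan(self) -> Tuple[int, int]:
        return (min(a.tstart for a in self.anchors), max(a.tend for a in self.anchors))

    def span_on(self, segment: str) -> Tuple[int, int]:
        if segment == self.qname:
            return self.qspan
        if segment == self.tname:
            return self.tspan
        raise ValueError(f"chain does not involve {segment!r}")

    def involves(self, segment: str) -> bool:
        return segment in (self.qname, self.tname)


@dataclass(frozen=True)
class ChainParams:
    gap_open: float = 100.0
    gap_scale: float = 0.05
    max_gap: int = 100_000
    max_overlap: int = 100
    min_chain_score: float = 10_000.0


@dataclass(frozen=True)
class PurgeParams:
    min_match: int = 500
    min_aln_len: int = 1000
    extreme_frac: float = 0.8
    cov_frac: float = 0.8
    end_tolerance_bp: int = 15_000
    end_tolerance_frac: float = 0.15

    def end_tolerance(self, span_len: int) -> int:
        return max(self.end_tolerance_bp, int(self.end_tolerance_frac * span_len))


@dataclass
class PurgePlan:
    """Resolved, non-overlapping labeled intervals on the original assembly."""

    intervals: List[BedInterval]
    classifications: Dict[str, str] = field(default_factory=dict)

    def removable(self, labels: Tuple[str, ...] = (JUNK, HAPLOTIG, OVLP)) -> List[BedInterval]:
        return [iv for iv in self.intervals if iv.label in labels]


# ---------------------------------------------------------------------------
# anchor filtering

def filter_self_alignments(
    records: Iterable[PafRecord],
    min_match: int = 500,
    min_aln_len: int = 1000,
) -> List[Anchor]:
    """Reduce self-alignment PAF to usable cross-segment anchors.

    Drops self-hits (qname == tname) and weak records; symmetric A->B /
    B->A duplicates are collapsed by mirroring every record into the
    lexicographically ordered pair orientation.
    """
    seen = set()
    out: List[Anchor] = []
    for rec in records:
        if rec.qname == rec.tname:
            continue
        if rec.nmatch < min_match or rec.alnlen < min_aln_len:
            continue
        if rec.qname <= rec.tname:
            a = Anchor(
                rec.qname, rec.tname, rec.qlen, rec.tlen,
                rec.qstart, rec.qend, rec.tstart, rec.tend,
                rec.strand, rec.nmatch,
            )
        else:  # mirror: swap roles; strand is symmetric
            a = Anchor(
                rec.tname, rec.qname, rec.tlen, rec.qlen,
                rec.tstart, rec.tend, rec.qstart, rec.qend,
                rec.strand, rec.nmatch,
            )
        key = (a.qname, a.tname, a.qstart, a.qend, a.tstart, a.tend, a.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# chaining

def _transition_ok(prev: Anchor, nxt: Anchor, params: ChainParams) -> bool:
    qgap = nxt.qstart - prev.qend
    if qgap < -params.max_overlap or qgap > params.max_gap:
        return False
    if prev.strand == "+":
        tgap = nxt.tstart - prev.tend
    else:
        tgap = prev.tstart - nxt.tend
    return -params.max_overlap <= tgap <= params.max_gap


def _gap_cost(prev: Anchor, nxt: Anchor, params: ChainParams) -> float:
    qgap = nxt.qstart - prev.qend
    if prev.strand == "+":
        tgap = nxt.tstart - prev.tend
    else:
        tgap = prev.tstart - nxt.tend
    return params.gap_open + abs(qgap - tgap) * params.gap_scale


def _chain_one_strand(anchors: List[Anchor], params: ChainParams) -> List[Chain]:
    """Best-score-first chain extraction by repeated collinear DP."""
    chains: List[Chain] = []
    pool = sorted(anchors, key=lambda a: (a.qstart, a.qend, a.tstart, a.tend))
    while pool:
        n = len(pool)
        score = [float(a.nmatch) for a in pool]
        parent = [-1] * n
        for i in range(n):
            for j in range(i):
                if not _transition_ok(pool[j], pool[i], params):
                    continue
                cand = score[j] - _gap_cost(pool[j], pool[i], params) + pool[i].nmatch
                if cand > score[i]:
                    score[i] = cand
                    parent[i] = j
        best = max(range(n), key=lambda i: (score[i], -pool[i].qstart, -pool[i].tstart))
        if score[best] < params.min_chain_score:
            break
        members = []
        i = best
        while i != -1:
            members.append(pool[i])
            i = parent[i]
        members.reverse()
        a0 = members[0]
        chains.append(
            Chain(a0.qname, a0.tname, a0.qlen, a0.tlen, a0.strand, members, score[best])
        )
        used = set(id(m) for m in members)
        pool = [a for a in pool if id(a) not in used]
    return chains


def chain_anchors(anchors: Sequence[Anchor], params: ChainParams | None = None) -> List[Chain]:
    """Chain anchors of ONE segment pair into collinear chains, per strand.

    Anchors are sorted by query start; the DP allows a transition j -> i
    when the query/target gaps are within ``[-max_overlap, max_gap]`` and
    target order matches the strand, charging
    ``gap_open + |qgap - tgap| * gap_scale``.  Chains are extracted
    best-score-first, each anchor belonging to at most one chain; chains
    scoring below ``min_chain_score`` are discarded.  The result is
    independent of input anchor order.
    """
    params = params or ChainParams()
    if not anchors:
        return []
    pairs = {(a.qname, a.tname) for a in anchors}
    if len(pairs) != 1:
        raise ValueError(f"chain_anchors expects one segment pair, got {sorted(pairs)}")
    chains: List[Chain] = []
    for strand in "+-":
        sub = [a for a in anchors if a.strand == strand]
        if sub:
            chains.extend(_chain_one_strand(sub, params))
    chains.sort(key=lambda c: (-c.score, c.strand, c.qspan, c.tspan))
    return chains


def chain_all(anchors: Sequence[Anchor], params: ChainParams | None = None) -> List[Chain]:
    """Group anchors by segment pair and chain each pair."""
    groups: Dict[Tuple[str, str], List[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.qname, a.tname), []).append(a)
    chains: List[Chain] = []
    for key in sorted(groups):
        chains.extend(chain_anchors(groups[key], params))
    return chains


# ---------------------------------------------------------------------------
# depth-extreme classification

def classify_depth_extremes(
    profile: DepthProfile,
    cutoffs: Cutoffs,
    segment: str,
    frac: float = 0.8,
) -> str:
    """JUNK / HIGHCOV / NONE by the fraction of bases at extreme depth."""
    if segment not in profile.depths:
        raise ValueError(f"segment {segment!r} not in depth profile")
    depths = profile.depths[segment]
    if depths.size == 0:
        return NONE
    if np.count_nonzero(depths < cutoffs.low) >= frac * depths.size:
        return JUNK
    if np.count_nonzero(depths > cutoffs.high) >= frac * depths.size:
        return HIGHCOV
    return NONE


# ---------------------------------------------------------------------------
# haplotig calling

def _union_len(intervals: List[Tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        if s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def call_haplotigs(
    chains: Sequence[Chain],
    profile: DepthProfile,
    cutoffs: Cutoffs,
    cov_frac: float = 0.8,
    excluded: Iterable[str] = (),
) -> Tuple[List[str], List[Chain]]:
    """Identify contained-duplication segments (haplotigs).

    A segment is a haplotig when chains to strictly longer segments cover
    at least ``cov_frac`` of it AND its mean depth is below the
    haploid/diploid transition (so it is haplotype-resolved, not a
    collapsed repeat).  Segments are visited in increasing length order so
    nested containments resolve deterministically; every chain touching a
    called haplotig leaves the working set.

    Returns the called segment names and the surviving chains.
    """
    excluded = set(excluded)
    lengths = profile.lengths
    working = [c for c in chains if not (excluded & {c.qname, c.tname})]
    involved = sorted(
        {s for c in working for s in (c.qname, c.tname)},
        key=lambda s: (lengths[s], s),
    )
    haplotigs: List[str] = []
    for seg in involved:
        seg_len = lengths[seg]
        spans = []
        for c in working:
            if not c.involves(seg):
                continue
            other = c.tname if c.qname == seg else c.qname
            if (lengths[other], other) <= (seg_len, seg):
                continue  # only matches to longer segments argue containment
            spans.append(c.span_on(seg))
        if not spans:
            continue
        if _union_len(spans) < cov_frac * seg_len:
            continue
        if mean_depth(profile, seg, 0, seg_len) >= cutoffs.transition:
            continue  # collapsed-repeat guard
        haplotigs.append(seg)
        working = [c for c in working if not c.involves(seg)]
    return haplotigs, working


# ---------------------------------------------------------------------------
# heterozygous-overlap calling

def _dovetail_ends(chain: Chain, params: PurgeParams) -> List[Tuple[str, str]]:
    """Consistent (query-end, target-end) pairs this chain reaches.

    Ends are 'L'/'R'.  A '+' alignment joins opposite ends (suffix of one
    to prefix of the other); a '-' alignment joins like ends.
    """
    qs, qe = chain.qspan
    ts, te = chain.tspan
    tol_q = params.end_tolerance(qe - qs)
    tol_t = params.end_tolerance(te - ts)
    q_ends = []
    if qs <= tol_q:
        q_ends.append("L")
    if chain.qlen - qe <= tol_q:
        q_ends.append("R")
    t_ends = []
    if ts <= tol_t:
        t_ends.append("L")
    if chain.tlen - te <= tol_t:
        t_ends.append("R")
    pairs = []
    for qend in q_ends:
        for tend in t_ends:
            if chain.strand == "+" and qend != tend:
                pairs.append((qend, tend))
            elif chain.strand == "-" and qend == tend:
                pairs.append((qend, tend))
    return pairs


def call_overlaps(
    chains: Sequence[Chain],
    profile: DepthProfile,
    cutoffs: Cutoffs,
    params: PurgeParams | None = None,
) -> List[BedInterval]:
    """Call unambiguous heterozygous dovetail overlaps.

    A chain is a candidate when it reaches (within the end tolerance) a
    strand-consistent end of each of its two segments.  A candidate is
    unambiguous when it is the only candidate touching each of those two
    segment ends.  It is heterozygous when the mean depth over the matched
    interval is below the transition cutoff on BOTH segments; the matched
    interval on the shorter segment (ties: lexicographically larger name)
    is returned, extended to the segment end when the residual overhang is
    within tolerance.
    """
    params = params or PurgeParams()
    lengths = profile.lengths

    candidates = []  # (chain, (qend, tend))
    for c in chains:
        pairs = _dovetail_ends(c, params)
        if pairs:
            # a chain near a corner can touch several consistent end pairs;
            # keep the one with the smallest combined overhang
            def overhang(p):
                qs, qe = c.qspan
                ts, te = c.tspan
                qo = qs if p[0] == "L" else c.qlen - qe
                to = ts if p[1] == "L" else c.tlen - te
                return qo + to

            candidates.append((c, min(pairs, key=overhang)))

    touch: Dict[Tuple[str, str], int] = {}
    for c, (qend, tend) in candidates:
        touch[(c.qname, qend)] = touch.get((c.qname, qend), 0) + 1
        touch[(c.tname, tend)] = touch.get((c.tname, tend), 0) + 1

    calls: List[BedInterval] = []
    for c, (qend, tend) in candidates:
        if touch[(c.qname, qend)] > 1 or touch[(c.tname, tend)] > 1:
            continue  # ambiguous: leave untouched rather than guess
        qs, qe = c.qspan
        ts, te = c.tspan
        if mean_depth(profile, c.qname, qs, qe) >= cutoffs.transition:
            continue
        if mean_depth(profile, c.tname, ts, te) >= cutoffs.transition:
            continue
        # trim the shorter segment (tie -> lexicographically larger name)
        lq, lt = lengths[c.qname], lengths[c.tname]
        if lq < lt or (lq == lt and c.qname > c.tname):
            seg, s, e = c.qname, qs, qe
        else:
            seg, s, e = c.tname, ts, te
        seg_len = lengths[seg]
        tol = params.end_tolerance(e - s)
        if s <= tol:
            s = 0
        if seg_len - e <= tol:
            e = seg_len
        calls.append(BedInterval(seg, s, e, OVLP))
    calls.sort()
    return calls


# ---------------------------------------------------------------------------
# plan assembly

def _overlay(intervals: List[BedInterval]) -> List[BedInterval]:
    """Resolve overlaps by label priority; merge touching same-label runs."""
    out: List[BedInterval] = []
    by_contig: Dict[str, List[BedInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    for contig in sorted(by_contig):
        ivs = by_contig[contig]
        # breakpoints of all intervals
        points = sorted({p for iv in ivs for p in (iv.start, iv.end)})
        pieces: List[BedInterval] = []
        for s, e in zip(points[:-1], points[1:]):
            covering = [iv for iv in ivs if iv.start <= s and iv.end >= e]
            if not covering:
                continue
            label = max(covering, key=lambda iv: _PRIORITY[iv.label]).label
            pieces.append(BedInterval(contig, s, e, label))
        merged: List[BedInterval] = []
        for p in pieces:
            if merged and merged[-1].end == p.start and merged[-1].label == p.label:
                merged[-1] = BedInterval(contig, merged[-1].start, p.end, p.label)
            else:
                merged.append(p)
        out.extend(merged)
    return out


def build_purge_plan(
    depth_labels: Dict[str, str],
    haplotigs: Sequence[str],
    overlaps: Sequence[BedInterval],
    smap: SegmentMap,
) -> PurgePlan:
    """Lift all calls onto original assembly coordinates and resolve them.

    ``depth_labels`` maps segment name to JUNK/HIGHCOV/NONE.  JUNK and
    HAPLOTIG calls span their full segment.  Overlapping lifted intervals
    merge with priority JUNK > HAPLOTIG > OVLP > HIGHCOV.
    """
    raw: List[BedInterval] = []
    classifications: Dict[str, str] = {}
    for seg, label in sorted(depth_labels.items()):
        if label == NONE:
            continue
        classifications[seg] = label
        seg_len = smap.segments[seg].end - smap.segments[seg].start
        raw.append(lift_interval(smap, seg, 0, seg_len, label))
    for seg in haplotigs:
        classifications[seg] = HAPLOTIG
        seg_len = smap.segments[seg].end - smap.segments[seg].start
        raw.append(lift_interval(smap, seg, 0, seg_len, HAPLOTIG))
    for iv in overlaps:
        classifications.setdefault(iv.contig, OVLP)
        raw.append(lift_interval(smap, iv.contig, iv.start, iv.end, OVLP))

    for iv in raw:
        length = smap.contig_lengths[iv.contig]
        if iv.end > length:  # invariant breach, not user error
            raise AssertionError(
                f"lifted interval {iv.contig}:{iv.start}-{iv.end} exceeds contig length {length}"
            )
    return PurgePlan(_overlay(raw), classifications)
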