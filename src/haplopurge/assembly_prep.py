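"""Scaffold-to-contig splitting at N-gaps, with exact coordinate lift-back.

Draft assemblies are often scaffolds whose contigs are joined by runs of
'N'.  Self-alignment and purging operate on the gap-free segments; the
:class:`SegmentMap` records where every segment came from so purge calls
can be lifted back onto the original input coordinates, and so the split
is exactly reversible.

A segment spanning an entire contig keeps the contig's original name;
segments of a contig that actually split are named
``<contig>:<start>-<end>`` (0-based half-open), which is self-describing
and collision-free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .io_formats import BedInterval, ContigSeq

__all__ = ["Segment", "SegmentMap", "split_at_gaps", "lift_interval", "reconstruct"]


@dataclass(frozen=True)
class Segment:
    name: str
    contig: str
    start: int
    end: int


@dataclass
class SegmentMap:
    """Lift table between split segments and original contigs."""

    segments: Dict[str, Segment] = field(default_factory=dict)
    by_contig: Dict[str, List[Segment]] = field(default_factory=dict)
    contig_lengths: Dict[str, int] = field(default_factory=dict)

    def add(self, seg: Segment) -> None:
        if seg.name in self.segments:
            raise ValueError(f"duplicate segment name {seg.name!r}")
        self.segments[seg.name] = seg
        self.by_contig.setdefault(seg.contig, []).append(seg)


def split_at_gaps(
    contigs: Sequence[ContigSeq], min_gap: int = 1
) -> Tuple[List[ContigSeq], SegmentMap]:
    """Cut each contig at N-runs of length >= ``min_gap``.

    Shorter N-runs stay inside segments.  Every emitted segment contains at
    least one non-N base; an all-N contig yields zero segments but is still
    recorded in the map (so reconstruction stays exact).
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    gap_re = re.compile("N{%d,}" % min_gap)
    segs: List[ContigSeq] = []
    smap = SegmentMap()
    for contig in contigs:
        smap.contig_lengths[contig.name] = len(contig.seq)
        smap.by_contig.setdefault(contig.name, [])
        pos = 0
        pieces: List[Tuple[int, int]] = []
        for m in gap_re.finditer(contig.seq):
            if m.start() > pos:
                pieces.append((pos, m.start()))
            pos = m.end()
        if pos < len(contig.seq):
            pieces.append((pos, len(contig.seq)))
        for start, end in pieces:
            sub = contig.seq[start:end]
            if set(sub) == {"N"}:  # min_gap > 1 can leave all-N slivers at ends
                continue
            if start == 0 and end == len(contig.seq):
                name = contig.name
            else:
                name = f"{contig.name}:{start}-{end}"
            seg = Segment(name, contig.name, start, end)
            smap.add(seg)
            segs.append(ContigSeq(name, sub))
    return segs, smap


def lift_interval(
    smap: SegmentMap, segment: str, start: int, end: int, label: str = "."
) -> BedInterval:
    """Translate a segment-local interval onto its original contig."""
    if segment not in smap.segments:
        raise ValueError(f"unknown segment {segment!r}")
    seg = smap.segments[segment]
    if not (0 <= start < end <= seg.end - seg.start):
        raise ValueError(
            f"interval {start}-{end} outside segment {segment!r} "
            f"(length {seg.end - seg.start})"
        )
    return BedInterval(seg.contig, seg.start + start, seg.start + end, label)


def reconstruct(smap: SegmentMap, segments: Sequence[ContigSeq]) -> List[ContigSeq]:
    """Rebuild the original contigs from split segments plus the map.

    Positions not covered by any segment are N by construction (they were
    either cut gaps or all-N slivers), so the rebuild is exact.
    """
    seqs = {s.name: s.seq for s in segments}
    out: List[ContigSeq] = []
    for contig, length in smap.contig_lengths.items():
        buf = ["N"] * length
        for seg in smap.by_contig.get(contig, []):
            sub = seqs[seg.name]
            if len(sub) != seg.end - seg.start:
                raise ValueError(f"segment {seg.name!r} length mismatch")
            buf[seg.start : seg.end] = sub
        out.append(ContigSeq(contig, "".join(buf)))
    return out
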