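"""Per-base read depth and the genome-wide depth histogram.

Long reads are mapped to the assembly upstream (minimap2, PAF in); here each
retained alignment contributes +1 depth over its full target span.  A record
is retained when it is primary (``tp:A:P`` when the tag exists; records
without the tag are kept) and its mapping quality is at least ``min_mapq``.
Span-level counting ignores per-base CIGAR detail, the standard
approximation for coverage-cutoff work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import numpy as np

from .io_formats import PafRecord

__all__ = ["DepthProfile", "DepthHistogram", "compute_depth", "build_histogram", "mean_depth"]


@dataclass
class DepthProfile:
    """Per-base read depth for every contig (or segment) of an assembly."""

    depths: Dict[str, np.ndarray]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: arr.size for name, arr in self.depths.items()}

    @property
    def total_bases(self) -> int:
        return sum(arr.size for arr in self.depths.values())

    def slice(self, contig: str, start: int, end: int) -> np.ndarray:
        return self.depths[contig][start:end]


@dataclass
class DepthHistogram:
    """Counts of assembly bases by depth, with depths > d_max pooled at d_max."""

    counts: np.ndarray  # index = depth 0..d_max
    d_max: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def compute_depth(
    alignments: Iterable[PafRecord],
    contig_lengths: Mapping[str, int],
    min_mapq: int = 0,
) -> DepthProfile:
    """Accumulate read depth from read-to-assembly alignments.

    ``depth[b]`` is the number of retained alignments whose target span
    covers base ``b``.  Implemented with difference arrays (add +1 at
    tstart, -1 at tend, prefix-sum), so it is order-invariant by
    construction.
    """
    diffs = {name: np.zeros(length + 1, dtype=np.int64) for name, length in contig_lengths.items()}
    for rec in alignments:
        if rec.tname not in diffs:
            raise ValueError(f"alignment target {rec.tname!r} not in assembly")
        if rec.tend > contig_lengths[rec.tname]:
            raise ValueError(
                f"alignment span {rec.tstart}-{rec.tend} exceeds length of {rec.tname!r}"
            )
        if not rec.is_primary() or rec.mapq < min_mapq:
            continue
        d = diffs[rec.tname]
        d[rec.tstart] += 1
        d[rec.tend] -= 1
    depths = {
        name: np.cumsum(d[:-1]).astype(np.int32) for name, d in diffs.items()
    }
    return DepthProfile(depths)


def build_histogram(profile: DepthProfile, d_max: int | None = None) -> DepthHistogram:
    """Genome-wide depth histogram; depths above ``d_max`` pool in the top bin.

    When ``d_max`` is None it defaults to 4x the modal nonzero depth with a
    floor of 500, which caps memory while keeping the repeat tail visible.
    """
    if d_max is not None and d_max < 1:
        raise ValueError("d_max must be >= 1")
    full = np.zeros(1, dtype=np.int64)
    for arr in profile.depths.values():
        if arr.size == 0:
            continue
        bc = np.bincount(arr)
        if bc.size > full.size:
            bc[: full.size] += full
            full = bc
        else:
            full[: bc.size] += bc
    if d_max is None:
        mode = int(np.argmax(full[1:])) + 1 if full.size > 1 else 1
        d_max = max(500, 4 * mode)
    counts = np.zeros(d_max + 1, dtype=np.int64)
    upto = min(d_max, full.size - 1)
    counts[: upto + 1] = full[: upto + 1]
    if full.size - 1 > d_max:
        counts[d_max] += int(full[d_max + 1 :].sum())
    return DepthHistogram(counts, d_max)


def mean_depth(profile: DepthProfile, contig: str, start: int, end: int) -> float:
    """Arithmetic mean of per-base depth over ``[start, end)``."""
    if contig not in profile.depths:
        raise ValueError(f"unknown contig {contig!r}")
    n = profile.depths[contig].size
    if not (0 <= start < end <= n):
        raise ValueError(f"empty or invalid interval {contig}:{start}-{end} (len {n})")
    return float(profile.depths[contig][start:end].mean())
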