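"""Automatic depth-cutoff selection from the read-depth histogram.

A diploid sample mapped onto its primary assembly produces a depth
histogram with up to two peaks: loci represented once per haplotype in the
assembly (haplotype-resolved duplication) collect reads from a single
haplotype and sit at the *haploid* depth h, while correctly collapsed loci
collect reads from both haplotypes and sit at the *diploid* depth d ~ 2h.
Three thresholds are derived from the histogram shape:

* ``low``  (L)  — junk floor; contigs mostly below it are debris,
* ``transition`` (T) — the haploid/diploid separator used to gate every
  haplotig and heterozygous-overlap call,
* ``high`` (H) — repeat ceiling; contigs mostly above it are collapsed
  repeats and are protected from purging.

Either peak may dominate (assemblies can be mostly haplotype-resolved or
mostly collapsed), and a single visible peak is interpreted as the diploid
peak.  All constants are exposed as parameters; the detection depends only
on histogram *shape*, so cutoffs are invariant under uniform scaling of
the counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy.signal import find_peaks

from .coverage import DepthHistogram
from .io_formats import FormatError

__all__ = [
    "Cutoffs",
    "InsufficientCoverageError",
    "smooth_histogram",
    "find_cutoffs",
    "manual_cutoffs",
    "read_cutoffs",
    "write_cutoffs",
]

MODES = ("haploid-dominant", "diploid-dominant", "unimodal", "manual")


class InsufficientCoverageError(ValueError):
    """Histogram has no usable mass; suggests supplying cutoffs manually."""


@dataclass(frozen=True)
class Cutoffs:
    """Depth thresholds L < T < H plus the peaks they were derived from."""

    low: int
    transition: int
    high: int
    peaks: List[int] = field(default_factory=list)
    mode: str = "manual"

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.transition < self.high):
            raise ValueError(
                f"cutoffs must satisfy 0 <= L < T < H, got "
                f"L={self.low} T={self.transition} H={self.high}"
            )
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def haploid_peak(self) -> int | None:
        return min(self.peaks) if len(self.peaks) >= 2 else None

    @property
    def diploid_peak(self) -> int:
        return max(self.peaks) if self.peaks else self.transition


def manual_cutoffs(low: int, transition: int, high: int) -> Cutoffs:
    """User-supplied thresholds; ordering L < T < H is still enforced."""
    return Cutoffs(low, transition, high, peaks=[], mode="manual")


def smooth_histogram(hist: DepthHistogram, window: int = 5) -> DepthHistogram:
    """Moving-average smoothing with reflected ends; total mass conserved.

    Ends are reflected edge-inclusively, which makes every bin participate
    in exactly ``window`` averages and so conserves the total count
    exactly (up to float rounding).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    counts = np.asarray(hist.counts, dtype=np.float64)
    if window == 1:
        return DepthHistogram(counts.copy(), hist.d_max)
    half = window // 2
    if counts.size <= half:
        return DepthHistogram(counts.copy(), hist.d_max)
    padded = np.pad(counts, half, mode="symmetric")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(padded, kernel, mode="valid")
    return DepthHistogram(smoothed, hist.d_max)


def _secondary_peak(
    smoothed: np.ndarray,
    p1: int,
    lo: int,
    hi: int,
    min_depth: int,
    secondary_ratio: float,
    valley_frac: float,
) -> int | None:
    """Best qualifying local maximum in [lo, hi], or None."""
    lo = max(lo, min_depth)
    hi = min(hi, smoothed.size - 2)  # cap bin excluded
    if hi < lo:
        return None
    peak_idx, _ = find_peaks(smoothed)
    cands = [p for p in peak_idx if lo <= p <= hi]
    best = None
    for p in cands:
        if smoothed[p] < secondary_ratio * smoothed[p1]:
            continue
        a, b = (p, p1) if p < p1 else (p1, p)
        if b - a < 2:
            continue
        valley = smoothed[a + 1 : b].min()
        if valley >= valley_frac * min(smoothed[a], smoothed[b]):
            continue
        if best is None or smoothed[p] > smoothed[best] or (
            smoothed[p] == smoothed[best] and p < best
        ):
            best = p
    return int(best) if best is not None else None


def find_cutoffs(
    hist: DepthHistogram,
    min_depth: int = 4,
    window: int = 5,
    secondary_ratio: float = 0.1,
    valley_frac: float = 0.95,
    upper_window: tuple = (1.5, 2.5),
    lower_window: tuple = (0.4, 0.65),
    unimodal_factor: float = 0.75,
    low_factor: float = 0.25,
    high_factor: float = 2.5,
) -> Cutoffs:
    """Select L, T, H from the depth histogram.

    Procedure: smooth; take the global peak p1 at depth >= ``min_depth``
    (the overflow bin excluded); look for a secondary peak in
    ``[0.4*p1, 0.65*p1]`` and then ``[1.5*p1, 2.5*p1]``.  If one is found, the
    smaller-depth peak is the haploid depth h and the larger the diploid
    depth d; T is the argmin of the smoothed counts strictly between them
    (ties toward the lower depth), L = max(2, round(h/4)), H = round(2.5 d),
    and the mode records which peak carries more (smoothed) mass.  With no
    secondary peak the histogram is unimodal: p1 is taken as the diploid
    peak, T = round(0.75 p1), L = max(2, round(0.375 p1)), H = round(2.5 p1).
    """
    sm = smooth_histogram(hist, window)
    smoothed = np.asarray(sm.counts)
    # global peak, ignoring sub-min_depth bins and the overflow bin
    usable = smoothed[min_depth : smoothed.size - 1]
    if usable.size == 0 or usable.sum() <= 0 or usable.max() <= 0:
        raise InsufficientCoverageError(
            f"no histogram mass at depth >= {min_depth}; "
            "coverage too low for automatic cutoffs - supply -L/-T/-H manually"
        )
    p1 = int(np.argmax(usable)) + min_depth

    # the lower window is searched first: when p1 is the diploid peak, a
    # collapsed-repeat bump near 2*p1 must not be mistaken for its partner
    p2 = _secondary_peak(
        smoothed, p1,
        int(np.ceil(lower_window[0] * p1)), int(np.floor(lower_window[1] * p1)),
        min_depth, secondary_ratio, valley_frac,
    )
    if p2 is None:
        p2 = _secondary_peak(
            smoothed, p1,
            int(np.ceil(upper_window[0] * p1)), int(np.floor(upper_window[1] * p1)),
            min_depth, secondary_ratio, valley_frac,
        )

    if p2 is not None and abs(p2 - p1) >= 2:
        h, d = min(p1, p2), max(p1, p2)
        valley_rel = int(np.argmin(smoothed[h + 1 : d])) + h + 1
        transition = valley_rel
        low = max(2, round(low_factor * h))
        high = round(high_factor * d)
        mode = "haploid-dominant" if smoothed[h] > smoothed[d] else "diploid-dominant"
        peaks = [h, d]
    else:
        transition = round(unimodal_factor * p1)
        low = max(2, round(0.375 * p1))
        high = round(high_factor * p1)
        mode = "unimodal"
        peaks = [p1]

    low = min(low, transition - 1)
    if low < 0:
        low = 0
    if high <= transition:
        high = transition + 1
    return Cutoffs(low, transition, high, peaks=peaks, mode=mode)


def write_cutoffs(cutoffs: Cutoffs, path: os.PathLike | str) -> None:
    """Single-line TSV: ``L<TAB>T<TAB>H<TAB>mode``."""
    with open(path, "w") as fh:
        fh.write(f"{cutoffs.low}\t{cutoffs.transition}\t{cutoffs.high}\t{cutoffs.mode}\n")


def read_cutoffs(path: os.PathLike | str) -> Cutoffs:
    with open(path) as fh:
        line = fh.readline()
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 4:
        raise FormatError("cutoffs file must have one line: L\\tT\\tH\\tmode")
    try:
        low, transition, high = int(cols[0]), int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise FormatError(f"cutoffs file: {exc}") from exc
    if cols[3] not in MODES:
        raise FormatError(f"cutoffs file: unknown mode {cols[3]!r}")
    return Cutoffs(low, transition, high, peaks=[], mode=cols[3])
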