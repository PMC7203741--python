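"""K-mer copy-number spectra for assembly duplication QC.

The joint spectrum of k-mer multiplicity in reads (columns of a
read-depth-style histogram) versus copy number in the assembly diagnoses
retained haplotypic duplication: single-locus k-mers (read multiplicity in
the haploid-to-diploid coverage band) should occur exactly once in a
primary assembly, so any excess assembly copies of band k-mers measure
duplication.  The reduction statistic compares that excess before and
after purging.

Counting is exact: canonical k-mers (lexicographic minimum of a k-mer and
its reverse complement, which under the 2-bit code A<C<G<T is the numeric
minimum) are packed into 64-bit integers, so k <= 31.  Exact hash-free
counting via sorting is entirely adequate at desk scale (tens of
megabases) and keeps the counts reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np

from .cutoffs import Cutoffs
from .io_formats import ContigSeq

__all__ = [
    "KmerCounts",
    "SpectrumMatrix",
    "count_kmers",
    "spectrum",
    "haploid_band",
    "duplicated_haploid_kmer_reduction",
    "write_spectrum",
    "plot_spectrum",
]

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = "ACGT"

_CHUNK_KMERS = 24_000_000  # collapse raw code buffers at ~192 MB


def _encode_seq(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _codes_one(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit-packed k-mer codes of one sequence; N windows skipped."""
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    b = _encode_seq(seq)
    bad = b > 3
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rc_src = (3 - b[::-1].astype(np.int16)).astype(np.uint64)  # complement of reversed
    rev = np.zeros(m, dtype=np.uint64)
    bu = b.astype(np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | bu[j : j + m]
        rev = (rev << np.uint64(2)) | rc_src[j : j + m]
    # rc code of window starting at i equals rev-window starting at n-k-i
    rc = rev[::-1]
    canon = np.minimum(fwd, rc)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        valid = (cs[k:] - cs[:-k]) == 0
        canon = canon[valid]
    return canon


def _merge_counts(
    codes_a: np.ndarray, counts_a: np.ndarray, codes_b: np.ndarray, counts_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    codes = np.concatenate((codes_a, codes_b))
    weights = np.concatenate((counts_a, counts_b))
    u, inv = np.unique(codes, return_inverse=True)
    c = np.bincount(inv, weights=weights).astype(np.int64)
    return u, c


@dataclass
class KmerCounts:
    """Exact counts of canonical k-mers, stored as sorted packed codes."""

    k: int
    codes: np.ndarray  # sorted uint64
    counts: np.ndarray  # int64, parallel to codes

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        """Count of one k-mer given as a string (canonicalized here)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        code = _codes_one(kmer, self.k)
        if code.size == 0:
            return 0
        i = np.searchsorted(self.codes, code[0])
        if i < self.codes.size and self.codes[i] == code[0]:
            return int(self.counts[i])
        return 0

    def items(self) -> Iterator[Tuple[str, int]]:
        """Decode to (kmer string, count) pairs; for small instances."""
        for code, count in zip(self.codes.tolist(), self.counts.tolist()):
            chars = []
            for shift in range(2 * (self.k - 1), -2, -2):
                chars.append(_DECODE[(code >> shift) & 3])
            yield "".join(chars), int(count)

    def to_dict(self) -> Dict[str, int]:
        return dict(self.items())


def count_kmers(sequences: Iterable[str | ContigSeq], k: int) -> KmerCounts:
    """Count canonical k-mers over all sequences; windows containing N skipped."""
    if not (1 <= k <= 31):
        raise ValueError(f"k must be in 1..31, got {k}")
    codes = np.empty(0, dtype=np.uint64)
    counts = np.empty(0, dtype=np.int64)
    buf: List[np.ndarray] = []
    buffered = 0

    def _flush():
        nonlocal codes, counts, buf, buffered
        if not buf:
            return
        raw = np.concatenate(buf)
        buf, buffered = [], 0
        u, c = np.unique(raw, return_counts=True)
        codes, counts = _merge_counts(codes, counts, u, c.astype(np.int64))

    for seq in sequences:
        s = seq.seq if isinstance(seq, ContigSeq) else seq
        arr = _codes_one(s.upper(), k)
        if arr.size:
            buf.append(arr)
            buffered += arr.size
        if buffered >= _CHUNK_KMERS:
            _flush()
    _flush()
    return KmerCounts(k, codes, counts)


@dataclass
class SpectrumMatrix:
    """M[r][c] = distinct canonical k-mers with read multiplicity r, assembly copy c.

    Row 0 holds assembly-only k-mers; column 0 holds read-only k-mers.
    The last row/column pool overflow at r_max / c_max.
    """

    k: int
    matrix: np.ndarray  # shape (r_max+1, c_max+1), int64

    @property
    def r_max(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def c_max(self) -> int:
        return self.matrix.shape[1] - 1

    @property
    def total_distinct(self) -> int:
        return int(self.matrix.sum())


def spectrum(
    read_counts: KmerCounts,
    asm_counts: KmerCounts,
    r_max: int = 100,
    c_max: int = 8,
) -> SpectrumMatrix:
    """Joint read-multiplicity x assembly-copy-number spectrum.

    Every distinct k-mer present in reads or assembly lands in exactly one
    cell; multiplicities above the caps accumulate in the top row/column.
    """
    if read_counts.k != asm_counts.k:
        raise ValueError("read and assembly k-mer counts use different k")
    union = np.union1d(read_counts.codes, asm_counts.codes)

    def _lookup(counts: KmerCounts) -> np.ndarray:
        out = np.zeros(union.size, dtype=np.int64)
        idx = np.searchsorted(counts.codes, union)
        idx_c = np.clip(idx, 0, max(counts.codes.size - 1, 0))
        if counts.codes.size:
            hit = counts.codes[idx_c] == union
            out[hit] = counts.counts[idx_c[hit]]
        return out

    r = np.clip(_lookup(read_counts), 0, r_max)
    c = np.clip(_lookup(asm_counts), 0, c_max)
    flat = np.bincount(r * (c_max + 1) + c, minlength=(r_max + 1) * (c_max + 1))
    return SpectrumMatrix(read_counts.k, flat.reshape(r_max + 1, c_max + 1).astype(np.int64))


def haploid_band(cutoffs: Cutoffs) -> Tuple[int, int]:
    """Read-multiplicity band [lo, hi) of single-locus (non-repeat) k-mers.

    Spans the haploid and diploid coverage peaks with half-peak margins:
    [h/2, d + h/2).  For a unimodal histogram the diploid peak d stands in
    with h taken as d/2.  Repeat-multiplicity k-mers fall above the band,
    sequencing-error k-mers (rare multiplicities) below it.
    """
    d = cutoffs.diploid_peak
    h = cutoffs.haploid_peak if cutoffs.haploid_peak is not None else max(1, round(d / 2))
    return max(1, round(h / 2)), round(d + h / 2)


def duplicated_haploid_kmer_reduction(
    before: SpectrumMatrix,
    after: SpectrumMatrix,
    band: Tuple[int, int],
) -> float:
    """Fraction of excess single-locus k-mer copies removed by purging.

    D(S) = sum over band rows r and columns c >= 2 of S[r][c] * (c - 1),
    the excess assembly copies of k-mers whose read multiplicity marks
    them as single-locus.  Returns 1 - D(after) / D(before).
    """
    if before.k != after.k:
        raise ValueError("spectra use different k")
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"invalid band [{lo}, {hi})")

    def _excess(s: SpectrumMatrix) -> int:
        rows = s.matrix[lo : min(hi, s.r_max + 1)]
        weights = np.arange(s.c_max + 1) - 1
        weights[weights < 0] = 0
        return int((rows * weights).sum())

    d_before = _excess(before)
    if d_before == 0:
        raise ValueError("no duplication to measure in the 'before' spectrum")
    return 1.0 - _excess(after) / d_before


def write_spectrum(spec: SpectrumMatrix, path) -> None:
    """TSV: header row of assembly copy numbers, one row per read multiplicity."""
    with open(path, "w") as fh:
        fh.write("read_mult\t" + "\t".join(f"copy_{c}" for c in range(spec.c_max + 1)) + "\n")
        for r in range(spec.r_max + 1):
            fh.write(str(r) + "\t" + "\t".join(str(int(x)) for x in spec.matrix[r]) + "\n")


def plot_spectrum(spec: SpectrumMatrix, path, max_copy: int = 4) -> None:
    """Line plot of distinct-k-mer counts by read multiplicity, one line per copy number."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    rs = np.arange(1, spec.r_max + 1)
    for c in range(0, min(max_copy, spec.c_max) + 1):
        ax.plot(rs, spec.matrix[1:, c], label=f"{c}x in assembly")
    ax.set_xlabel(f"k-mer multiplicity in reads (k={spec.k})")
    ax.set_ylabel("distinct k-mers")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
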