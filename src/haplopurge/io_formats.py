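"""On-disk formats used across the toolkit.

Every downstream module consumes only the domain types defined here:
:class:`ContigSeq` for assembly sequence, :class:`PafRecord` for pairwise
alignments (minimap2 PAF, 12 mandatory columns plus optional SAM-style
tags) and :class:`BedInterval` for labeled assembly intervals.  The depth
track is a run-length-encoded TSV of maximal equal-depth runs.  All
coordinates everywhere are 0-based half-open; no reader or writer ever
emits 1-based coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "ContigSeq",
    "PafRecord",
    "BedInterval",
    "read_fasta",
    "write_fasta",
    "read_fastx_seqs",
    "read_paf",
    "write_paf",
    "read_bed",
    "write_bed",
    "read_depth_track",
    "write_depth_track",
]

_DELETE_VALID = b"ACGTN"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ContigSeq:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise FormatError(f"invalid sequence name {self.name!r}")
        if len(self.seq) < 1:
            raise FormatError(f"empty sequence for {self.name!r}")
        # translate() drops valid characters; anything left is an error
        leftover = self.seq.encode("ascii", "replace").translate(None, _DELETE_VALID)
        if leftover:
            raise FormatError(
                f"sequence {self.name!r} contains invalid character "
                f"{chr(leftover[0])!r} (expected A/C/G/T/N, uppercase)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PafRecord:
    """One pairwise alignment in PAF coordinates (0-based half-open)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"invalid strand {self.strand!r}")
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise FormatError(
                f"invalid query span {self.qstart}-{self.qend} (len {self.qlen}) "
                f"for {self.qname}"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise FormatError(
                f"invalid target span {self.tstart}-{self.tend} (len {self.tlen}) "
                f"for {self.tname}"
            )
        if self.nmatch > self.alnlen:
            raise FormatError(f"nmatch {self.nmatch} > alignment length {self.alnlen}")
        if not (0 <= self.mapq <= 255):
            raise FormatError(f"mapq {self.mapq} out of range 0-255")

    def is_primary(self) -> bool:
        """True unless an explicit tp tag marks this record non-primary."""
        tp = self.tags.get("tp")
        if tp is None:
            return True
        return tp.rsplit(":", 1)[-1] == "P"


@dataclass(frozen=True, order=True)
class BedInterval:
    """A labeled half-open interval on an assembly sequence."""

    contig: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: os.PathLike | str) -> List[ContigSeq]:
    """Read a FASTA file into a list of :class:`ContigSeq`.

    Sequences are uppercased; record order is preserved.  Duplicate names
    and empty records raise :class:`FormatError`.
    """
    out: List[ContigSeq] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        out.append(ContigSeq(rec.id, seq))
    return out


def write_fasta(contigs: Iterable[ContigSeq], path: os.PathLike | str, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` characters per line."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width])
                fh.write("\n")


def read_fastx_seqs(path: os.PathLike | str) -> Iterator[str]:
    """Yield uppercase sequences from a FASTA or FASTQ file (by extension)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    for rec in SeqIO.parse(p, fmt):
        yield str(rec.seq).upper()


# ---------------------------------------------------------------------------
# PAF

def _parse_paf_line(line: str, lineno: int) -> PafRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise FormatError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
    try:
        rec = PafRecord(
            qname=cols[0],
            qlen=int(cols[1]),
            qstart=int(cols[2]),
            qend=int(cols[3]),
            strand=cols[4],
            tname=cols[5],
            tlen=int(cols[6]),
            tstart=int(cols[7]),
            tend=int(cols[8]),
            nmatch=int(cols[9]),
            alnlen=int(cols[10]),
            mapq=int(cols[11]),
            tags={t.split(":", 1)[0]: t.split(":", 1)[1] for t in cols[12:] if ":" in t},
        )
    except ValueError as exc:  # includes FormatError
        raise FormatError(f"PAF line {lineno}: {exc}") from exc
    return rec


def read_paf(path: os.PathLike | str) -> List[PafRecord]:
    """Read a PAF file (12 mandatory columns; trailing tags captured)."""
    out: List[PafRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            out.append(_parse_paf_line(line, lineno))
    return out


def write_paf(records: Iterable[PafRecord], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.qname, str(r.qlen), str(r.qstart), str(r.qend), r.strand,
                r.tname, str(r.tlen), str(r.tstart), str(r.tend),
                str(r.nmatch), str(r.alnlen), str(r.mapq),
            ]
            cols.extend(f"{k}:{v}" for k, v in r.tags.items())
            fh.write("\t".join(cols))
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED4

def read_bed(path: os.PathLike | str) -> List[BedInterval]:
    out: List[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise FormatError(f"BED line {lineno}: expected 4 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"BED line {lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"BED line {lineno}: empty or inverted interval {start}-{end}"
                )
            out.append(BedInterval(cols[0], start, end, cols[3]))
    return out


def write_bed(intervals: Iterable[BedInterval], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# Depth track (run-length-encoded per-base depth)

def write_depth_track(profile, path: os.PathLike | str) -> None:
    """Write a depth profile as RLE TSV: ``contig<TAB>start<TAB>end<TAB>depth``.

    Runs are maximal equal-depth stretches, 0-based half-open, contiguous
    and covering each contig exactly.
    """
    import numpy as np

    with open(path, "w") as fh:
        for name, depths in profile.depths.items():
            arr = np.asarray(depths)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{name}\t{s}\t{e}\t{int(arr[s])}\n")


def read_depth_track(path: os.PathLike | str):
    """Read an RLE depth track back into a :class:`~haplopurge.coverage.DepthProfile`.

    Raises :class:`FormatError` on overlapping or non-contiguous runs.
    """
    import numpy as np

    from .coverage import DepthProfile  # deferred: avoids import cycle

    runs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 4:
                raise FormatError(f"depth track line {lineno}: expected 4 columns")
            name = cols[0]
            try:
                s, e, d = int(cols[1]), int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise FormatError(f"depth track line {lineno}: {exc}") from exc
            if s >= e or d < 0:
                raise FormatError(f"depth track line {lineno}: invalid run")
            runs.setdefault(name, []).append((s, e, d))

    depths = {}
    for name, rr in runs.items():
        expect = 0
        for s, e, _ in rr:
            if s != expect:
                raise FormatError(
                    f"depth track for {name}: runs not contiguous at {s} (expected {expect})"
                )
            expect = e
        arr = np.zeros(expect, dtype=np.int32)
        for s, e, d in rr:
            arr[s:e] = d
        depths[name] = arr
    return DepthProfile(depths)
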