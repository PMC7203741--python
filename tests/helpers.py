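"""Independent oracles and random-instance generators for the test suite.

Everything here deliberately avoids the library's own algorithm paths:
oracles are naive per-base loops, exhaustive enumerations or dictionary
joins, so agreement with the package is a real check.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from haplopurge.io_formats import PafRecord
from haplopurge.purge_core import Anchor, ChainParams


# ---------------------------------------------------------------------------
# depth oracle

def naive_depth(records: Sequence[PafRecord], lengths: Dict[str, int], min_mapq: int = 0):
    """Per-base counting loop over every alignment (O(n * L))."""
    depth = {name: [0] * n for name, n in lengths.items()}
    for rec in records:
        tp = rec.tags.get("tp")
        primary = tp is None or tp.endswith("P")
        if not primary or rec.mapq < min_mapq:
            continue
        arr = depth[rec.tname]
        for b in range(rec.tstart, rec.tend):
            arr[b] += 1
    return depth


# ---------------------------------------------------------------------------
# chaining oracle

def _gap(prev: Anchor, nxt: Anchor) -> Tuple[int, int]:
    qgap = nxt.qstart - prev.qend
    if prev.strand == "+":
        tgap = nxt.tstart - prev.tend
    else:
        tgap = prev.tstart - nxt.tend
    return qgap, tgap


def _ok(prev: Anchor, nxt: Anchor, p: ChainParams) -> bool:
    qgap, tgap = _gap(prev, nxt)
    return (-p.max_overlap <= qgap <= p.max_gap) and (-p.max_overlap <= tgap <= p.max_gap)


def best_chain_score_bruteforce(anchors: Sequence[Anchor], params: ChainParams) -> float:
    """Exhaustive DFS over every anchor sequence obeying the transition rules."""
    best = 0.0

    def extend(last: Anchor, score: float) -> None:
        nonlocal best
        best = max(best, score)
        for a in anchors:
            if a is last or a.strand != last.strand:
                continue
            if not _ok(last, a, params):
                continue
            qgap, tgap = _gap(last, a)
            extend(a, score + a.nmatch - (params.gap_open + abs(qgap - tgap) * params.gap_scale))

    for a in anchors:
        extend(a, float(a.nmatch))
    return best


def random_anchor_instance(rng: np.random.Generator, max_anchors: int = 12) -> List[Anchor]:
    """Random anchors between one segment pair.

    A mix of roughly collinear 'trail' anchors (so chains of several
    anchors form) and scattered decoys, on both strands, with occasional
    small overlaps between neighbours.
    """
    n = int(rng.integers(2, max_anchors + 1))
    qlen = tlen = 500_000
    anchors: List[Anchor] = []
    q = int(rng.integers(0, 50_000))
    t = int(rng.integers(0, 50_000))
    strand = "+" if rng.random() < 0.7 else "-"
    for _ in range(n):
        if rng.random() < 0.25:  # scattered decoy
            qs = int(rng.integers(0, qlen - 5000))
            ts = int(rng.integers(0, tlen - 5000))
            span = int(rng.integers(500, 5000))
            tspan = int(rng.integers(500, 5000))
            s = "+" if rng.random() < 0.7 else "-"
            anchors.append(Anchor("segA", "segB", qlen, tlen, qs, qs + span,
                                  ts, ts + tspan, s, int(rng.integers(200, span + 1))))
            continue
        span = int(rng.integers(500, 5000))
        tspan = span + int(rng.integers(-50, 51))
        qs, ts = q, t
        anchors.append(Anchor("segA", "segB", qlen, tlen, qs, qs + span,
                              min(ts, tlen - tspan - 1), min(ts, tlen - tspan - 1) + tspan,
                              strand, int(rng.integers(200, span + 1))))
        q = qs + span + int(rng.integers(-80, 8000))
        t = ts + tspan + int(rng.integers(-80, 8000))
        q = max(0, min(q, qlen - 6000))
        t = max(0, min(t, tlen - 6000))
    # target coordinates for '-' trails should descend; flip them
    if strand == "-":
        flipped = []
        for a in anchors:
            if a.strand == "-":
                flipped.append(Anchor(a.qname, a.tname, a.qlen, a.tlen, a.qstart,
                                      a.qend, tlen - a.tend, tlen - a.tstart, "-", a.nmatch))
            else:
                flipped.append(a)
        anchors = flipped
    return anchors


# ---------------------------------------------------------------------------
# k-mer oracle

_RC = str.maketrans("ACGTN", "TGCAN")


def naive_kmer_counts(seqs: Sequence[str], k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            mer = seq[i : i + k]
            if "N" in mer:
                continue
            canon = min(mer, mer.translate(_RC)[::-1])
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def naive_spectrum(read_counts: Dict[str, int], asm_counts: Dict[str, int],
                   r_max: int, c_max: int) -> np.ndarray:
    mat = np.zeros((r_max + 1, c_max + 1), dtype=np.int64)
    for mer in set(read_counts) | set(asm_counts):
        r = min(read_counts.get(mer, 0), r_max)
        c = min(asm_counts.get(mer, 0), c_max)
        mat[r, c] += 1
    return mat


# ---------------------------------------------------------------------------
# truth-mask metrics for the synthetic closed loop

def base_masks(lengths: Dict[str, int], intervals, labels) -> Dict[str, np.ndarray]:
    masks = {n: np.zeros(l, dtype=bool) for n, l in lengths.items()}
    for iv in intervals:
        if iv.label in labels:
            masks[iv.contig][iv.start : iv.end] = True
    return masks


def recovery_metrics(sim, plan_intervals) -> Dict[str, float]:
    """Sensitivity / false-positive rate / repeat loss of a purge plan."""
    lengths = {c.name: len(c.seq) for c in sim.draft}
    truth_dup = base_masks(lengths, sim.truth.intervals, {"HAPLOTIG", "OVLP"})
    truth_any = base_masks(lengths, sim.truth.intervals, {"HAPLOTIG", "OVLP", "JUNK", "HIGHCOV"})
    truth_rep = base_masks(lengths, sim.truth.intervals, {"HIGHCOV"})
    called = base_masks(lengths, plan_intervals, {"HAPLOTIG", "OVLP", "JUNK", "SHORT"})
    tp = sum(int((called[n] & truth_dup[n]).sum()) for n in lengths)
    dup_total = sum(int(truth_dup[n].sum()) for n in lengths)
    fp = sum(int((called[n] & ~truth_any[n]).sum()) for n in lengths)
    clean_total = sum(int((~truth_any[n]).sum()) for n in lengths)
    rep_lost = sum(int((called[n] & truth_rep[n]).sum()) for n in lengths)
    return {
        "sensitivity": tp / dup_total if dup_total else float("nan"),
        "false_positive_rate": fp / clean_total,
        "repeat_bases_removed": rep_lost,
    }


# ---------------------------------------------------------------------------
# PAF lift onto a purged assembly (for the near-idempotence check)

def kept_fragments(lengths: Dict[str, int], plan_intervals, min_keep: int = 1000):
    """Replicate kept-fragment bookkeeping: contig -> [(new_name, start, end)]."""
    removed: Dict[str, List[Tuple[int, int]]] = {}
    for iv in plan_intervals:
        if iv.label in ("JUNK", "HAPLOTIG", "OVLP"):
            removed.setdefault(iv.contig, []).append((iv.start, iv.end))
    frags: Dict[str, List[Tuple[str, int, int]]] = {}
    for name, length in lengths.items():
        cuts = sorted(removed.get(name, []))
        if not cuts:
            frags[name] = [(name, 0, length)]
            continue
        keep = []
        pos = 0
        for s, e in cuts:
            if s > pos:
                keep.append((pos, s))
            pos = max(pos, e)
        if pos < length:
            keep.append((pos, length))
        keep = [(s, e) for s, e in keep if e - s >= min_keep]
        frags[name] = [(f"{name}_{i}", s, e) for i, (s, e) in enumerate(keep, 1)]
    return frags


def lift_paf(records: Sequence[PafRecord], frags, lift_query: bool = False) -> List[PafRecord]:
    """Re-express PAF records on the kept fragments; boundary-crossers drop."""
    new_len = {}
    for pieces in frags.values():
        for name, s, e in pieces:
            new_len[name] = e - s

    def locate(contig: str, start: int, end: int):
        for name, s, e in frags.get(contig, []):
            if start >= s and end <= e:
                return name, start - s, end - s
        return None

    out = []
    for r in records:
        t = locate(r.tname, r.tstart, r.tend)
        if t is None:
            continue
        tname, ts, te = t
        if lift_query:
            q = locate(r.qname, r.qstart, r.qend)
            if q is None:
                continue
            qname, qs, qe = q
            out.append(PafRecord(qname, new_len[qname], qs, qe, r.strand,
                                 tname, new_len[tname], ts, te, r.nmatch, r.alnlen, r.mapq))
        else:
            out.append(PafRecord(r.qname, r.qlen, r.qstart, r.qend, r.strand,
                                 tname, new_len[tname], ts, te, r.nmatch, r.alnlen, r.mapq))
    return out
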