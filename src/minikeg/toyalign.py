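"""Desk-scale seed–filter–extend engine.

This module makes partitioning quality *measurable* without genome-scale
data or an accelerator.  It mirrors the classic pipeline shape:

1. **Seed** — exact k-mer matches between target and query, both query
   orientations (:func:`find_seeds`).
2. **Filter** — gap-free x-drop extension of seeds into HSPs above a score
   threshold (:func:`ungapped_extend`, :func:`seed_and_filter`), written as
   segment files.
3. **Gapped extension** — banded affine-gap y-drop extension of each HSP's
   anchor, with anchor-crossing suppression (:func:`gapped_extend`): once
   an extension's path passes through the midpoint of a not-yet-processed
   same-strand anchor, that anchor is skipped.

Suppression is exactly the dependency that partitioning can violate: two
anchors on one alignment that land in different partitions are both
extended, yielding straddling (duplicate/extra) output.
:func:`evaluate_strategies` quantifies this per partitioning strategy as a
:class:`StraddleReport`.

Reverse-strand bookkeeping: a ``-`` HSP pairs an ascending target interval
with a descending query interval.  Internally all minus-strand work is done
against the reverse complement of the query ("work coordinates"); public
records and alignments carry forward-strand query coordinates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from . import maf
from ._kernels import OP_ALIGN, OP_QGAP, OP_TGAP, xdrop_ungapped, ydrop_one_sided
from .diagpart import Partition, Strategy, partition_records
from .scoring import ScoreModel, encode, revcomp
from .segio import FORWARD, REVERSE, SegmentRecord

__all__ = [
    "SeedMatch",
    "ToyAlignment",
    "StraddleReport",
    "find_seeds",
    "ungapped_extend",
    "seed_and_filter",
    "gapped_extend",
    "evaluate_strategies",
    "alignment_key",
]


# ---------------------------------------------------------------------------
# seeding


@dataclass(frozen=True, slots=True)
class SeedMatch:
    """An exact k-mer match: target start, forward-strand query start, strand."""

    target_pos: int
    query_pos: int
    strand: str
    length: int


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return dict(index)


def find_seeds(target: str, query: str, k: int) -> list[SeedMatch]:
    """All exact k-mer matches between target and query, both orientations.

    Minus-strand matches are reported with the query start on the forward
    strand (the match pairs ``target[t:t+k]`` with the reverse complement
    of ``query[q:q+k]``).
    """
    if k < 4:
        raise ValueError(f"seed length must be >= 4, got {k}")
    target = target.upper()
    index = _kmer_index(target, k)
    out: list[SeedMatch] = []
    for strand, work in ((FORWARD, query.upper()), (REVERSE, revcomp(query).upper())):
        qlen = len(work)
        for j in range(qlen - k + 1):
            hits = index.get(work[j : j + k])
            if not hits:
                continue
            for ti in hits:
                qpos = j if strand == FORWARD else qlen - k - j
                out.append(SeedMatch(ti, qpos, strand, k))
    return out


# ---------------------------------------------------------------------------
# gap-free (filter) stage


def _sub5(model: ScoreModel) -> np.ndarray:
    """5x5 substitution matrix; code 4 (ambiguous) scores like the worst mismatch."""
    worst = int(model.matrix.min())
    sub = np.full((5, 5), worst, dtype=np.int64)
    sub[:4, :4] = model.matrix
    return sub


def _extend_match(
    enc_t: np.ndarray,
    enc_wq: np.ndarray,
    ti: int,
    wq: int,
    k: int,
    model: ScoreModel,
    sub5: np.ndarray,
) -> tuple[int, int, int]:
    """x-drop extension in work coordinates -> (score, t_lo, t_hi)."""
    score, left, right = xdrop_ungapped(enc_t, enc_wq, ti, wq, k, sub5, model.x_drop)
    return int(score), ti - int(left), ti + k + int(right)


def ungapped_extend(
    target: str,
    query: str,
    match: SeedMatch,
    model: ScoreModel,
    target_name: str = "target",
    query_name: str = "query",
) -> SegmentRecord | None:
    """Extend a seed without gaps into an HSP, or ``None`` below threshold.

    Both directions extend while the running score stays within ``x_drop``
    of that direction's maximum; the reported span is the max-scoring one.
    """
    enc_t = encode(target.upper())
    qlen = len(query)
    if match.strand == FORWARD:
        enc_wq = encode(query.upper())
        wq = match.query_pos
    else:
        enc_wq = encode(revcomp(query).upper())
        wq = qlen - match.query_pos - match.length
    sub5 = _sub5(model)
    score, t_lo, t_hi = _extend_match(enc_t, enc_wq, match.target_pos, wq, match.length, model, sub5)
    if score < model.hsp_threshold:
        return None
    off = match.target_pos - wq  # work-diagonal offset
    wq_lo, wq_hi = t_lo - off, t_hi - off
    if match.strand == FORWARD:
        q_lo, q_hi = wq_lo, wq_hi
    else:
        q_lo, q_hi = qlen - wq_hi, qlen - wq_lo
    return SegmentRecord(target_name, t_lo, t_hi, query_name, q_lo, q_hi, match.strand, score)


def seed_and_filter(
    target: str,
    query: str,
    model: ScoreModel,
    target_name: str = "target",
    query_name: str = "query",
) -> list[SegmentRecord]:
    """Seed + filter pipeline: deduplicated HSPs above the score threshold.

    Seeds falling inside a span already extended on the same work diagonal
    are skipped, so each gap-free stretch is extended once.
    """
    target = target.upper()
    k = model.seed_length
    index = _kmer_index(target, k)
    enc_t = encode(target)
    sub5 = _sub5(model)
    qlen = len(query)
    records: list[SegmentRecord] = []
    seen: set[tuple[int, int, int, int, str]] = set()
    for strand in (FORWARD, REVERSE):
        work = query.upper() if strand == FORWARD else revcomp(query).upper()
        enc_wq = encode(work)
        covered_end: dict[int, int] = {}
        for j in range(len(work) - k + 1):
            hits = index.get(work[j : j + k])
            if not hits:
                continue
            for ti in hits:
                diag = ti - j
                if covered_end.get(diag, -1) > j:
                    continue
                score, t_lo, t_hi = _extend_match(enc_t, enc_wq, ti, j, k, model, sub5)
                covered_end[diag] = t_hi - diag
                if score < model.hsp_threshold:
                    continue
                wq_lo, wq_hi = t_lo - diag, t_hi - diag
                if strand == FORWARD:
                    q_lo, q_hi = wq_lo, wq_hi
                else:
                    q_lo, q_hi = qlen - wq_hi, qlen - wq_lo
                key = (t_lo, t_hi, q_lo, q_hi, strand)
                if key in seen:
                    continue
                seen.add(key)
                records.append(
                    SegmentRecord(target_name, t_lo, t_hi, query_name, q_lo, q_hi, strand, score)
                )
    return records


# ---------------------------------------------------------------------------
# gapped extension


@dataclass(slots=True)
class ToyAlignment:
    """A gapped alignment in forward-strand coordinates.

    ``ops`` is the column list in target order: 0 aligned pair, 1 target
    base against a gap, 2 (work-)query base against a gap.  For ``-``
    strand alignments the ops run along the reverse complement of the
    query; ``work_query_start`` is the alignment start in that frame.
    """

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str
    score: int
    ops: np.ndarray
    query_length: int

    @property
    def work_query_start(self) -> int:
        if self.strand == FORWARD:
            return self.query_start
        return self.query_length - self.query_end

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Aligned pairs as (target positions, forward-query positions) arrays."""
        t_step = (self.ops != OP_QGAP).astype(np.int64)
        q_step = (self.ops != OP_TGAP).astype(np.int64)
        t_pos = self.target_start + np.cumsum(t_step) - t_step
        wq_pos = self.work_query_start + np.cumsum(q_step) - q_step
        aligned = self.ops == OP_ALIGN
        t_idx = t_pos[aligned]
        wq_idx = wq_pos[aligned]
        if self.strand == FORWARD:
            return t_idx, wq_idx
        return t_idx, self.query_length - 1 - wq_idx

    def pairs(self) -> list[tuple[int, int]]:
        """Aligned (target, forward-strand query) position pairs."""
        t_idx, q_idx = self.pair_arrays()
        return list(zip(t_idx.tolist(), q_idx.tolist()))


def score_from_ops(
    enc_t: np.ndarray,
    enc_wq: np.ndarray,
    t_start: int,
    wq_start: int,
    ops: np.ndarray,
    model: ScoreModel,
) -> int:
    """Score an op list under the model: substitutions plus affine gap costs."""
    sub5 = _sub5(model)
    score = 0
    ti, wq = t_start, wq_start
    prev_gap = 0
    for op in ops:
        if op == OP_ALIGN:
            score += int(sub5[enc_t[ti], enc_wq[wq]])
            ti += 1
            wq += 1
            prev_gap = 0
        else:
            if op != prev_gap:
                score -= model.gap_open
            score -= model.gap_extend
            prev_gap = int(op)
            if op == OP_TGAP:
                ti += 1
            else:
                wq += 1
    return score


def _band_cap(model: ScoreModel, m: int) -> int:
    if model.gap_extend <= 0 or model.y_drop >= 10**8:
        return m
    return min(m, 2 * (model.y_drop // model.gap_extend) + 8)


def _extend_anchor(
    enc_t: np.ndarray,
    enc_wq: np.ndarray,
    renc_t: np.ndarray,
    renc_wq: np.ndarray,
    tmid: int,
    wqmid: int,
    model: ScoreModel,
    sub5: np.ndarray,
) -> tuple[int, int, int, int, int, np.ndarray]:
    """Y-drop extension through an anchor (work coordinates).

    The anchor pair is extended independently backward (on reversed
    sequences) and forward; the reported alignment glues the two optimal
    half-paths at the anchor column, so its score is the optimal
    extension score *through* the anchor:
    ``best_backward + best_forward - s(anchor)`` (the anchor substitution
    is counted by both halves).  Both halves use the same fill-order tie
    rules.  Returns ``(score, t_lo, t_hi, wq_lo, wq_hi, ops)``.
    """
    n_t, n_q = enc_t.shape[0], enc_wq.shape[0]
    cap_b = _band_cap(model, wqmid + 1)
    score_b, bi, bj, ops_b = ydrop_one_sided(
        renc_t,
        renc_wq,
        n_t - 1 - tmid,
        n_q - 1 - wqmid,
        sub5,
        model.gap_open,
        model.gap_extend,
        model.y_drop,
        max(1, cap_b),
    )
    cap_f = _band_cap(model, n_q - wqmid)
    score_f, fi, fj, ops_f = ydrop_one_sided(
        enc_t,
        enc_wq,
        tmid,
        wqmid,
        sub5,
        model.gap_open,
        model.gap_extend,
        model.y_drop,
        max(1, cap_f),
    )
    anchor_sub = int(sub5[enc_t[tmid], enc_wq[wqmid]])
    score = int(score_b) + int(score_f) - anchor_sub
    # ops_b runs anchor -> far start in reversed frame; flip it and drop
    # its anchor column, which the forward half contributes
    ops = np.concatenate([ops_b[::-1][:-1], ops_f])
    return score, tmid - bi, tmid + fi + 1, wqmid - bj, wqmid + fj + 1, ops


def gapped_extend(
    target: str,
    query: str,
    segment_records: Sequence[SegmentRecord],
    model: ScoreModel,
    suppress: bool = True,
) -> list[ToyAlignment]:
    """Gapped y-drop extension of HSP anchors with crossing suppression.

    Records are processed in input (file) order; each is anchored at its
    interval midpoints.  After an extension, any later same-strand record
    whose anchor midpoint lies on an aligned pair of an already-produced
    alignment is covered and is not extended.  This is the in-file
    dependency that breaks when such records end up in different partition
    files — each partition re-extends its own copy of the alignment.
    """
    target = target.upper()
    query = query.upper()
    enc_t = encode(target)
    qlen = len(query)
    work = {FORWARD: encode(query), REVERSE: encode(revcomp(query))}
    renc_t = enc_t[::-1].copy()
    rwork = {s: w[::-1].copy() for s, w in work.items()}
    sub5 = _sub5(model)
    # covered anchor points, packed as t * qlen + q per strand
    covered: dict[str, set[int]] = {FORWARD: set(), REVERSE: set()}
    out: list[ToyAlignment] = []
    for idx, rec in enumerate(segment_records):
        # Anchor at the HSP midpoint: the target-interval midpoint and its
        # paired query position along the HSP's own (gap-free) diagonal.
        tmid = rec.target_mid
        offset = tmid - rec.target_start
        if rec.strand == FORWARD:
            qmid = rec.query_start + offset
        else:
            qmid = rec.query_end - 1 - offset
        if not (0 <= tmid < len(target) and 0 <= qmid < qlen):
            raise ValueError(
                f"record {idx}: anchor ({tmid}, {qmid}) outside sequence bounds"
            )
        if suppress and tmid * qlen + qmid in covered[rec.strand]:
            continue
        wqmid = qmid if rec.strand == FORWARD else qlen - 1 - qmid
        score, t_lo, t_hi, wq_lo, wq_hi, ops = _extend_anchor(
            enc_t, work[rec.strand], renc_t, rwork[rec.strand], tmid, wqmid, model, sub5
        )
        if rec.strand == FORWARD:
            q_lo, q_hi = wq_lo, wq_hi
        else:
            q_lo, q_hi = qlen - wq_hi, qlen - wq_lo
        aln = ToyAlignment(t_lo, t_hi, q_lo, q_hi, rec.strand, score, ops, qlen)
        out.append(aln)
        if suppress and idx + 1 < len(segment_records):
            t_idx, q_idx = aln.pair_arrays()
            covered[rec.strand].update((t_idx * qlen + q_idx).tolist())
    return out


def alignment_key(aln: ToyAlignment) -> tuple:
    """Hashable identity of an alignment (coordinates, strand, score, path)."""
    return (
        aln.strand,
        aln.target_start,
        aln.target_end,
        aln.query_start,
        aln.query_end,
        aln.score,
        aln.ops.tobytes(),
    )


# ---------------------------------------------------------------------------
# strategy evaluation


@dataclass(slots=True)
class StraddleReport:
    """Straddling-alignment bookkeeping for one partitioned run.

    ``duplicated_columns`` counts target positions covered by same-strand
    alignments from at least two different partitions of the same chunk;
    ``overlapping_pairs`` counts such alignment pairs with overlapping
    target intervals.  Both are zero for an unpartitioned run.
    """

    total_alignments: int = 0
    duplicated_columns: int = 0
    overlapping_pairs: int = 0
    output_bytes: int = 0
    num_partitions: int = 0
    alignments: list = field(default_factory=list, repr=False)


def _chunk_records(
    records: Sequence[SegmentRecord], chunk_size: int
) -> dict[tuple[int, int], list[SegmentRecord]]:
    chunks: dict[tuple[int, int], list[SegmentRecord]] = defaultdict(list)
    for rec in records:
        chunks[(rec.target_mid // chunk_size, rec.query_mid // chunk_size)].append(rec)
    return dict(chunks)


def _merged_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _duplicated_columns(groups: Mapping[tuple, list[tuple[int, int]]]) -> int:
    """Target columns covered by >= 2 partition-level coverages, per group."""
    total = 0
    for per_partition in groups.values():
        events: list[tuple[int, int]] = []
        for intervals in per_partition:
            for lo, hi in _merged_intervals(intervals):
                events.append((lo, 1))
                events.append((hi, -1))
        events.sort()
        depth = 0
        prev = 0
        for pos, delta in events:
            if depth >= 2:
                total += pos - prev
            depth += delta
            prev = pos
    return total


def evaluate_strategies(
    target: str,
    query: str,
    model: ScoreModel,
    chunk_size: int,
    max_size: int,
    strategies: Sequence[Strategy] = ("none", "row", "diagonal"),
    target_name: str = "target",
    query_name: str = "query",
    records: Sequence[SegmentRecord] | None = None,
) -> dict[str, StraddleReport]:
    """Compare partitioning strategies end to end on one sequence pair.

    HSPs from seed-and-filter are grouped into ``chunk_size`` x
    ``chunk_size`` dot-plot tiles (each tile's HSPs form one segment
    file).  Per strategy, each tile's records are split at ``max_size``
    and every partition is gap-extended independently; straddle statistics
    are counted within tiles, between partitions.
    """
    if records is None:
        records = seed_and_filter(target, query, model, target_name, query_name)
    chunks = _chunk_records(records, chunk_size)
    reports: dict[str, StraddleReport] = {}
    for strategy in strategies:
        labeled: list[tuple[tuple[int, int], int, ToyAlignment]] = []
        n_parts = 0
        for key in sorted(chunks):
            parts = partition_records(
                chunks[key], None if strategy == "none" else max_size, strategy
            )
            n_parts += len(parts)
            for part in parts:
                for aln in gapped_extend(target, query, part.records, model):
                    labeled.append((key, part.index, aln))
        groups: dict[tuple, dict[int, list[tuple[int, int]]]] = defaultdict(
            lambda: defaultdict(list)
        )
        for key, part_idx, aln in labeled:
            groups[(key, aln.strand)][part_idx].append((aln.target_start, aln.target_end))
        coverage = {
            g: list(parts.values()) for g, parts in groups.items() if len(parts) > 1
        }
        overlapping = 0
        for g, parts in groups.items():
            flat = [
                (iv, pi) for pi, ivs in parts.items() for iv in ivs
            ]
            for a in range(len(flat)):
                for b in range(a + 1, len(flat)):
                    (lo1, hi1), p1 = flat[a]
                    (lo2, hi2), p2 = flat[b]
                    if p1 != p2 and lo1 < hi2 and lo2 < hi1:
                        overlapping += 1
        alignments = [aln for _, _, aln in labeled]
        text = maf.render_maf(alignments, target_name, query_name, target, query)
        reports[strategy] = StraddleReport(
            total_alignments=len(alignments),
            duplicated_columns=_duplicated_columns(coverage),
            overlapping_pairs=overlapping,
            output_bytes=len(text.encode("utf-8")),
            num_partitions=n_parts,
            alignments=alignments,
        )
    return reports
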