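"""Diagonal partitioning of HSP segment files.

Gapped extension runs along dot-plot diagonals: a forward-strand alignment
keeps ``target - query`` roughly constant, a reverse-strand alignment keeps
``target + query`` roughly constant, with small horizontal/vertical
excursions at gaps.  Anchors that belong to the same eventual alignment
therefore cluster on nearby diagonals — and an extension that crosses a
later anchor suppresses it, so those anchors are *dependent* and must stay
in the same gapped-extension job.  Splitting an oversized segment file into
contiguous diagonal bands bounds the per-job workload (taming tail latency)
while keeping dependent anchors together, which is what naive row-wise
splitting gets wrong: row cuts sever alignments mid-extension and every
severed anchor is re-extended in another job, producing straddling
(duplicate and extra) alignments.

Each HSP is reduced to a single anchor point — the midpoint of both of its
intervals — so partitioning needs no knowledge of the scoring model.  The
maximum partition size can be fixed, or chosen adaptively as the upper
quartile of the sizes of segment files seen so far.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .segio import (
    FORWARD,
    REVERSE,
    PathLike,
    SegmentRecord,
    read_segments,
    stat_segment_file,
    write_segments,
)

__all__ = [
    "Anchor",
    "Partition",
    "SizePolicy",
    "SplitResult",
    "anchor_of",
    "diagonal_key",
    "partition_by_diagonal",
    "partition_rowwise",
    "partition_none",
    "partition_records",
    "adaptive_max_size",
    "split_segment_file",
    "Strategy",
]

Strategy = Literal["diagonal", "row", "none"]
STRATEGIES: tuple[str, ...] = ("diagonal", "row", "none")


@dataclass(frozen=True, slots=True)
class Anchor:
    """The single point on an HSP where gapped extension starts.

    The true extension start used by lastZ is the position along the HSP
    the optimal alignment most likely passes through; computing it needs
    the scoring model, so for partitioning it is approximated by the
    interval midpoints.  ``diag_key`` is the anchor's dot-plot diagonal:
    ``target_mid - query_mid`` on '+' (constant along a forward extension),
    ``target_mid + query_mid`` on '-' (constant along a reverse one).
    """

    record: SegmentRecord
    target_mid: int
    query_mid: int
    strand: str
    diag_key: int


def diagonal_key(target_mid: int, query_mid: int, strand: str) -> int:
    """Strand-dependent dot-plot diagonal through ``(target_mid, query_mid)``."""
    if strand == FORWARD:
        return target_mid - query_mid
    return target_mid + query_mid


def anchor_of(record: SegmentRecord) -> Anchor:
    """Anchor an HSP at the floor-midpoint of both of its intervals."""
    tmid = record.target_mid
    qmid = record.query_mid
    return Anchor(record, tmid, qmid, record.strand, diagonal_key(tmid, qmid, record.strand))


@dataclass(slots=True)
class Partition:
    """A contiguous diagonal (or row) band of same-strand records.

    ``diag_min``/``diag_max`` are the extreme anchor diagonals of the
    members; within one partitioning plan, same-strand partitions cover
    non-interleaving diagonal ranges.
    """

    index: int
    strand: str
    records: list[SegmentRecord]
    diag_min: int
    diag_max: int

    def __len__(self) -> int:
        return len(self.records)


def _cut_sorted(
    anchors: list[tuple[Anchor, int]], strand: str, max_size: int, start_index: int
) -> list[Partition]:
    parts: list[Partition] = []
    for offset in range(0, len(anchors), max_size):
        chunk = anchors[offset : offset + max_size]
        keys = [a.diag_key for a, _ in chunk]
        # membership comes from the sorted cut; within the partition the
        # records keep input (file) order, the order extension processes
        members = [a.record for a, _ in sorted(chunk, key=lambda pair: pair[1])]
        parts.append(
            Partition(
                index=start_index + len(parts),
                strand=strand,
                records=members,
                diag_min=min(keys),
                diag_max=max(keys),
            )
        )
    return parts


def _partition_sorted(
    records: Sequence[SegmentRecord],
    max_size: int,
    sort_key,
) -> list[Partition]:
    if max_size < 1:
        raise ValueError(f"max_size must be >= 1, got {max_size}")
    by_strand: dict[str, list[tuple[Anchor, int]]] = {FORWARD: [], REVERSE: []}
    for idx, rec in enumerate(records):
        by_strand[rec.strand].append((anchor_of(rec), idx))
    parts: list[Partition] = []
    for strand in (FORWARD, REVERSE):
        anchors = by_strand[strand]
        if not anchors:
            continue
        # input index as the final tie-break keeps the cut deterministic
        anchors.sort(key=lambda pair: (*sort_key(pair[0]), pair[1]))
        parts.extend(_cut_sorted(anchors, strand, max_size, len(parts)))
    return parts


def partition_by_diagonal(records: Sequence[SegmentRecord], max_size: int) -> list[Partition]:
    """Split records into contiguous diagonal bands of at most ``max_size``.

    Records are separated by strand; within a strand, anchors are ordered
    by (diag_key, target_mid, query_mid, input order) and cut greedily
    every ``max_size`` anchors.  Anchors sharing one overfull diagonal are
    split at the size boundary: the size cap is hard, at the cost of rare
    residual straddling where many anchors crowd together.
    """
    return _partition_sorted(
        records, max_size, lambda a: (a.diag_key, a.target_mid, a.query_mid)
    )


def partition_rowwise(records: Sequence[SegmentRecord], max_size: int) -> list[Partition]:
    """Baseline splitter: same greedy cut but ordered by (target_mid, query_mid).

    Cuts run perpendicular to the extension direction, so this is the
    straddling-prone scheme diagonal partitioning is compared against.
    """
    return _partition_sorted(records, max_size, lambda a: (a.target_mid, a.query_mid))


def partition_none(records: Sequence[SegmentRecord]) -> list[Partition]:
    """Wrap all records (both strands together) in a single partition."""
    if not records:
        return []
    keys = [anchor_of(r).diag_key for r in records]
    strands = {r.strand for r in records}
    strand = strands.pop() if len(strands) == 1 else FORWARD
    return [Partition(0, strand, list(records), min(keys), max(keys))]


def partition_records(
    records: Sequence[SegmentRecord], max_size: int | None, strategy: Strategy
) -> list[Partition]:
    """Dispatch to the named strategy; ``max_size=None`` means unbounded."""
    if strategy == "none" or max_size is None or max_size >= len(records):
        if strategy == "diagonal":
            return partition_by_diagonal(records, max(1, len(records)))
        if strategy == "row":
            return partition_rowwise(records, max(1, len(records)))
        return partition_none(records)
    if strategy == "diagonal":
        return partition_by_diagonal(records, max_size)
    if strategy == "row":
        return partition_rowwise(records, max_size)
    raise ValueError(f"unknown strategy {strategy!r}")


@dataclass(slots=True)
class SizePolicy:
    """How the maximum segment-file size is chosen.

    In ``adaptive`` mode the cap is the nearest-rank upper quartile
    (order statistic ``ceil(0.75 n)``) of the pre-split sizes of segment
    files seen so far, falling back to ``default_max`` while the history
    is empty.  The history is process-local state standing in for the
    shared folder of already-written segment files that an aligner run
    scans implicitly.
    """

    mode: Literal["fixed", "adaptive"] = "adaptive"
    fixed_max: int = 15000
    default_max: int = 15000
    history: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fixed_max < 1:
            raise ValueError("fixed_max must be positive")
        if self.default_max < 1:
            raise ValueError("default_max must be positive")

    def observe(self, size: int) -> None:
        """Record the pre-split size of one more segment file."""
        self.history.append(size)


def adaptive_max_size(policy: SizePolicy) -> int:
    """Current maximum partition size under ``policy``.

    Nearest-rank 75th percentile: with history sorted ascending, the value
    at rank ``ceil(0.75 n)`` (1-based).
    """
    if policy.mode == "fixed":
        return policy.fixed_max
    if not policy.history:
        return policy.default_max
    ordered = sorted(policy.history)
    rank = math.ceil(0.75 * len(ordered))
    return ordered[rank - 1]


@dataclass(slots=True)
class SplitResult:
    """Output of :func:`split_segment_file`: the emitted files and their plan."""

    paths: list[Path]
    partitions: list[Partition]
    max_size_used: int
    estimated_lines: int


def split_segment_file(
    path: PathLike,
    policy: SizePolicy,
    output_dir: PathLike,
    strategy: Strategy = "diagonal",
) -> SplitResult:
    """Split one segment file into partition files if it is oversized.

    The decision to split uses the byte-size line-count estimate, not a
    full read.  Files at or under the current cap (and any file under
    ``strategy='none'``) pass through as a single partition file.  The
    file's pre-split estimated size is appended to the policy history
    either way.  Partition files are named
    ``<stem>.part<k>.<strand>.segments``.
    """
    path = Path(path)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    stats = stat_segment_file(path)
    max_size = adaptive_max_size(policy)
    policy.observe(stats.estimated_lines)

    records = read_segments(path)
    if strategy == "none" or stats.estimated_lines <= max_size:
        parts = partition_none(records)
    else:
        parts = partition_records(records, max_size, strategy)

    stem = path.stem
    paths: list[Path] = []
    for part in parts:
        out = output_dir / f"{stem}.part{part.index}.{'plus' if part.strand == FORWARD else 'minus'}.segments"
        write_segments(part.records, out)
        paths.append(out)
    return SplitResult(paths, parts, max_size, stats.estimated_lines)


def write_plan_manifest(partitions_and_paths: Iterable[tuple[Partition, Path]], path: PathLike) -> Path:
    """Write a plan manifest TSV (file, strand, size, diag_min, diag_max)."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("file\tstrand\tsize\tdiag_min\tdiag_max\n")
        for part, ppath in partitions_and_paths:
            fh.write(
                f"{ppath.name}\t{part.strand}\t{len(part)}\t{part.diag_min}\t{part.diag_max}\n"
            )
    return path
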