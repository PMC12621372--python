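"""Reading and writing lastZ-style segment files.

A segment file lists high-scoring ungapped alignment pairs (HSPs), one per
line::

    target_name  target_start  target_end  query_name  query_start  query_end  strand  score

On disk the coordinate intervals are 1-based and closed (the lastZ
convention).  Internally every :class:`SegmentRecord` holds 0-based
half-open intervals; the conversion happens here, at the I/O boundary, and
nowhere else.  ``#`` comment lines are skipped on read; fields may be
separated by any run of tabs or spaces, and single tabs are emitted on
write.  The ``score`` column is optional on read (defaulting to 0) and is
always written.

The module also implements the byte-size line-count estimate used to decide
whether a segment file needs partitioning without reading it through: the
file size divided by the size of one sampled line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

__all__ = [
    "SegmentRecord",
    "SegmentFileStats",
    "SegmentParseError",
    "read_segments",
    "write_segments",
    "estimate_line_count",
    "stat_segment_file",
]

PathLike = Union[str, os.PathLike]

FORWARD = "+"
REVERSE = "-"
_STRANDS = frozenset((FORWARD, REVERSE))


class SegmentParseError(ValueError):
    """A malformed line in a segment file, reported with its line number."""


@dataclass(frozen=True, slots=True)
class SegmentRecord:
    """One HSP: paired target/query intervals, strand and score.

    Intervals are 0-based half-open.  On the ``-`` strand the query
    interval is given in forward-strand coordinates; the target runs
    ascending while the query runs descending.
    """

    target_name: str
    target_start: int
    target_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str = FORWARD
    score: int = 0

    def __post_init__(self) -> None:
        if self.target_start > self.target_end:
            raise ValueError(
                f"target interval reversed: [{self.target_start}, {self.target_end})"
            )
        if self.query_start > self.query_end:
            raise ValueError(
                f"query interval reversed: [{self.query_start}, {self.query_end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    @property
    def target_mid(self) -> int:
        """Midpoint of the target interval (floor)."""
        return (self.target_start + self.target_end) // 2

    @property
    def query_mid(self) -> int:
        """Midpoint of the query interval (floor)."""
        return (self.query_start + self.query_end) // 2


@dataclass(frozen=True, slots=True)
class SegmentFileStats:
    """Byte-level statistics used to estimate a segment file's line count."""

    path: Path
    byte_size: int
    sample_line_bytes: int
    estimated_lines: int


def _parse_line(line: str, lineno: int) -> SegmentRecord:
    fields = line.split()
    if len(fields) < 7:
        raise SegmentParseError(
            f"line {lineno}: expected >= 7 fields, got {len(fields)}"
        )
    tname, ts, te, qname, qs, qe, strand = fields[:7]
    try:
        ts_i, te_i, qs_i, qe_i = int(ts), int(te), int(qs), int(qe)
    except ValueError as exc:
        raise SegmentParseError(f"line {lineno}: non-numeric coordinate: {exc}") from None
    if strand not in _STRANDS:
        raise SegmentParseError(f"line {lineno}: bad strand {strand!r}")
    score = 0
    if len(fields) >= 8:
        try:
            score = int(fields[7])
        except ValueError:
            raise SegmentParseError(f"line {lineno}: non-numeric score {fields[7]!r}") from None
    try:
        # 1-based closed on disk -> 0-based half-open in memory.
        return SegmentRecord(tname, ts_i - 1, te_i, qname, qs_i - 1, qe_i, strand, score)
    except ValueError as exc:
        raise SegmentParseError(f"line {lineno}: {exc}") from None


def read_segments(path: PathLike) -> list[SegmentRecord]:
    """Read a segment file into a list of records, in file order."""
    records: list[SegmentRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            records.append(_parse_line(stripped, lineno))
    return records


def iter_segments(path: PathLike) -> Iterator[SegmentRecord]:
    """Lazily iterate over the records of a segment file."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield _parse_line(stripped, lineno)


def format_segment(record: SegmentRecord) -> str:
    """Render one record as an on-disk line (1-based closed coordinates)."""
    return "\t".join(
        (
            record.target_name,
            str(record.target_start + 1),
            str(record.target_end),
            record.query_name,
            str(record.query_start + 1),
            str(record.query_end),
            record.strand,
            str(record.score),
        )
    )


def write_segments(records: Iterable[SegmentRecord], path: PathLike) -> Path:
    """Write records to ``path`` in the segment-file dialect; returns the path."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for record in records:
            fh.write(format_segment(record))
            fh.write("\n")
    return path


def estimate_line_count(byte_size: int, sample_line_bytes: int) -> int:
    """Estimate a file's line count as ``floor(byte_size / sample_line_bytes)``.

    This is how an oversized segment file is recognised without reading it:
    the estimate is exact for fixed-width rows and within the relative
    row-width spread otherwise.
    """
    if sample_line_bytes <= 0:
        raise ValueError(f"sample_line_bytes must be positive, got {sample_line_bytes}")
    if byte_size < 0:
        raise ValueError(f"byte_size must be non-negative, got {byte_size}")
    return byte_size // sample_line_bytes


def stat_segment_file(path: PathLike) -> SegmentFileStats:
    """Stat ``path`` and estimate its line count from the first data line.

    The sampled line is the first non-comment line, including its newline
    byte.  An empty (or all-comment) file yields zero estimated lines.
    """
    path = Path(path)
    byte_size = path.stat().st_size
    sample = 0
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            sample = len(line.encode("utf-8"))
            break
    estimated = estimate_line_count(byte_size, sample) if sample > 0 else 0
    return SegmentFileStats(path, byte_size, sample, estimated)
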