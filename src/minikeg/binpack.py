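"""Chromosome-to-bin assignment with longest-processing-time-first (LPT).

Running one aligner instance per pair of whole genomes leaves accelerator
and CPU capacity idle; running one per chromosome pair creates wildly
uneven work.  The middle ground is to pack chromosomes into similarly
sized bins of roughly a target capacity (~200 Mbp by default) and run one
instance per bin pair.  Chromosomes are never split across bins — splitting
a sequence would create straddling alignments at the cut and force
coordinate fix-ups afterwards.

LPT is the classic greedy multiprocessor-scheduling rule: sort items by
decreasing length and always place the next one in the currently lightest
bin.  Its makespan is within a factor ``4/3 - 1/(3m)`` of optimal for
``m`` bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .segio import PathLike

__all__ = [
    "SeqMeta",
    "Bin",
    "lpt_pack",
    "pack_to_capacity",
    "make_bin_pairs",
    "read_seq_lengths",
    "write_bin_manifest",
    "DEFAULT_BIN_CAPACITY",
]

#: Default bin capacity in base pairs (about one large mammalian chromosome).
DEFAULT_BIN_CAPACITY = 200_000_000


@dataclass(frozen=True, slots=True)
class SeqMeta:
    """A named sequence and its length in base pairs."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"sequence {self.name!r} has non-positive length {self.length}")


@dataclass(slots=True)
class Bin:
    """One bin of whole sequences; ``load`` is the summed length."""

    index: int
    members: list[SeqMeta] = field(default_factory=list)
    load: int = 0

    def add(self, item: SeqMeta) -> None:
        self.members.append(item)
        self.load += item.length


def lpt_pack(items: Sequence[SeqMeta], num_bins: int) -> list[Bin]:
    """Pack items into ``num_bins`` bins by the LPT rule.

    Items are taken in decreasing length (ties by name, for a
    deterministic, input-order-independent result) and each goes to the
    least-loaded bin, lowest index winning ties.
    """
    if num_bins < 1:
        raise ValueError(f"num_bins must be >= 1, got {num_bins}")
    if not items:
        raise ValueError("cannot pack an empty item collection")
    bins = [Bin(i) for i in range(num_bins)]
    for item in sorted(items, key=lambda s: (-s.length, s.name)):
        target = min(bins, key=lambda b: (b.load, b.index))
        target.add(item)
    return bins


def pack_to_capacity(items: Sequence[SeqMeta], target_bin_size: int = DEFAULT_BIN_CAPACITY) -> list[Bin]:
    """Derive a bin count from a capacity, then LPT-balance.

    ``num_bins = max(1, ceil(total / target_bin_size))``.  A single
    sequence longer than the capacity still occupies one bin whole.
    """
    if target_bin_size <= 0:
        raise ValueError(f"target_bin_size must be positive, got {target_bin_size}")
    total = sum(item.length for item in items)
    num_bins = max(1, -(-total // target_bin_size))
    return lpt_pack(items, num_bins)


def make_bin_pairs(target_bins: Sequence[Bin], query_bins: Sequence[Bin]) -> list[tuple[Bin, Bin]]:
    """Cross product of target and query bins, ordered by (target, query) index.

    Each pair is one independent aligner work unit.
    """
    if not target_bins or not query_bins:
        raise ValueError("both bin collections must be non-empty")
    return [(t, q) for t in target_bins for q in query_bins]


def read_seq_lengths(path: PathLike) -> list[SeqMeta]:
    """Read sequence lengths from a FASTA file or a 2-column name/length TSV."""
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.read(1)
    if first == ">":
        return [SeqMeta(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    metas: list[SeqMeta] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name and length")
            metas.append(SeqMeta(fields[0], int(fields[1])))
    return metas


def write_bin_manifest(bins: Iterable[Bin], path: PathLike) -> Path:
    """Write a TSV of (bin index, load, member, member length)."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("bin\tload\tsequence\tlength\n")
        for b in bins:
            for m in b.members:
                fh.write(f"{b.index}\t{b.load}\t{m.name}\t{m.length}\n")
    return path
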