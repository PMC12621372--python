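"""Simulation of diverged sequence pairs.

A target core of random DNA is copied into a query core through a simple
i.i.d. mutation process: substitutions at a chosen divergence rate and
short indels (1-5 bp, insertions and deletions equally likely) at a
per-base indel rate.  Unrelated random flanks are appended to both ends of
both sequences so that alignments have somewhere to stop.  The generator
covers the divergence range (0-40%) over which seed-and-extend aligners
are typically exercised; the defaults (1% indels, 1 kb flanks) represent a
routine mammalian-style simulation setting.

The returned truth records where the homologous cores sit in each
sequence, so downstream checks can ask whether an alignment stayed inside
the homology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scoring import decode
from .segio import PathLike

__all__ = ["SimSpec", "SimResult", "simulate_pair", "write_fasta", "write_truth_bed"]


@dataclass(frozen=True, slots=True)
class SimSpec:
    """Parameters of one simulated target/query pair."""

    core_length: int = 100_000
    divergence: float = 0.02
    indel_rate: float = 0.01
    indel_len_range: tuple[int, int] = (1, 5)
    flank_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_length < 1:
            raise ValueError("core_length must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be non-negative")
        lo, hi = self.indel_len_range
        if not 1 <= lo <= hi:
            raise ValueError("indel_len_range must satisfy 1 <= lo <= hi")
        if self.flank_length < 0:
            raise ValueError("flank_length must be non-negative")


@dataclass(frozen=True, slots=True)
class SimResult:
    """A simulated pair plus the true homologous interval in each sequence."""

    target: str
    query: str
    target_core: tuple[int, int]
    query_core: tuple[int, int]
    spec: SimSpec


def _mutate_core(core: np.ndarray, spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    n = core.size
    # Substitutions: replace with one of the three other bases.
    mutated = core.copy()
    sub_mask = rng.random(n) < spec.divergence
    shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
    mutated[sub_mask] = (mutated[sub_mask] + shifts) % 4
    if spec.indel_rate <= 0:
        return mutated
    # Indels: at each position, with probability indel_rate, either delete
    # the next 1-5 bases or insert 1-5 random bases before this one.
    indel_mask = rng.random(n) < spec.indel_rate
    lo, hi = spec.indel_len_range
    pieces: list[np.ndarray] = []
    cursor = 0
    for pos in np.flatnonzero(indel_mask):
        if pos < cursor:
            continue  # swallowed by a previous deletion
        length = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.5:
            pieces.append(mutated[cursor:pos])
            cursor = pos + length  # deletion
        else:
            pieces.append(mutated[cursor:pos])
            pieces.append(rng.integers(0, 4, size=length).astype(np.uint8))
            cursor = pos
    pieces.append(mutated[cursor:])
    return np.concatenate(pieces)


def simulate_pair(spec: SimSpec) -> SimResult:
    """Generate one (target, query) pair with known homologous cores.

    A fixed seed reproduces the pair exactly.
    """
    rng = np.random.default_rng(spec.seed)
    core = rng.integers(0, 4, size=spec.core_length).astype(np.uint8)
    query_core = _mutate_core(core, spec, rng)
    f = spec.flank_length
    flanks = [rng.integers(0, 4, size=f).astype(np.uint8) for _ in range(4)]
    target = np.concatenate([flanks[0], core, flanks[1]])
    query = np.concatenate([flanks[2], query_core, flanks[3]])
    return SimResult(
        target=decode(target),
        query=decode(query),
        target_core=(f, f + core.size),
        query_core=(f, f + query_core.size),
        spec=spec,
    )


def write_fasta(path: PathLike, name: str, seq: str, width: int = 80) -> Path:
    """Write one sequence to a FASTA file."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width])
            fh.write("\n")
    return path


def write_truth_bed(path: PathLike, result: SimResult, target_name: str, query_name: str) -> Path:
    """Write the true core intervals as a 2-line BED file."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        ts, te = result.target_core
        qs, qe = result.query_core
        fh.write(f"{target_name}\t{ts}\t{te}\tcore\n")
        fh.write(f"{query_name}\t{qs}\t{qe}\tcore\n")
    return path
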