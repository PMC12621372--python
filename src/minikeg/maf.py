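"""Minimal MAF (Multiple Alignment Format) output.

Each alignment becomes an ``a`` line followed by two ``s`` lines (target
then query).  Starts are 0-based and, per the MAF convention, given on the
aligning strand: a ``-`` strand query start counts from the reverse
complement's origin, i.e. ``srcSize - forward_end``.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .segio import PathLike

if TYPE_CHECKING:  # pragma: no cover
    from .toyalign import ToyAlignment

__all__ = ["MAF_HEADER", "render_maf", "write_maf", "concat_maf_texts"]

MAF_HEADER = "##maf version=1 scoring=minikeg\n"

_GAP = ord("-")


def _texts(aln: "ToyAlignment", target: str, query: str) -> tuple[str, str]:
    from ._kernels import OP_ALIGN, OP_QGAP, OP_TGAP

    work_query = query if aln.strand == "+" else None
    if work_query is None:
        from .scoring import revcomp

        work_query = revcomp(query)
    t_arr = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    q_arr = np.frombuffer(work_query.encode("ascii"), dtype=np.uint8)
    t_step = (aln.ops != OP_QGAP).astype(np.int64)
    q_step = (aln.ops != OP_TGAP).astype(np.int64)
    t_pos = aln.target_start + np.cumsum(t_step) - t_step
    q_pos = aln.work_query_start + np.cumsum(q_step) - q_step
    t_text = np.where(t_step.astype(bool), t_arr[t_pos], _GAP).astype(np.uint8)
    q_text = np.where(q_step.astype(bool), q_arr[q_pos], _GAP).astype(np.uint8)
    return t_text.tobytes().decode("ascii"), q_text.tobytes().decode("ascii")


def render_block(
    aln: "ToyAlignment",
    target_name: str,
    query_name: str,
    target: str,
    query: str,
) -> str:
    """Render one alignment as a MAF block (without the file header)."""
    t_text, q_text = _texts(aln, target, query)
    t_size = aln.target_end - aln.target_start
    q_size = aln.query_end - aln.query_start
    q_start_maf = (
        aln.query_start if aln.strand == "+" else len(query) - aln.query_end
    )
    lines = [
        f"a score={aln.score}",
        f"s {target_name} {aln.target_start} {t_size} + {len(target)} {t_text}",
        f"s {query_name} {q_start_maf} {q_size} {aln.strand} {len(query)} {q_text}",
        "",
    ]
    return "\n".join(lines)


def render_maf(
    alignments: Iterable["ToyAlignment"],
    target_name: str,
    query_name: str,
    target: str,
    query: str,
) -> str:
    """Render alignments as a complete MAF document."""
    parts = [MAF_HEADER]
    for aln in alignments:
        parts.append(render_block(aln, target_name, query_name, target, query))
    return "\n".join(parts)


def write_maf(
    alignments: Sequence["ToyAlignment"],
    target_name: str,
    query_name: str,
    target: str,
    query: str,
    path: PathLike,
) -> Path:
    """Write alignments to a MAF file."""
    path = Path(path)
    path.write_text(
        render_maf(alignments, target_name, query_name, target, query), encoding="utf-8"
    )
    return path


def concat_maf_texts(texts: Sequence[str]) -> str:
    """Concatenate MAF documents, keeping only the first header block.

    Comment lines (``#``) of every document after the first are stripped so
    the result remains a single valid MAF file.
    """
    out: list[str] = []
    for idx, text in enumerate(texts):
        if idx == 0:
            out.append(text)
            continue
        kept = [ln for ln in text.splitlines() if not ln.startswith("#")]
        while kept and not kept[0].strip():
            kept.pop(0)
        if kept:
            out.append("\n".join(kept) + ("\n" if text.endswith("\n") else ""))
    return "".join(out)
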