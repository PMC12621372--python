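"""Scoring model for the toy seed–filter–extend engine.

Defaults follow the long-standing conventions of lastZ-style genome
aligners: the HOXD70 substitution matrix (derived for human-mouse distance
non-coding DNA), affine gap penalties of 400 to open and 30 per base to
extend, a 12-mer exact seed, an x-drop of 300 for gap-free extension and a
y-drop of 3000 for gapped extension.  All values are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScoreModel", "HOXD70", "encode", "decode", "revcomp", "revcomp_encoded"]

#: HOXD70 substitution scores, rows/cols ordered A, C, G, T.
HOXD70 = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=np.int32,
)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _base in enumerate(b"ACGT"):
    _ENCODE[_base] = _i
    _ENCODE[_base + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0 C=1 G=2 T=3 (other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_encoded(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on encoded codes (3 - code, N preserved)."""
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


@dataclass(slots=True)
class ScoreModel:
    """Substitution matrix, gap penalties, drop thresholds and seed length.

    ``x_drop`` bounds how far a gap-free extension may fall below its
    running maximum before that direction stops; ``y_drop`` plays the same
    role for gapped extension.  ``hsp_threshold`` is the minimum score for
    a gap-free extension to be reported as an HSP.
    """

    matrix: np.ndarray = field(default_factory=lambda: HOXD70.copy())
    gap_open: int = 400
    gap_extend: int = 30
    x_drop: int = 300
    y_drop: int = 3000
    seed_length: int = 12
    hsp_threshold: int = 3000

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int32)
        if self.matrix.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if (np.diag(self.matrix) <= 0).any():
            raise ValueError("match scores (matrix diagonal) must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")

    def substitution(self, a: str, b: str) -> int:
        """Score for aligning base ``a`` to base ``b``."""
        ea, eb = encode(a)[0], encode(b)[0]
        if ea > 3 or eb > 3:
            return 0
        return int(self.matrix[ea, eb])


def read_score_matrix(path) -> np.ndarray:
    """Read a lastZ-style substitution matrix file.

    Expected layout: an optional header row naming the columns (A C G T)
    followed by four rows of four integers, each optionally prefixed with
    the row base.  Comment lines start with ``#``.
    """
    rows: list[list[int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if all(f.upper() in "ACGT" for f in fields):
                continue  # header row
            if fields[0].upper() in "ACGT":
                fields = fields[1:]
            rows.append([int(f) for f in fields])
    mat = np.array(rows, dtype=np.int32)
    if mat.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {mat.shape}")
    return mat
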