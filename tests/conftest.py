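"""Shared fixtures: deterministic random segment records and small simulated pairs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from minikeg.scoring import ScoreModel
from minikeg.segio import SegmentRecord
from minikeg.sim import SimSpec, simulate_pair

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_records(rng: np.random.Generator, n: int, span: int = 100_000) -> list[SegmentRecord]:
    """Generate n valid segment records with mixed strands."""
    t_start = rng.integers(0, span, n)
    t_len = rng.integers(1, 400, n)
    q_start = rng.integers(0, span, n)
    q_len = rng.integers(1, 400, n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    scores = rng.integers(0, 100_000, n)
    return [
        SegmentRecord(
            "chrT",
            int(t_start[i]),
            int(t_start[i] + t_len[i]),
            "chrQ",
            int(q_start[i]),
            int(q_start[i] + q_len[i]),
            str(strands[i]),
            int(scores[i]),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_pair():
    """A 5 kb simulated pair at 2% divergence with 1% indels."""
    return simulate_pair(SimSpec(core_length=5000, divergence=0.02, indel_rate=0.01,
                                 flank_length=500, seed=11))


@pytest.fixture(scope="session")
def model():
    return ScoreModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
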