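"""Seed finding, x-drop filtering, y-drop extension and suppression.

Oracles used here are deliberately naive: all-pairs k-mer comparison for
seeding, exhaustive span enumeration for gap-free extension, and a full
(unbanded) affine-gap dynamic program for gapped extension.
"""

import numpy as np
import pytest

from minikeg.scoring import ScoreModel, encode, revcomp
from minikeg.segio import SegmentRecord
from minikeg.toyalign import (
    SeedMatch,
    alignment_key,
    evaluate_strategies,
    find_seeds,
    gapped_extend,
    seed_and_filter,
    ungapped_extend,
)

BASES = "ACGT"


def random_dna(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def brute_force_seeds(target, query, k):
    """All-pairs k-mer comparison over both query orientations."""
    out = set()
    rq = revcomp(query)
    for i in range(len(target) - k + 1):
        for j in range(len(query) - k + 1):
            if target[i : i + k] == query[j : j + k]:
                out.add((i, j, "+"))
        for j in range(len(rq) - k + 1):
            if target[i : i + k] == rq[j : j + k]:
                out.add((i, len(query) - k - j, "-"))
    return out


def affine_best_from(t, q, t0, q0, sub, go, ge):
    """Best-scoring affine path starting at aligned pair (t0, q0), full DP."""
    n, m = len(t) - t0, len(q) - q0
    NEG = -(10**9)
    M = np.full((n, m), NEG, dtype=np.int64)
    Ix = np.full((n, m), NEG, dtype=np.int64)
    Iy = np.full((n, m), NEG, dtype=np.int64)
    M[0, 0] = sub[t[t0], q[q0]]
    for j in range(1, m):
        Iy[0, j] = max(M[0, j - 1] - go, Iy[0, j - 1]) - ge
    for i in range(1, n):
        Ix[i, 0] = max(M[i - 1, 0] - go, Ix[i - 1, 0]) - ge
        for j in range(1, m):
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + sub[
                t[i + t0], q[j + q0]
            ]
            Ix[i, j] = max(M[i - 1, j] - go, Ix[i - 1, j]) - ge
            Iy[i, j] = max(M[i, j - 1] - go, Iy[i, j - 1]) - ge
    return int(M.max())


def oracle_anchor_score(target, query, t0, q0, model):
    """Optimal extension score through anchor (t0, q0): backward + forward DP."""
    from minikeg.toyalign import _sub5

    t = encode(target)
    q = encode(query)
    sub = _sub5(model)
    fwd = affine_best_from(t, q, t0, q0, sub, model.gap_open, model.gap_extend)
    bwd = affine_best_from(
        t[::-1].copy(), q[::-1].copy(), len(t) - 1 - t0, len(q) - 1 - q0,
        sub, model.gap_open, model.gap_extend,
    )
    return fwd + bwd - int(sub[t[t0], q[q0]])


def score_alignment_independent(aln, target, query, model):
    """Recompute an alignment's score from its column list, by hand."""
    work = query if aln.strand == "+" else revcomp(query)
    ti, qi = aln.target_start, aln.work_query_start
    score = 0
    prev = 0
    for op in aln.ops:
        if op == 0:
            score += model.substitution(target[ti], work[qi])
            ti += 1
            qi += 1
            prev = 0
        else:
            score -= model.gap_extend + (model.gap_open if op != prev else 0)
            prev = int(op)
            if op == 1:
                ti += 1
            else:
                qi += 1
    return score


# ---------------------------------------------------------------------------


class TestFindSeeds:
    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(5):
            target = random_dna(rng, 60)
            query = random_dna(rng, 50)
            got = {(s.target_pos, s.query_pos, s.strand) for s in find_seeds(target, query, 6)}
            assert got == brute_force_seeds(target, query, 6)

    def test_identical_30mers_give_21_diagonal_matches(self, rng):
        while True:  # a 30-mer with 21 distinct 10-mers and no rc self-match
            s = random_dna(rng, 30)
            kmers = {s[i : i + 10] for i in range(21)}
            rc = {revcomp(s)[i : i + 10] for i in range(21)}
            if len(kmers) == 21 and not (kmers & rc):
                break
        seeds = find_seeds(s, s, 10)
        fwd = [m for m in seeds if m.strand == "+"]
        assert len(fwd) == 21
        assert all(m.target_pos == m.query_pos for m in fwd)

    def test_disjoint_kmer_alphabets_give_nothing(self):
        assert find_seeds("A" * 30, "C" * 30, 8) == []

    def test_reverse_only_seed_found_on_minus_strand(self, rng):
        target = random_dna(rng, 40)
        insert = revcomp(target[10:25])
        query = random_dna(rng, 10) + insert + random_dna(rng, 10)
        got = {(s.target_pos, s.query_pos, s.strand) for s in find_seeds(target, query, 8)}
        oracle = brute_force_seeds(target, query, 8)
        assert got == oracle
        assert any(strand == "-" for _, _, strand in oracle)


class TestUngappedExtend:
    def test_seed_inside_exact_match_spans_it(self, rng, model):
        core = random_dna(rng, 80)
        target = random_dna(rng, 20) + core + random_dna(rng, 20)
        query = random_dna(rng, 35) + core + random_dna(rng, 35)
        m = SeedMatch(20 + 30, 35 + 30, "+", model.seed_length)
        small = ScoreModel(hsp_threshold=100)
        rec = ungapped_extend(target, query, m, small)
        assert rec is not None
        # the exact 80 bp region never drops the score, so it is fully spanned
        assert rec.target_start <= 20 and rec.target_end >= 100
        assert rec.score >= 80 * 91

    def test_all_mismatch_context_leaves_bare_seed(self):
        seed = "ACGTACGTACGT"  # k=12
        target = "C" * 10 + seed + "C" * 10
        query = "G" * 10 + seed + "G" * 10
        rec = ungapped_extend(target, query, SeedMatch(10, 10, "+", 12),
                              ScoreModel(hsp_threshold=0))
        assert (rec.target_start, rec.target_end) == (10, 22)
        assert (rec.query_start, rec.query_end) == (10, 22)

    def test_one_mismatch_region_matches_span_enumeration(self):
        rng = np.random.default_rng(99)
        region = random_dna(rng, 40)
        query = region[:17] + ("A" if region[17] != "A" else "C") + region[18:]
        unit = ScoreModel(
            matrix=np.where(np.eye(4, dtype=bool), 1, -1).astype(np.int32),
            x_drop=5, hsp_threshold=0, seed_length=8,
        )
        rec = ungapped_extend(region, query, SeedMatch(4, 4, "+", 8), unit)
        # exhaustive enumeration of all diagonal spans containing the seed
        best = max(
            sum(1 if region[p] == query[p] else -1 for p in range(lo, hi))
            for lo in range(0, 5)
            for hi in range(12, 41)
        )
        assert best == 38
        assert rec.score == best

    def test_below_threshold_returns_none(self):
        seed = "ACGTACGTACGT"
        target = "C" * 10 + seed + "C" * 10
        query = "G" * 10 + seed + "G" * 10
        assert ungapped_extend(target, query, SeedMatch(10, 10, "+", 12),
                               ScoreModel(hsp_threshold=3000)) is None

    def test_minus_strand_coordinates_on_forward_query(self, rng, model):
        core = random_dna(rng, 60)
        target = random_dna(rng, 15) + core + random_dna(rng, 15)
        query = random_dna(rng, 25) + revcomp(core) + random_dna(rng, 25)
        recs = seed_and_filter(target, query, ScoreModel(hsp_threshold=1000))
        minus = [r for r in recs if r.strand == "-"]
        assert minus
        r = minus[0]
        assert revcomp(query[r.query_start : r.query_end]) == target[r.target_start : r.target_end]


class TestGappedExtend:
    def test_single_anchor_matches_full_dp_oracle(self, rng):
        model = ScoreModel(y_drop=10**9)
        for _ in range(10):
            n = int(rng.integers(50, 150))
            t = random_dna(rng, n)
            q_arr = encode(t).copy()
            mask = rng.random(n) < 0.08
            q_arr[mask] = (q_arr[mask] + rng.integers(1, 4, mask.sum())) % 4
            q = "".join(BASES[c] for c in q_arr)
            t0 = q0 = n // 2
            rec = SegmentRecord("t", t0, t0 + 1, "q", q0, q0 + 1, "+", 0)
            (aln,) = gapped_extend(t, q, [rec], model)
            assert aln.score == oracle_anchor_score(t, q, t0, q0, model)

    def test_score_stored_equals_independent_recomputation(self, small_pair, model):
        recs = seed_and_filter(small_pair.target, small_pair.query, model)
        alns = gapped_extend(small_pair.target, small_pair.query, recs[:10], model)
        for aln in alns:
            assert aln.score == score_alignment_independent(
                aln, small_pair.target, small_pair.query, model
            )

    def test_suppression_bounds_output_count(self, small_pair, model):
        recs = seed_and_filter(small_pair.target, small_pair.query, model)
        suppressed = gapped_extend(small_pair.target, small_pair.query, recs, model)
        assert len(suppressed) <= len(recs)
        free = gapped_extend(small_pair.target, small_pair.query, recs, model,
                             suppress=False)
        assert len(free) == len(recs)

    def test_two_anchors_one_call_one_alignment(self, small_pair, model):
        recs = seed_and_filter(small_pair.target, small_pair.query, model)
        two = recs[:2]
        together = gapped_extend(small_pair.target, small_pair.query, two, model)
        assert len(together) == 1

    def test_two_anchors_split_calls_two_overlapping_alignments(self, small_pair, model):
        recs = seed_and_filter(small_pair.target, small_pair.query, model)
        two = recs[:2]
        a = gapped_extend(small_pair.target, small_pair.query, [two[0]], model)
        b = gapped_extend(small_pair.target, small_pair.query, [two[1]], model)
        assert len(a) == len(b) == 1
        lo = max(a[0].target_start, b[0].target_start)
        hi = min(a[0].target_end, b[0].target_end)
        assert hi > lo  # overlapping target regions

    def test_extension_extents_and_score_are_anchor_stable(self, small_pair, model):
        # every anchor on one alignment re-extends to the same region,
        # column count and score (interior gap ties may be placed
        # differently, but never change extent, length or score)
        recs = seed_and_filter(small_pair.target, small_pair.query, model)
        summaries = {
            (
                a.target_start, a.target_end, a.query_start, a.query_end,
                a.strand, a.score, a.ops.size,
            )
            for r in recs[:15]
            for a in gapped_extend(small_pair.target, small_pair.query, [r], model)
        }
        assert len(summaries) == 1

    def test_empty_record_collection(self, small_pair, model):
        assert gapped_extend(small_pair.target, small_pair.query, [], model) == []

    def test_out_of_bounds_record_is_named(self, small_pair, model):
        bad = SegmentRecord("t", 10**7, 10**7 + 10, "q", 0, 10, "+", 0)
        with pytest.raises(ValueError, match="record 0"):
            gapped_extend(small_pair.target, small_pair.query, [bad], model)

    def test_reverse_strand_extension_crosses_indels(self, rng):
        model = ScoreModel()
        core = random_dna(rng, 3000)
        mutated = core[:1000] + core[1003:2000] + "AC" + core[2000:]
        target = random_dna(rng, 200) + core + random_dna(rng, 200)
        query = random_dna(rng, 200) + revcomp(mutated) + random_dna(rng, 200)
        recs = [r for r in seed_and_filter(target, query, model) if r.strand == "-"]
        assert len(recs) >= 2  # the two indels break the gap-free blocks
        alns = gapped_extend(target, query, recs, model)
        assert len(alns) == 1  # one alignment spans both indels
        assert alns[0].target_end - alns[0].target_start >= 2990


class TestEvaluateStrategies:
    def test_none_equals_unpartitioned_baseline(self, small_pair, model):
        reports = evaluate_strategies(
            small_pair.target, small_pair.query, model,
            chunk_size=10**9, max_size=10**9,
        )
        base_keys = {alignment_key(a) for a in reports["none"].alignments}
        for name, rep in reports.items():
            assert {alignment_key(a) for a in rep.alignments} == base_keys
            assert rep.duplicated_columns == 0
            assert rep.overlapping_pairs == 0

    def test_partitioned_run_duplicates_output(self, small_pair, model):
        reports = evaluate_strategies(
            small_pair.target, small_pair.query, model,
            chunk_size=10**9, max_size=5,
        )
        assert reports["none"].duplicated_columns == 0
        for name in ("row", "diagonal"):
            assert reports[name].total_alignments > reports["none"].total_alignments
            assert reports[name].duplicated_columns > 0
            assert reports[name].output_bytes > reports["none"].output_bytes
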