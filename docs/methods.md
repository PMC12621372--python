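# Methods

## Model of the pipeline

The package treats pairwise whole-genome alignment as the classic
three-stage pipeline: exact-seed finding, gap-free (x-drop) extension of
seeds into HSPs, and gapped (y-drop) extension of HSP anchors into final
alignments.  The contribution it implements sits between stages two and
three: how a chunk's HSP segment file is split into bounded-size
partitions without separating anchors that depend on each other through
the extender's crossing-suppression rule.

Coordinates are 0-based half-open internally; segment files on disk use
the 1-based closed lastZ convention and the conversion happens only in
`segio`.  A `-` strand HSP pairs an ascending target interval with a
descending query interval given in forward-strand coordinates; all
minus-strand computation runs against the reverse complement of the query
and is converted back at the boundary.

## Anchors and diagonal keys

For partitioning, an HSP is reduced to the floor midpoints of its two
intervals, keyed by `t_mid − q_mid` on `+` and `t_mid + q_mid` on `−` —
the dot-plot diagonal along which an extension from that HSP travels.
Per strand, anchors sorted by key (ties: target midpoint, query midpoint,
input order) are cut greedily into runs of at most `max_size`.  The cut
determines *membership* only; inside each partition, records keep their
original file order, which is the order a gapped extender processes a
segment file.  Without this, partitioning would change which anchor of an
alignment extends first even when nothing is split, and an unsplit
pipeline could not reproduce the unpartitioned output path-for-path.

For gapped extension the anchor must be a point *on* the HSP, so it is
the target-interval midpoint paired with its query position along the
HSP's own gap-free diagonal.  For `-` HSPs of even length the floor/floor
midpoint is not on the HSP (the anti-diagonal pairing needs one axis
rounded up), and using it would silently disable suppression for half of
all reverse HSPs.

Anchors sharing one overfull diagonal are split at the size boundary: the
size cap is hard, at the cost of rare residual straddling where many
anchors crowd together.

## Adaptive partition sizing

The best `max_size` depends on genome size, similarity and core count,
so by default the cap is chosen from the data: the nearest-rank 75th
percentile (`sorted(history)[ceil(0.75 n) − 1]`) of the pre-split sizes
of segment files seen so far, falling back to `default_max` (15 000, the
magnitude that suits large high-identity genomes) while the history is
empty.  Nearest-rank is used because the inputs are integer counts; the
history records the byte-estimated line counts — file size divided by the
size of the first data line — because that estimate is what the splitter
can know without reading each file, which is the point of the heuristic.
The history is process-local state; the shared-folder registry a
production run would scan is reproduced by feeding files through one
`SizePolicy` instance.

## The toy extension engine

The GPU seeding/filter stages are replaced by exact k-mer seeding (k=12)
plus x-drop gap-free extension on CPU; partitioning behaviour depends
only on the HSP sets, not on seeder performance.  Seeds already inside a
span extended on the same work diagonal are skipped, so each gap-free
stretch is extended once.  An HSP is kept when its best span scores at
least `hsp_threshold` (default 3000).

Gapped extension is a banded affine-gap dynamic program with y-drop
pruning: cells whose best state falls more than `y_drop` below the
running maximum are dropped, and extension stops when a row's live window
empties.  The live window is additionally capped at `2·(y_drop /
gap_extend) + 8` columns — beyond that distance from the best diagonal
the gap cost alone exceeds the drop threshold, so the cap only binds when
`y_drop` is effectively infinite (as in the oracle tests, which pass an
unbounded band by using a huge `y_drop`).

Each anchor is extended independently backward (on reversed sequences)
and forward; the reported alignment glues the two optimal half-paths at
the anchor column, so its score is exactly the optimal extension score
through the anchor — the quantity a full unbanded affine DP oracle
computes, which the tests verify on random pairs with substitutions and
indels.  Tie-breaking is fixed in the fill order (aligned column over
target-gap over query-gap; closing a gap over extending it) and identical
in both directions.  Consequences worth knowing: alignments from
different anchors of the same homology have identical extents, column
counts and scores, but may place interior gap runs at different ends of a
repeat; and because ties never differ *between strategies*, straddle
byte/column comparisons between row and diagonal partitioning are exact.

After each extension, every not-yet-processed same-strand record whose
anchor lies on an aligned pair of the produced alignment is covered and
skipped.  This is the dependency that partitioning can violate: anchors
of one alignment placed in different partitions are each re-extended, and
the evaluator counts the damage as duplicated target columns (positions
covered by alignments from ≥2 partitions of the same chunk), overlapping
alignment pairs, and output MAF bytes.

Default scores are the HOXD70 substitution matrix with gap open 400, gap
extend 30 (a gap of length L costs 400 + 30·L), x-drop 300, y-drop 3000 —
the parameter magnitudes conventional for lastZ-style aligners.  All are
configurable, including the matrix via a score file.

## Simulator

`simulate_pair` copies a random DNA core through an i.i.d. mutation
process: substitutions at the divergence rate (default 2%), indels at a
per-base rate (default 1%, lengths uniform on 1–5, insertions and
deletions equally likely), then unrelated uniform-random flanks (default
1000 bp) on both ends of both sequences.  The defaults represent the
standard simulation setting for exercising seed-and-extend aligners
across the 0–40% divergence range; fixtures used by the tests are 5 kb to
100 kb cores at 1–10% divergence.

What the simulator does *not* emulate: repeats, segmental duplications,
rearrangements, GC/composition bias, or many separate homologous blocks.
A simulated pair contains a single collinear homology, so every partition
of its chunk re-extends the same alignment and row and diagonal cuts
produce *equal* straddle counts — the tests therefore assert the
direction "diagonal ≤ row", which on this generator holds with equality.
Passing tests show correctness of the mechanism (conservation, banding,
suppression, re-extension accounting), not the size of the advantage on
real genomes, where anchors of many distinct alignments interleave in
target rows and row-wise cuts scatter each alignment across partitions.

## Binning and the keg

Chromosomes are packed whole (never split — splitting would manufacture
straddling at the cut and force coordinate lifting) into
`ceil(total/capacity)` bins, default capacity 200 Mbp, by the
longest-processing-time-first rule with ties to the lowest bin index;
LPT's makespan is within `4/3 − 1/(3m)` of optimal, which the tests check
against brute-force optima.  Each target×query bin pair is one instance
work unit.

The keg archive (`.tar.gz`) carries the partition files, one rendered
command per partition in plan order, and the plan manifest.  Batch
execution writes each command's output to its own file and concatenates
by command index — never through a pipe — so results are byte-identical
for any worker count; MAF headers are deduplicated on concatenation,
keeping the first.  Priority-lowering for extension processes is exposed
as `SubprocessExecutor(nice_increment=…)` and left untested
(OS-dependent).

## Problem sizes used by the tests and the acceptance script

Unit tests use 5–10 kb cores.  The straddle-direction suite runs ten
100 kb cores at 2% divergence with 50 kb chunks over partition caps
{10, 25, 50, 100} (~8 min); pipeline-equivalence fixtures are 50 kb
cores at 1% and 10% divergence.  `scripts/acceptance.py` uses three
50 kb replicates at 2% divergence with a cap of 25, 50 LPT instances
small enough for exhaustive optima, and 25 oracle pairs of ≤200 bp.

## Known limitations

- The extender aims for internal consistency (score validity, DP-oracle
  agreement), not equivalence with any production aligner's alignments.
- Straddle statistics are counted within chunks; cross-chunk duplicate
  alignments (present in any chunked pipeline) are deliberately outside
  the measure.
- The adaptive cap's closeness to the runtime-optimal cap on real genomes
  is an empirical claim that desk-scale fixtures cannot test and the
  package does not assert.
- `find_seeds` materialises every k-mer match and is meant for
  verification at desk scale; `seed_and_filter` with the per-diagonal
  skip is the pipeline path.
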