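# minikeg

Diagonal partitioning of HSP segment files for pairwise whole-genome
alignment, with a desk-scale seed–filter–extend engine that makes the
partitioning's correctness and benefit measurable without genome-sized
downloads or an accelerator.

## The problem

Seed-and-extend genome aligners split the target×query dot plot into
square chunks and hand each chunk's high-scoring ungapped pairs (HSPs) to
an independent gapped-extension job.  HSP density varies over orders of
magnitude between chunks, so a handful of jobs dominate the wall clock
while every other core idles — *tail latency*.  Capping the number of
HSPs per job restores balance, but a naive cap splits *dependent* anchors
apart: a gapped extension that crosses a later anchor normally suppresses
it, and when the two anchors sit in different files both are extended,
producing *straddling* (duplicate and extra) alignments that inflate both
output size and total CPU work.

## The remedy

Extensions run along dot-plot diagonals.  Each HSP is collapsed to an
anchor at its interval midpoints, with a strand-dependent diagonal key

```
d = t_mid − q_mid   ('+' strand)        d = t_mid + q_mid   ('−' strand)
```

Per strand, anchors are sorted by `d` and cut greedily into runs of at
most `max_size`: contiguous diagonal *bands* that keep dependent anchors
together while enforcing a hard per-job size cap.  The cap itself can be
chosen adaptively as the nearest-rank upper quartile of the sizes of
segment files seen so far, and oversized files are recognised cheaply by
dividing the file's byte size by the byte size of one sampled line.

Around this core the package provides:

- `minikeg.segio` — lastZ-style segment-file I/O (1-based closed on disk,
  0-based half-open in memory) and the byte-size line estimate;
- `minikeg.diagpart` — anchors, diagonal/row partitioning, adaptive
  sizing, segment-file splitting with a plan manifest;
- `minikeg.binpack` — longest-processing-time-first packing of
  chromosomes into ~200 Mbp bins and bin-pair work units;
- `minikeg.keg` — the "keg": a `.tar.gz` bundling partition files with
  one gapped-extension command per partition, plus a worker pool that
  executes the batch and concatenates MAF output deterministically;
- `minikeg.toyalign` / `minikeg.sim` — exact k-mer seeding, x-drop
  gap-free filtering, banded affine y-drop gapped extension with
  anchor-crossing suppression (HOXD70 scores by default), a divergence /
  indel / flank sequence simulator, and a straddle-quantifying strategy
  evaluator.

## Worked example

```
$ minikeg simulate --core-length 20000 --divergence 0.05 --seed 3 --out sim
target 22000 bp, query 21946 bp -> sim
$ minikeg seed sim/target.fa sim/query.fa --chunk-size 10000 --out segs
144 HSPs in 4 chunk segment files -> segs
$ minikeg partition segs/*.segments --strategy diagonal --max-segment-size 10 --out parts
4 segment files -> 16 partitions (diagonal)
$ minikeg keg parts/*.segments --out run.keg.tar.gz
keg with 16 partitions -> run.keg.tar.gz
$ minikeg run-batch run.keg.tar.gz sim/target.fa sim/query.fa --workers 4 --out batch
16 commands ok -> batch/combined.maf
```

A 20 kb core at 5% divergence (1 kb random flanks on both sides) yields
144 HSPs across four 10 kb×10 kb chunks; capping partitions at 10 HSPs
splits them into 16 partition files, so the keg carries 16 extension
commands whose MAF outputs are concatenated in plan order.  The plan
manifest shows the contiguous diagonal bands, e.g. the first chunk's
forward anchors cut into `[-11,-4] [-4,-1] [-1,3] [4,6]`.

```
$ minikeg evaluate sim/target.fa sim/query.fa --chunk-size 10000 --max-segment-size 10 --out eval
none: 4 alignments, 0 duplicated columns, 162536 bytes
row: 16 alignments, 40000 duplicated columns, 650048 bytes
diagonal: 16 alignments, 40000 duplicated columns, 650048 bytes
```

The unpartitioned run is the zero-straddling floor: one alignment per
chunk.  Any partitioned run re-extends each alignment once per partition
touching it — here every partition holds anchors of its chunk's single
homology, so 16 alignments appear and each chunk's ~10 kb of target is
covered four times (40 000 duplicated columns).  On fixtures with a
single collinear homology the diagonal and row cuts group the same
anchors, so their straddle counts coincide; diagonal partitioning is
never worse, and on real genomes — where one target row region holds
anchors of many distinct alignments — row cuts scatter each alignment
over many partitions while diagonal bands do not.

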