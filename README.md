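# breakscan

Reference-free variant calling by direct comparison of sequencing reads
from two samples.

Most variant callers map reads to a reference genome first and then
model mismatches; reads that fail to map — often exactly the
variant-carrying ones — are lost, and the mapping step drags in a large
tail of candidates that must be filtered statistically.  `breakscan`
takes the opposite route for the two-sample setting (wild-type vs.
mutant, parent vs. genome-edited offspring, germline pairs): it compares
the reads of a *normal* and a *mutated* group directly against each
other and reports **breakpoints** — positions at which the two samples'
sequences begin to differ — together with the local consensus sequence
of each sample and an inferred variant type: SNV, insertion, deletion,
inversion, or a decomposable complex of these.  No reference is needed
to call; a reference is only consulted afterwards, optionally, to attach
genomic coordinates.

## Method in brief

For minimum suffix length *d* (default 30) and prefix length *k*
(default 3):

1. **Pack.**  All reads are 2-bit encoded (A=00, C=01, G=10, T=11) and
   held in memory in blocks of 64 reads with 2-byte in-block offsets —
   an amortized 2 + 8/64 = 2.125 index bytes per read.
2. **Partition and sort.**  Every suffix of length ≥ *d* of every read
   (both orientations for non-strand-specific libraries) is assigned to
   one of 4^*k* batches by its first *k* bases.  Batches are sorted
   lexicographically one at a time and released, so peak memory is the
   packed reads plus a single batch.  The choice of *k* does not change
   the results.
3. **Scan.**  A run of sorted suffixes sharing its first *d* bases (the
   *anchor*) whose next column shows ≥ 2 distinct bases, with both
   sample groups represented, is a breakpoint cluster.
4. **Filter.**  Clusters pass read-support cutoffs (*c*min ≤ support ≤
   *c*max per group), a variant-fraction window *q* ∈ [*q*min, *q*max]
   over the mutated group (0.9–1.0 for a pure mutated sample, 0.35–0.6
   for a heterozygous one), and a ≤ 5% cap on mutated-like reads in the
   normal group.
5. **Type.**  Per group, a consensus is extended from the anchor by
   strict per-column majority vote; the pair of consensus sequences is
   compared in the fixed order indel → SNV → inversion → complex.
   Strand-mirrored clusters of the same breakpoint are merged, and
   merged-but-untyped breakpoints are retyped after stitching their two
   consensus pairs into longer sequences.

A bundled simulator generates benchmark data (random reference,
implanted variants with bounded spacing, paired-end reads with
Normal(200, 10) fragments) and an evaluator scores calls against the
implanted truth (sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), F-measure
= their harmonic mean).

## Worked example

From Python (see `examples/` for more):

```python
from breakscan import (CallOptions, SimParams, call_variants,
                       evaluate_report, locate_by_exact_match,
                       read_truth, simulate_benchmark)

files = simulate_benchmark(
    SimParams(ref_length=20_000, n_snv=10, n_ins=3, n_del=3,
              coverage=30, error_rate=0.001, seed=7),
    "bench/")
report = call_variants(files.normal, files.mutated, CallOptions(d=30, k=3))
locate_by_exact_match(report, files.reference)
result = evaluate_report(report, read_truth(files.truth))
```

Running `python examples/simulate_and_call.py` prints:

```
simulated 16 variants into 20000 bp; reads in /tmp/breakscan_example_gqvk17sw
16 calls:
  SNV       pos=220    T>C support=19/21 q=1.00
  SNV       pos=251    C>G support=10/8 q=1.00
  SNV       pos=276    G>A support=14/8 q=1.00
  deletion  pos=321    TAGTTAA>- support=17/25 q=1.00
  deletion  pos=369    TA>- support=28/24 q=1.00
  SNV       pos=415    C>T support=28/17 q=1.00
  ...
SNV:   sens=1.000 PPV=1.000 F=1.000
indel: sens=1.000 PPV=1.000 F=1.000
```

Each call line shows the type, the located 1-based position, the
normal→mutated alleles on the reference forward strand, the number of
supporting reads in the normal/mutated groups, and the variant fraction
*q* (here 1.0: every informative mutated read carries the variant, as
expected for a pure mutated sample).  The summary lines are the
evaluator's per-class metrics against the implanted truth.

The same pipeline is available from the shell:

```sh
breakscan simulate --length 20000 --snv 10 --ins 3 --dele 3 --seed 7 --out bench
breakscan call --normal bench/normal_R1.fastq --normal bench/normal_R2.fastq \
               --mutated bench/mutated_R1.fastq --mutated bench/mutated_R2.fastq \
               --ref bench/reference.fa --vcf --out run
breakscan evaluate --calls run/calls.tsv --truth bench/truth.tsv --out eval
```

`call` writes `calls.tsv`, `consensus.fa` (the consensus normal
sequences, mappable with any external aligner as an alternative to the
built-in exact-match locator), optionally `calls.vcf`, and a
`manifest.json` that records every parameter of the run.

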