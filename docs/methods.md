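# Methods

## Model and assumptions

`breakscan` detects differences between two read sets — a *normal* and a
*mutated* group — without mapping either to a reference.  The object it
detects is the **breakpoint**: a position at which the two samples'
aligned sequences begin to differ.  Operationally, a breakpoint is
witnessed by read suffixes: if the mutated sample carries a variant at
position *x*, then reads of both groups that cover the *d* bases left
of *x* contain suffixes sharing those *d* bases (the *anchor*) and
disagreeing at base *d*+1.  Sorting all suffixes lexicographically makes
such suffixes adjacent, so breakpoints can be found in a single linear
scan of the sorted list.

Assumptions inherited from this design:

- Substitution-dominated sequencing noise.  Base qualities are read for
  format validation but never used; the filters operate on read counts
  and allele fractions only.
- Reads are barcode/adapter-free ACGT text.  Reads containing any other
  symbol (N, IUPAC codes) are dropped at load and counted, not recoded:
  fabricating a base could seed a false breakpoint.  Reads shorter than
  *d*+1 are likewise dropped — they cannot reach a divergence column.
- Paired-end mates are treated as independent reads.  Pairing enters
  only indirectly, through the strand-merging and re-inference steps.
- The two groups are sequenced to comparable depth, and the mutated
  sample is either pure (every mutated-group read over a variant site
  carries it) or heterozygous (about half do).

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| *d* | 30 | minimum suffix length; anchor length; divergence tested at column *d*+1 (bases) |
| *k* | 3 | suffix-prefix partition length: 4^k batches processed sequentially; no effect on results |
| *c*min | 6 | minimum reads per group in a cluster |
| *c*max | 28 | maximum reads per group (`None`/0 disables); guards repeat-collapsed clusters |
| *q*min, *q*max | 0.9, 1.0 | variant-fraction window over the mutated group; heterozygous preset 0.35, 0.6 |
| *p*norm | 0.05 | maximum fraction of mutated-like reads tolerated in the normal group at the divergence column |
| *m* | 10 | confirmation bases that must match beyond an event for indel/inversion/complex typing |
| min_cov | 2 | minimum reads covering a column for a consensus vote |
| L | 15 | length (bp) of breakpoint-spanning substrings used to recognize strand-mirrored clusters |
| E | 5 | maximum edit runs for a complex call to be decomposed |

The variant fraction *q* is computed per read over the mutated-group
reads that *cover* the divergence column.  A member suffix of length
exactly *d* ends at the anchor and is blind to that column; counting
such reads in the denominator would dilute *q* below the window at
genuine breakpoints, so they count toward support (*c*min/*c*max) but
not toward *q*.  The same denominator is used for the
normal-contamination fraction.

## Consensus and typing

Per group, each column left and right of the anchor gets the base held
by a strict majority (> 50%) of that group's reads covering it, with at
least `min_cov` = 2 covering reads; extension halts independently in
each direction at the first undecidable column.  Only the variant
subpopulation of the mutated group votes for the mutated consensus —
reads whose divergence-column base differs from the normal majority —
because in a heterozygous sample the reference-carrying half would
otherwise vote the consensus back to reference.  The q-window filter
guarantees this subpopulation is substantial before consensus building
runs.

Typing compares the consensus pair (Nc, Mc) at breakpoint column *b* in
a fixed order; the first test that succeeds wins:

1. **indel**, size *g* = 1, 2, …: deletion if `Nc[b+g : b+g+m] == Mc[b : b+m]`,
   insertion for the symmetric condition; smallest *g* wins, and an
   exact tie between the two interpretations at the same *g* is
   reported as the deletion (a deterministic convention — the two are
   indistinguishable without a reference).
2. **SNV**: `Nc[b] != Mc[b]` with the next `min(m, available)` ≥ 1 bases
   identical.
3. **inversion**, size ℓ = 2, 3, …: `Mc[b : b+ℓ]` equals the reverse
   complement of `Nc[b : b+ℓ]`, with *m* matching bases after the
   segment.  Length-1 inversions do not exist (they are SNVs or
   identities).
4. **complex**: a global unit-cost edit script (edlib) between the two
   windows; accepted when it has 1–E runs of non-match operations *and*
   ends in a run of ≥ *m* matching bases, in which case it is decomposed
   into individual SNV/insertion/deletion components.  The trailing-match
   requirement mirrors the *m*-base confirmation of the simple types:
   without it, windows too short for a legitimate indel/inversion test
   realign as shifted edit scripts and shed spurious components.
5. otherwise **unassigned**.

Indel and inversion tests require the full *m*-base window; the SNV test
tolerates a truncated window because a single-column event needs no
length estimate, only evidence that the divergence is not the edge of a
larger event.

### Strand merging and re-inference

With non-strand-specific input every breakpoint is found twice — once
anchored on each side, in opposite orientations.  Two calls are merged
when each one's set of length-L windows spanning the breakpoint (from
the normal consensus, and likewise from the mutated consensus) contains
the reverse complement of a window of the other.  The merged call keeps
the orientation of the cluster with the lexicographically smaller
anchor; if exactly one side was typed, the typed side's orientation is
kept instead, since discarding the typed side would lose the call.
Support counts are summed and *q* is their support-weighted mean.

If both sides are unassigned, their consensus pairs are stitched on a
unique exact overlap of ≥ L bases (normal and mutated sides stitched
independently, since an indel shifts their overlaps differently) and the
extended pair is retyped.  This is what makes indels and inversions
larger than a single cluster's consensus reach callable: each side alone
has ~`read_length − d − 1` bases of extent past the breakpoint, but the
stitched pair spans both anchors.  Ambiguous or inconsistent overlaps
leave the call unassigned rather than guessing.

## Locating and reporting

Calls are complete without a reference.  When one is supplied, each
call's consensus normal sequence is searched as an exact substring of
both strands; a unique hit assigns (contig, 1-based position of the
event, strand), re-orients alleles to the forward strand, and records
the base before the event for left-anchored VCF output.  Zero or
multiple hits mark the call `unmapped` / `ambiguous` — made explicit
rather than silently dropped.  Exact matching is a deliberate desk-scale
surrogate: consensus sequences are also exported as FASTA for mapping
with an external aligner when mismatch-tolerant placement is wanted.
Positions follow VCF-style conventions: an SNV's substituted base, the
first deleted/inverted base, the first reference base after an
insertion; indels are left-anchored in VCF output.

## The synthetic benchmark

The generator emulates a two-group resequencing benchmark at desk
scale.  A random i.i.d. reference (configurable GC) stands in for a real
chromosome; SNVs, indels and inversions are implanted at positions
whose successive spacings are drawn uniformly from 25–50 bp — the
variant density of the study conditions — and recorded in a truth table
that reconstructs the mutated haplotype byte-for-byte (a tested
invariant).  Reads are 50 bp paired-end from fragments of length
Normal(200, 10) truncated at the read length, drawn uniformly from
either strand; the mutated group samples the mutated haplotype (pure) or
either haplotype with probability ½ (heterozygous).  The fragment count
is `ref_length × coverage / (2 × read_length)`, so coverage accounting
is exact by construction.

Sequencing noise is a uniform per-base substitution rate (default
0.001) with constant quality characters, replacing an empirical
platform profile; since the caller ignores qualities, the profile's
only relevant feature is the error rate itself.  Real data differ in
ways the simulator does not model: indel sequencing errors, PCR
duplicates, coverage bias, repeat structure beyond what an i.i.d.
sequence contains, and contamination of the normal sample.  Passing
tests on this benchmark therefore demonstrates correctness of the
machinery and behaviour at the stated noise/density conditions, not
performance on real libraries — particularly regarding repeats, which
an i.i.d. 100 kb reference underrepresents.

## Resolution limits at 25–50 bp variant spacing

Anchor-based detection needs *d* consecutive variant-free bases on at
least one side of a breakpoint: if another variant falls inside the
anchor window, normal and mutated suffixes disagree within their first
*d* bases and never share a run.  With spacings uniform on 25–50 bp and
*d* = 30, each flank is clean with probability ≈ 0.77 (less for the
right flank of a deletion, which displaces the anchor by its own
length), so a few percent of SNVs and a larger share of indels are
invisible at *d* = 30.  Typing adds a second limit: a size-*g* indel
needs *g* + *m* bases of consensus extent beyond the breakpoint, and a
single 50 bp-read cluster provides at most `50 − d − 1` = 19 — so
single-sided calls top out near *g* ≈ 7 and larger events depend on the
stitching step, i.e. on both flanks being clean.  On the bundled 100 kb
benchmark (seed 1) this yields SNV sensitivity 0.91 with PPV 1.0 and
indel F ≈ 0.82 at *d* = 30, while the identical pipeline at *d* = 20–24
recovers every implanted variant (F = 1.0).  Choose *d* ≈ 20–24 for
variant-dense applications and larger *d* (more specific anchors) for
sparse ones; *d* = 30 is kept as the default for the genome-editing
use case, where candidate variants are rare and isolated.

## Numerical and procedural choices

- **Sorting.**  The pipeline sorts each batch on fixed-width keys of the
  first *d*+1 suffix bases (pad ordered before every base, so a proper
  prefix precedes its extensions), then on the tie-break (group, strand,
  read id, offset).  Cluster identity depends only on those columns, so
  this equals a full-text sort for everything downstream; the reference
  API `sort_suffix_refs` performs the full-text sort, and the two are
  cross-checked in the tests.  The fixed tie-break makes reports
  byte-reproducible, and cluster ids are assigned after sorting clusters
  by anchor text, which makes reports independent of *k*.
- **Deduplication.**  Within a cluster, one vote per (read, strand); a
  read whose repeat structure contributes several qualifying offsets
  keeps the smallest.
- **Cluster merging (identical anchors).**  Clusters are merged when
  their anchors are identical; with a single *d* per run, distinct
  clusters almost never share an anchor (it would require the same
  30-mer at two divergent loci), so this step is usually the identity.
- **Normal-group majority ties** at the divergence column break
  alphabetically; strict-majority voting elsewhere cannot tie.
- **Degenerate inputs.**  Clusters whose voting populations have < 2
  reads covering the divergence column, or no strict majority there, are
  dropped with a logged reason.  Empty groups are usage errors.
- **Randomness.**  Every stochastic step derives its generator from the
  single user seed plus a fixed stream tag, so benchmark FASTQ output is
  byte-identical across runs of the same seed.

## Known limitations

- Translocations are not called; no procedure is defined for them.
- The exact-match locator places only error-free consensus sequences;
  a consensus containing a miscalled base goes `unmapped` (use the FASTA
  export with a real aligner instead).
- Memory grows linearly with total bases (2 bits/base plus suffix
  handles); the design targets exomes and small genomes, not
  deep-coverage human whole-genome data.
- Sensitivity degrades predictably with variant spacing below *d* (see
  above) and for indels larger than roughly `read_length − d` even with
  stitching.
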