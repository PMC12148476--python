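# Methods

## Detection model

A CpX island is operationally defined by three quantities over a span of
*N* bp: the CX percentage `(c + x)/N` (just `c/N` when X = C, since C and X
are then the same base), the observed CpX dinucleotide count `cpx`
(positions *i* with base *i* = C and base *i+1* = X, both inside the span;
overlapping occurrences all count, so "CCC" holds two CpC), and the
observed/expected ratio `cpx · N / (c · x)`. The expected count `c·x/N` is
the number of CX dinucleotides a sequence of the same base composition
would contain if neighbouring bases were independent; O/E near 1 means no
depletion, and in methylated genomes CpG is typically depleted (O/E ≪ 1)
outside islands. When `c·x = 0` the O/E is defined as 0, which simply makes
such windows unqualifiable.

Detection is the Takai–Jones sliding-window procedure. Its published
descriptions leave several steps open; this implementation pins one
variant, and all of its tests are written against this exact pinning:

- **Seed**: the smallest start whose *W*-window qualifies (both thresholds
  inclusive, per the "minimum" wording of the criteria).
- **Extend**: test the window displaced by exactly *W*; while it
  qualifies, advance. On the first failure (or sequence end), roll the
  failing window back 1 bp at a time toward 5′ until it qualifies, bounded
  at the previous qualifying window's start. The candidate runs from the
  seed start to the last qualifying window's end.
- **Trim**: if the whole candidate qualifies, keep it. Otherwise shave
  1 bp alternately 5′-then-3′, re-testing after every shave, while the
  span exceeds *W*; if width *W* is reached without qualifying, fall back
  to the 5′-most qualifying *W*-window of the original span (the seed
  guarantees one exists, so every seed yields an island and the procedure
  terminates).
- **Merge**: islands separated by ≤ `max_merge_gap` bp are coalesced
  unconditionally and transitively, and the merged span's CX% and O/E are
  recomputed; the merged span is *not* re-tested against the thresholds,
  so only unmerged islands are guaranteed to satisfy them. The gap is
  measured in half-open coordinates (`next.start − prev.end`), and the
  strict inequality means a 101-bp gap at the default survives.
- The seed search resumes at each accepted island's *end* (not the
  untrimmed candidate's end), so sequence trimmed away 3′ can still seed a
  new island.

Exact dm6 island counts are sensitive to these choices (merge re-testing
and the rollback bound in particular), which is why the catalogue-level
numbers are treated as reproduction targets for a genome run rather than
unit-test constants.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `window_size` | 500 bp | scan width and minimum island length |
| `min_cx` | 0.55 | minimum CX fraction, inclusive |
| `min_oe` | 0.65 | minimum observed/expected CpX ratio, inclusive |
| `max_merge_gap` | 100 bp | maximum inter-island gap coalesced |
| `second_nt` | G | the X of CpX; the first base is always C |

The defaults are the classical CpG-island criteria; they are deliberately
shared across X so that CpA/CpT/CpC scans are directly comparable to CpG
ones (with the caveat that criteria tuned for CpG may be strict for CpC,
where a qualifying window needs ≥ 55% cytosine alone).

### Numerical choices

Window statistics are integer counts; CX% and O/E are formed by one
floating-point multiply/divide in the same order everywhere (`cpx·N/(c·x)`),
so the production prefix-sum scan, the constant-work 1-bp shift update, and
the naive per-window full recount produce bit-identical qualification
decisions — the test suite asserts exact mask equality, not approximate.
Threshold comparisons are `≥` on those floats. Ambiguity codes are
normalized to N on input; N counts as neither C nor X and any dinucleotide
containing N counts 0, so N-rich windows fail the thresholds naturally and
need no special rejection rule.

A property worth noting: raising `min_cx` or `min_oe` shrinks the set of
qualifying windows pointwise (a guaranteed monotonicity, and the form the
tests assert), but *not* necessarily the total island-covered bp — a
stricter threshold can move a seed and let the jump/rollback extension
settle on a longer span (a 40-bp sequence exhibiting this was found by
property testing). Claims of coverage monotonicity should be made at the
window level only.

## Coordinates and formats

Internal, BED and BedGraph coordinates are 0-based half-open; the CSV
export is 1-based inclusive, genome-browser style. BedGraph admits exactly
one value column, so the writer exposes a choice (CX% or O/E) and the full
record goes to BED4+3 (name, CX%, O/E, length) or CSV (which also carries a
40-base sequence preview, ellipsis-marked when truncated). Whether 0- or
1-based starts are the "right" CSV convention is genuinely ambiguous in the
wild; the pairing chosen here matches the named standards and is asserted
by round-trip tests.

## Summary statistics, long islands, shores

Per chromosome: island count, summed island bp (islands are
non-overlapping, so this is covered bp), median length (mean-of-middle-pair
for even counts; exports round to integer bp), frequency = count /
chromosome length × 1000, coverage = covered bp / chromosome length × 100.
The genome-total row pools all islands (its median is over the pooled
lengths, not an average of medians). Exports round frequency to 3 decimals
and coverage to 1, matching how such tables are conventionally printed.

Long-island subsets are a simple inclusive length filter (≥ 3000 bp being
the conventional cut for "long"). Shores are the 2-kb flanks of each island
clipped to the chromosome, with overlapping shore fragments merged and all
island bodies subtracted, so shores and islands are bp-disjoint even when
islands sit closer than twice the flank.

## Overlap reporting and the permutation null

The per-feature-type report counts (feature, island) pairs with ≥ 1 bp
intersection in half-open coordinates (touching intervals do not overlap).
Counting pairs rather than distinct features is what lets a long
transposable element spanning several islands exceed 100%: the reported
percentage is pairs / features-of-type × 100, rounded half away from zero
to an integer. The default enrichment screen keeps types with ≥ 75% overlap
and ≥ 10 loci; both thresholds are arbitrary conventions exposed as
parameters. Pair counting uses independently sorted start/end arrays per
chromosome (exact because "starts after the query" and "ends before the
query" are disjoint failure modes), and is tested against a quadratic
all-pairs oracle.

The permutation control relocates every island uniformly at random on its
own chromosome (start ~ U[0, chrom_len − island_len]), preserving lengths
and chromosome assignment; shuffled islands may overlap each other.
Overlap is measured as the *summed* intersection of each island with the
union of the features, identically for observed and permuted
configurations. The sum (rather than intersecting the union of islands) is
deliberate: it makes each island's contribution exchangeable under the
null, whereas a union-based measure shrinks when shuffled islands
self-overlap and biases the fold upward by tens of percent even for
independently placed sets. Reported are the fold (observed / permuted
mean; flagged undefined when the permuted mean is 0, with the value inf
for positive observed overlap and 0 otherwise) and the add-one empirical
p-value `(1 + #{perm ≥ obs}) / (n_perm + 1)`, which is never 0 and equals
1 when features are empty. 100 permutations is the default, matching
common practice for this kind of control; it bounds the attainable p at
~0.01.

## Synthetic genomes

The generator samples order-1 Markov chains over {A, C, G, T} — order 1
because CX% and O/E respond to dinucleotide transition structure, the very
quantity under test, which an i.i.d. sampler cannot shape independently of
base composition.

- **Background** (`background_model`): stationary base composition
  A/T 0.29, C/G 0.21 (42% GC, a fly-like euchromatic value) with the C→X
  transition forced to 0.05 and the C row renormalized. This emulates the
  CpX depletion that makes islands detectable; background windows sit far
  below the O/E threshold, and 20-kb background sequences yield zero
  islands across seeds.
- **Island segments** (`island_model`): for X ≠ C, base composition C 0.35
  / X 0.30 / others 0.175 with P(X|C) = 0.50 (O/E ≈ 1.5, CX% ≈ 0.65);
  for X = C, an i.i.d. 62%-C model (O/E ≈ 1 by construction). Calibration:
  500-bp windows of pure island-model sequence qualify under the defaults
  in ≥ 95 of 100 seeds (asserted by test), so planted segments ≥ 800 bp
  are reliably seedable.

`plant_islands` draws background and each segment from independent child
streams (`numpy` PCG64 via `SeedSequence.spawn`) of one integer seed, so a
seed fully determines the record across runs and platforms.

What the synthetic genomes do **not** emulate: chromosome-scale
heterogeneity (isochores, pericentromeric repeats), N-gaps (N handling is
tested with hand-built strings instead), repeat families, and the soft
boundaries of real islands. Passing the planted-recovery tests therefore
shows the scanner finds and localizes high-CpX segments against a depleted
background — it does not certify biological island calls, whose edges are
a property of the criteria as much as of the sequence. Recovery is scored
by Jaccard overlap with the planted truth; the window method smears each
boundary by up to ~W bp, so an 800-bp planted island typically scores
0.6–0.8 and occasionally dips just under 0.6 on unlucky seeds — the
fixed-seed tests use the 0.6 bar established by reference runs.

## Problem sizes

The test suite and acceptance script run on synthetic material sized for a
thorough but quick desk check: 200 random 2–20 kb sequences for the
scanner/oracle equivalence suite, 30-kb genomes with three planted islands
(800/1500/3000 bp) for recovery, 20-kb backgrounds for the zero-island
controls, and a 1-Mb chromosome with 500 islands × 100 features × 100
permutations for the null fold. Whole-chromosome scans scale linearly (the
scan is one prefix-sum pass plus per-island work) and were exercised up to
tens of Mb in development.

## Known limitations

- Exact reproduction of a published dm6 island catalogue depends on
  unstated variant details of the original scanner (merge re-testing,
  rollback bounds, tie-breaks); agreement should be checked at the ±2%
  count level rather than island-by-island.
- The CSV export convention (1-based inclusive) is a choice, not a fact
  about other tools' exports; convert before diffing against third-party
  output.
- The permutation null preserves island lengths and chromosome assignment
  but not inter-island spacing or local composition; it answers "more
  overlap than random placement?", not "more than compositionally matched
  placement?".
- `detect` holds one chromosome's sequence and prefix sums in memory
  (~17 bytes/bp); a 250-Mb chromosome needs ~4 GiB.
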