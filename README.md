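# cpxislands

Sliding-window detection of cytosine-based dinucleotide islands — CpG and
its CpA, CpT and CpC generalizations — in genome FASTA, with per-chromosome
summary statistics, long-island subsets and shores, feature-overlap
reporting, and a permutation enrichment control.

## The problem

CpG islands are genomic regions with elevated C+G content and an elevated
observed/expected CpG dinucleotide frequency. They mark promoters and other
regulatory elements and are the canonical substrate of cytosine methylation.
Non-CpG methylation (CpA, CpT, CpC) is increasingly reported in neurons,
embryonic stem cells and invertebrate genomes, which motivates scanning for
*CpX islands*: the same criteria applied to cytosine followed by any second
base X ∈ {G, A, T, C}. This package is for genomicists who want those scans
scriptable and reproducible: a library plus a small CLI that goes from FASTA
to BED/BedGraph/CSV intervals and summary tables.

## The method

A window of fixed width *W* slides over the sequence. For a window of *N* bp
with counts `c = #C`, `x = #X` and `cpx = #CX` dinucleotides (counted at
every position, overlapping allowed; when X = C, "CCC" holds two CpC and
`x := c`):

```
CX% = (c + x) / N          (c / N when X = C)
O/E = cpx / (c · x / N)    (0 when c·x = 0)
```

A window *qualifies* when `CX% ≥ min_cx` and `O/E ≥ min_oe` (both
inclusive). Detection follows the classical Takai–Jones procedure,
generalized to any X:

1. **Seed** — find the first qualifying *W*-window.
2. **Extend** — jump 3′ in steps of exactly *W* while the displaced window
   qualifies; after the first failure, roll the failing window back 1 bp at
   a time until it qualifies (bounded by the previous qualifying window).
3. **Trim** — if the whole candidate span does not itself qualify, shave
   1 bp alternately from the 5′ and 3′ ends, re-testing after each shave,
   down to width *W*; the seed window is the guaranteed fallback.
4. **Merge** — coalesce islands separated by ≤ `max_merge_gap` bp
   (unconditionally, transitively) and recompute CX% and O/E over the
   merged span.

Defaults are the standard island criteria: `W = 500 bp`, `min_cx = 0.55`,
`min_oe = 0.65`, `max_merge_gap = 100 bp`, `X = G`. Bases `N` (and any
IUPAC ambiguity code, which input normalization maps to N) count as neither
C nor X, and dinucleotides containing N never count.

Downstream, the package computes per-chromosome count / covered bp / median
length / frequency per 1000 bp / coverage %, filters long islands (e.g.
≥ 3000 bp), derives shores (2 kb flanks minus island bodies), tallies
per-feature-type overlap percentages against annotation BED (counting
(feature, island) pairs, so one long transposon spanning several islands
can exceed 100%), and estimates overlap enrichment against a null in which
islands are relocated uniformly at random on their own chromosomes.

## Worked example

Generate a 50-kb synthetic chromosome with two planted CpG-island segments,
then detect with defaults:

```
$ cpxislands simulate --length 50000 --islands 8000:1200,30000:3500 \
      --seed 42 --fasta-out genome.fa --truth-bed-out truth.bed
$ cpxislands detect --fasta genome.fa --bed islands.bed \
      --summary-tsv summary.tsv --chrom-sizes-out sizes.tsv
$ cat islands.bed
synthetic	7812	9373	CpG_1	0.5996	1.2907	1561
synthetic	29745	33716	CpG_2	0.6404	1.3354	3971
```

Both planted segments ([8000, 9200) and [30000, 33500)) are recovered, with
boundaries smeared by up to one window width — the window method cannot
localize edges more finely. Columns are chrom, 0-based start, half-open
end, name, CX%, O/E, length. The summary table:

```
$ cat summary.tsv
seq_id	count	sum_bp	median_length_bp	freq_per_1000bp	coverage_pct
synthetic	2	5532	2766	0.04	11.1
total	2	5532	2766	0.04	11.1
```

i.e. 2 islands covering 5532 bp, 11.1% of the 50-kb sequence, at a
frequency of 0.04 islands per 1000 bp. Shores are the 2-kb flanks minus
island bodies:

```
$ cpxislands shores --bed islands.bed --chrom-sizes sizes.tsv --out shores.bed
$ cat shores.bed
synthetic	5812	7812
synthetic	9373	11373
synthetic	27745	29745
synthetic	33716	35716
```

`cpxislands overlap` produces the per-feature-type report and, with
`--perms`, the permutation fold and empirical p-value. Every command logs
its parameters, package version and input checksums.

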