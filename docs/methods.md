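# Methods

## Background model and read threshold

Counts of 5′ ends at a single (position, strand) are modelled as
Poisson with a uniform genome-wide rate λ = N / 2L, where N is the library
depth and L the summed chromosome length. Both strands count as
background positions because calling is strand-specific: each
(position, strand) pair is an independent test. The threshold is the
smallest integer k with 2L · P(Poisson(λ) ≥ k) < 1, i.e. fewer than one
expected false-positive position genome-wide; the bound (default 1.0) and
the depth are configurable, and a fixed threshold (the widely used
working value is 5 reads) can be supplied instead when the depth that
produced it is not available. The upper tail is evaluated through the
survival function of the Poisson distribution rather than term summation,
and the selection uses exponential-plus-binary search on k, so it is
stable for any λ. No mappability or local-rate correction is applied —
the model is deliberately the simplest uniform background.

## Search windows

Every non-redundant annotated mRNA (`NM_`) TSS seeds a symmetric
2000-nt window (±1000 nt): "about" an annotated start is read as
centered, which also captures upstream alternative starts. Overlapping
windows of the same gene are unioned; overlapping windows of different
genes are cut at the floor midpoint between the nearest pair of member
TSSs; windows are clipped to chromosome bounds and a window emptied by
truncation is dropped with a log line. After resolution windows are
disjoint, so window signal is never masked by neighbours.

## Gene-TSS calling

Within a window, calling happens on the gene strand only and requires
some position to reach the read threshold. Two candidates are formed:

* the window-wide argmax of per-base counts;
* the argmax within the best 200-nt bin, where bins start every 10 nt
  and only fully contained bins are evaluated (a window shorter than one
  bin is a single truncated bin; if no full bin holds signal there is no
  bin candidate).

The candidate closer to the nearest member annotated TSS is called; the
call's count is the count at the called base. Tie-breaks are fully
deterministic: argmax ties resolve by proximity to the annotated TSS and
then by smallest coordinate; bin-sum ties resolve to the leftmost bin;
the candidate comparison ties to the window-wide argmax.

## Antisense calling and daTSS filters

uaTSS and daTSS search spaces are 1–1000 nt upstream and 1–2000 nt
downstream of the called gene TSS in gene orientation, on the opposite
strand; the call is the plain argmax (ties: nearest the gene TSS, then
smallest coordinate) subject to the same threshold. The two-candidate bin
rule is not applied to antisense calls — the antisense procedure is
defined as position-of-greatest-density, and no annotation anchor exists
to arbitrate a second candidate.

daTSS calls pass two filters; uaTSS calls are unfiltered.

1. *Hidden-gene uaTSS*: drop if any gene-strand position 1–1000 nt
   upstream of the daTSS holds ≥ 10% of the gene-TSS count. "Upstream" is
   taken in the daTSS's own transcriptional orientation (genomically
   downstream of a plus-strand gene's TSS): that is the only geometry in
   which the flagged signal and the daTSS mirror a gene-TSS/uaTSS pair.
2. *Potential gene TSS*: drop if an annotated TSS on the daTSS's strand
   lies within ±1000 nt (unsigned distance).

## Matrices, profiles and transforms

Anchored matrices use the anchor base as offset 0 with a half-open
window [−flank, +flank); minus-strand anchors are flipped so increasing
offset runs downstream of the anchor (for a flipped anchor the genomic
span covering those offsets is [pos−flank+1, pos+flank+1)). Heatmap
matrices use 40-bp bins; average profiles 10-bp bins, and a profile
equals the column means of the same-bin matrix exactly. Rows sort by
(chrom, position) or by antisense distance (ties by position). Stranded
signal is taken same-strand as the anchor by default, opposite-strand on
request; matrices are emitted as TSV with a JSON sidecar — image
rendering is out of scope.

Antisense-centered profiles are mapped onto gene-TSS coordinates by
reflecting the offset axis about the antisense TSS and translating by the
median gene-TSS distance (downstream for daTSSs, upstream for uaTSSs).
The shift is rounded to whole bins — exact whenever the median is a
multiple of the bin width, otherwise off by at most half a bin — and the
transform is its own inverse on the overlapping support.

Base composition reports per-offset A/C/G/T fractions over [−1000, +1000)
(the stated −1000..+999 span), reverse-complemented for minus-strand
anchors; N and off-contig positions are excluded from the denominator and
reported separately. CpG-edge distances score only daTSSs whose linked
gene TSS overlaps a (merged) island; the downstream edge is the island
end for plus-strand genes and the start for minus-strand genes.

## Inference

* Co-occurrence: two-sided Fisher's exact test on
  {both, ua-only, da-only, neither}; two-sidedness by the
  probability-mass-at-most-observed rule (the common exact-test
  convention, and what `scipy.stats.fisher_exact` implements).
* Positional enrichment: signal mass in a 100-bp window about each daTSS
  versus a 100-bp window shifted downstream of the gene TSS by the median
  gene-TSS–daTSS distance at genes lacking daTSSs; the same median is
  reused for every signal type and is exposed as a flag. Window mass, not
  the single base, is compared. The test is the two-sided Mann–Whitney
  rank sum with normal approximation, continuity and tie correction
  (group sizes in practice far exceed the exact-enumeration range; the
  test suite checks the approximation against exact enumeration at small
  n and its type-I error at scale).
* Count correlation: Spearman rank correlation between gene-TSS and daTSS
  counts, restricted to genes without uaTSSs.
* Expression comparisons: rank-sum and two-sample Kolmogorov–Smirnov
  p-values between architecture-defined gene groups, with the same
  no-uaTSS restriction available.
* Intron overlap: a daTSS is intronic if it lies within some transcript's
  span outside that transcript's exons. The null re-places each
  transcript uniformly at random on its own chromosome, preserving length
  and exon offsets and allowing overlaps among shuffled models — the
  simplest null consistent with random re-placement. The generator is
  seeded and iteration counts configurable.
* Cross-dataset support: a call is supported if any nonzero same-strand
  signal of the other dataset lies within ±10 nt (configurable);
  enlarging the tolerance can only grow the supported set.

P-values are reported raw; no multiple-testing correction is applied, as
each query is a single planned contrast.

## Synthetic data

The generator emulates what the caller assumes about real promoter
landscapes: one 10-Mb chromosome, 500 well-separated (≥10 kb) two-exon
genes with seeded random strands, per-gene uaTSS/daTSS presence from a
four-category joint law (defaults: 53% ua, 28% da, 17.5% both — a
positive association), uaTSS distances uniform on [1, 1000] and daTSS
distances uniform on [1, 2000], per-TSS read totals negative binomial
(means 776 / 467 / 276 for gene/ua/da, size 2.0 — overdispersed TSS
strength, unlike a Poisson), each spike spread over ±5 nt with 60% of the
mass at the exact base and geometric decay (ratio 0.5) outward, and
uniform Poisson background at 1e-5 reads per stranded base. 10% of
daTSS-bearing genes also receive a sense-strand decoy spike of
⌈10% of the gene total⌉ reads 1–1000 nt upstream of the daTSS in its own
orientation — exactly the geometry filter 1 targets, and always above its
10%-of-called-count bar because the called count never exceeds the total.

One constraint is imposed on the daTSS distance law: distances of ≤ 5 nt
(the spike half-width) are redrawn. A daTSS inside the gene-TSS read
spread is geometrically indistinguishable from the hidden-gene decoy
pattern and would be — correctly, by the method's own definition —
filtered; excluding that sliver keeps the planted non-decoy daTSSs
recoverable by construction, which is what the truth-based evaluation
assumes.

What the generator does **not** emulate: sequence content, mappability
structure, nucleosome-phased daTSS placement, broad/multi-modal
promoters, expression-correlated TSS strength, or chained/overlapping
gene neighbourhoods. Passing recovery tests therefore demonstrates the
correctness of the calling logic and filters under the assumed signal
model, not performance on real libraries with alignment artefacts or
dispersed initiation.

Truth-based evaluation matches calls to planted TSSs one-to-one (greedy
by distance, strands equal, within a tolerance; default ±0 nt) and
reports per-class precision/recall, positional errors and a filter
confusion table (planted decoys removed vs. genuine daTSSs removed).
Everything is reproducible from a single seed.

## Numerical and degenerate-input choices

* All internal coordinates are 0-based half-open; the minus-strand TSS is
  `tx_end − 1`. refFlat is converted on read; BED/bedGraph are native.
* Even-length fragment centers take the floor midpoint; fragments running
  off a contig are clipped before centering, so every read deposits
  exactly one center.
* Library depth defaults to the sum of loaded counts but is overridable,
  since a loaded track subset can undercount the depth that a threshold
  should reflect.
* Windows of different genes sharing an anchor position: first by sort
  order wins (logged). Empty windows, empty call sets, all-zero signal
  and off-contig anchors all degrade to empty outputs rather than errors;
  genuinely contradictory inputs (negative counts, inconsistent table
  margins, unknown modes) raise `ValueError`.
* Quartile splits place remainders in the earliest groups (n=5 → 2,1,1,1)
  and break distance ties by position.

## Problem sizes

The test suite and examples run the full pipeline on the default
500-gene / 10-Mb landscape (≈0.5 M reads, seconds per run), exhaustive
caller equivalence on 10⁴ randomized windows, Fisher enumeration over all
2×2 tables up to n = 40, and 1,000-replicate null calibration of the
enrichment test — sizes chosen so the whole suite completes in about a
minute while every code path is exercised at scale sufficient for the
statistical assertions.

## Known limitations

* The caller emits at most one TSS per class per gene: broad promoters
  with several comparable initiation positions collapse to the argmax.
* The uniform background ignores mappability and chromatin-accessibility
  structure; thresholds on real libraries are conservative where coverage
  is locally enriched.
* daTSSs beyond 2 kb and enhancer RNAs are out of scope by definition of
  the search spaces.
* The reflect-and-shift transform operates on binned vectors; sub-bin
  positional accuracy is not preserved.
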