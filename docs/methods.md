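# Methods

This note records the models, conventions and parameter choices behind
`fipkit`, and what the synthetic-data suites do and do not demonstrate.

## Two-round barcoding model

A transcript carries a well-specific **round1** index (added by indexed
Tn5 tagmentation of RNA/cDNA hybrids before encapsulation) and the
droplet **round2** barcode (added by template switching inside the
emulsion). The pair is the cell identity; the composite barcode string
is `ROUND2-ROUND1` with the round1 *index name*, not its sequence, which
mirrors the suffix convention of aggregated droplet matrices and is
collision-free.

Demultiplexing is exact-match only: the assay's design forbids
mismatches because the 96 index sequences are not guaranteed to be
error-correcting, so a read whose index bases differ from every
whitelist entry — even by one base — goes to the `unassigned` bin.
Reads too short to contain the index at its configured location are
counted as malformed rather than silently dropped, and read conservation
(assigned + unassigned + malformed = input) is asserted in tests. The
index location within the read triplet (read, offset, length) is
configuration, defaulting to the first bases of R2 (the Tn5-adapter side
of the cDNA read); no layout is hard-coded.

QC thresholds follow the common practice for these libraries: minimum
1,000 UMIs per cell, maximum 5% mitochondrial fraction, minimum 50
detected genes. Each is independently optional. Mitochondrial genes are
recognized by name prefix (`MT-`/`mt-` by default, configurable).

Depth sensitivity is computed by **binomial count thinning** rather than
read-level subsampling: each count is replaced by a
Binomial(count, p) draw with p = target mean / current mean. Thinning
operates on the quantity actually compared across depths (genes detected
per cell) and needs no aligner; the mean detected-gene curve is
non-decreasing in depth by construction, which the tests verify over
averaged seeds.

## Droplet loading, multiplets and barcode collisions

Cells partition into droplets approximately independently, so occupancy
is Poisson(λ = N/D) and a cell-containing droplet holds k cells with
zero-truncated Poisson probability. The multiplet rate of the
non-preindexed workflow is the probability a cell-containing droplet
holds ≥2 cells:

    P(multiplet) = 1 − λ e^(−λ) / (1 − e^(−λ)).

With a B-plex preindex, a droplet with k cells spreads them uniformly
over B indices; the expected number of occupied composite barcodes is
B(1 − (1−1/B)^k) of which B(1 − (1−1/B)^k − (k/B)(1−1/B)^(k−1)) hold ≥2
cells. Both expectations are summed against Poisson weights, truncating
the occupancy sum where the remaining tail mass falls below 1e-12
(bounded, documented error). The collision rate is the ratio of the two
sums — i.e. collisions are counted **per recovered composite barcode**,
once per collapsed barcode rather than once per constituent cell,
matching how mixed-species barcodes are counted against the total
recovered-cell denominator in a barnyard experiment.

The mixed-species rate multiplies each ≥2-cell barcode by the
probability its members span species (1 − Σ_s f_s^j for j members); in
the small-λ limit this reduces to the familiar 2h(1−h) factor on
doublets, which is asserted as a property. A seeded Monte-Carlo twin
(`simulate_loading`) draws the same model explicitly and must agree with
the closed forms within 3 binomial standard errors; the analytic and
simulated routes are kept strictly separate so each checks the other.

Species calls use strict thresholds: species A above 90% A-fraction,
species B below 10%, otherwise mixed — values exactly at a boundary are
mixed, reading the rule literally.

The analytic expectation at 96-plex (≈0.08%) is lower than collision
rates typically observed in real mixing experiments (≈0.2%); ambient
RNA and barcode hopping, which inflate the observed rate, are
deliberately not modelled.

## eRNA calling

Candidates are ATAC peaks whose distance to every annotated TSS exceeds
2,000 bp, measured from the nearer peak edge to the TSS point (distance
0 if the TSS lies inside the peak) with a strict inequality. Peaks on
chromosomes missing from the annotation are retained with a warning —
no nearby TSS is known, so exclusion would be arbitrary.

For each candidate, the ±2 kb window around the peak center is split
into 400 10-bp bins of mean per-base 5′ signal (windows crossing a
chromosome edge are skipped whole; no partial windows). The 100 core
bins (center ±500 bp) are tested against the 300 flank bins with the
one-sided rank-sum test; because binned coverage is tie-heavy, the
normal approximation uses midranks and tie-corrected variance. BH
adjustment spans all distal peaks tested in one run. A peak is an eRNA
locus when RPKM > 1 **and** adjusted p < 0.01.

RPKM counts a read toward a peak when its 5′ start lies inside the peak
(the assay is 5′-anchored), over the peak length in kb and the library
size in millions; the library-size denominator defaults to the total
assigned reads of the analyzed condition and is configurable. Bin
values are raw coverage; any normalization is left to the caller.

## TSS clusters, usage and switches

### Density clustering

Tag clusters are called per (chromosome, strand) by recursive
weakest-link splitting: for a block of sites, the weakest prefix/suffix
break density is the block's `d_max` (the largest density at which the
whole block is still a maximal-scoring segment for score
`total − d·span`); the block splits there and the recursion continues.
Break densities use base-distance denominators (the bases freed by the
split); reported cluster densities use the inclusive span
(end − start + 1).

Two non-obvious conventions were settled against the mathematical
definition (the set of clusters equals the union over all densities d of
the maximal-scoring segments, verified exhaustively against a
Ruzzo–Tompa-style enumeration on thousands of random instances):

* A visited block is only **emitted** when its density interval
  (`d_min`, min(`d_max`, own density)) is nonempty; the weak side of a
  split can be transitional — reached by the recursion yet maximal at no
  density — and is descended into without being emitted.
* Children inherit `max(d_min, d_max)` of their block as their `d_min`:
  a transitional block's children are still absorbed by coherent
  ancestors up to the ancestor threshold.

Single sites get the sentinels `d_min = 0` (at top level) and
`d_max = +∞`. Clusters form a laminar family and a child's maximality
interval starts where its parent's ends (`child.d_min ≥ parent.d_max`).
Note the cluster's *average* density is not monotone under nesting — an
isolated weak site can be maximal at high densities inside a denser
parent — so only the interval ordering is asserted.

### Companion filter and TSS peaks

The stability filter keeps clusters with `d_max/d_min ≥ 2`, total ≥ 30
tags and span ≤ 200 bp — the cluster caller's conventional companion
settings, each disableable, chosen because the procedure itself fixes
none. Surviving clusters from all groups are union-merged; merged peaks
wider than 300 bp are dropped, and peaks whose edge-to-point distance to
an annotated TSS is below 100 bp survive as TSS peaks. Reads are
assigned to a TSS peak when their 5′ start falls inside it.

### Stages, usage, switches

Pseudotime (an input, not estimated here) is cut into 10 equal-width
bins; bins 1–3 are the early stage, 4–7 medium, 8–10 late. Relative TSS
usage per (gene, group) is the read proportion of the gene's TSS total,
×100 and ceiled to an integer (so scaled usages sum to between 100 and
100 + n_TSS − 1). A (gene, group) is missing when the gene's total falls
strictly below the group's 0.5 quantile or strictly above its 0.99
quantile of per-gene totals, which controls for overall expression
differences.

Switches are tested per gene: Fisher's exact test on the 2×n table of
**scaled usage integers** for each pair of non-missing groups (the
scaling-to-integers step exists precisely to feed this test; raw-count
input is available as a switch), BH adjustment within the gene's
comparisons, and the minimum adjusted p reported. Per TSS, the reported
variance is the two-value sample variance (denominator 1) of the two
highest group usages — the convention is isolated in `top2_variance`.

## Statistical primitives

* **Rank-sum** (one-sided, "x greater"): exact by enumerating all
  C(n+m, n) assignments of pooled midranks when n + m ≤ 12 (ties
  handled by permuting the observed values), otherwise a tie-corrected
  normal approximation with continuity correction. The switchover is a
  configuration key; 12 keeps exact enumeration under a thousand
  assignments.
* **BH adjustment**: statsmodels' step-up implementation, validated
  against a from-the-definition oracle; inputs restricted to (0, 1].
* **Fisher 2×n**: two-sided under the "no more probable" convention (as
  in R's `fisher.test`), by vectorized enumeration of all first-row
  vectors with the observed margins when their count is ≤ 1e6, else a
  seeded Monte-Carlo estimate using the (b+1)/(B+1) estimator with 1e5
  replicates — never exactly zero, deterministic per seed. Observed-vs-
  candidate probability comparison uses a 1e-7 relative tolerance.
* **Diversity**: Shannon in natural-log units (the common default of
  repertoire tooling), inverse Simpson, and Chao1 with the
  bias-corrected fallback f1(f1−1)/2 when no doubletons exist. Shannon
  and inverse Simpson are scale-invariant; Chao1 depends on absolute
  counts and is documented as such.

## Synthetic data: what it emulates, and what it does not

Generator defaults mirror the study conditions the pipeline targets:
15,300 cells on 100,000 droplets, 96-plex preindex, a 1:1 two-species
mixture, and uniform per-cell depth. The toy genome is two chromosomes
of 4 Mb — the smallest size that holds the 1,000 disjoint 4-kb peak
windows of the enhancer suites plus the TSS gene grid with clean
separation between features.

* `gen_reads` places the round1 index at its configured location with
  optional truth-labelled off-whitelist mismatches. It emulates barcode
  structure only: no sequencing-error model, no quality variation.
* `gen_species_mix` collapses co-barcoded cells' counts exactly as a
  real collision would; with equal per-cell depth a spanning barcode
  can never reach a 90% majority, so calls match truth exactly — real
  data, with unequal depths and ambient RNA, is harsher.
* `gen_coverage` plants enhancer loci by adding core-concentrated reads
  (core density 5× background by default, i.e. 200 extra core reads
  over a 200-read uniform window background) on half the distal peaks;
  null peaks are uniform, hence exchangeable bins for the FDR check.
  Planted RPKMs are far above the gate, so the suites exercise the
  test, not the RPKM threshold.
* `gen_tss_tags` gives each gene two TSSs 300 bp apart (far enough that
  the enclosing cluster fails the 200-bp span filter and each TSS gets
  its own peak), 300 reads per gene per stage, ±2 bp positional jitter;
  switch genes move from 80/20 to 20/80 usage (a 60-point swap), null
  genes stay at 60/40.
* `gen_clonotypes` draws clone sizes from a truncated Zipf law
  (exponent 2.2) and plants round2-barcode duplications (2%) and
  unannotated barcodes (2%) to exercise the singlet filter.

Passing suites therefore demonstrate correctness of the implementations
under the stated statistical models — not robustness to ambient RNA,
barcode hopping, mapping artefacts, unequal cell depths or annotation
errors, none of which are modelled.

## Problem sizes and determinism

The acceptance script and suites run at 10⁵ simulated droplets, 10⁵
demultiplexed reads, 500 + 500 peaks, 200 + 200 genes and 2,000 T cells
— sizes at which every stochastic check sits several standard errors
from its threshold while the whole run stays desk-scale. A single seed
is expanded into independent per-generator substreams
(`numpy.random.SeedSequence`), so each stage is reproducible in
isolation and every reported number is a pure function of the seed.

## Known limitations

* Barcode error correction is out of scope by design (exact match only).
* The collision model ignores ambient RNA and barcode hopping (see
  above); observed collision rates in real data exceed the analytic
  expectation.
* Alignment, UMI collapsing, embedding/clustering, pseudotime
  estimation and V/J assembly are consumed as inputs, never computed.
* Fisher Monte-Carlo p-values are estimates; their resolution is
  1/(B+1) and tests comparing them to exact values allow 3 binomial
  standard errors.
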