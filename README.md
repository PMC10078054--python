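# fipkit

Processing toolkit for **preindexed droplet single-cell 5′ RNA-seq** —
assays in which cells are first labelled in wells with an indexed-Tn5
*round1* barcode (typically 96-plex) and then heavily overloaded onto a
droplet platform that adds the usual *round2* droplet barcode. The pair
(round2, round1) identifies a single cell, so a channel can be loaded
with far more cells than the standard workflow tolerates while keeping
the barcode-collision rate low.

The package is aimed at people analyzing such libraries (or designing
them): it covers everything downstream of alignment/UMI counting and
upstream of the usual Seurat/scanpy embedding steps.

## What it does

* **barcoding** — demultiplex read triplets by round1 index (exact
  match, no mismatches), merge per-index gene×barcode matrices into one
  matrix of composite-barcode cells (`ROUND2-ROUND1`), QC filtering
  (UMI / mitochondrial fraction / detected genes), and depth-sensitivity
  curves by binomial count thinning.
* **droplet_model** — Poisson loading theory and its Monte-Carlo twin.
  With λ = N/D cells per droplet, a cell-containing droplet is a
  multiplet with probability
  `1 − λe^(−λ)/(1 − e^(−λ))`,
  and with a B-plex preindex the expected fraction of composite barcodes
  formed by ≥2 cells (a *barcode collision*) follows by summing Poisson
  occupancy against same-index probabilities. Also: occupancy histograms
  keyed by droplet, and species-mixing calls (>90% / <10% rules).
* **erna** — call transcribed enhancers: among ATAC peaks >2 kb from any
  annotated TSS, bin the ±2 kb window around the peak center into 400
  10-bp bins, rank-test the 100 core bins (±500 bp) against the 300
  flanks one-sidedly, BH-adjust, and call eRNA where RPKM > 1 and
  adjusted p < 0.01.
* **tss_usage** — Paraclu-style density clustering of 5′ tag starts
  (clusters are segments maximal for score `total − d·span` at some
  density `d`), stability filtering, merging into TSS peaks near
  annotation, per-gene relative TSS usage (proportion ×100, ceiled) with
  quantile missingness, and per-gene TSS-switch testing via Fisher's
  exact test on 2×n usage tables with BH-adjusted minima across pairwise
  group comparisons.
* **repertoire** — TCR singlet filtering by cross-referencing round2
  barcodes against annotated RNA cells, paired (TRA, TRB) CDR3
  clonotypes, top-k clonal proportion, Shannon / inverse Simpson / Chao1
  diversity, and a Treg-composition "cancer index".
* **simulate** — seeded generators for every input above (reads with
  truth labels, species mixtures, coverage tracks with planted enhancer
  loci, per-stage TSS tag pileups with planted switches, clonotype
  tables), so the whole pipeline is testable without external data.
* **core_stats** — the shared primitives: one-sided rank-sum test (exact
  enumeration for small samples, tie-corrected normal approximation
  otherwise), BH step-up adjustment, Fisher's exact test on 2×n tables
  (full fixed-margin enumeration or seeded Monte Carlo), and the
  diversity indices.

## Worked example

How much overloading does the preindex buy? Load 15,300 cells on a
~100,000-droplet channel with a 96-plex preindex:

```python
from fipkit.droplet_model import (
    LoadingModel, conditional_multiplet_rate, expected_collision_rates,
)

m = LoadingModel(n_cells=15_300, n_droplets=100_000, plexity=96)
print(f"occupancy rate lambda: {m.occupancy_rate}")
print(f"multiplet rate (no preindex): {conditional_multiplet_rate(m):.4%}")
collision, mixed = expected_collision_rates(m, species_fractions=(0.5, 0.5))
print(f"barcode collision rate: {collision:.4%}")
print(f"observed mixed-species rate (1:1 mix): {mixed:.4%}")
```

prints

```
occupancy rate lambda: 0.153
multiplet rate (no preindex): 7.4550%
barcode collision rate: 0.0797%
observed mixed-species rate (1:1 mix): 0.0398%
```

Without the preindex, 7.5% of recovered cells would be multiplets; with
96 round1 indices the expected composite-barcode collision rate drops
by roughly two orders of magnitude, and only about half of those
collisions are visible in a 1:1 barnyard mixture (two same-species cells
colliding look pure). The same numbers are available from the CLI:

```bash
fipkit droplets -n 15300 -d 100000 -b 96
```

The other stages follow the same pattern — e.g. `fipkit sim reads`,
`fipkit demux`, `fipkit erna`, `fipkit tss call`, `fipkit vdj filter`
(see `fipkit --help`).

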