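# pantissue

Gene-centric co-expression analysis across tissues of shared individuals.

When the same individuals are profiled by bulk RNA-seq in many tissues —
as in multi-tissue population archives such as GTEx, or inbred mouse
panels such as the HMDP — the inter-individual correlation between a gene
in one organ and genes in every other organ carries information about
shared regulation and organ-to-organ (endocrine-style) signaling.
`pantissue` implements that analysis end to end for anyone with per-tissue
gene × individual expression matrices:

- **Seed-gene queries.** A gene in a seed tissue is correlated against
  every other gene-tissue combination with the *biweight midcorrelation*
  (bicor), a robust coefficient that down-weights observations far from
  the median: with `u_i = (x_i − med x)/(9·MAD x)` and Tukey weights
  `w_i = (1 − u_i²)² · 1(|u_i| < 1)`, the transformed values
  `x̃_i = (x_i − med x)·w_i` give `r = Σ x̃ỹ / (‖x̃‖‖ỹ‖)` over
  pairwise-complete individuals. Significance uses the Student transform
  `t = r√((n−2)/(1−r²))` with n−2 df, and one global Benjamini–Hochberg
  family yields q-values; tissue binning at q < 0.1 / 0.01 / 0.001 shows
  where the correlates concentrate.
- **Enrichment.** Preranked GSEA (weighted Kolmogorov–Smirnov running
  sum, bicor coefficients as rank weights, gene-label permutations) and
  hypergeometric overrepresentation of the top correlates, over GMT gene
  sets.
- **Cross-tissue connectivity.** Tissue × tissue counts of significant
  gene–gene correlations among a pathway's members, tissue rank-ordering,
  size-matched random-gene null draws, and a diagnostic correlating
  per-tissue missing-data burden with significant-gene counts.
- **Networks.** Seed-centered undirected graphs over the strongest
  within-tissue and peripheral correlates, with edges kept in a
  0.6 ≤ |r| ≤ 0.99 window (the upper bound removes duplicate
  transcripts), exported as TSV edge lists and GraphML.
- **Deconvolution.** Cell-type proportions per individual from a
  marker × cell-type signature by simplex-constrained least squares
  (`min ‖Af − b‖², f ≥ 0, Σf = 1`), and bicor of inferred abundances
  against any gene.
- **Traits.** Ranked clinical-trait correlations for a gene-tissue pair,
  with a strain-mean mode for inbred panels, plus sex/age group summaries
  with rank-sum tests.
- **Simulator.** A ground-truth generator emulating the archive shape:
  shared individuals, block missingness, gross outliers, planted
  latent-factor modules and pathways, cell-type mixtures and linked
  traits — every pipeline stage is testable without external data.

## Worked example

```python
from pantissue import (PlantedSignal, SimulationConfig, seed_gene_query,
                       simulate_archive, tissue_binning)

cfg = SimulationConfig(
    seed=1, signals=(PlantedSignal("adipose", "SEED", "liver", 50, 0.8),))
tensor, metadata, traits, truth = simulate_archive(cfg)

table = seed_gene_query(tensor, "adipose", "SEED")
binning = tissue_binning(table)
```

This simulates 300 individuals across five tissues of 1,000 genes each,
with an adipose seed gene whose latent factor drives a 50-gene liver
module at ρ = 0.8, then queries the seed. `examples/01_seed_gene_query.py`
prints, for the q < 0.1 threshold:

```
q < 0.1: 55 significant genes
  adipose       1  1.8%
  heart         0  0.0%
  intestine     2  3.6%
  liver        52  94.5%
  muscle       0  0.0%
```

All 50 planted liver genes are recovered (plus a handful of false
positives at the loosest threshold), and the binning localizes ~95% of
significant correlates to the target tissue — the pie-chart view of where
the seed gene's covariation lives. The other scripts in `examples/`
demonstrate enrichment, connectivity nulls, networks, deconvolution and
trait ranking the same way, each printing the numbers it computes and a
line on what they mean. The `pantissue` command-line tool composes the
same operations over TSV/GMT inputs (`pantissue --help`).

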