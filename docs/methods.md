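# Methods

This note documents the statistical procedures `pantissue` implements,
the defaults it ships, the design choices that were genuinely open, and
what the synthetic-data generator does and does not emulate.

## Data model

An archive is a set of tissues, each a gene × individual matrix, all
aligned on one shared, ordered individual index. Individuals absent from
a tissue are kept as explicit all-NaN columns rather than dropped: every
downstream statistic is pairwise-complete, and per-pair sample sizes
(`n_used`) are first-class outputs because multi-tissue archives have
strongly overlapping but unequal donor sets per tissue. Individuals are
matched by exact string identity after whitespace trimming — a silent
fuzzy match is worse than a hard error. Gene identifiers are opaque,
case-sensitive strings; no symbol/accession mapping is attempted.

A detection filter is available (off by default in the library, a flag in
the CLI): within each tissue a gene is kept only if every *non-missing*
value is strictly positive. This is the count-detection convention for
population archives — it suppresses genes expressed in only a few
individuals of a few tissues, which otherwise dominate cross-tissue
significance tails. Missing values do not disqualify a gene. The filter
is idempotent. Expression units are taken as provided; the mixture model
in deconvolution additionally *requires* linear-scale values (mixing is
linear in transcript abundance, not in log abundance).

## Robust correlation core

The biweight midcorrelation down-weights observations far from the
median. For each vector, deviations from the median are scaled by nine
times the unscaled median absolute deviation; Tukey biweights
`(1 − u²)²` are applied inside the unit window and zero outside; the
correlation is the normalized inner product of the transformed vectors,
over complete pairs only. Degenerate cases:

- MAD = 0 (more than half the values tied): the weighting is undefined,
  so that vector falls back to plain mean-centering with unit weights
  (Pearson-style) and the result carries a `fallback` flag.
- Fewer than `min_n` complete pairs (default 10): the coefficient is
  reported undefined (NaN), never raised as an error. The default is a
  tool choice balancing the t-approximation's stability against data
  loss; it is configurable everywhere it appears.
- Transformed norm 0 (constant vector): undefined, flagged.

The matrix form groups gene rows by their missingness pattern, so
archives with block missingness reduce to a handful of dense matrix
products while preserving exact pairwise-complete semantics (each pair's
biweight transform is recomputed on the shared column subset).

Two-sided p-values use `t = r√((n−2)/(1−r²))` against Student's t with
n−2 df; |r| = 1 maps to p = 0 by convention and n < 3 is undefined.
q-values are Benjamini–Hochberg step-up, implemented directly with the
definition's `p·m/j` arithmetic; NaN p-values are excluded from the
family size and returned NaN.

## Seed-gene query and binning

A query correlates the seed vector against every gene in every tissue,
excluding only the identical (seed tissue, seed gene) pair — the same
gene ID in *other* tissues is a legitimate cross-tissue correlate. Rows
whose coefficient is undefined or whose complete-pair count falls below
`min_n` are dropped entirely, so the returned table and the BH family
coincide; q is computed once, globally across tissues, because the
tissue binning compares tissues on a single q scale (per-tissue families
would distort the shares). This global-family choice is the main place
where another convention is defensible; it is a visible default, not
buried behavior. Binning counts rows passing q < 0.1, 0.01, 0.001 per
tissue and normalizes to fractions within each level; a level with no
passing rows reports its fractions as undefined rather than zeros.

## Enrichment

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum with
weight exponent 1: hits increment by `|w|/Σ_hits|w|`, misses decrement by
`1/(L−K)`, and the enrichment score is the extremum of largest magnitude
(ties broken toward the positive extremum, with a 1e-12 tolerance so
summation-order noise cannot flip the sign). If all hit weights are zero
the increments degrade to uniform `1/K`. The null permutes gene labels —
the set lands on K uniformly random positions and inherits the list's
weights there — matching preranked semantics where the ranked list, not
the sample labels, is the input. The p-value is sign-matched with +1
smoothing, `p = (1 + #{same-sign |ES*| ≥ |ES|})/(1 + #same-sign)`, and
tail comparisons carry the same 1e-12 tolerance so exactly-tied
permutation scores count as exceedances. NES divides ES by the mean
|ES*| of same-sign permutations. Sets with fewer than 5 or more than
2,000 members in the universe, or covering the whole list, are skipped
and reported untested. Defaults (exponent 1, min/max set size) are
conventional for the weighted statistic and configurable.

Overrepresentation uses the exact upper-tail hypergeometric probability
P(X ≥ k) for the overlap k between a selection (by default the top-500
genes of a tissue by |bicor|) and each set, against the background of all
genes tested in that tissue; BH across sets.

## Cross-tissue connectivity

For a pathway, every gene–gene bicor among its members is computed for
every tissue pair. Two counting modes exist because the two natural
summaries answer different questions: `pairs` counts significant
correlations (the heatmap view; within-tissue diagonal omitted by
default), `genes` counts distinct gene nodes touched by at least one
significant correlation (the ranking view). Within a tissue,
self-correlations are excluded and unordered pairs counted once; across
tissues all pairs count, including the same gene ID on both sides (it is
a genuine cross-tissue pair). Normalization divides by the pathway's
gene count. Thresholds apply to the Student p by default; a q mode forms
one BH family over the whole grid first. The random-gene null redraws
size-matched gene sets per tissue and recomputes the identical statistic;
100 draws is the default (compute-bounded, configurable), and the
observed-vs-95th-percentile comparison is the headline readout.

The sparsity diagnostic asks whether tissues that look poorly connected
are simply poorly measured: per-tissue missing burden (mean NA entries
per individual) is correlated, with bicor, against per-(tissue, pathway)
significant-gene counts within a tertile of the tissue ranking. Pathways
are stacked within the tertile — the aggregation across pathways was an
open choice; stacking keeps per-pathway variation visible while the
burden enters per tissue. Zero variance in either vector yields a
flagged undefined result.

## Networks

Node selection takes the top `n_within` seed-tissue and `n_peripheral`
other-tissue correlates by |r| to the seed; edges are then computed
between **all** node pairs, not just seed spokes — the interesting
topology is the inter-correlate structure. The window
0.6 ≤ |r| ≤ 0.99 applies to the absolute coefficient, so strong negative
correlations form (sign-labelled) edges; applying it to signed r was the
alternative, but negative edges are meaningful and their exclusion would
be silent. The upper bound exists to drop duplicate/identical
transcripts (r = 1.0). Graphs are simple and undirected; exports are a
TSV edge list and GraphML with tissue/gene node attributes.

## Deconvolution

Per individual, proportions solve `min ‖Af − b‖²` over the simplex on the
marker-gene intersection (required to exceed 2× the number of cell
types). Because a hard sum-to-one constraint cannot absorb an arbitrary
overall scale of the bulk column, the solver first runs an unconstrained
non-negative least squares to estimate the scale c = Σf, rescales the
bulk by 1/c, and then solves the simplex-constrained problem via NNLS on
an augmented system (a heavily weighted all-ones row), renormalizing to
machine precision. This makes proportions exactly invariant to positive
rescaling of the bulk — which is the correct behavior for a composition
— and satisfies the simplex constraints to 1e-8. The per-individual
residual ‖Af − b/c‖ is reported as a fit diagnostic. Abundance–gene
association reuses bicor with BH across cell types; constant abundance
columns are flagged undefined.

## Traits and group summaries

Every trait is correlated (bicor, pairwise-complete per trait) against
the gene's expression over the shared IDs; traits are ranked by p (the
significance ordering, not |r|), BH-adjusted, and the top-k returned as a
prefix of the full table with positive/negative direction labels. The
strain mode averages individuals to strain means before correlating, for
inbred panels where the strain is the unit of replication. Group
summaries report per-group n/mean/sd and attach a two-sided
Mann–Whitney rank-sum p only when exactly two groups carry data.

## Synthetic data

The generator's defaults are the package's reference study conditions:
300 individuals, five tissues of 1,000 background genes, unit noise SD.
Planted structure uses the latent-factor construction
`x = √ρ·z + √(1−ρ)·ε`, which gives an exact population correlation ρ
between any two members of a module (and the seed) at O(genes) cost and
is analytically checkable. Order of construction: correlation structure,
then outlier contamination (entries shifted by ±κ·σ, κ = 8 by default —
beyond the 9-MAD biweight window), then block missingness (whole
individuals removed from a tissue, the way donors are absent from
archive tissues; the count is exactly `round(fraction · n)`). Metadata
draws sex labels at the 210:100 male:female ratio of the reference human
archive and decade age groups over 20–79. Traits are linear in the
standardized expression of their linked gene-tissue pair plus unit
noise. Signatures give each cell type an equal block of markers at ~20×
baseline with lognormal jitter; bulk mixtures are signature·proportions
plus Gaussian noise.

What the generator does **not** emulate: count-level sampling (negative
binomial reads, library size), genetic architecture (eQTLs, relatedness),
sex- or age-specific effects beyond labels, correlated background
structure, and compositional coupling between cell-type proportions and
the tissue's own expression. Passing tests therefore demonstrate that the
machinery recovers the statistical structure it targets under clean
Gaussian conditions with realistic missingness and outliers — not that
real archives satisfy those conditions.

## Numerical choices and limitations

- Coefficients are clipped to [−1, 1] after the inner product; p-values
  to [0, 1].
- Median of an even number of values is the midpoint average.
- Rank ties in `rank_genes` break lexicographically by gene ID, so
  rankings are reproducible across runs and platforms.
- Problem sizes in the test suite and acceptance script (e.g. 150–300
  individuals, hundreds to a thousand genes per tissue, 50–100 null
  draws) are the package's desk-scale reference conditions; all scale
  parameters are plain arguments.
- The robustness comparison with Pearson (one 10-SD outlier in 100
  points) favors bicor in the large majority of draws but is not a
  theorem: when the contaminated point happens to fall near the Pearson
  regression line, Pearson can move less than the reweighted
  coefficient.
- Correlation-based results conflate causal and reactive covariation;
  nothing here infers direction. Mediation, genetic correlation and
  module-based (eigengene) methods are intentionally out of scope.
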