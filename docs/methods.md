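# Methods

## Model of the data

A parallel knockout screen is a matrix **X** of effect sizes with genes as
rows and cell lines as columns (unitless; more negative = stronger growth
defect). We model each observed gene profile as a sum of (i) a per-gene
baseline essentiality, (ii) a small number of *confounder signatures* —
directions in cell-line space that act on every gene with gene-specific
susceptibility, capturing screen-quality and Cas9-toxicity variation —
(iii) for functionally coupled genes, shared biological factors, and (iv)
independent noise. Control genes (olfactory receptors, curated nonessential
genes) are assumed phenotype-free: they carry confounders and noise only.
Correlation between corrected profiles is then the evidence for functional
coupling.

## Confounder correction

PCA is computed on the control submatrix with control genes as
*observations* and cell lines as *variables*; each cell-line column is
centered by its mean over controls. This orientation is forced by what the
components must be: a single number per cell line that predicts nonspecific
essentiality genome-wide, comparable across different control sets.
Centering by cell-line means (rather than by gene means) lets the leading
component absorb the shared mean-essentiality direction, which is part of
the nonspecific signal; correction consequently removes per-gene mean
information, which does not affect correlation-based calling.

The number of significant components is chosen by a permutation scheme in
the parallel-analysis family: effect sizes are shuffled independently
within each cell-line column (preserving each screen's marginal
distribution while destroying cross-gene covariance), per-rank variance
fractions are recomputed for each of `n_perm` (default 100) permutations,
and the selected rank *k* is the longest prefix of ranks where the true
fraction strictly exceeds the per-rank **maximum** over all permutations.
Comparing to the max rather than a quantile is the conservative reading of
"exceeds all permutations"; the prefix rule stops at the first failure so a
noise rank can never be skipped over.

Correction projects the k-dimensional orthonormal basis **V** out of every
raw (uncentered) gene profile, controls included:
**x** → **x** − **V**(**Vᵀx**). The map is an exact orthogonal projection:
idempotent, and corrected profiles satisfy |**Vᵀx**| < 1e-8 (enforced in
tests at that tolerance; component signs are fixed by making each column's
largest-magnitude entry positive, since eigenvector signs are arbitrary).

## Empirical null and edge calling

The null distribution of corrected-profile correlations is estimated from
the controls themselves, with cross-validation to avoid the deflation that
correcting controls with a basis fit on those same controls would cause:
controls are split into `n_folds` (default 5) seeded folds; for each fold a
basis of the same rank *k* is fit on the other folds only; held-out
controls are corrected with it; and all within-fold pairwise correlations
are pooled. The null is N(0, σ) with σ = RMS of the pooled correlations
(the mean is fixed at zero rather than estimated — the null is symmetric by
construction). The basis used for genome-wide correction is fit on *all*
controls; cross-validation exists only for σ.

Every tested unordered gene pair receives a two-sided p-value
p = 2(1 − Φ(|r|/σ)) — both correlation signs are eligible — and
Benjamini–Hochberg q-values across all tested pairs; q ≤ FDR (default
10%) defines a co-functional edge. Genes whose corrected profile has zero
variance are dropped with a warning before correlation. On pure-noise
screens σ converges to the analytic null s.d. of a Pearson correlation,
(n_cells − 1)^(−1/2), and non-control p-values are uniform; both are
asserted in the acceptance tests.

## Network, communities, topology

Called edges form an undirected simple graph over all tested genes
(isolates included) with weight |r| and distance 1 − |r|; negative-r edges
participate through |r| with the sign kept as metadata. Communities come
from Infomap (the map equation) with |r| as flow, best of `trials`
(default 10) seeded runs by codelength; isolates become singletons.
Centrality is *local closeness*: within each community's induced subgraph,
the reciprocal of the summed weighted shortest-path distance from a gene to
its reachable co-members. Restricting paths to the community keeps core
essential genes from dominating every centrality score; genes disconnected
within their community are reported missing rather than penalized with
infinities.

Community summaries report size, internal edge density, mean member
knockout effect, and census-gene counts; community pairs are flagged when
their inter-community edge frequency (observed inter-edges / size_a ×
size_b) exceeds the network-wide pair-calling rate; communities above 100
genes with more than half their members on one chromosome are flagged as
likely proximity artifacts. Census enrichment per community is a one-sided
binomial upper tail with success probability equal to the global census
fraction, BH-corrected across communities.

Each community of at least `min_size` (default 8) members is summarized per
cell line by the first principal component of its members' corrected
profiles (cell lines as observations, per-gene means removed). Loadings are
unit-norm and sign-fixed so their mean is nonnegative, making high scores
mean "this cell line drives the community's knockout phenotype".

## Enrichment statistics

Aggregate enrichment of co-annotated pairs is log2((e_fc/e_c)/(e_f/e)),
where e counts all pairs in the universe, e_f co-functional pairs, e_c
co-annotated pairs and e_fc both. Per-set significance uses a
degree-matched permutation test: tested genes are placed in equal-occupancy
degree bins (`n_bins`, default 100, with zero-degree genes as their own
bin), and each permutation redraws every set member uniformly from its bin
without replacement within the set; the null statistic is the redrawn set's
subgraph edge count. Sets with fewer than `min_edges` (default 5) observed
edges are excluded. p follows the add-one convention
(1 + #{perm ≥ obs})/(1 + n_perm), floored at 0.5/n_perm when no permutation
reaches the observed count; BH at 5% by default. The bin count must be well
below the number of positive-degree genes or bins degenerate to singletons
and the permutation becomes the identity — desk-scale analyses should pass
an `n_bins` matched to their network (the tests use 8–10 bins for networks
with ~100–300 connected genes).

Stratified call rates (`rate_by_stratum`) serve several comparisons with
one operation — reference-network path-length bins (shortest paths on a
user-supplied edge list, "Inf" for separate components), annotation
confidence bins, genomic distance, complex size — reporting per stratum the
call rate and the negative-sign fraction among calls. Per-complex
expectations use Binomial(m, rate) over a complex's m pairs with the
central 90% interval.

## Associations

Drug–gene correlation uses complete-case pairing per drug over shared cell
lines (≥10 required; no imputation of response values), returning the full
table plus the top-N by |r| (4 for network display, 30 for enrichment, by
convention). Label prediction scores every unordered pair of cell lines by
the correlation of their profile columns and computes AUC with midrank tie
handling. Response binarization is an exact 1-D two-means: the optimal
partition is an interval split, found by scanning boundaries between
distinct sorted values; the lower-mean cluster is labeled "sensitive".
Mutation-vs-loading tests use the two-sided Wilcoxon rank-sum (exact for
small tie-free groups, normal approximation with tie correction otherwise;
≥3 lines per group), BH across genes.

## Synthetic screens

The generator draws X[g,c] = μ_g + Σ_j s_gj·L_j[c] + Σ_m a_gm·B_m[c] +
ε[g,c], with confounder factors L_j and module factors B_m i.i.d. standard
normal across cell lines, susceptibilities s_gj ~ N(0, confounder_strength²)
per gene, baselines μ_g ~ N(0, gene_mean_sd²), and Gaussian noise (a
Student-t switch exists for robustness checks). Design choices:

- Controls are phenotype-free by construction: zero module loading *and*
  zero baseline, confounders + noise only. This is the premise that lets
  control-learned components transfer genome-wide, and it means the mean-
  essentiality direction of the biology genes is not a control component.
- Module members load on their factor with a fixed coefficient equal to the
  stated effect size, so the per-cell contribution of the factor has
  exactly that standard deviation for every member. A random per-member
  loading would make module membership heterogeneous and recovery targets
  meaningless for low-draw members.
- Genes belong to at most one module, keeping truth edges unambiguous.

Default conditions (used by the test suite and the acceptance script):
1,000 genes of which 250 controls, 200 cell lines, two confounders at
strength 1 (susceptibility s.d. equal to the noise s.d.), ten modules of
ten genes at effect 0.8, baseline s.d. 0.5, noise s.d. 1. In this regime
the expected within-module correlation after perfect correction is
0.64/1.64 ≈ 0.39 against a null σ ≈ 1/√199 ≈ 0.071, so calling is powered
but not trivial; without correction the confounded null (σ ≈ 0.4) swamps
the signal entirely, reproducing the corrected-vs-raw discovery contrast
qualitatively. Problem sizes throughout the tests (hundreds of genes,
50–400 cell lines) were chosen as the smallest at which the statistical
regimes of interest are unambiguous.

What the generator does *not* emulate: copy-number artifacts and guide-level
structure (the input is assumed CERES-corrected), heavy-tailed screen
failures, gene-gene overlap of modules, non-Gaussian confounder loadings,
and the physical-proximity correlation of real screens. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not performance on any particular real release.

## Numerical choices and edge cases

- Orthonormality and projection tolerances: 1e-8; idempotence: 1e-10;
  eigensolver defaults otherwise (LAPACK SVD via numpy).
- p-values are clipped to the smallest positive float so p ∈ (0, 1].
- |r| = 1 edges have distance 0; closeness can then be infinite within a
  clique of perfectly correlated genes (reported as inf, not an error).
- Gene symbols are uppercased and `"(Entrez)"` suffixes stripped on read;
  collisions after stripping are an error, never a silent merge.
- Matrix orientation auto-detection uses cell-line id patterns (ACH-…)
  first and a >5× shape ratio as fallback; square ambiguous files are an
  error listing both candidate shapes.
- Missing effect values default to dropping the gene (logged); mean
  imputation is available. Controls missing from the guide map are kept
  with a warning — guide dedup is a conservative filter.
- Guide dedup collapses each connected component of the guide-sharing graph
  to one seeded-uniform survivor; deterministic given the seed, idempotent.

## Known limitations

- The Gaussian null is fit to control correlations; heavy-tailed deviations
  of real screens from normality would make tail p-values approximate.
- Permutation selection compares against the max over permutations; with
  very few permutations the threshold is noisy (100 is the default for the
  stated guarantee).
- The degree-matched test treats sets independently; multiplicity across
  strongly overlapping sets is handled only through BH.
- Full-scale (17k-gene) pair tables are materialized in memory by the
  convenience API; the blockwise correlation core supports streaming, but
  a streaming BH pass is not implemented.
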