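# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what the synthetic-data tests do and do not show.

## Statistical conventions

* **z-transformation** standardises each gene row to mean 0 and sample
  standard deviation 1 (denominator n−1). Constant rows map to all-zero
  rows rather than erroring, so flat genes cannot poison signature scores.
  Standardisation is per cohort by default (each cohort's own mean/sd),
  with a pooled mode available; the per-cohort default matches the
  anchor-split convention, which is also per cohort.
* **Spearman correlation** uses average ranks for ties. Two-sided p-values
  come from the t approximation for n ≥ 10 and from exact enumeration of
  all n! pairings for n < 10. A constant vector leaves ρ undefined: the
  result carries NaN and a warning instead of raising, because constant
  genes are a data property, not a caller error.
* **Normalisation** of bulk counts is median-of-ratios: the reference is
  the per-gene geometric mean over genes with all-positive counts, the
  size factor a sample's median count/reference ratio (linear-space
  median), followed by log₂(x+1). If no gene has all-positive counts the
  code falls back to library-size factors scaled to geometric mean 1, with
  a warning.

## Differential expression and the derivation chain

The DE engine is a per-gene Welch t-test on the log-normalised values.
This is a deliberate divergence from count-model DE: the gene-inclusion
rule downstream consumes only "nominal p < 0.05 plus direction", and the
derivation is validated by planted-module recovery, not by effect-size
estimates. Degenerate genes (zero variance in both groups) receive p = 1
when the group means agree and the smallest positive float when they
separate exactly. A Benjamini–Hochberg FDR column is reported for
information only; the DEG definition itself is nominal.

"Upregulated" means log₂FC > 0 in anchor-high samples of *both* cohorts.
The anchor split labels a sample high when its normalised anchor
expression is strictly above the cohort mean; equality goes to low.

The correlation filter starts from the TF-constrained candidates and
repeatedly drops the gene with the lowest mean Spearman ρ against the
anchor plus the remaining candidates (ties broken lexicographically)
until every survivor has ρ ≥ ρ_min with the anchor and mean pairwise
ρ ≥ ρ_min. ρ_min defaults to 0.4: cohort-wide signature–anchor
correlations of 0.65–0.80 are reported for the real cohorts but no
gene-inclusion cutoff is published, so 0.4 is a conservative exposed
parameter, not a reproduction claim. By default a gene must survive the
filter in each cohort separately; a pooled mode filters once on the
concatenated per-cohort z-scores. Undefined correlations (constant rows)
count as 0 in the filter.

K-means co-expression clustering of z-scored gene rows (k-means++, 25
restarts, seeded; k defaults to 6) is reporting-only: the derivation
chain itself is the DE → intersection → TF → correlation composition and
does not consume cluster membership.

## The min/max-point line and stratification

The stratification reference is not a least-squares fit: it is the line
through the componentwise extremes (max x, max y) and (min x, min y) of
the (MetSig, anchor-z) pairs. The componentwise reading is total (always
defined when the x-range is positive) and coincides with the
extreme-sample reading whenever the x and y extremes co-occur. The anchor
is the predicted variable (y) by default. A sample is inside when
|predicted − observed| < threshold with a *strict* inequality; the
threshold defaults to 1.0 on the z-scored anchor scale, where "less than
1" and "within one standard deviation" are the same statement — that
equivalence holds only on a standardised scale, which is why scoring
z-transforms the anchor before the line is fitted.

The extreme-point construction is noise-sensitive by design: two extreme
order statistics per axis determine the line, so a single outlying draw
can tilt it. The planted-truth tests quantify how much misclassification
this costs under the generator's conditions (~2–3 % of samples); users
with heavy-tailed scores should expect more.

The clinical association is the Spearman of (MetSig, DAS28) on the inside
subset only, with the inside fraction and an inside-vs-outside Wilcoxon
rank-sum comparison of MetSig reported alongside (two-sided, via the
Mann–Whitney U implementation, which is the same test). Fewer than three
inside samples leaves the correlation undefined and flagged. The
genome-wide screen reports genes with |ρ| > 0.5 against DAS28,
partitioned into direct and inverse hits.

## Single-cell stage

Cells are retained with 500–4,500 detected features and ≤ 20 %
mitochondrial counts (the standard exclusion reading of those canonical
cut-offs); per-criterion removal counts are logged. Normalisation is
counts-per-10⁴ with natural log1p. Clustering is PCA (top 2,000 genes by
variance, unit-scaled, 10 components by default) followed by seeded
k-means with 25 restarts, k = 15 by default; the graph/UMAP pipeline of
typical single-cell toolkits is intentionally replaced by this explicit,
seedable procedure because downstream only the labels and k are consumed.

A cluster's signature score is Σ_g (aggregate expression of g in the
cluster) / n_cells — computed on log-normalised values by default (a
raw-counts mode exists; the original convention is unstated). The arg-max
cluster is flagged high; ties within 1e-9 flag every tied cluster, and if
the signature-high and anchor-high clusters disagree both rankings are
reported rather than resolved. Markers of a cluster are called against
all remaining cells by a two-sided Wilcoxon rank-sum on log-normalised
values after pre-filtering on |log₂FC| > 0.25 (expm1-mean convention with
ε = 1e-9) and detection ≥ 25 % in at least one group; Bonferroni-adjusted
p-values accompany the nominal ones.

## The synthetic-data generator

**Bulk.** Each sample carries a latent factor L ~ N(0,1); gene g has NB
counts with log-mean b_g + β_g·L (β = 1 for the anchor and the 20 module
genes by default, 0 otherwise) and size parameter 10 (variance
μ + μ²/10; size = ∞ switches to Poisson). Baselines b_g are uniform on
(3, 7) natural-log units (≈ 20–1,100 counts); the anchor's baseline is
pinned to the top of that range because the anchor is modelled as an
abundantly expressed gene, whose log-scale noise should reflect biological
dispersion rather than shot noise. The generator has two regimes:

* *Coupled* (tracked_fraction = 1): every sample's anchor follows the
  module. Derivation experiments use this regime — the anchor-split DE
  chain presumes the co-expression structure holds cohort-wide.
* *Mixed* (tracked_fraction = 0.5 by default): untracked samples have the
  anchor log-mean displaced by outlier_offset (default 2.0) *toward the
  cohort mean* (−offset·sign(L)). The direction is a modelling choice with
  two motivations: it keeps the anchor's marginal level comparable between
  tracked and untracked groups, as observed for the real anchor, and it
  keeps the pooled anchor variance near 1 so the planted departure
  survives standardisation — an outward or random-sign displacement is
  provably compressed below √2 z-units by pooled z-scoring no matter how
  large the offset. The cost of this choice is that untracked anchors
  anti-correlate with L, which is exactly why derivation uses the coupled
  regime.

DAS28 is 5.0 + slope·(standardised module score) + N(0, σ) for tracked
samples (defaults slope = 1, σ = 0.72, implying a population Spearman of
≈ 0.80, the strength reported for the tracked patient subset) and
matched-variance independent noise for untracked samples, clipped to
[0, 10]. The truth object carries both the analytic Spearman target and
the correlation actually realised in the generated dataset; recovery
tests compare against the realised value, which isolates pipeline error
from the generator's own sampling noise at n ≈ 50.

**Single cell.** Per-gene baseline means are drawn once (log-normal,
median ≈ 1 count) and shared across clusters, so cluster differences are
purely the planted folds: 40 marker genes per cluster at 4-fold, the six
signature genes plus the anchor at signature_fold (default 3) in the
designated high cluster, 13 "MT-" genes, and constructed QC violators
(alternately 20× down-scaled cells that fail the feature floor, and
25×-mito cells that fail the mitochondrial cap). 1,500 genes keep normal
cells' feature counts (~700–800) inside the 500–4,500 QC window. The
40-marker default is what makes the planted populations separable: with
many fewer markers the cluster-signal eigenvalues fall below the
random-matrix detection edge at 300 cells and k-means recovers nothing.

**What the generator does not emulate:** library-size confounding, batch
effects, doublets, gene–gene correlation beyond the single latent factor,
and zero-inflation beyond what the NB produces. Passing tests therefore
show the pipeline's logic is correct under the planted model, not that it
is robust to those real-data features.

## Problem sizes and determinism

Tests and the acceptance script run the stochastic checks at the sizes
stated in their docstrings (bulk: 100 samples × 2,000 genes; derivation:
2 × 60 samples × 2,000 genes; single cell: 300 cells × 1,500 genes; 10–20
replicate seeds), chosen so a full run completes in well under a minute
on one CPU while keeping recovery rates stable. Every stochastic
component is seeded; the pipeline orchestrator fans a single global seed
into per-stage child seeds by a fixed derivation, and identical
(config, seed) pairs produce byte-identical reports.

## Known limitations

* The Welch-test DE stage is not a count-model DE; at very low counts or
  tiny groups its calibration degrades before a negative-binomial GLM's
  would.
* The min/max-point line inherits the variance of extreme order
  statistics; it is faithful to the published procedure, not a recommended
  estimator.
* The correlation filter's greedy pruning is order-deterministic but not
  globally optimal; with strongly blocked correlation structures it can
  drop a valid gene before a worse one.
* Single-cell clustering assumes roughly spherical clusters in PC space;
  k is a parameter, not estimated.
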