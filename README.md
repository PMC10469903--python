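# metsig

Derivation, scoring and clinical stratification of an anchor-correlated
metabolic gene signature ("MetSig") in bulk and single-cell RNA-seq, with a
synthetic-data generator that plants the statistical structure the analysis
assumes.

The package is aimed at translational transcriptomics: situations where a
gene signature is defined relative to an *anchor gene* — here CDC42, a
Rho-GTPase of blood CD14⁺ monocytes in rheumatoid arthritis — and the
question is which patients' clinical disease activity tracks that
signature.

## The method

**Signature derivation (two cohorts).** Samples of each cohort are split at
the cohort mean of the anchor's normalised expression (median-of-ratios
size factors, log₂(x+1)). Genes with nominal Welch-test p < 0.05 and
positive log₂ fold change in anchor-high samples of *both* cohorts are
intersected, restricted to transcriptional targets of a named TF set
(NFE2L1, HOXA2, NFRKB by default, supplied as a GMT file), and pruned by an
iterative Spearman filter until every remaining gene satisfies
ρ(gene, anchor) ≥ ρ_min and mean pairwise ρ ≥ ρ_min. The published
six-gene signature (*ATP5BP, COX7A2, PSMB6, PSME3, GTF3C6, GTF2E2*, anchor
*CDC42*) ships as a built-in.

**Scoring.** For sample *i*, MetSig_i = Σ_g z_{g,i} over signature genes,
where z is the per-gene (ddof = 1) standardisation within a cohort; the
anchor's z-score is carried alongside.

**Stratification (min/max-point line).** The reference line joins the
componentwise extremes (max MetSig, max anchor-z) and (min MetSig, min
anchor-z). A sample is *inside* (MetSigʰⁱ, signature-tracked) when
|predicted − observed anchor-z| < 1, strictly — one standard deviation on
the standardised anchor scale. The Spearman correlation between MetSig and
the DAS28 disease-activity score is then computed on the inside subset
only, with an inside-vs-outside Wilcoxon rank-sum comparison of MetSig.

**Single-cell projection.** Cells pass QC with 500–4,500 detected features
and ≤ 20 % mitochondrial counts, are depth-normalised (counts per 10⁴,
log1p), clustered (PCA + seeded k-means), and each cluster is scored by the
summed per-cell-mean aggregate expression of the signature genes; the
arg-max cluster is flagged signature-high and its markers are called by a
two-sided Wilcoxon rank-sum test with |log₂FC| > 0.25 and ≥ 25 % detection.

**Synthetic data.** `simulate_bulk_cohort` draws negative-binomial counts
whose log-means are linear in a latent per-sample factor shared by the
anchor and a planted gene module; a configurable fraction of samples is
"tracked" (anchor coupled to the module) and the rest have the anchor
displaced off the module–anchor line; DAS28 is linear in the module score
for tracked samples. `simulate_sc_dataset` plants clustered cell
populations, a signature-high cluster, 4-fold marker genes, mitochondrial
genes and constructed QC violators. Both return ground truth for testing.

## Worked example

```bash
printf 'sc_k: 5\n' > demo.yaml
metsig run --config demo.yaml --seed 7
```

simulates two coupled derivation cohorts, two mixed evaluation cohorts and
a single-cell dataset, derives the signature, scores and stratifies the
patients, and prints the run report (also written to `metsig_run/`):

```json
"bulk": {
  "anchor": "CDC42",
  "planted_module_recall": 1.0,
  "false_genes": 0,
  "per_cohort": {
    "A": {"accuracy_vs_truth": 0.99, "clinical_rho": 0.736939,
          "inside_fraction": 0.49, "planted_clinical_rho": 0.797974},
    "B": {"accuracy_vs_truth": 0.96, "clinical_rho": 0.526358,
          "inside_fraction": 0.54}
  },
  "pooled_inside_fraction": 0.515
}
```

Reading: the derivation chain recovered all 20 planted module genes with no
false gene; about half of each evaluation cohort lies inside the
min/max-point line (the simulated tracked fraction is 0.5) and the
inside/outside call agrees with the planted truth for 96–99 % of samples;
the MetSig–DAS28 Spearman correlation recovered on the inside subset of
cohort A is 0.74 against a planted 0.80. The `single_cell` block reports
293/300 cells surviving QC (7 constructed violators), the signature-high
cluster and its marker count.

Per-stage commands (`metsig simulate-bulk`, `derive-signature`, `score`,
`stratify`, `clin-screen`, `simulate-sc`, `sc-score`) expose the same
stages on TSV/CSV/GMT/matrix-market files; see `metsig --help`.

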