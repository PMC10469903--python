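"""Synthetic bulk cohorts and single-cell datasets with planted structure.

The bulk generator emulates the study design the analysis assumes: a latent
per-sample factor drives both an anchor gene and a co-expressed gene module
on the log scale of negative-binomial counts.  A "tracked" subset of samples
keeps the anchor coupled to the module; in the remaining samples the anchor
log-mean is displaced by ``outlier_offset`` toward the cohort mean, so they
depart from the module–anchor line while the anchor's marginal level stays
comparable between groups (as observed for CDC42 in the study population).
A clinical disease-activity score (DAS28-like, 0–10) is linear in the
standardised module score for tracked samples and pure noise otherwise.

The single-cell generator plants ``k_clusters`` cell populations, one of
which ("hi") has the six signature genes and the anchor elevated
``signature_fold``-fold, per-cluster 4-fold marker genes, mitochondrial
genes with an ``MT-`` prefix, and a constructed set of QC-violating cells
(too few detected features, or >20% mitochondrial counts).

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .datamodel import METSIG_ANCHOR, METSIG_GENES, ExpressionMatrix

MARKER_FOLD = 4.0  # planted per-cluster marker elevation
DAS28_MID = 5.0  # mid-scale of the 0-10 clinical score


@dataclass
class BulkSimSpec:
    """Parameters of one simulated bulk RNA-seq cohort.

    ``dispersion`` is the NB size parameter (variance μ + μ²/size);
    ``math.inf`` switches to Poisson counts.  ``baseline_log_mean_range``
    is the natural-log mean range from which per-gene baselines are drawn.
    ``clinical_slope``/``clinical_noise_sd`` default to values whose implied
    tracked-sample MetSig–DAS28 Spearman is ≈0.8, the strength reported for
    the tracked patient subset.
    """

    n_samples: int = 100
    n_genes: int = 2000
    module_genes: int = 20
    anchor_beta: float = 1.0
    module_beta: float = 1.0
    dispersion: float = 10.0
    baseline_log_mean_range: tuple[float, float] = (3.0, 7.0)
    tracked_fraction: float = 0.5
    outlier_offset: float = 2.0
    clinical_slope: float = 1.0
    clinical_noise_sd: float = 0.72
    seed: int = 0
    cohort: str = "SIM"
    anchor_id: str = METSIG_ANCHOR

    def __post_init__(self) -> None:
        for name in ("anchor_beta", "module_beta", "outlier_offset",
                     "clinical_slope", "clinical_noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (self.dispersion > 0):
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.tracked_fraction <= 1.0:
            raise ValueError("tracked_fraction must lie in [0, 1]")
        if self.module_genes + 1 > self.n_genes:
            raise ValueError("need module_genes + 1 (anchor) <= n_genes")


@dataclass
class BulkSimTruth:
    """Ground truth accompanying a simulated cohort."""

    latent: np.ndarray
    module_gene_ids: list[str]
    anchor_id: str
    tracked_mask: np.ndarray
    #: population Spearman implied by (clinical_slope, clinical_noise_sd)
    true_clinical_link: float
    #: Spearman actually realised between the latent module score and the
    #: generated clinical score on the tracked samples of this dataset —
    #: the planted value a perfect analysis of this dataset would recover
    realized_clinical_rho: float = float("nan")


@dataclass
class SCSimSpec:
    """Parameters of a simulated single-cell dataset."""

    n_cells: int = 300
    n_genes: int = 1500
    k_clusters: int = 5
    hi_cluster_index: int = 0
    signature_fold: float = 3.0
    marker_genes_per_cluster: int = 40
    mito_genes: int = 13
    qc_violators: int = 7
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hi_cluster_index >= self.k_clusters:
            raise ValueError("hi_cluster_index must be < k_clusters")
        if self.n_cells < self.k_clusters:
            raise ValueError("need n_cells >= k_clusters")
        if self.signature_fold < 1.0:
            raise ValueError("signature_fold must be >= 1")
        needed = len(METSIG_GENES) + 1 + self.mito_genes \
            + self.k_clusters * self.marker_genes_per_cluster
        if self.n_genes < needed:
            raise ValueError(f"n_genes must be >= {needed} to host all planted genes")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    if math.isinf(size):
        return rng.poisson(mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def planted_clinical_spearman(clinical_slope: float, clinical_noise_sd: float) -> float:
    """Population Spearman implied by the planted linear clinical link.

    For a bivariate normal with Pearson correlation ρ the Spearman
    correlation is (6/π)·asin(ρ/2).
    """
    rho = clinical_slope / math.hypot(clinical_slope, clinical_noise_sd)
    return 6.0 / math.pi * math.asin(rho / 2.0)


def simulate_bulk_cohort(
    spec: BulkSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, BulkSimTruth]:
    """Simulate one bulk cohort; returns (counts, annotation, truth).

    Per sample i a latent factor L_i ~ N(0,1) enters gene g's NB log-mean
    as b_g + β_g·L_i, with β_g = ``module_beta`` for module genes,
    ``anchor_beta`` for the anchor and 0 otherwise.  Untracked samples get
    the anchor log-mean displaced by ``outlier_offset`` toward the cohort
    mean (−offset·sign(L_i)), decoupling anchor from module without making
    the untracked group anchor-extreme.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    latent = rng.standard_normal(n)

    module_ids = [f"MOD{i:04d}" for i in range(spec.module_genes)]
    n_bg = g - spec.module_genes - 1
    gene_ids = [spec.anchor_id] + module_ids + [f"G{i:05d}" for i in range(n_bg)]

    lo, hi = spec.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=g)
    # the anchor is modelled as an abundantly expressed gene (as the study's
    # anchor CDC42 is): its baseline sits at the top of the range so anchor
    # measurement noise reflects biological dispersion, not shot noise
    baseline[0] = hi
    beta = np.zeros(g)
    beta[0] = spec.anchor_beta
    beta[1 : 1 + spec.module_genes] = spec.module_beta

    n_tracked = int(round(n * spec.tracked_fraction))
    tracked = np.zeros(n, dtype=bool)
    tracked[rng.permutation(n)[:n_tracked]] = True

    log_mu = baseline[:, None] + beta[:, None] * latent[None, :]
    sign = np.where(latent >= 0, 1.0, -1.0)
    log_mu[0, ~tracked] -= spec.outlier_offset * sign[~tracked]
    counts = _nb_counts(rng, np.exp(log_mu), spec.dispersion)

    sample_ids = [f"{spec.cohort}_S{i:03d}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        unit="raw_counts",
    )

    # clinical score: linear in the standardised module score for tracked
    # samples, matched-variance independent noise for the rest
    module_score = latent  # module genes share the latent factor
    zscore = (module_score - module_score.mean()) / module_score.std(ddof=1)
    das28 = np.empty(n)
    das28[tracked] = (
        DAS28_MID
        + spec.clinical_slope * zscore[tracked]
        + rng.normal(0.0, spec.clinical_noise_sd, tracked.sum())
    )
    marginal_sd = math.hypot(spec.clinical_slope, spec.clinical_noise_sd)
    das28[~tracked] = DAS28_MID + rng.normal(0.0, marginal_sd, (~tracked).sum())
    das28 = np.clip(das28, 0.0, 10.0)

    treatment = rng.choice(
        ["MTX", "TNFi", "JAKi", "none"], size=n, p=[0.3, 0.17, 0.40, 0.13]
    )
    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": spec.cohort,
            "das28": das28,
            "treatment": treatment,
        }
    ).set_index("sample_id", drop=False)

    if tracked.sum() >= 3 and np.ptp(das28[tracked]) > 0:
        from .stats import spearman as _spearman

        realized = _spearman(latent[tracked], das28[tracked]).rho
    else:
        realized = float("nan")
    truth = BulkSimTruth(
        latent=latent,
        module_gene_ids=module_ids,
        anchor_id=spec.anchor_id,
        tracked_mask=tracked,
        true_clinical_link=planted_clinical_spearman(
            spec.clinical_slope, spec.clinical_noise_sd
        ),
        realized_clinical_rho=realized,
    )
    return matrix, ann, truth


def simulate_sc_dataset(spec: SCSimSpec) -> ad.AnnData:
    """Simulate a clustered single-cell dataset with planted structure.

    Returns an AnnData (cells × genes) with raw counts in ``X`` and
    ``layers['counts']``; truth in ``obs['true_cluster']`` (int) and
    ``obs['qc_violator']`` (bool), planted roles in ``var['role']``
    (``signature``/``anchor``/``mito``/``marker_k``/``background``).
    Per-gene baseline means are drawn once and shared across clusters, so
    cluster differences are purely the planted fold changes.
    """
    rng = np.random.default_rng(spec.seed)
    n, g, k = spec.n_cells, spec.n_genes, spec.k_clusters

    sig_genes = list(METSIG_GENES)
    mito_ids = [f"MT-G{i:02d}" for i in range(spec.mito_genes)]
    marker_ids = [
        f"MK{c}_{j:02d}" for c in range(k) for j in range(spec.marker_genes_per_cluster)
    ]
    n_bg = g - len(sig_genes) - 1 - spec.mito_genes - len(marker_ids)
    gene_ids = sig_genes + [METSIG_ANCHOR] + mito_ids + marker_ids + [
        f"BG{i:05d}" for i in range(n_bg)
    ]
    role = np.array(
        ["signature"] * len(sig_genes)
        + ["anchor"]
        + ["mito"] * spec.mito_genes
        + [f"marker_{c}" for c in range(k) for _ in range(spec.marker_genes_per_cluster)]
        + ["background"] * n_bg
    )

    base = np.exp(rng.normal(0.0, 0.8, size=g))  # shared per-gene baselines
    base[role == "signature"] = np.exp(rng.normal(0.3, 0.3, size=len(sig_genes)))
    base[role == "anchor"] = np.exp(rng.normal(0.3, 0.3))
    base[role == "mito"] = np.exp(rng.normal(1.6, 0.3, size=spec.mito_genes))

    clusters = rng.integers(0, k, size=n)
    mean = np.tile(base, (n, 1))  # cells x genes
    for c in range(k):
        in_c = clusters == c
        mean[np.ix_(in_c, role == f"marker_{c}")] *= MARKER_FOLD
    in_hi = clusters == spec.hi_cluster_index
    mean[np.ix_(in_hi, (role == "signature") | (role == "anchor"))] *= spec.signature_fold

    # constructed QC violators: alternately low-coverage (fails the minimum
    # feature count) and mito-loaded (fails the mitochondrial fraction rule)
    violator = np.zeros(n, dtype=bool)
    if spec.qc_violators:
        idx = rng.permutation(n)[: spec.qc_violators]
        violator[idx] = True
        for j, cell in enumerate(idx):
            if j % 2 == 0:
                mean[cell, :] *= 0.05
            else:
                mean[cell, role == "mito"] *= 25.0

    counts = _nb_counts(rng, mean, spec.dispersion).astype(float)
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"true_cluster": clusters, "qc_violator": violator},
            index=pd.Index([f"CELL{i:05d}" for i in range(n)], name="cell_id"),
        ),
        var=pd.DataFrame(
            {"role": role, "mito": [gid.startswith("MT-") for gid in gene_ids]},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
    )
    adata.layers["counts"] = counts.copy()
    from .sc import compute_qc_metrics

    compute_qc_metrics(adata)
    return adata
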