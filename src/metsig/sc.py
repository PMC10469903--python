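"""Single-cell stage: QC filtering, normalisation, clustering, per-cluster
signature scoring and marker calling.

The container is an AnnData (cells × genes).  Raw counts live in
``layers['counts']``; ``lognormalize_cells`` puts counts-per-10k log1p
values into ``X``.  ``var['mito']`` marks mitochondrial genes;
``obs['n_features']`` and ``obs['mito_fraction']`` are the per-cell QC
metrics; ``obs['cluster']`` holds cluster labels.

Defaults follow the study: cells kept with 500–4,500 detected features and
≤20% mitochondrial counts; 15 clusters; markers called by a two-sided
Wilcoxon rank-sum test of the cluster against all remaining cells, with
|log2FC| > 0.25 and detection ≥25% in at least one group.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans

from .datamodel import SignatureDefinition

QC_MIN_FEATURES = 500
QC_MAX_FEATURES = 4500
QC_MAX_MITO = 0.20
DEFAULT_K = 15
DEFAULT_N_PCS = 10
MARKER_LFC_MIN = 0.25
MARKER_PCT_MIN = 0.25
_EPS = 1e-9


def _counts(adata: ad.AnnData) -> np.ndarray:
    return np.asarray(adata.layers.get("counts", adata.X))


def compute_qc_metrics(adata: ad.AnnData) -> ad.AnnData:
    """Fill ``obs['n_features']`` and ``obs['mito_fraction']`` from counts."""
    counts = _counts(adata)
    if "mito" not in adata.var:
        adata.var["mito"] = adata.var_names.str.startswith("MT-")
    mito = adata.var["mito"].to_numpy(dtype=bool)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, counts[:, mito].sum(axis=1) / total, 0.0)
    adata.obs["n_features"] = (counts > 0).sum(axis=1)
    adata.obs["mito_fraction"] = frac
    return adata


def qc_filter(
    adata: ad.AnnData,
    min_features: int = QC_MIN_FEATURES,
    max_features: int = QC_MAX_FEATURES,
    max_mito: float = QC_MAX_MITO,
) -> ad.AnnData:
    """Drop cells outside the feature-count window or above the mito cap.

    Returns a copy of the retained cells; per-criterion removal counts go to
    ``uns['qc_removed']`` as ``{low_features, high_features, high_mito}``
    (a cell can appear in more than one).  Removing every cell is an error.
    """
    if "n_features" not in adata.obs or "mito_fraction" not in adata.obs:
        compute_qc_metrics(adata)
    nf = adata.obs["n_features"].to_numpy()
    mf = adata.obs["mito_fraction"].to_numpy()
    low = nf < min_features
    high = nf > max_features
    mito = mf > max_mito
    keep = ~(low | high | mito)
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    out = adata[keep].copy()
    out.uns["qc_removed"] = {
        "low_features": int(low.sum()),
        "high_features": int(high.sum()),
        "high_mito": int(mito.sum()),
        "total_removed": int((~keep).sum()),
    }
    return out


def lognormalize_cells(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Counts-per-``target_sum`` followed by natural log1p, via scanpy.

    Raw counts are preserved in ``layers['counts']``.  A zero-total cell is
    an error (it should have been removed by QC).
    """
    import scanpy as sc

    counts = _counts(adata)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(adata.obs_names[totals == 0])
        raise ValueError(f"cell(s) with zero total counts: {bad}")
    out = adata.copy()
    out.layers["counts"] = counts.copy()
    out.X = counts.astype(float).copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    out.uns["lognormalized"] = True
    return out


def cluster_cells(
    adata: ad.AnnData,
    k: int = DEFAULT_K,
    n_pcs: int = DEFAULT_N_PCS,
    seed: int = 0,
    n_top_genes: int = 2000,
) -> pd.Series:
    """K-means clustering of cells on PCA of the scaled top-variance genes.

    Genes are restricted to the ``n_top_genes`` most variable (all genes if
    fewer), scaled to unit variance, reduced to ``n_pcs`` principal
    components, and clustered with k-means++ (25 restarts, seeded).  Labels
    are written to ``obs['cluster']`` and returned.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > adata.n_obs:
        raise ValueError("k exceeds the number of cells")
    if not adata.uns.get("lognormalized"):
        raise ValueError("cluster_cells expects log-normalised data")
    X = np.asarray(adata.X, dtype=float)
    variances = X.var(axis=0)
    if X.shape[1] > n_top_genes:
        top = np.argsort(variances)[::-1][:n_top_genes]
        X = X[:, top]
        variances = variances[top]
    keep = variances > 0
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, init="k-means++", n_init=25, random_state=seed)
    labels = km.fit_predict(pcs)
    series = pd.Series(labels, index=adata.obs_names, name="cluster")
    adata.obs["cluster"] = series
    return series


def cluster_metsig(adata: ad.AnnData, sig: SignatureDefinition) -> pd.DataFrame:
    """Score clusters by summed per-cell-mean aggregate signature expression.

    For cluster c the score is Σ_g (Σ_{cells in c} x_gc) / n_cells(c) over
    the signature genes, on the values currently in ``X``.  Returns a
    DataFrame indexed by cluster with columns ``n_cells``, ``metsig``,
    ``anchor_mean``, ``hi`` (True on the arg-max cluster; ties within 1e-9
    flag every tied cluster and set ``uns['metsig_tie']``).
    """
    if "cluster" not in adata.obs:
        raise ValueError("no cluster labels: run cluster_cells first")
    missing = [g for g in [*sig.genes, sig.anchor_gene] if g not in adata.var_names]
    if missing:
        raise KeyError(f"signature gene(s) absent from dataset: {missing}")
    X = np.asarray(adata.X, dtype=float)
    gidx = [adata.var_names.get_loc(g) for g in sig.genes]
    aidx = adata.var_names.get_loc(sig.anchor_gene)
    rows = []
    for c, idx in adata.obs.groupby("cluster", observed=True).indices.items():
        n_c = len(idx)
        score = float(X[np.ix_(idx, gidx)].sum(axis=0).sum() / n_c)
        rows.append(
            {
                "cluster": c,
                "n_cells": n_c,
                "metsig": score,
                "anchor_mean": float(X[idx, aidx].mean()),
            }
        )
    df = pd.DataFrame(rows).set_index("cluster").sort_index()
    best = df["metsig"].max()
    df["hi"] = df["metsig"] >= best - 1e-9
    if df["hi"].sum() > 1:
        warnings.warn("signature-hi cluster is tied", stacklevel=2)
        adata.uns["metsig_tie"] = True
    if df.loc[df["hi"], "anchor_mean"].max() < df["anchor_mean"].max() - 1e-9:
        # the signature-hi cluster is not the anchor-hi cluster: report both
        df["anchor_hi"] = df["anchor_mean"] >= df["anchor_mean"].max() - 1e-9
        adata.uns["metsig_anchor_disagree"] = True
    return df


def find_markers(
    adata: ad.AnnData,
    cluster_label,
    lfc_min: float = MARKER_LFC_MIN,
    pct_min: float = MARKER_PCT_MIN,
) -> pd.DataFrame:
    """Markers of one cluster against all remaining cells.

    Genes are pre-filtered by effect size and detection (|log2FC| > lfc_min
    and detection fraction ≥ pct_min in at least one group), then tested
    with a two-sided Wilcoxon rank-sum on the log-normalised values.  The
    fold change is log2((mean_in + ε) / (mean_out + ε)) with ε = 1e-9 and
    means taken on the expm1 (de-logged) normalised scale.  Bonferroni-
    adjusted p-values accompany the nominal ones.
    """
    if "cluster" not in adata.obs:
        raise ValueError("no cluster labels: run cluster_cells first")
    labels = adata.obs["cluster"].to_numpy()
    in_mask = labels == cluster_label
    if not in_mask.any():
        raise ValueError(f"unknown cluster label: {cluster_label!r}")
    if in_mask.sum() < 3:
        raise ValueError("cluster has fewer than 3 cells")
    X = np.asarray(adata.X, dtype=float)
    counts = _counts(adata)
    expm1 = np.expm1(X)
    mean_in = expm1[in_mask].mean(axis=0)
    mean_out = expm1[~in_mask].mean(axis=0)
    lfc = np.log2((mean_in + _EPS) / (mean_out + _EPS))
    pct_in = (counts[in_mask] > 0).mean(axis=0)
    pct_out = (counts[~in_mask] > 0).mean(axis=0)
    eligible = (np.abs(lfc) > lfc_min) & (np.maximum(pct_in, pct_out) >= pct_min)
    if not eligible.any():
        return pd.DataFrame(
            columns=["gene_id", "cluster", "log2_fold_change", "p_value",
                     "p_bonferroni", "pct_in", "pct_out"]
        )
    idx = np.where(eligible)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.mannwhitneyu(
            X[np.ix_(in_mask, idx)],
            X[np.ix_(~in_mask, idx)],
            alternative="two-sided",
            axis=0,
        )
    pvals = np.atleast_1d(res.pvalue)
    df = pd.DataFrame(
        {
            "gene_id": adata.var_names[idx],
            "cluster": cluster_label,
            "log2_fold_change": lfc[idx],
            "p_value": pvals,
            "p_bonferroni": np.minimum(pvals * idx.size, 1.0),
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
        }
    )
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
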