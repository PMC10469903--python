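"""Bulk stage: anchor split, normalisation, differential expression,
cohort intersection, co-expression clustering, the TF and correlation
filters that define the signature, and per-sample signature scoring.

The derivation chain mirrors the study design: samples of each cohort are
split at the cohort mean of the anchor gene's normalised expression; genes
differentially expressed (nominal p < 0.05) and upregulated in anchor-high
samples of *both* cohorts are intersected; candidates are restricted to
transcriptional targets of the named TFs; and an iterative correlation
filter keeps only genes that stay Spearman-correlated with the anchor and
with each other.  The per-sample score ("MetSig") is the sum of the
signature genes' row z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix, SignatureDefinition
from .stats import _zscore_array, spearman_matrix, zscore_rows

DEFAULT_ALPHA = 0.05
DEFAULT_RHO_MIN = 0.4
DEFAULT_KMEANS_K = 6
_TINY = np.finfo(float).tiny


class EmptySignatureError(RuntimeError):
    """Raised when the filter chain leaves no signature gene."""


def split_by_anchor(m: ExpressionMatrix, anchor: str) -> pd.Series:
    """Label samples hi/lo by the cross-sample mean of the anchor gene.

    The split is computed on the normalised log scale (raw counts are
    normalised first).  hi ⇔ strictly above the mean; ties go to lo.  An
    all-equal anchor yields all-lo with a warning.
    """
    if anchor not in m.data.index:
        raise KeyError(f"anchor gene {anchor!r} absent from matrix")
    if m.unit == "raw_counts":
        m = normalize_counts(m)
    values = m.data.loc[anchor].to_numpy(dtype=float)
    if np.ptp(values) == 0:
        warnings.warn(
            f"anchor {anchor!r} is constant: every sample labelled 'lo'", stacklevel=2
        )
    labels = np.where(values > values.mean(), "hi", "lo")
    return pd.Series(labels, index=m.data.columns, name="anchor_group")


def normalize_counts(m: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size-factor normalisation followed by log2(x+1).

    Size factors are per-sample medians of count ratios to the geometric-
    mean reference gene, computed over genes with all-positive counts; if
    no such gene exists, library-size factors (scaled to geometric mean 1)
    are used with a warning.
    """
    if m.unit != "raw_counts":
        raise ValueError("normalize_counts expects raw counts")
    counts = m.data.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.any():
        ref = np.exp(np.log(counts[allpos]).mean(axis=1, keepdims=True))
        sf = np.median(counts[allpos] / ref, axis=0)
    else:
        warnings.warn(
            "no gene with all-positive counts: falling back to library-size factors",
            stacklevel=2,
        )
        lib = counts.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    norm = np.log2(counts / sf + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(norm, index=m.data.index, columns=m.data.columns),
        unit="log_normalized",
    )


def de_test(m: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-gene Welch t-test of hi vs lo samples on log-normalised values.

    Returns a DataFrame with ``gene_id, log2_fold_change, p_value, mean_hi,
    mean_lo, fdr`` (Benjamini–Hochberg, informational only — the DEG
    definition downstream is the nominal p).  Degenerate genes with zero
    variance in both groups get p = 1 when the means agree and the smallest
    positive float when they separate exactly.
    """
    if m.unit != "log_normalized":
        raise ValueError("de_test expects log-normalised values")
    labels = labels.reindex(m.data.columns)
    hi = (labels == "hi").to_numpy()
    lo = (labels == "lo").to_numpy()
    if hi.sum() < 3 or lo.sum() < 3:
        raise ValueError("both groups need at least 3 samples")
    values = m.data.to_numpy(dtype=float)
    a, b = values[:, hi], values[:, lo]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
        res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    mean_hi = a.mean(axis=1)
    mean_lo = b.mean(axis=1)
    lfc = mean_hi - mean_lo  # values are already log2
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = _TINY
    p = np.clip(p, _TINY, 1.0)
    fdr = sps.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {
            "gene_id": m.data.index,
            "log2_fold_change": lfc,
            "p_value": p,
            "mean_hi": mean_hi,
            "mean_lo": mean_lo,
            "fdr": fdr,
        }
    )


def intersect_degs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    direction: str = "concordant",
) -> tuple[set[str], float, float]:
    """Genes significant (p < alpha) in both cohorts with concordant sign.

    ``direction='up'`` additionally requires log2FC > 0 in both (the
    signature derivation uses this).  Returns (common set, fraction of
    cohort-a DEGs shared, fraction of cohort-b DEGs shared); fractions are
    NaN for empty DEG sets.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    def degs(df: pd.DataFrame) -> pd.DataFrame:
        sig = df[df["p_value"] < alpha]
        if direction == "up":
            sig = sig[sig["log2_fold_change"] > 0]
        return sig.set_index("gene_id")

    da, db = degs(a), degs(b)
    shared = da.index.intersection(db.index)
    if direction == "concordant":
        concordant = (
            np.sign(da.loc[shared, "log2_fold_change"]).to_numpy()
            == np.sign(db.loc[shared, "log2_fold_change"]).to_numpy()
        )
        shared = shared[concordant]
    common = set(shared)
    frac_a = len(common) / len(da) if len(da) else float("nan")
    frac_b = len(common) / len(db) if len(db) else float("nan")
    return common, frac_a, frac_b


def kmeans_coexpression(m: ExpressionMatrix, k: int = DEFAULT_KMEANS_K, seed: int = 0) -> pd.Series:
    """K-means co-expression clustering of z-scored gene rows.

    Euclidean k-means++ with 25 restarts, best inertia kept; deterministic
    given the seed.  Informational: the derivation chain itself does not
    consume cluster membership.
    """
    if m.unit != "z_scored":
        raise ValueError("kmeans_coexpression expects a row-z-scored matrix")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m.shape[0]:
        raise ValueError("k exceeds the number of genes")
    km = KMeans(n_clusters=k, init="k-means++", n_init=25, random_state=seed)
    labels = km.fit_predict(m.data.to_numpy(dtype=float))
    return pd.Series(labels, index=m.data.index, name="coexpression_cluster")


def tf_target_filter(
    genes: set[str], tfmap: dict[str, set[str]], tfs: set[str]
) -> set[str]:
    """Restrict ``genes`` to targets of any of the named TFs.

    A TF missing from the map is an error naming it; an empty result is a
    warning, not an error.
    """
    if not tfs:
        raise ValueError("tfs must be non-empty")
    missing = sorted(t for t in tfs if t not in tfmap)
    if missing:
        raise KeyError(f"TF(s) absent from the target map: {missing}")
    union: set[str] = set()
    for tf in tfs:
        union |= tfmap[tf]
    kept = set(genes) & union
    if not kept:
        warnings.warn("no candidate gene is a target of the named TFs", stacklevel=2)
    return kept


def correlation_filter(
    candidates: set[str],
    anchor: str,
    m: ExpressionMatrix,
    rho_min: float = DEFAULT_RHO_MIN,
) -> tuple[set[str], list[tuple[str, float]]]:
    """Iteratively prune candidates until all are anchor- and mutually correlated.

    At each step the gene with the lowest mean Spearman rho to the anchor
    plus the remaining candidates is dropped (ties broken lexicographically)
    until every remaining gene has rho ≥ rho_min with the anchor AND mean
    pairwise rho ≥ rho_min.  Returns (kept genes, pruning trace of
    (dropped gene, its mean rho)).  Pruning everything is an error carrying
    the trace.  Undefined correlations (constant rows) count as 0.
    """
    if not 0.0 < rho_min < 1.0:
        raise ValueError("rho_min must lie in (0, 1)")
    if anchor not in m.data.index:
        raise KeyError(f"anchor gene {anchor!r} absent from matrix")
    remaining = sorted(set(candidates) - {anchor})
    order = [anchor, *remaining]
    sub = m.restrict(order)
    rho = spearman_matrix(sub.data.to_numpy(dtype=float))
    rho = np.nan_to_num(rho, nan=0.0)
    names = np.array(order)
    active = np.ones(len(order), dtype=bool)  # index 0 = anchor, always active
    trace: list[tuple[str, float]] = []
    while active[1:].any():
        idx = np.where(active)[0]
        cand = idx[idx != 0]
        sub_rho = rho[np.ix_(cand, idx)]
        mean_rho = (sub_rho.sum(axis=1) - 1.0) / (len(idx) - 1)  # exclude self
        anchor_rho = rho[cand, 0]
        ok = (anchor_rho >= rho_min) & (mean_rho >= rho_min)
        if ok.all():
            return set(names[cand]), trace
        lowest = np.lexsort((names[cand], mean_rho))[0]
        trace.append((str(names[cand][lowest]), float(mean_rho[lowest])))
        active[cand[lowest]] = False
    raise EmptySignatureError(
        f"correlation filter pruned every candidate (rho_min={rho_min}); trace: {trace}"
    )


def derive_signature(
    cohort_a: ExpressionMatrix,
    cohort_b: ExpressionMatrix,
    tfmap: dict[str, set[str]],
    tfs: set[str],
    anchor: str,
    labels_a: pd.Series | None = None,
    labels_b: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    rho_min: float = DEFAULT_RHO_MIN,
    corr_mode: str = "both",
) -> SignatureDefinition:
    """Full derivation chain across two cohorts.

    Stages: normalise each cohort → split by anchor mean (unless labels are
    given) → per-cohort Welch DE → intersect genes upregulated in anchor-hi
    samples of both cohorts (nominal p < alpha) → keep TF targets →
    correlation filter.  ``corr_mode='both'`` (default) requires a gene to
    survive the correlation filter in each cohort separately;
    ``corr_mode='pooled'`` filters once on the column-concatenated
    per-cohort z-scored matrices.  Provenance is recorded per gene.
    """
    norms, label_sets = [], []
    for m, lab in ((cohort_a, labels_a), (cohort_b, labels_b)):
        norm = normalize_counts(m) if m.unit == "raw_counts" else m
        if anchor not in norm.data.index:
            raise KeyError(f"anchor gene {anchor!r} absent from a cohort")
        norms.append(norm)
        label_sets.append(lab if lab is not None else split_by_anchor(norm, anchor))

    de_a = de_test(norms[0], label_sets[0])
    de_b = de_test(norms[1], label_sets[1])
    common, _, _ = intersect_degs(de_a, de_b, alpha=alpha, direction="up")
    common.discard(anchor)
    if not common:
        raise EmptySignatureError("no gene is upregulated in anchor-hi samples of both cohorts")

    targets = tf_target_filter(common, tfmap, set(tfs))
    if not targets:
        raise EmptySignatureError("no common DEG is a target of the named TFs")

    tf_hits = {
        g: sorted(tf for tf in tfs if g in tfmap[tf]) for g in targets
    }

    if corr_mode == "both":
        kept = set(targets)
        for norm in norms:
            kept_i, _ = correlation_filter(kept, anchor, norm, rho_min=rho_min)
            kept &= kept_i
            if not kept:
                raise EmptySignatureError("correlation filter emptied the candidate set")
    elif corr_mode == "pooled":
        pooled = ExpressionMatrix(
            pd.concat([zscore_rows(n).data for n in norms], axis=1), unit="log_normalized"
        )
        kept, _ = correlation_filter(set(targets), anchor, pooled, rho_min=rho_min)
    else:
        raise ValueError("corr_mode must be 'both' or 'pooled'")
    if not kept:
        raise EmptySignatureError("correlation filter emptied the candidate set")

    # order by mean anchor correlation across cohorts, descending
    mean_anchor_rho: dict[str, float] = {}
    for g in kept:
        rhos = []
        for norm in norms:
            pair = norm.restrict([anchor, g]).data.to_numpy(dtype=float)
            r = spearman_matrix(pair)[0, 1]
            rhos.append(0.0 if np.isnan(r) else r)
        mean_anchor_rho[g] = float(np.mean(rhos))
    ordered = sorted(kept, key=lambda g: (-mean_anchor_rho[g], g))
    provenance = {
        g: {
            "de_both_cohorts": True,
            "tf_target": tf_hits[g],
            "correlation_pass": True,
            "mean_anchor_rho": mean_anchor_rho[g],
        }
        for g in ordered
    }
    return SignatureDefinition(anchor, ordered, provenance)


def metsig_score(
    m: ExpressionMatrix,
    sig: SignatureDefinition,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample signature score: sum of the signature genes' row z-scores.

    ``anchor_z`` is the anchor gene's z-score computed the same way.  With
    ``groups`` (e.g. cohort labels) the z-transformation is applied within
    each group — the default standardisation of the pipeline — otherwise
    across all samples.  Missing genes are an error listing them.
    Raw counts are normalised first.
    """
    if m.shape[1] < 2:
        raise ValueError("scoring needs at least 2 samples")
    if m.unit == "raw_counts":
        m = normalize_counts(m)
    wanted = [*sig.genes, sig.anchor_gene]
    missing = [g for g in wanted if g not in m.data.index]
    if missing:
        raise KeyError(f"signature gene(s) absent from matrix: {missing}")
    sub = m.data.loc[wanted]
    if groups is None:
        z = _zscore_array(sub.to_numpy(dtype=float))
    else:
        groups = groups.reindex(sub.columns)
        z = np.empty(sub.shape)
        for _, cols in groups.groupby(groups, observed=True).groups.items():
            pos = [sub.columns.get_loc(c) for c in cols]
            if len(pos) < 2:
                raise ValueError("each standardisation group needs >= 2 samples")
            z[:, pos] = _zscore_array(sub.to_numpy(dtype=float)[:, pos])
    scores = pd.DataFrame(
        {
            "metsig": z[: len(sig.genes)].sum(axis=0),
            "anchor_z": z[-1],
        },
        index=pd.Index(sub.columns, name="sample_id"),
    )
    return scores


class MetSigScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer computing signature scores for new samples.

    ``fit`` learns per-gene means and standard deviations (ddof=1) from a
    training ExpressionMatrix (or gene-by-sample DataFrame); ``transform``
    standardises new samples against those statistics and returns the
    (metsig, anchor_z) score table.  ``fit_transform`` on a single matrix
    reproduces :func:`metsig_score` without grouping.
    """

    def __init__(self, signature: SignatureDefinition | None = None):
        self.signature = signature

    def _matrix(self, X) -> pd.DataFrame:
        if isinstance(X, ExpressionMatrix):
            X = normalize_counts(X) if X.unit == "raw_counts" else X
            return X.data
        return pd.DataFrame(X)

    def fit(self, X, y=None):
        sig = self.signature if self.signature is not None else None
        if sig is None:
            from .datamodel import builtin_signature

            sig = builtin_signature()
        data = self._matrix(X)
        wanted = [*sig.genes, sig.anchor_gene]
        missing = [g for g in wanted if g not in data.index]
        if missing:
            raise KeyError(f"signature gene(s) absent from matrix: {missing}")
        sub = data.loc[wanted].to_numpy(dtype=float)
        self.signature_ = sig
        self.gene_order_ = wanted
        self.mean_ = sub.mean(axis=1)
        self.scale_ = sub.std(axis=1, ddof=1)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise RuntimeError("MetSigScorer is not fitted")
        data = self._matrix(X)
        sub = data.loc[self.gene_order_].to_numpy(dtype=float)
        scale = np.where(self.scale_ == 0, 1.0, self.scale_)
        z = (sub - self.mean_[:, None]) / scale[:, None]
        z[self.scale_ == 0, :] = 0.0
        n_genes = len(self.signature_.genes)
        return pd.DataFrame(
            {"metsig": z[:n_genes].sum(axis=0), "anchor_z": z[-1]},
            index=pd.Index(data.columns, name="sample_id"),
        )
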