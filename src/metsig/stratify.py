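"""Min/max-point line model, inside/outside stratification and the
clinical-score association.

The reference line is not a least-squares fit: it joins the componentwise
extremes (max x, max y) and (min x, min y) of the score pair — by default
x = MetSig (sum of signature z-scores) and y = the anchor gene's z-score.
A sample is "inside" (signature-tracked, MetSig^hi) when the absolute
difference between the line-predicted and observed y is strictly less
than the threshold (default 1.0, i.e. one standard deviation on the
z-scored anchor scale).  Disease-activity association (Spearman of MetSig
vs DAS28) is computed on the inside subset only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .datamodel import ExpressionMatrix
from .stats import CorrelationResult, spearman, spearman_rows

DEFAULT_THRESHOLD = 1.0
DEFAULT_RHO_CUT = 0.5


@dataclass
class LineModel:
    """The min/max-point line and the residual cutoff for 'inside'."""

    slope: float
    intercept: float
    threshold: float = DEFAULT_THRESHOLD
    x_name: str = "metsig"
    y_name: str = "anchor_z"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if not np.isfinite(self.slope):
            raise ValueError("slope is not finite (zero x-range?)")

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class ClinicalAssociation:
    """MetSig–DAS28 association on the inside subset."""

    subset: list[str]
    corr: CorrelationResult
    inside_fraction: float
    group_stats: pd.DataFrame
    rank_test_p: float  # inside-vs-outside MetSig, two-sided Wilcoxon rank-sum
    flags: list[str] = field(default_factory=list)


def fit_minmax_line(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    x_name: str = "metsig",
    y_name: str = "anchor_z",
) -> LineModel:
    """Line through (max x, max y) and (min x, min y).

    The two coordinates of each point are the independent componentwise
    extremes, not the coordinates of any single sample.  A zero x-range is
    an error.
    """
    x = scores[x_name].to_numpy(dtype=float)
    y = scores[y_name].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to fit the line")
    if np.ptp(x) == 0:
        raise ValueError("zero range in x: line undefined")
    slope = (y.max() - y.min()) / (x.max() - x.min())
    intercept = y.max() - slope * x.max()
    return LineModel(slope, intercept, threshold, x_name, y_name)


def classify_inside(scores: pd.DataFrame, model: LineModel) -> pd.DataFrame:
    """Residuals (predicted − observed y) and strict inside labels.

    inside ⇔ |residual| < threshold ("less than", strict: a residual of
    exactly the threshold is outside).
    """
    x = scores[model.x_name].to_numpy(dtype=float)
    y = scores[model.y_name].to_numpy(dtype=float)
    residual = model.predict(x) - y
    return pd.DataFrame(
        {"residual": residual, "inside": np.abs(residual) < model.threshold},
        index=scores.index,
    )


class MinMaxLineStratifier(BaseEstimator):
    """Sklearn-style classifier wrapping the min/max-point line model.

    ``fit(X)`` learns ``slope_``/``intercept_`` from a two-column array or
    a scores DataFrame (x first, y second); ``predict`` returns the boolean
    inside labels and ``decision_function`` the signed residuals.
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD):
        self.threshold = threshold

    def _xy(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            cols = list(X.columns[:2])
            return X[cols[0]].to_numpy(float), X[cols[1]].to_numpy(float)
        arr = np.asarray(X, dtype=float)
        return arr[:, 0], arr[:, 1]

    def fit(self, X, y=None):
        x, yy = self._xy(X)
        if np.ptp(x) == 0:
            raise ValueError("zero range in x: line undefined")
        self.slope_ = (yy.max() - yy.min()) / (x.max() - x.min())
        self.intercept_ = yy.max() - self.slope_ * x.max()
        return self

    def decision_function(self, X) -> np.ndarray:
        x, yy = self._xy(X)
        return (self.slope_ * x + self.intercept_) - yy

    def predict(self, X) -> np.ndarray:
        return np.abs(self.decision_function(X)) < self.threshold

    def to_line_model(self) -> LineModel:
        return LineModel(self.slope_, self.intercept_, self.threshold)


def associate_clinical(
    strat: pd.DataFrame, scores: pd.DataFrame, ann: pd.DataFrame
) -> ClinicalAssociation:
    """Spearman of (MetSig, DAS28) on the inside subset, plus group summary.

    Also reports the inside fraction and a two-sided Wilcoxon rank-sum test
    of MetSig between inside and outside samples.  Fewer than 3 inside
    samples leaves the correlation undefined (flagged); an empty outside
    group flags the rank test as absent but the correlation is returned.
    """
    joined = strat.join(scores).join(ann["das28"], how="left")
    inside = joined[joined["inside"]]
    outside = joined[~joined["inside"]]
    if inside["das28"].isna().any():
        bad = list(inside.index[inside["das28"].isna()])
        raise ValueError(f"das28 missing for inside sample(s): {bad}")
    flags: list[str] = []
    if len(inside) >= 3:
        corr = spearman(inside["metsig"], inside["das28"])
    else:
        flags.append("inside subset < 3: association undefined")
        corr = CorrelationResult(float("nan"), float("nan"), len(inside))
    if len(outside) and len(inside):
        rank_p = float(
            sps.mannwhitneyu(
                inside["metsig"], outside["metsig"], alternative="two-sided"
            ).pvalue
        )
    else:
        flags.append("one stratum is empty: rank test absent")
        rank_p = float("nan")
    group_stats = (
        joined.groupby("inside")[["metsig", "das28"]].median().rename_axis("inside")
    )
    return ClinicalAssociation(
        subset=list(inside.index),
        corr=corr,
        inside_fraction=len(inside) / len(joined),
        group_stats=group_stats,
        rank_test_p=rank_p,
        flags=flags,
    )


def clinical_gene_screen(
    m: ExpressionMatrix, ann: pd.DataFrame, rho_cut: float = DEFAULT_RHO_CUT
) -> pd.DataFrame:
    """Genes whose expression correlates with DAS28 beyond |rho| > rho_cut.

    Spearman per gene against the per-sample clinical score; the result is
    partitioned into direct (rho > 0) and inverse (rho < 0) hits via the
    ``direction`` column.
    """
    if not 0.0 < rho_cut < 1.0:
        raise ValueError("rho_cut must lie in (0, 1)")
    if m.unit == "raw_counts":
        from .bulk import normalize_counts

        m = normalize_counts(m)
    das28 = ann["das28"].reindex(m.data.columns)
    if das28.isna().any():
        raise ValueError("das28 missing for some samples")
    rho, p = spearman_rows(m.data.to_numpy(dtype=float), das28.to_numpy(dtype=float))
    df = pd.DataFrame({"gene_id": m.data.index, "rho": rho, "p_value": p})
    hits = df[np.abs(df["rho"]) > rho_cut].copy()
    hits["direction"] = np.where(hits["rho"] > 0, "direct", "inverse")
    return hits.sort_values("rho", ascending=False, kind="stable").reset_index(drop=True)
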