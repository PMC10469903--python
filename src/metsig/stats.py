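"""Shared statistical utilities: row z-transformation and Spearman correlation.

Conventions used throughout the pipeline:

* z-transformation standardises each gene row to mean 0 and *sample*
  standard deviation 1 (denominator n−1); rows with zero variance map to
  all-zero rows so flat housekeeping genes cannot poison signature scores.
* Spearman correlation uses average ranks for ties.  The two-sided p-value
  comes from the t approximation for n ≥ 10 and from exact enumeration of
  all n! pairings for n < 10, where the approximation is unreliable.
  A constant input vector leaves the correlation undefined; the result then
  carries ``rho = NaN`` rather than raising.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ExpressionMatrix


class CorrelationResult(NamedTuple):
    """Spearman correlation with its two-sided p-value and sample count."""

    rho: float
    p_value: float
    n: int


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene row to mean 0, sample sd 1 (ddof=1).

    Constant rows become all-zero rows.  Raises if the matrix is already
    z-scored or has fewer than two samples (z undefined).
    """
    if m.unit == "z_scored":
        raise ValueError("matrix is already z-scored")
    if m.shape[1] < 2:
        raise ValueError("z-transformation needs at least 2 samples")
    values = m.data.to_numpy(dtype=float)
    z = _zscore_array(values)
    return ExpressionMatrix(
        pd.DataFrame(z, index=m.data.index, columns=m.data.columns), unit="z_scored"
    )


def _zscore_array(values: np.ndarray) -> np.ndarray:
    """Row-wise (ddof=1) z-scores of a 2-D array; constant rows -> zeros."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return z


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks and a two-sided p-value.

    For n < 10 the p-value is exact, computed by enumerating all n!
    pairings of the rank vectors; for n ≥ 10 it is the usual t
    approximation.  Constant input yields ``rho = NaN`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return CorrelationResult(float("nan"), float("nan"), n)
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        p = float(sps.spearmanr(x, y).pvalue)
    else:
        p = _exact_perm_pvalue(rx, ry, rho)
    return CorrelationResult(rho, min(p, 1.0), n)


def _exact_perm_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided p by full enumeration of pairings (n < 10 only)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = math.sqrt(float(rxc @ rxc)) * np.sqrt((ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_rows(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Spearman of every row of ``values`` against ``y``.

    Returns (rho, two-sided p) arrays; the p-value uses the t approximation
    (intended for the gene screens, where n is tens of samples).  Constant
    rows get ``rho = NaN``, ``p = NaN``.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    ranks = sps.rankdata(values, axis=1, method="average")
    ry = _rank(y)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    yc = ry - ry.mean()
    denom = np.sqrt((rc**2).sum(axis=1)) * math.sqrt(float(yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc @ yc) / denom
    rho[~np.isfinite(rho)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, np.clip(p, np.finfo(float).tiny, 1.0))
    # perfect monotone relations give |rho|=1, t=inf -> p=0 -> keep tiny
    return rho, p


def spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation matrix of the rows of ``values``.

    Constant rows yield NaN against everything (diagonal forced to 1).
    """
    values = np.asarray(values, dtype=float)
    ranks = sps.rankdata(values, axis=1, method="average")
    sd = ranks.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ranks)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr
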