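"""Differential expression and Pearson-correlation primitives.

DEGs (differentially expressed genes) between the high-risk (HRM) and
low-risk (LRM) groups are genes passing both a two-group t-test on FPKM
values (p below a threshold) and a twofold mean-change rule in either
direction. The Pearson routines here also back the co-expression network
and the edge weighting of the protein-interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import HRM, LRM, CohortLabels


class ZeroVarianceError(ValueError):
    """Correlation is undefined when either profile has zero variance."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation ω = cov(X, Y) / (σ_x σ_y) with a two-sided p-value.

    The p-value is the classical t transform ``t = r·sqrt((n−2)/(1−r²))``
    referred to a Student t distribution with n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


def pairwise_pearson(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p for the rows of *matrix*.

    Rows with zero variance yield NaN in both outputs; callers are expected
    to drop them beforehand or ignore the NaNs.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("need at least 3 columns (samples)")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(matrix)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |r| == 1 exactly
    np.fill_diagonal(p, 0.0)
    return r, p


def detect_degs(
    expr: pd.DataFrame,
    labels: CohortLabels,
    p_threshold: float = 0.01,
    fold_threshold: float = 2.0,
    pseudocount: float = 0.1,
    equal_var: bool = True,
    log2: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group t-test and fold change on an FPKM matrix.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``, ``fold``
    and boolean ``deg``. The fold change is
    ``(mean_HRM + ε) / (mean_LRM + ε)`` with pseudocount ε guarding zero
    means, and a gene is flagged as a DEG when ``p < p_threshold`` and the
    fold change is at least *fold_threshold* in either direction.
    With ``log2=True`` the test runs on log2(FPKM + ε); the fold change is
    always computed on the raw scale.
    """
    hrm = [s for s in labels.group(HRM) if s in expr.columns]
    lrm = [s for s in labels.group(LRM) if s in expr.columns]
    if len(hrm) < 2 or len(lrm) < 2:
        raise ValueError("need at least two expressed samples per group")
    h = expr[hrm].to_numpy(dtype=float)
    l = expr[lrm].to_numpy(dtype=float)
    fold = (h.mean(axis=1) + pseudocount) / (l.mean(axis=1) + pseudocount)
    if log2:
        h = np.log2(h + pseudocount)
        l = np.log2(l + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(h, l, axis=1, equal_var=equal_var)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    deg = (p < p_threshold) & ((fold >= fold_threshold) | (fold <= 1.0 / fold_threshold))
    return pd.DataFrame(
        {"t": t, "p": p, "fold": fold, "deg": deg}, index=expr.index.copy()
    )


def deg_genes(degs: pd.DataFrame) -> set[str]:
    """Gene symbols flagged as differentially expressed."""
    return set(degs.index[degs["deg"]])


class DifferentialExpressionSelector(BaseEstimator):
    """Scikit-learn style selector of differentially expressed genes.

    ``fit(X, y)`` expects ``X`` as samples × genes and ``y`` as group
    labels, ``"HRM"`` and ``"LRM"`` (the fold change is HRM over LRM).

    Attributes
    ----------
    support_ : boolean array marking DEG columns
    pvalues_, fold_changes_, statistics_ : per-gene test results
    """

    def __init__(
        self,
        p_threshold: float = 0.01,
        fold_threshold: float = 2.0,
        pseudocount: float = 0.1,
        equal_var: bool = True,
        log2: bool = False,
    ):
        self.p_threshold = p_threshold
        self.fold_threshold = fold_threshold
        self.pseudocount = pseudocount
        self.equal_var = equal_var
        self.log2 = log2

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        samples = [str(s) for s in X.index]
        labels = CohortLabels(dict(zip(samples, y)))
        expr = X.T
        expr.columns = samples
        table = detect_degs(
            expr,
            labels,
            p_threshold=self.p_threshold,
            fold_threshold=self.fold_threshold,
            pseudocount=self.pseudocount,
            equal_var=self.equal_var,
            log2=self.log2,
        )
        self.results_ = table
        self.support_ = table["deg"].to_numpy()
        self.pvalues_ = table["p"].to_numpy()
        self.fold_changes_ = table["fold"].to_numpy()
        self.statistics_ = table["t"].to_numpy()
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        X = np.asarray(X) if not isinstance(X, pd.DataFrame) else X
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return X[:, self.support_]
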