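"""Rank statistics, multiple-testing correction and diagonal LDA.

Every downstream stage calls these; they are implemented here (rather than
delegated) because the permutation null reruns them on hundreds of thousands
of small problems, which needs the vectorised matrix variants, and because
the bin-wise tests are the substance of the analysis.  scipy/statsmodels
equivalents serve as independent oracles in the test suite.

Conventions (documented because borderline p-values depend on them):

* Kruskal–Wallis and Friedman use midranks for ties and the chi-square
  approximation (k−1 df) with the standard tie-correction factor.
* The rank-sum test uses the normal approximation with midrank tie
  correction and a 0.5 continuity correction, two-sided.
* Diagonal LDA pools a single per-feature variance across classes; a
  variance floor (default 1e-9 Hz^2) guards silent bins; prediction ties go
  to the lowest class index in model order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata

__all__ = [
    "kruskal_wallis",
    "friedman",
    "rank_sum",
    "rank_sum_matrix",
    "bh_reject",
    "DiagLDAModel",
    "diag_lda_fit",
    "diag_lda_predict",
]


def _tie_term(x: np.ndarray) -> np.ndarray:
    """Sum of (t^3 - t) over tied groups, per row of a 2-D array."""
    rmax = _rankdata(x, method="max", axis=-1)
    rmin = _rankdata(x, method="min", axis=-1)
    m = rmax - rmin + 1.0
    return np.sum(m * m, axis=-1) - x.shape[-1]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H and its chi-square p-value (k−1 df).

    Accepts two or more nonempty samples; ties get midranks with the usual
    correction.  If every observation is identical, H = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled[None, :])[0] / (n**3 - n)
    if correction <= 0:  # all observations identical
        return 0.0, 1.0
    h /= correction
    p = float(_chi2.sf(h, len(groups) - 1))
    return float(h), p


def friedman(block_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over a trials × conditions matrix.

    Rows are blocks (trials), columns the repeated factor (epochs); within-row
    midranks, tie-corrected statistic, chi-square p with k−1 df.
    """
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 rows and >=2 columns")
    n, k = x.shape
    ranks = _rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    correction = 1.0 - _tie_term(x).sum() / (n * k * (k**2 - 1))
    if correction <= 0:  # every row fully tied
        return 0.0, 1.0
    stat /= correction
    p = float(_chi2.sf(stat, k - 1))
    return float(stat), p


def rank_sum_matrix(x: np.ndarray, n1: int) -> np.ndarray:
    """Two-sided rank-sum p-values for many tests at once.

    ``x`` has shape (cases, n1+n2): the first ``n1`` columns of each row form
    sample A, the rest sample B.  Normal approximation with midrank tie
    correction and continuity correction.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    n2 = n - n1
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    ranks = _rankdata(x, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    tie = _tie_term(x)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    d = w - mu
    z = np.zeros_like(d)
    pos = var > 0
    cc = np.sign(d) * 0.5
    z[pos] = (d[pos] - cc[pos]) / np.sqrt(var[pos])
    p = 2.0 * _norm.sf(np.abs(z))
    return np.minimum(p, 1.0)


def rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return float(rank_sum_matrix(np.concatenate([a, b])[None, :], a.size)[0])


def bh_reject(pvals: np.ndarray, alpha: float = 0.05, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up rejections at level ``alpha``.

    ``m`` is the family size; it may exceed ``len(pvals)`` when the family
    includes tests whose p-values are handled elsewhere, and defaults to
    ``len(pvals)``.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * np.arange(1, p.size + 1) / m
    passing = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(p.size, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


@dataclass(frozen=True)
class DiagLDAModel:
    """Gaussian classifier with per-class means and one pooled diagonal covariance."""

    classes: np.ndarray      # (k,) ordered labels
    class_means: np.ndarray  # (k, d)
    pooled_var: np.ndarray   # (d,)
    priors: np.ndarray       # (k,)


VAR_FLOOR = 1e-9  # Hz^2; silent bins yield exactly-zero within-class spread


def diag_lda_fit(
    features: np.ndarray, labels: np.ndarray, var_floor: float = VAR_FLOOR
) -> DiagLDAModel:
    """Fit a diagonal linear discriminant model.

    Per-class feature means; a single within-class variance per feature pooled
    across classes (SSE / (n − k)); priors from training frequencies.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).ravel()
    classes, inv = np.unique(y, return_inverse=True)
    k = classes.size
    if k < 2:
        raise ValueError("need at least two classes")
    n, d = x.shape
    counts = np.bincount(inv, minlength=k)
    if np.any(counts < 2):
        raise ValueError("each class needs at least two training trials")
    means = np.zeros((k, d))
    np.add.at(means, inv, x)
    means /= counts[:, None]
    resid = x - means[inv]
    pooled = (resid**2).sum(axis=0) / (n - k)
    pooled = np.maximum(pooled, var_floor)
    return DiagLDAModel(
        classes=classes,
        class_means=means,
        pooled_var=pooled,
        priors=counts / n,
    )


def diag_lda_predict(model: DiagLDAModel, features: np.ndarray) -> np.ndarray:
    """Predict labels by maximum Gaussian log-density plus log prior.

    Exact ties go to the lowest class index in model order.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.class_means.shape[1]:
        raise ValueError("feature dimension does not match model")
    # (n, k): -(1/2) sum_j (x_j - mu_cj)^2 / var_j + log prior
    diff = x[:, None, :] - model.class_means[None, :, :]
    scores = -0.5 * np.sum(diff**2 / model.pooled_var, axis=2) + np.log(model.priors)
    return model.classes[np.argmax(scores, axis=1)]
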