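"""Pairwise dependency metrics: Spearman correlation and Kraskov kNN
mutual information, with histogram export helpers.

Used to characterise a gene panel's correlation regime (near-Gaussian vs
bimodal pairwise-correlation histograms) and the dependence between each
gene and the extracted malignancy risk.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import spearmanr

__all__ = ["spearman_pairs", "kraskov_mi", "mi_pairs", "dependency_histogram"]


def spearman_pairs(X: pd.DataFrame, extra: pd.Series | None = None) -> pd.DataFrame:
    """Spearman rank correlation (average ranks on ties) for every
    unordered feature pair, plus each feature against ``extra`` when
    given.  Constant columns yield missing rho with a warning.

    Returns a long DataFrame with columns feature_a, feature_b,
    spearman_rho.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 samples")
    cols = list(X.columns)
    mat = X.to_numpy(dtype=float)
    constant = [c for c, v in zip(cols, mat.T) if np.ptp(v) == 0]
    if extra is not None and np.ptp(np.asarray(extra, dtype=float)) == 0:
        constant.append(extra.name or "extra")
    if constant:
        warnings.warn(f"constant columns have undefined rho: {constant}")

    if extra is not None:
        full = np.column_stack([mat, np.asarray(extra, dtype=float)])
        names = cols + [extra.name or "extra"]
    else:
        full, names = mat, cols

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(full, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])

    rows = []
    p = len(cols)
    for i in range(p):
        for j in range(i + 1, p):
            rows.append((names[i], names[j], rho[i, j]))
    if extra is not None:
        for i in range(p):
            rows.append((names[i], names[-1], rho[i, -1]))
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "spearman_rho"])


def kraskov_mi(x, y, k: int = 3, seed: int = 0) -> float:
    """Kraskov-Stoegbauer-Grassberger mutual information (algorithm 1),
    in nats.

    MI = psi(k) + psi(N) - <psi(n_x + 1) + psi(n_y + 1)>, where the k-th
    neighbour distance is taken in the max norm on (x, y) and n_x, n_y
    count strictly closer marginal neighbours.  Exact ties are broken by
    a deterministic sub-resolution jitter, as the estimator assumes
    continuous marginals.  The estimate may dip slightly below zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} points, got {n}")
    if k >= n - 1:
        raise ValueError(f"k={k} must be < N-1={n - 1}")

    def dejitter(v):
        if len(np.unique(v)) < len(v):
            rng = np.random.default_rng(seed)
            scale = np.ptp(v) if np.ptp(v) > 0 else 1.0
            return v + rng.normal(0.0, 1e-10 * scale, size=len(v))
        return v

    x, y = dejitter(x), dejitter(y)
    z = np.column_stack([x, y])
    tree = cKDTree(z)
    # k+1 because the query point is its own nearest neighbour
    dist, _ = tree.query(z, k=k + 1, p=np.inf)
    eps = dist[:, k]

    def strict_counts(v):
        order = np.argsort(v)
        sv = v[order]
        lo = np.searchsorted(sv, v - eps, side="right")
        hi = np.searchsorted(sv, v + eps, side="left")
        return hi - lo - 1  # exclude the point itself

    nx = strict_counts(x)
    ny = strict_counts(y)
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


def mi_pairs(
    X: pd.DataFrame, extra: pd.Series | None = None, k: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Kraskov MI for every unordered feature pair (and each feature vs
    ``extra``), long format."""
    cols = list(X.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rows.append(
                (cols[i], cols[j], kraskov_mi(X[cols[i]], X[cols[j]], k=k, seed=seed))
            )
    if extra is not None:
        name = extra.name or "extra"
        for c in cols:
            rows.append((c, name, kraskov_mi(X[c], extra, k=k, seed=seed)))
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "mi_nats"])


def dependency_histogram(values, bin_width: float = 0.05) -> pd.DataFrame:
    """Bin dependency values into fixed-width bins (CSV-exportable summary
    mirroring the correlation/MI histogram figures)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    lo = np.floor(v.min() / bin_width) * bin_width if len(v) else 0.0
    hi = np.ceil(v.max() / bin_width) * bin_width if len(v) else bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(v, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
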