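"""Deterministic feature rankings on a training set.

Two filter rankers: the Wilcoxon rank-sum test with Benjamini-Hochberg
correction (features ranked by ascending adjusted p-value) and ReliefF
(features ranked by descending weight).  Both return a
:class:`FeatureRanking`, a full permutation of the input features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu, rankdata, norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureRanking",
    "rank_sum_pvalues",
    "wilcoxon_rank",
    "relieff_rank",
    "select_top",
]

#: combined-sample-size limit below which exact rank-sum p-values are used
EXACT_RANKSUM_LIMIT = 25


@dataclass
class FeatureRanking:
    """Ordered feature identifiers with their selection scores.

    ``scores[i]`` belongs to ``features[i]``: BH-adjusted p-values
    (nondecreasing) for the Wilcoxon ranker, weights (nonincreasing) for
    ReliefF.
    """

    features: list = field(default_factory=list)
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    method: str = ""

    def __len__(self):
        return len(self.features)


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def _as_binary(y):
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    return (y == classes[1]).astype(int)


def rank_sum_pvalues(X, y) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per column.

    Exact distribution when the combined sample size is <= 25 and the
    column has no ties; otherwise the normal approximation with tie
    correction (no continuity correction, so identical groups give
    p = 1).  Zero-variance columns give p = 1.
    """
    X, _ = _as_matrix(X)
    yb = _as_binary(y)
    n, p = X.shape
    n1, n2 = int(yb.sum()), int((1 - yb).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")

    ranks = rankdata(X, axis=0)
    r1 = ranks[yb == 1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    pvals = np.empty(p)
    for j in range(p):
        col = X[:, j]
        has_ties = len(np.unique(col)) < n
        if n <= EXACT_RANKSUM_LIMIT and not has_ties:
            pvals[j] = mannwhitneyu(
                col[yb == 1], col[yb == 0], alternative="two-sided", method="exact"
            ).pvalue
        else:
            _, t = np.unique(col, return_counts=True)
            tie_term = float(((t**3) - t).sum())
            var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
            if var <= 0:
                pvals[j] = 1.0
            else:
                z = (u1[j] - mu) / np.sqrt(var)
                pvals[j] = min(1.0, 2.0 * norm.sf(abs(z)))
    return pvals


def wilcoxon_rank(X, y) -> FeatureRanking:
    """Rank features by BH-adjusted two-sided rank-sum p-value, ascending;
    ties broken by raw p-value, then by feature index."""
    _, names = _as_matrix(X)
    raw = rank_sum_pvalues(X, y)
    adj = multipletests(raw, method="fdr_bh")[1]
    order = np.lexsort((np.arange(len(raw)), raw, adj))
    return FeatureRanking(
        features=[names[i] for i in order], scores=adj[order], method="wilcoxon"
    )


def relieff_rank(
    X, y, k_neighbors: int = 10, m="all", seed: int | None = None
) -> FeatureRanking:
    """ReliefF feature weights, ranked descending (ties by feature index).

    For each sampled instance the k nearest hits (same class) and k
    nearest misses per other class (weighted by prior odds
    P(miss class)/(1 - P(own class))) update the weights:
    W[f] -= diff(f, inst, hit)/(m k) and += w_c * diff(f, inst, miss)/(m k),
    with diff the feature-wise absolute difference on min-max-scaled
    values and Manhattan distance for the neighbour search.  With
    ``m='all'`` every training instance is used exactly once and the
    result is fully deterministic; constant features get weight 0.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y)
    n, p = Xm.shape
    classes, counts = np.unique(yv, return_counts=True)
    if k_neighbors > counts.min() - 1:
        raise ValueError(
            f"k_neighbors={k_neighbors} exceeds smallest class size - 1 = {counts.min() - 1}"
        )
    priors = dict(zip(classes, counts / n))

    rng_range = np.ptp(Xm, axis=0)
    safe_range = np.where(rng_range > 0, rng_range, 1.0)
    Xs = (Xm - Xm.min(axis=0)) / safe_range

    dist = cdist(Xs, Xs, metric="cityblock")

    if m == "all":
        instances = np.arange(n)
    else:
        m = int(m)
        if not 1 <= m <= n:
            raise ValueError(f"m must be in [1, {n}] or 'all', got {m}")
        rng = np.random.default_rng(seed)
        instances = rng.choice(n, size=m, replace=False)
    m_eff = len(instances)

    class_idx = {c: np.where(yv == c)[0] for c in classes}
    W = np.zeros(p)
    for i in instances:
        own = yv[i]
        hits_pool = class_idx[own][class_idx[own] != i]
        order = np.argsort(dist[i, hits_pool], kind="stable")
        hits = hits_pool[order[:k_neighbors]]
        W -= np.abs(Xs[hits] - Xs[i]).sum(axis=0) / (m_eff * k_neighbors)
        for c in classes:
            if c == own:
                continue
            pool = class_idx[c]
            order = np.argsort(dist[i, pool], kind="stable")
            misses = pool[order[:k_neighbors]]
            w_c = priors[c] / (1.0 - priors[own])
            W += w_c * np.abs(Xs[misses] - Xs[i]).sum(axis=0) / (m_eff * k_neighbors)

    order = np.lexsort((np.arange(p), -W))
    return FeatureRanking(
        features=[names[i] for i in order], scores=W[order], method="relieff"
    )


def select_top(ranking: FeatureRanking, N: int) -> set:
    """The first N identifiers of a ranking, as a set of size N."""
    if not 1 <= N <= len(ranking):
        raise ValueError(f"N must be in [1, {len(ranking)}], got {N}")
    return set(ranking.features[:N])
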