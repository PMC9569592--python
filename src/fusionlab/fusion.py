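"""Fusion strategies under bootstrap evaluation.

Three ways of combining a gene-expression matrix with the single
extracted clinical feature (malignancy risk):

* ``early``  — the risk column joins the gene matrix *before* feature
  selection and competes in the ranking;
* ``late``   — genes are ranked and selected first, then the risk column
  is appended (a model with nFeatures + 1 inputs);
* ``none``   — genes only (the reference model);
* ``clinical_only`` — the risk feature alone.

Each bootstrap iteration draws n samples with replacement (in-bag) and
tests on the out-of-bag samples; fusion, selection, z-score
normalization (train-fitted) and the linear-kernel SVM all sit inside
the loop so no information leaks from test to train.  In-bag draws are
shared across grid cells at equal iteration index, so strategies are
compared on identical resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .feature_selection import (
    FeatureRanking,
    rank_sum_pvalues,
    relieff_rank,
    select_top,
    wilcoxon_rank,
)
from . import stability as _stability

__all__ = [
    "RISK_ID",
    "STRATEGIES",
    "BootstrapRecord",
    "EvaluationGrid",
    "zscore_normalize",
    "run_iteration",
    "run_experiment",
    "summarize_accuracy",
    "compare_models",
]

RISK_ID = "Malignancy_risk"
STRATEGIES = ("early", "late", "none", "clinical_only")


@dataclass
class BootstrapRecord:
    """One bootstrap iteration: resample indices, the final classifier
    feature set, and out-of-bag accuracy."""

    iteration: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    selected: frozenset
    accuracy: float


@dataclass
class EvaluationGrid:
    """All bootstrap records per (strategy, method, nFeatures) cell."""

    records: dict = field(default_factory=dict)
    n_genes: int = 0
    risk_id: str = RISK_ID

    def accuracies(self, strategy, method, n_features) -> np.ndarray:
        return np.array(
            [r.accuracy for r in self.records[(strategy, method, n_features)]]
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for (strategy, method, nf), recs in sorted(self.records.items()):
            med, lo, hi = summarize_accuracy(recs)
            seq = _stability.gather_late_fusion_sets(
                recs, strategy, self.n_genes, risk_id=self.risk_id
            )
            kun = (
                _stability.kuncheva_index(seq)
                if 0 < seq.k < seq.n_universe
                else np.nan
            )
            rows.append(
                {
                    "strategy": strategy,
                    "method": method,
                    "n_features": nf,
                    "median_acc": med,
                    "ci_low": lo,
                    "ci_high": hi,
                    "kuncheva": kun,
                }
            )
        return pd.DataFrame(rows)

    def iteration_log(self) -> pd.DataFrame:
        rows = []
        for (strategy, method, nf), recs in sorted(self.records.items()):
            for r in recs:
                rows.append(
                    {
                        "strategy": strategy,
                        "method": method,
                        "n_features": nf,
                        "iteration": r.iteration,
                        "accuracy": r.accuracy,
                        "selected": ";".join(sorted(map(str, r.selected))),
                    }
                )
        return pd.DataFrame(rows)


def zscore_normalize(train: pd.DataFrame, test: pd.DataFrame | None = None):
    """Standardize both matrices with per-column mean/SD fitted on the
    training matrix (SD with the n-1 denominator); zero-SD columns map
    to all-zeros.  Test columns must all be present in train."""
    if len(train) == 0:
        raise ValueError("train must be nonempty")
    if test is not None:
        missing = set(test.columns) - set(train.columns)
        if missing:
            raise ValueError(f"test columns absent from train: {sorted(missing)}")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    ok = sd.to_numpy() > 0
    safe = sd.where(sd > 0, 1.0)

    def apply(df):
        z = (df - mu[df.columns]) / safe[df.columns]
        z.loc[:, [c for c, good in zip(train.columns, ok) if not good and c in df.columns]] = 0.0
        return z

    if test is None:
        return apply(train)
    return apply(train), apply(test[train.columns] if list(test.columns) != list(train.columns) else test)


def _rank(method: str, X: pd.DataFrame, y, relieff_k: int) -> FeatureRanking:
    if method == "wilcoxon":
        return wilcoxon_rank(X, y)
    if method == "relieff":
        return relieff_rank(X, y, k_neighbors=relieff_k, m="all")
    raise ValueError(f"unknown feature-selection method {method!r}")


def _fit_predict_accuracy(X_tr, y_tr, X_te, y_te, svm_C):
    # canonical column order: a linear kernel is permutation-invariant,
    # and fixing the order keeps the computation bit-reproducible across
    # strategies that assemble the same feature set differently
    cols = sorted(X_tr.columns, key=str)
    clf = SVC(kernel="linear", C=svm_C)
    clf.fit(X_tr[cols].to_numpy(), y_tr)
    return float(np.mean(clf.predict(X_te[cols].to_numpy()) == y_te))


def _iteration_core(
    X_genes,
    risk,
    y,
    inbag,
    oob,
    strategy,
    method,
    n_features,
    iteration=0,
    svm_C=1.0,
    relieff_k=10,
    leaky_normalization=False,
):
    y = np.asarray(y)
    y_tr, y_te = y[inbag], y[oob]
    p = X_genes.shape[1]

    def norm_pair(tr, te):
        if leaky_normalization:
            # literal whole-dataset reading, for sensitivity analysis only
            full = pd.concat([tr, te])
            ztr = zscore_normalize(full)
            return ztr.iloc[: len(tr)], ztr.iloc[len(tr):]
        return zscore_normalize(tr, te)

    if strategy == "early":
        if not 1 <= n_features <= p + 1:
            raise ValueError(f"n_features must be in [1, {p + 1}] for early fusion")
        pool = X_genes.copy()
        pool[RISK_ID] = np.asarray(risk, dtype=float)
        tr, te = pool.iloc[inbag], pool.iloc[oob]
        ztr, zte = norm_pair(tr, te)
        ranking = _rank(method, ztr, y_tr, relieff_k)
        sel = ranking.features[:n_features]
        X_tr, X_te = ztr[sel], zte[sel]
    elif strategy in ("late", "none"):
        if not 1 <= n_features <= p:
            raise ValueError(f"n_features must be in [1, {p}]")
        tr, te = X_genes.iloc[inbag], X_genes.iloc[oob]
        ranking = _rank(method, tr, y_tr, relieff_k)
        sel = ranking.features[:n_features]
        tr_sel, te_sel = tr[sel].copy(), te[sel].copy()
        if strategy == "late":
            tr_sel[RISK_ID] = np.asarray(risk, dtype=float)[inbag]
            te_sel[RISK_ID] = np.asarray(risk, dtype=float)[oob]
            sel = sel + [RISK_ID]
        X_tr, X_te = norm_pair(tr_sel, te_sel)
    elif strategy == "clinical_only":
        r = np.asarray(risk, dtype=float)
        tr = pd.DataFrame({RISK_ID: r[inbag]}, index=X_genes.index[inbag])
        te = pd.DataFrame({RISK_ID: r[oob]}, index=X_genes.index[oob])
        X_tr, X_te = norm_pair(tr, te)
        sel = [RISK_ID]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    acc = _fit_predict_accuracy(X_tr, y_tr, X_te, y_te, svm_C)
    return BootstrapRecord(
        iteration=iteration,
        train_idx=np.asarray(inbag),
        test_idx=np.asarray(oob),
        selected=frozenset(sel),
        accuracy=acc,
    )


def draw_inbag(rng, y, max_redraws: int = 100):
    """One bootstrap resample: n draws with replacement, out-of-bag as the
    test set.  Redraws (logged) if the in-bag part misses a class or the
    out-of-bag part is empty."""
    y = np.asarray(y)
    n = len(y)
    for _ in range(max_redraws):
        inbag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), inbag)
        if len(oob) > 0 and len(np.unique(y[inbag])) == 2:
            return inbag, oob
        warnings.warn("degenerate bootstrap draw; redrawing")
    raise RuntimeError("could not draw a valid bootstrap resample")


def run_iteration(
    X_genes,
    risk,
    y,
    strategy,
    method,
    n_features,
    rng,
    svm_C: float = 1.0,
    relieff_k: int = 10,
    leaky_normalization: bool = False,
) -> BootstrapRecord:
    """A single self-contained bootstrap iteration for one grid cell."""
    inbag, oob = draw_inbag(rng, y)
    return _iteration_core(
        X_genes,
        risk,
        y,
        inbag,
        oob,
        strategy,
        method,
        n_features,
        svm_C=svm_C,
        relieff_k=relieff_k,
        leaky_normalization=leaky_normalization,
    )


def run_experiment(
    X_genes: pd.DataFrame,
    risk,
    y,
    strategies=("early", "late", "none", "clinical_only"),
    methods=("wilcoxon", "relieff"),
    n_features_range=(1, 2, 3, 5, 8, 15),
    B: int = 500,
    seed: int = 0,
    svm_C: float = 1.0,
    relieff_k: int = 10,
    leaky_normalization: bool = False,
) -> EvaluationGrid:
    """Full bootstrap evaluation over the strategy x method x nFeatures
    grid.

    In-bag draws are generated once per iteration index and shared
    across every cell, so between-strategy comparisons are paired.
    Rankings are computed once per (iteration, method, candidate pool)
    and reused across nFeatures, which is exactly equivalent to running
    each cell independently (the rankers are deterministic).  The
    clinical_only strategy occupies a single cell per method (it ignores
    nFeatures; its model always has the one risk feature).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not strategies or not methods or (len(n_features_range) == 0):
        raise ValueError("empty evaluation grid")
    y = np.asarray(y)
    p = X_genes.shape[1]
    risk = np.asarray(risk, dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 97]))
    draws = [draw_inbag(rng, y) for _ in range(B)]

    grid = EvaluationGrid(records={}, n_genes=p, risk_id=RISK_ID)

    def add(cell, rec):
        grid.records.setdefault(cell, []).append(rec)

    gene_strats = [s for s in strategies if s in ("early", "late", "none")]
    for b, (inbag, oob) in enumerate(draws):
        y_tr = y[inbag]
        rankings: dict[tuple, FeatureRanking] = {}

        # candidate pools, built once per iteration
        tr_genes = X_genes.iloc[inbag]
        te_genes = X_genes.iloc[oob]
        pool = X_genes.copy()
        pool[RISK_ID] = risk
        if leaky_normalization:
            zpool = zscore_normalize(pool)
            ztr_pool, zte_pool = zpool.iloc[inbag], zpool.iloc[oob]
        else:
            ztr_pool, zte_pool = zscore_normalize(pool.iloc[inbag], pool.iloc[oob])

        for method in methods:
            if any(s in ("late", "none") for s in gene_strats):
                rankings[(method, "genes")] = _rank(method, tr_genes, y_tr, relieff_k)
            if "early" in gene_strats:
                rankings[(method, "pool")] = _rank(method, ztr_pool, y_tr, relieff_k)

        for strategy in strategies:
            if strategy == "clinical_only":
                rec = _iteration_core(
                    X_genes, risk, y, inbag, oob, "clinical_only", methods[0], 1,
                    iteration=b, svm_C=svm_C, relieff_k=relieff_k,
                    leaky_normalization=leaky_normalization,
                )
                for method in methods:
                    add((strategy, method, 1), rec)
                continue
            for method in methods:
                for nf in n_features_range:
                    if strategy == "early":
                        if not 1 <= nf <= p + 1:
                            raise ValueError(
                                f"n_features={nf} out of range for early fusion"
                            )
                        sel = rankings[(method, "pool")].features[:nf]
                        X_tr, X_te = ztr_pool[sel], zte_pool[sel]
                    else:
                        if not 1 <= nf <= p:
                            raise ValueError(f"n_features={nf} out of range")
                        sel = rankings[(method, "genes")].features[:nf]
                        tr_sel, te_sel = tr_genes[sel].copy(), te_genes[sel].copy()
                        if strategy == "late":
                            tr_sel[RISK_ID] = risk[inbag]
                            te_sel[RISK_ID] = risk[oob]
                            sel = sel + [RISK_ID]
                        if leaky_normalization:
                            full = pd.concat([tr_sel, te_sel])
                            zfull = zscore_normalize(full)
                            X_tr, X_te = zfull.iloc[: len(tr_sel)], zfull.iloc[len(tr_sel):]
                        else:
                            X_tr, X_te = zscore_normalize(tr_sel, te_sel)
                    acc = _fit_predict_accuracy(X_tr, y_tr, X_te, y[oob], svm_C)
                    add(
                        (strategy, method, nf),
                        BootstrapRecord(
                            iteration=b,
                            train_idx=inbag,
                            test_idx=oob,
                            selected=frozenset(sel),
                            accuracy=acc,
                        ),
                    )
    return grid


def summarize_accuracy(records) -> tuple[float, float, float]:
    """Median and 2.5/97.5 percentile bounds of per-iteration accuracies."""
    acc = np.array([r.accuracy for r in records], dtype=float)
    if len(acc) < 2:
        raise ValueError("need at least 2 records")
    lo, hi = np.percentile(acc, [2.5, 97.5])
    return float(np.median(acc)), float(lo), float(hi)


def compare_models(acc_a, acc_b) -> float:
    """Two-sided Mann-Whitney U p-value (tie-corrected, no continuity
    correction, exact for small tie-free samples) comparing two models'
    bootstrap accuracy distributions."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both accuracy vectors need length >= 2")
    X = np.concatenate([a, b])[:, None]
    y = np.concatenate([np.ones(len(a), dtype=int), np.zeros(len(b), dtype=int)])
    return float(rank_sum_pvalues(X, y)[0])
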