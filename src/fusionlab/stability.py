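"""Feature-selection stability across resamplings: the Kuncheva index.

The index is the chance-corrected mean pairwise overlap of the K
equal-size feature sets selected across bootstrap iterations.  For late
fusion — where the clinical risk feature is appended after selection —
the gathered sets are *all* features entering the classifier (selected
genes plus the risk identifier), so early- and late-fusion indices live
on a shared universe of size n_genes + 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelectionSequence", "kuncheva_index", "gather_late_fusion_sets", "stability_curve"]


@dataclass
class SelectionSequence:
    """K feature sets of equal cardinality k drawn from a universe of n
    features."""

    sets: list
    n_universe: int

    def __post_init__(self):
        self.sets = [frozenset(s) for s in self.sets]

    @property
    def k(self) -> int:
        return len(self.sets[0]) if self.sets else 0


def kuncheva_index(seq: SelectionSequence) -> float:
    """Kuncheva stability index.

    kappa(S) = 2/(K(K-1)) * sum_{i<j} (|S_i ^ S_j| - k^2/n) / (k - k^2/n).

    Equals 1 iff all sets are identical; the expectation under uniformly
    random selection is 0.  Undefined (rejected) when k = n.
    """
    sets = seq.sets
    K = len(sets)
    if K < 2:
        raise ValueError("need at least 2 selection sets")
    k = len(sets[0])
    if any(len(s) != k for s in sets):
        raise ValueError("all sets must have equal cardinality")
    n = seq.n_universe
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n (k={k}, n={n}); k = n is undefined")

    # incidence matrix: pairwise intersections via a Gram product
    universe = sorted(set().union(*sets))
    if len(universe) > n:
        raise ValueError("sets contain more distinct features than the universe size")
    idx = {f: i for i, f in enumerate(universe)}
    M = np.zeros((K, len(universe)))
    for i, s in enumerate(sets):
        for f in s:
            M[i, idx[f]] = 1.0
    inter = M @ M.T
    iu = np.triu_indices(K, k=1)
    chance = k * k / n
    terms = (inter[iu] - chance) / (k - chance)
    return float(terms.mean())


def gather_late_fusion_sets(
    records,
    strategy: str,
    n_genes: int,
    risk_id: str = "Malignancy_risk",
) -> SelectionSequence:
    """Build the selection sequence for one grid cell.

    For late fusion every gathered set is the selected genes plus the
    risk identifier (the records already store the full classifier
    feature set); for early fusion and no fusion the recorded selections
    pass through unchanged.  The universe is n_genes + 1 whenever the
    risk feature is in the candidate pool (early/late/clinical_only) and
    n_genes otherwise.  Records whose cardinality deviates from the
    modal cardinality are excluded with a warning rather than padded.
    """
    sets = [frozenset(r.selected) for r in records]
    if not sets:
        raise ValueError("no records")
    if strategy == "late" and any(risk_id not in s for s in sets):
        raise ValueError("late-fusion record missing the risk identifier")
    sizes = np.array([len(s) for s in sets])
    modal = int(np.bincount(sizes).argmax())
    if (sizes != modal).any():
        warnings.warn(
            f"excluding {(sizes != modal).sum()} record(s) with non-modal cardinality"
        )
        sets = [s for s in sets if len(s) == modal]
    n_universe = n_genes + 1 if strategy in ("early", "late", "clinical_only") else n_genes
    return SelectionSequence(sets=sets, n_universe=n_universe)


def stability_curve(grid, strategy: str, method: str) -> pd.Series:
    """Kuncheva index per nFeatures for one (strategy, method) of an
    evaluation grid; the degenerate k = n point is omitted."""
    cells = {
        nf: recs
        for (s, m, nf), recs in grid.records.items()
        if s == strategy and m == method
    }
    if not cells:
        raise ValueError(f"no grid cells for strategy={strategy!r}, method={method!r}")
    out = {}
    for nf in sorted(cells):
        seq = gather_late_fusion_sets(
            cells[nf], strategy, grid.n_genes, risk_id=grid.risk_id
        )
        if seq.k >= seq.n_universe:
            continue  # index undefined at k = n
        out[nf] = kuncheva_index(seq)
    return pd.Series(out, name="kuncheva").rename_axis("n_features")
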