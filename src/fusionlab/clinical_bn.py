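"""Clinical feature extraction via a discrete Bayesian network.

The raw clinical variables (sex, age, tumor size, Bethesda category) are
discretized into expert bands, a fully directed Bayesian network over
{Sex, Age, Size, Bethesda, Risk} is learned with Tabu search under the
AIC score, CPTs are estimated as Dirichlet posterior means (Bayesian
smoothing, so no zero probabilities), and each sample's *malignancy
risk* — P(Risk = malignant | clinical evidence) — is computed by
likelihood weighting with evidence restricted to the Markov blanket of
the Risk node.  Risk values are cross-fitted with stratified k-fold
splits so no sample is scored by a network trained on itself.
"""

from __future__ import annotations

import itertools
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "AGE_BANDS",
    "SIZE_BANDS",
    "discretize_clinical",
    "aic_score",
    "learn_structure",
    "estimate_parameters",
    "BayesNet",
    "query_risk",
    "exact_posterior",
    "sample_from_net",
    "extract_malignancy_risk",
]

AGE_BANDS = ("<20", "(20,45]", "(45,60]", ">60")
SIZE_BANDS = ("XS", "S", "M", "L", "XL", "XXL")

_AGE_EDGES = [0.0, 20.0, 45.0, 60.0, np.inf]
_SIZE_EDGES = [0.0, 0.5, 1.0, 1.5, 2.5, 4.0, np.inf]


def discretize_clinical(raw: pd.DataFrame) -> pd.DataFrame:
    """Map raw age/size to clinical bands; sex, Bethesda and the label pass
    through.

    Age bands: <20, (20,45], (45,60], >60 years.  Size bands at 0.5, 1,
    1.5, 2.5 and 4 cm (XS..XXL).  Intervals are left-open right-closed
    with the lowest bin closed at 0, so age 20 falls in "<20" and size
    0.5 cm in XS — the boundary values themselves are otherwise
    unassigned by the band definitions, and this convention makes the
    mapping total and deterministic.
    """
    for col in ("age", "tumor_size"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            idx = list(raw.index[bad])[:5]
            raise ValueError(f"non-positive or non-finite {col} at rows {idx}")
    age_band = pd.cut(raw["age"], _AGE_EDGES, labels=AGE_BANDS, right=True)
    size_band = pd.cut(raw["tumor_size"], _SIZE_EDGES, labels=SIZE_BANDS, right=True)
    out = pd.DataFrame(
        {
            "sex": raw["sex"],
            "age_band": age_band,
            "size_band": size_band,
            "bethesda": raw["bethesda"],
            "label": raw["label"],
        },
        index=raw.index,
    )
    for col in out:
        out[col] = out[col].astype("category")
    return out


# ---------------------------------------------------------------------------
# scoring


def _encode(data: pd.DataFrame):
    """Integer-code every column; domain = declared categories when the
    column is categorical (unobserved levels keep probability mass under
    smoothing), observed sorted uniques otherwise."""
    codes, domains = {}, {}
    for col in data.columns:
        s = data[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            domains[col] = list(s.cat.categories)
            codes[col] = s.cat.codes.to_numpy()
            if (codes[col] < 0).any():
                raise ValueError(f"missing values in column {col!r}")
        else:
            levels, c = np.unique(np.asarray(s), return_inverse=True)
            domains[col] = list(levels)
            codes[col] = c
    return codes, domains


def _family_counts(codes, domains, node, parents):
    r = len(domains[node])
    if parents:
        dims = [len(domains[p]) for p in parents]
        cfg = np.ravel_multi_index([codes[p] for p in parents], dims)
        q = int(np.prod(dims))
    else:
        cfg = np.zeros(len(codes[node]), dtype=int)
        q = 1
    counts = np.bincount(cfg * r + codes[node], minlength=q * r).reshape(q, r)
    return counts, r, q


def _family_score(codes, domains, node, parents):
    """Per-family AIC contribution: multinomial log-likelihood at the MLE
    minus (r-1)*q free parameters."""
    counts, r, q = _family_counts(codes, domains, node, parents)
    n_j = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / n_j), 0.0).sum()
    return float(ll) - (r - 1) * q


def aic_score(dag: dict, data: pd.DataFrame) -> float:
    """AIC of a DAG (``{node: tuple-of-parents}``): log-likelihood minus
    the number of free CPT parameters.  Decomposes over node families."""
    if len(data) == 0:
        raise ValueError("empty data")
    codes, domains = _encode(data)
    missing = set(dag) - set(data.columns)
    if missing:
        raise ValueError(f"dag nodes missing from data: {sorted(missing)}")
    return sum(
        _family_score(codes, domains, node, tuple(sorted(dag[node]))) for node in dag
    )


# ---------------------------------------------------------------------------
# structure learning (Tabu search)


def _has_path(parents, src, dst):
    """True if a directed path src -> ... -> dst exists."""
    children = {n: [] for n in parents}
    for child, pas in parents.items():
        for p in pas:
            children[p].append(child)
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(children[u])
    return False


def learn_structure(
    data: pd.DataFrame,
    seed: int = 0,
    tabu_length: int = 10,
    max_iter: int = 200,
) -> dict:
    """Learn a completely directed acyclic graph by Tabu search over
    single-edge add/delete/reverse moves scored by AIC.

    Deterministic given the data: moves are enumerated in lexicographic
    order and ties break toward the first enumerated move.  The tabu
    list forbids the inverses of the last ``tabu_length`` moves, with
    aspiration (a tabu move is allowed if it beats the best score seen).
    Returns ``{node: tuple of parents}``.
    """
    del seed  # the search is deterministic; accepted for interface stability
    if len(data.columns) < 2:
        raise ValueError("need at least 2 columns to learn a structure")
    codes, domains = _encode(data)
    nodes = sorted(data.columns)

    if all(len(np.unique(codes[n])) <= 1 for n in nodes):
        warnings.warn("constant dataset: returning the empty graph")
        return {n: () for n in nodes}

    cache: dict[tuple, float] = {}

    def fam(node, parents):
        key = (node, parents)
        if key not in cache:
            cache[key] = _family_score(codes, domains, node, parents)
        return cache[key]

    parents = {n: () for n in nodes}
    current = sum(fam(n, ()) for n in nodes)
    best_parents, best_score = dict(parents), current
    tabu: deque = deque(maxlen=tabu_length)

    def with_parent(node, add=None, remove=None):
        pa = set(parents[node])
        if add is not None:
            pa.add(add)
        if remove is not None:
            pa.discard(remove)
        return tuple(sorted(pa))

    for _ in range(max_iter):
        moves = []  # (delta, op_rank, u, v, op)
        for u, v in itertools.permutations(nodes, 2):
            if u in parents[v]:
                d_del = fam(v, with_parent(v, remove=u)) - fam(v, parents[v])
                moves.append((d_del, 1, u, v, "delete"))
                # reverse u->v to v->u
                tmp = dict(parents)
                tmp[v] = with_parent(v, remove=u)
                if not _has_path(tmp, u, v):
                    d_rev = d_del + fam(u, with_parent(u, add=v)) - fam(u, parents[u])
                    moves.append((d_rev, 2, u, v, "reverse"))
            else:
                if not _has_path(parents, v, u):  # u->v must not close a cycle
                    d_add = fam(v, with_parent(v, add=u)) - fam(v, parents[v])
                    moves.append((d_add, 0, u, v, "add"))

        chosen = None
        for delta, op_rank, u, v, op in sorted(
            moves, key=lambda m: (-m[0], m[1], m[2], m[3])
        ):
            move = (op, u, v)
            if move in tabu and current + delta <= best_score:
                continue  # tabu without aspiration
            chosen = (delta, op, u, v)
            break
        if chosen is None:
            break
        delta, op, u, v = chosen
        if op == "add":
            parents[v] = with_parent(v, add=u)
            tabu.append(("delete", u, v))
        elif op == "delete":
            parents[v] = with_parent(v, remove=u)
            tabu.append(("add", u, v))
        else:
            parents[v] = with_parent(v, remove=u)
            parents[u] = with_parent(u, add=v)
            tabu.append(("reverse", v, u))
        current += delta
        if current > best_score + 1e-12:
            best_score, best_parents = current, dict(parents)

    return best_parents


def all_dags(nodes):
    """Every DAG over the given labeled nodes (exhaustive oracle; feasible
    for <= 4 nodes — 3 DAGs on 2 nodes, 25 on 3, 543 on 4)."""
    nodes = list(nodes)
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        parents = {n: set() for n in nodes}
        for (a, b), s in zip(pairs, states):
            if s == 1:
                parents[b].add(a)
            elif s == 2:
                parents[a].add(b)
        dag = {n: tuple(sorted(p)) for n, p in parents.items()}
        order, rest = [], dict(parents)
        ok = True
        while rest:
            roots = [n for n, p in rest.items() if not (p & set(rest))]
            if not roots:
                ok = False
                break
            for n in roots:
                order.append(n)
                del rest[n]
        if ok:
            yield dag


# ---------------------------------------------------------------------------
# parameters and inference


@dataclass
class BayesNet:
    """Discrete Bayesian network: DAG plus one CPT per node.

    ``cpts[node]`` has shape ``(r_node, q)`` where column ``j`` is
    P(node | j-th parent configuration), parent configurations raveled
    over ``parents[node]`` in order.  Every entry is strictly positive.
    """

    nodes: list
    domains: dict
    parents: dict
    cpts: dict

    def topological_order(self):
        order, placed = [], set()
        rest = set(self.nodes)
        while rest:
            roots = sorted(n for n in rest if set(self.parents[n]) <= placed)
            if not roots:
                raise ValueError("graph is not acyclic")
            order.extend(roots)
            placed.update(roots)
            rest.difference_update(roots)
        return order

    def children(self, node):
        return sorted(c for c in self.nodes if node in self.parents[c])

    def markov_blanket(self, node):
        mb = set(self.parents[node])
        for c in self.children(node):
            mb.add(c)
            mb.update(self.parents[c])
        mb.discard(node)
        return mb


def estimate_parameters(dag: dict, data: pd.DataFrame, iss: float = 1.0) -> BayesNet:
    """Bayesian CPT estimation with a uniform Dirichlet prior of total
    imaginary sample size ``iss``: each entry is the posterior mean
    (n_ijk + iss/(r q)) / (n_ij + iss/q), hence strictly positive."""
    if iss <= 0:
        raise ValueError(f"iss must be positive, got {iss}")
    codes, domains = _encode(data)
    parents = {n: tuple(sorted(dag[n])) for n in dag}
    # acyclicity check via topological sort
    net = BayesNet(nodes=sorted(dag), domains=domains, parents=parents, cpts={})
    net.topological_order()
    for node in net.nodes:
        counts, r, q = _family_counts(codes, domains, node, parents[node])
        n_j = counts.sum(axis=1, keepdims=True)
        cpt = (counts + iss / (r * q)) / (n_j + iss / q)
        net.cpts[node] = np.ascontiguousarray(cpt.T)  # (r, q)
    return net


def _encode_evidence(net: BayesNet, evidence: dict) -> dict:
    enc = {}
    for node, val in evidence.items():
        dom = net.domains[node]
        if val not in dom:
            raise ValueError(f"value {val!r} not in domain of {node!r}: {dom}")
        enc[node] = dom.index(val)
    return enc


def _parent_cfg(net, node, sample_codes):
    pas = net.parents[node]
    if not pas:
        return np.zeros(sample_codes["__n__"], dtype=int)
    dims = [len(net.domains[p]) for p in pas]
    return np.ravel_multi_index([sample_codes[p] for p in pas], dims)


def query_risk(
    net: BayesNet,
    evidence: dict,
    n_draws: int = 10_000,
    seed: int = 0,
    target: str = "Risk",
    positive="malignant",
) -> float:
    """Likelihood-weighting estimate of P(target = positive | evidence).

    Evidence is restricted to the Markov blanket of the target; variables
    outside the blanket are ignored with a warning (they carry no
    information about the target beyond the blanket).  Non-evidence
    nodes are sampled in topological order; each draw is weighted by the
    product of the evidence likelihoods.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    mb = net.markov_blanket(target)
    extra = sorted(set(evidence) - mb - {target})
    if extra:
        warnings.warn(
            f"evidence outside the Markov blanket of {target!r} ignored: {extra}"
        )
    evidence = {k: v for k, v in evidence.items() if k in mb}
    enc = _encode_evidence(net, evidence)
    rng = np.random.default_rng(seed)

    samples = {"__n__": n_draws}
    logw = np.zeros(n_draws)
    for node in net.topological_order():
        cfg = _parent_cfg(net, node, samples)
        probs = net.cpts[node][:, cfg]  # (r, n_draws)
        if node in enc:
            code = enc[node]
            logw += np.log(probs[code, np.arange(n_draws)])
            samples[node] = np.full(n_draws, code, dtype=int)
        else:
            u = rng.random(n_draws)
            cum = np.cumsum(probs, axis=0)
            samples[node] = (u[None, :] >= cum).sum(axis=0)
    w = np.exp(logw - logw.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("likelihood weighting produced zero total weight")
    pos_code = net.domains[target].index(positive)
    return float((w * (samples[target] == pos_code)).sum() / total)


def exact_posterior(net: BayesNet, target: str, evidence: dict) -> dict:
    """Exact posterior over ``target`` by full joint enumeration (oracle
    for small networks; cost is the product of all domain sizes)."""
    enc = _encode_evidence(net, evidence)
    nodes = net.topological_order()
    dims = [len(net.domains[n]) for n in nodes]
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    flat = {n: g.ravel() for n, g in zip(nodes, grids)}
    flat["__n__"] = len(flat[nodes[0]])
    logp = np.zeros(flat["__n__"])
    for node in nodes:
        cfg = _parent_cfg(net, node, flat)
        logp += np.log(net.cpts[node][flat[node], cfg])
    p = np.exp(logp - logp.max())
    mask = np.ones(flat["__n__"], dtype=bool)
    for node, code in enc.items():
        mask &= flat[node] == code
    p = np.where(mask, p, 0.0)
    t = flat[target]
    post = np.array(
        [p[t == c].sum() for c in range(len(net.domains[target]))], dtype=float
    )
    return dict(zip(net.domains[target], post / post.sum()))


def sample_from_net(net: BayesNet, n: int, seed: int = 0) -> pd.DataFrame:
    """Forward (ancestral) sampling of ``n`` joint observations."""
    rng = np.random.default_rng(seed)
    samples = {"__n__": n}
    for node in net.topological_order():
        cfg = _parent_cfg(net, node, samples)
        probs = net.cpts[node][:, cfg]
        u = rng.random(n)
        cum = np.cumsum(probs, axis=0)
        samples[node] = (u[None, :] >= cum).sum(axis=0)
    return pd.DataFrame(
        {
            node: pd.Categorical.from_codes(samples[node], categories=net.domains[node])
            for node in net.nodes
        }
    )


# ---------------------------------------------------------------------------
# cross-fitted risk extraction

_NODE_MAP = {
    "sex": "Sex",
    "age_band": "Age",
    "size_band": "Size",
    "bethesda": "Bethesda",
    "label": "Risk",
}


def extract_malignancy_risk(
    data: pd.DataFrame,
    k: int = 10,
    iss: float = 1.0,
    n_draws: int = 10_000,
    seed: int = 0,
    method: str = "lw",
) -> pd.Series:
    """Cross-fitted malignancy risk: one probability per sample.

    Samples are split into ``k`` stratified folds.  For each fold the
    network structure and CPTs are learned on the other folds (with the
    histopathology label as the Risk node) and every held-out sample is
    scored by querying P(Risk = malignant | its clinical values), with
    evidence restricted to the Markov blanket of Risk.  ``method='lw'``
    uses likelihood weighting with ``n_draws`` draws per distinct
    evidence pattern; ``method='exact'`` uses joint enumeration.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if method not in ("lw", "exact"):
        raise ValueError(f"unknown method {method!r}")
    frame = data[list(_NODE_MAP)].rename(columns=_NODE_MAP)
    for col in frame:
        frame[col] = frame[col].astype("category")
    y = frame["Risk"].to_numpy()

    risks = pd.Series(np.nan, index=data.index, name="Malignancy_risk")
    fold_seed = seed
    for _attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed & 0x7FFFFFFF)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
        warnings.warn("single-class training split; repartitioning with a new seed")
        fold_seed += 1
    else:
        raise ValueError("could not build stratified folds with both classes")

    clinical_nodes = ["Sex", "Age", "Size", "Bethesda"]
    for fold, (tr, te) in enumerate(splits):
        train = frame.iloc[tr]
        dag = learn_structure(train, seed=seed)
        net = estimate_parameters(dag, train, iss=iss)
        mb = net.markov_blanket("Risk")
        cache: dict[tuple, float] = {}
        q_seed = int(np.random.SeedSequence([seed & 0x7FFFFFFF, fold]).generate_state(1)[0] >> 1)
        for row_pos, i in enumerate(te):
            row = frame.iloc[i]
            ev = {n: row[n] for n in clinical_nodes if n in mb}
            key = tuple(sorted(ev.items()))
            if key not in cache:
                if method == "exact":
                    cache[key] = exact_posterior(net, "Risk", ev)["malignant"]
                else:
                    cache[key] = query_risk(
                        net, ev, n_draws=n_draws, seed=q_seed + len(cache)
                    )
            risks.iloc[i] = cache[key]
    return risks
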