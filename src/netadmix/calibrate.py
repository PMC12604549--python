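"""Network calibration: ultrametrize a network against gene-tree distances.

The selected network's topology and inheritance probabilities are held
fixed while node ages are fitted so that the network's expected pairwise
distances match the mean patristic distances observed across (normalised)
gene trees. Because inferred internal branch lengths carry real signal but
a compressed scale, the objective adds a penalty on changes to the
internal branch lengths, weighted by the ratio of the mean distance-matrix
entry to the mean internal branch length, and a power transform D^p of the
distance matrix whose exponent is optimised within [p_init/10, 10 p_init].

On an ultrametric network the expected distance between two leaves is
linear in node ages:

    d(i, j) = sum_T p_T * 2 * age(mrca_T(i, j))

over displayed trees T, so for fixed exponent p the inner problem is a
linear least squares in the age vector; ages are accepted from the closed
form when they satisfy the parent-older-than-child ordering and refined
with constrained optimisation (multistart SLSQP) otherwise. Ultrametricity
and hybrid-below-parent feasibility are structural in this
parameterisation, never penalised.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .network import SpeciesNetwork

__all__ = [
    "mean_pairwise_distances",
    "power_transform",
    "internal_weight",
    "calibrate",
    "ultrametric_check",
    "CalibrationProblem",
    "CalibratedNetwork",
]


# ----------------------------------------------------------------------
def mean_pairwise_distances(trees, taxa=None, allow_missing: bool = False):
    """Mean patristic distance per taxon pair over the trees containing
    both. Returns (distance DataFrame, co-presence count DataFrame);
    raises when a pair co-occurs in no tree unless `allow_missing`."""
    if taxa is None:
        taxa = sorted({lab for t in trees for lab in t.leaf_labels})
    taxa = list(taxa)
    n = len(taxa)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for t in trees:
        present = [x for x in taxa if t.has_leaf(x)]
        if len(present) < 2:
            continue
        idx = [taxa.index(x) for x in present]
        d = t.patristic_matrix(present)
        ix = np.ix_(idx, idx)
        acc[ix] += d
        cnt[ix] += 1
    np.fill_diagonal(cnt, 1)  # avoid 0/0 on the diagonal
    never = (cnt == 0)
    if never.any():
        pairs = [
            (taxa[i], taxa[j]) for i, j in zip(*np.where(never)) if i < j
        ]
        if not allow_missing:
            raise ValueError(f"taxon pairs never co-present in any tree: {pairs}")
        warnings.warn(f"pairs never co-present, left NaN: {pairs}")
        cnt[never] = np.nan
    out = acc / cnt
    np.fill_diagonal(out, 0.0)
    np.fill_diagonal(cnt, 0)
    return (
        pd.DataFrame(out, index=taxa, columns=taxa),
        pd.DataFrame(cnt, index=taxa, columns=taxa),
    )


def power_transform(d, p: float):
    """Elementwise d**p; order-preserving, identity at p = 1."""
    if p <= 0:
        raise ValueError("exponent p must be > 0")
    return np.asarray(d, dtype=float) ** p


def internal_edges(net: SpeciesNetwork) -> list:
    leaves = set(net.leaves)
    return [
        (u, v) for u, v in net.graph.edges if v not in leaves
    ]


def internal_weight(dbar, net: SpeciesNetwork) -> float:
    """w = mean(off-diagonal of the distance matrix) / mean initial
    internal branch length of the network."""
    d = np.asarray(dbar, dtype=float)
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    lens = [net.edge_length(u, v) for u, v in internal_edges(net)]
    if not lens or any(l is None for l in lens):
        raise ValueError("network lacks internal branch lengths")
    mean_int = float(np.mean(lens))
    if mean_int <= 0:
        raise ValueError("mean internal branch length is zero; w undefined")
    return float(off.mean()) / mean_int


# ----------------------------------------------------------------------
@dataclass
class CalibrationProblem:
    network: SpeciesNetwork  # topology + gamma fixed; lengths = l0 where known
    dbar: pd.DataFrame  # mean pairwise distances (taxa x taxa)
    p_init: float = 1.0
    w: float | None = None  # None -> internal_weight(dbar, network); 0 allowed
    multistarts: int = 8
    seed: int = 0
    tol: float = 1e-12

    def __post_init__(self):
        d = self.dbar.to_numpy()
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any() or (d < 0).any():
            raise ValueError("distance matrix needs zero diagonal, entries >= 0")
        if set(self.dbar.index) != set(self.network.leaves):
            raise ValueError("distance-matrix taxa must equal network leaves")
        if self.p_init <= 0:
            raise ValueError("p_init must be > 0")


@dataclass
class CalibratedNetwork:
    network: SpeciesNetwork  # edge lengths induced by the fitted ages
    ages: dict  # node -> age (leaves at 0)
    p: float
    objective: float
    distance_term: float
    penalty_term: float
    w: float
    converged: bool
    trace: list = field(default_factory=list)  # (p, objective) evaluations

    def normalized_ages(self) -> dict:
        root_age = self.ages[self.network.root]
        return {v: a / root_age for v, a in self.ages.items()}


def _displayed_mrca_maps(net: SpeciesNetwork):
    """Per displayed tree: (probability, {leaf pair -> mrca network node}).

    The MRCA is taken in the resolved (pre-suppression) tree, where it is
    always a surviving branching node of the network.
    """
    g = net.graph
    hybrids = net.hybrid_nodes
    leaves = net.leaves
    parent_sets = [sorted(g.predecessors(h)) for h in hybrids]
    out = []
    for combo in itertools.product(*parent_sets):
        prob = 1.0
        parent_of = {}
        choice = dict(zip(hybrids, combo))
        for v in g:
            preds = list(g.predecessors(v))
            if not preds:
                continue
            if len(preds) == 1:
                parent_of[v] = preds[0]
            else:
                parent_of[v] = choice[v]
                prob *= g.edges[choice[v], v]["gamma"]
        chains = {}
        for leaf in leaves:
            chain = [leaf]
            while chain[-1] in parent_of:
                chain.append(parent_of[chain[-1]])
            chains[leaf] = chain
        mrca = {}
        for i, a in enumerate(leaves):
            pos = {v: k for k, v in enumerate(chains[a])}
            for b in leaves[i + 1:]:
                v = next(x for x in chains[b] if x in pos)
                mrca[(a, b)] = v
        out.append((prob, mrca))
    return out


def _design(problem: CalibrationProblem):
    """Rows of the stacked least-squares system (distance + penalty)."""
    net = problem.network
    leaves = net.leaves
    internal = [v for v in net.graph if net.graph.out_degree(v) > 0]
    col = {v: k for k, v in enumerate(internal)}
    pairs = [(a, b) for i, a in enumerate(leaves) for b in leaves[i + 1:]]
    A_dist = np.zeros((len(pairs), len(internal)))
    for prob, mrca in _displayed_mrca_maps(net):
        for r, pr in enumerate(pairs):
            A_dist[r, col[mrca[pr]]] += 2.0 * prob
    dvec = np.array([problem.dbar.loc[a, b] for a, b in pairs])

    pen_edges = internal_edges(net)
    l0 = np.array([net.edge_length(u, v) for u, v in pen_edges], dtype=float)
    A_pen = np.zeros((len(pen_edges), len(internal)))
    for r, (u, v) in enumerate(pen_edges):
        A_pen[r, col[u]] += 1.0
        A_pen[r, col[v]] -= 1.0
    # edge ordering constraints: age(parent) - age(child) >= 0
    cons_rows = []
    for u, v in net.graph.edges:
        row = np.zeros(len(internal))
        row[col[u]] = 1.0
        if v in col:
            row[col[v]] -= 1.0
        cons_rows.append(row)
    return internal, col, pairs, A_dist, dvec, A_pen, l0, np.array(cons_rows)


def _solve_ages(A_dist, dvec_p, A_pen, l0, w, cons, multistarts, seed):
    """Minimise ||A_dist x - d||^2 + w ||A_pen x - l0||^2 s.t. cons @ x >= 0."""
    sw = np.sqrt(w)
    A = np.vstack([A_dist, sw * A_pen]) if w > 0 else A_dist
    t = np.concatenate([dvec_p, sw * l0]) if w > 0 else dvec_p
    x, *_ = np.linalg.lstsq(A, t, rcond=None)
    if cons.size == 0 or (cons @ x).min() >= -1e-12:
        r = A @ x - t
        return x, float(r @ r), True

    def obj(x):
        r = A @ x - t
        return float(r @ r)

    def grad(x):
        return 2.0 * A.T @ (A @ x - t)

    rng = np.random.default_rng(seed)
    best, best_f = None, np.inf
    x0_base = np.maximum(x, 0)
    for k in range(max(1, multistarts)):
        x0 = x0_base * (1 + 0.3 * rng.standard_normal(len(x))) if k else x0_base
        res = optimize.minimize(
            obj,
            x0,
            jac=grad,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": lambda y: cons @ y,
                          "jac": lambda y: cons}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.fun < best_f:
            best, best_f = res.x, res.fun
    ok = best is not None and (cons @ best).min() >= -1e-8
    return best, float(best_f), ok


def calibrate(problem: CalibrationProblem) -> CalibratedNetwork:
    """Fit node ages and the transform exponent; see the module docstring."""
    net = problem.network
    w = problem.w if problem.w is not None else internal_weight(
        problem.dbar.to_numpy(), net
    )
    internal, col, pairs, A_dist, dvec, A_pen, l0, cons = _design(problem)
    trace = []

    def inner(p):
        x, f, ok = _solve_ages(
            A_dist, power_transform(dvec, p), A_pen, l0, w, cons,
            problem.multistarts, problem.seed,
        )
        trace.append((float(p), f))
        return x, f, ok

    lo, hi = problem.p_init / 10.0, problem.p_init * 10.0
    res = optimize.minimize_scalar(
        lambda lp: inner(np.exp(lp))[1],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    p_best = float(np.exp(res.x))
    # guard against a local optimum missing the identity transform
    if inner(problem.p_init)[1] < res.fun - 1e-15:
        p_best = problem.p_init
    x, f, ok = inner(p_best)
    if x is None:
        raise RuntimeError("calibration failed to produce a feasible age vector")

    ages = {v: float(x[col[v]]) for v in internal}
    for leaf in net.leaves:
        ages[leaf] = 0.0
    out_net = net.copy()
    for u, v in out_net.graph.edges:
        out_net.graph.edges[u, v]["length"] = max(ages[u] - ages[v], 0.0)
    r_dist = A_dist @ x - power_transform(dvec, p_best)
    r_pen = A_pen @ x - l0
    return CalibratedNetwork(
        network=out_net,
        ages=ages,
        p=p_best,
        objective=f,
        distance_term=float(r_dist @ r_dist),
        penalty_term=float(r_pen @ r_pen),
        w=float(w),
        converged=ok,
        trace=trace,
    )


# ----------------------------------------------------------------------
def ultrametric_check(net: SpeciesNetwork, tol: float = 1e-8) -> dict:
    """Max deviation of root-to-leaf path lengths (over all displayed
    paths through hybrid nodes) from their common value."""
    net.require_lengths()
    g = net.graph
    totals = []
    stack = [(net.root, 0.0)]
    while stack:
        v, acc = stack.pop()
        if g.out_degree(v) == 0:
            totals.append(acc)
        else:
            for c in g.successors(v):
                stack.append((c, acc + g.edges[v, c]["length"]))
    totals = np.array(totals)
    ref = totals.mean()
    dev = float(np.abs(totals - ref).max())
    return {"pass": dev < tol, "max_deviation": dev, "root_age": float(ref)}
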