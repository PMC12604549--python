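"""Discrete-trait ancestral state reconstruction on calibrated networks.

The substitution model is the k-state equal-rates Markov chain (the Mk
model; called the equal-rates substitution model, ERSM, in the network
literature): a single rate alpha, uniform stationary distribution, and

    P(i -> j | t) = 1/k - (1/k)  exp(-k alpha t)     (i != j)
    P(i -> i | t) = 1/k + (1-1/k) exp(-k alpha t)

On a network the likelihood is the inheritance-weighted mixture over
displayed trees, each scored with Felsenstein pruning under a uniform root
prior; marginal ancestral posteriors are computed per displayed tree by
the standard up-down pass and combined with weights proportional to
gamma-product times tree likelihood. A node suppressed in a displayed
tree (a degree-2 pass-through) inherits the posterior of its surviving
edge's child.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .network import SpeciesNetwork
from .snp import TraitTable
from .trees import Tree

__all__ = [
    "ersm_transition_matrix",
    "network_trait_loglik",
    "fit_ersm",
    "marginal_asr",
    "reconstruct_all",
    "simulate_discrete_trait",
    "ASRResult",
]

ALPHA_BOUNDS = (1e-8, 1e3)


def ersm_transition_matrix(k: int, alpha: float, t: float) -> np.ndarray:
    """Equal-rates transition probabilities over duration t."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    e = np.exp(-k * alpha * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, (1.0 - e) / k + e)
    return P


# ----------------------------------------------------------------------
def _tree_partials(tree: Tree, tip_states: dict, k: int, alpha: float):
    """Per-node partial likelihood arrays (pruning, post-order)."""
    L = np.zeros((tree.n_nodes, k))
    order = tree.topo_order()
    for v in reversed(order):
        if tree.is_leaf(v):
            s = tip_states[tree.label[v]]
            L[v, s] = 1.0
        else:
            acc = np.ones(k)
            for c in tree.children[v]:
                P = ersm_transition_matrix(k, alpha, float(tree.length[c]))
                acc *= P @ L[c]
            L[v] = acc
    return L


def _tree_loglik_from_partials(L_root: np.ndarray, k: int) -> float:
    return float(np.log(np.clip(L_root.mean(), 1e-300, None)))


def tree_trait_loglik(tree: Tree, tip_states: dict, k: int, alpha: float) -> float:
    """Pruning log-likelihood on a single tree with a uniform root prior."""
    L = _tree_partials(tree, tip_states, k, alpha)
    return _tree_loglik_from_partials(L[tree.root], k)


def _tree_marginals(tree: Tree, tip_states: dict, k: int, alpha: float):
    """Marginal posterior per node (up-down pass); returns (post, loglik)."""
    L = _tree_partials(tree, tip_states, k, alpha)
    out = np.zeros((tree.n_nodes, k))
    out[tree.root] = 1.0 / k
    order = tree.topo_order()
    # cache per-child contributions M_c(s) = sum_s' P(s,s') L_c(s')
    M = {}
    for v in order:
        for c in tree.children[v]:
            P = ersm_transition_matrix(k, alpha, float(tree.length[c]))
            M[c] = (P, P @ L[c])
    for v in order:
        kids = tree.children[v]
        for c in kids:
            P, _ = M[c]
            prod = out[v].copy()
            for d in kids:
                if d != c:
                    prod *= M[d][1]
            out[c] = prod @ P
    post = L * out
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    post = post / norm
    return post, _tree_loglik_from_partials(L[tree.root], k)


# ----------------------------------------------------------------------
def _prepare(net: SpeciesNetwork, states: dict, state_order=None):
    leaves = net.leaves
    missing = [t for t in leaves if t not in states]
    if missing:
        raise ValueError(f"leaves without a trait state: {missing}")
    if state_order is None:
        state_order = sorted(set(states.values()))
    if len(state_order) < 2:
        raise ValueError(
            "state space has fewer than 2 states; pass state_order explicitly "
            "when all tips share one state"
        )
    index = {s: i for i, s in enumerate(state_order)}
    tip_states = {t: index[states[t]] for t in leaves}
    return tip_states, list(state_order)


def network_trait_loglik(
    net: SpeciesNetwork, states: dict, alpha: float, state_order=None
) -> float:
    """log of the displayed-tree mixture likelihood sum_T P(T) L_T(alpha)."""
    tip_states, order = _prepare(net, states, state_order)
    k = len(order)
    parts = []
    for dt in net.displayed_trees():
        ll = tree_trait_loglik(dt.tree, tip_states, k, alpha)
        parts.append(np.log(dt.probability) + ll if dt.probability > 0 else -np.inf)
    m = max(parts)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(sum(np.exp(p - m) for p in parts)))


def fit_ersm(
    net: SpeciesNetwork,
    states,
    state_order=None,
    bounds=ALPHA_BOUNDS,
) -> dict:
    """Maximum-likelihood alpha by 1-D search on a log scale.

    `states` may be one taxon->state mapping or a list of them; with
    several, alpha is fitted jointly (summed log-likelihood over
    independent characters). A flat likelihood (all tips identical) pins
    alpha at the lower boundary and is flagged, not raised.
    """
    if isinstance(states, dict):
        states = [states]

    def negll(log_a):
        a = float(np.exp(log_a))
        return -sum(
            network_trait_loglik(net, s, a, state_order) for s in states
        )

    res = optimize.minimize_scalar(
        negll,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(np.exp(res.x))
    at_bound = (
        alpha <= bounds[0] * (1 + 1e-6) or alpha >= bounds[1] * (1 - 1e-6)
    )
    return {
        "alpha": alpha,
        "loglik": float(-res.fun),
        "at_boundary": bool(at_bound),
    }


# ----------------------------------------------------------------------
@dataclass
class ASRResult:
    posteriors: pd.DataFrame  # index: network node, columns: states
    alpha: float
    loglik: float
    tree_weights: list  # (choices, weight) per displayed tree
    states: list


def marginal_asr(
    net: SpeciesNetwork, states: dict, alpha: float, state_order=None
) -> ASRResult:
    """Marginal ancestral posteriors at every network node.

    Displayed-tree marginals are mixed with weights P(T) L_T / L; a
    network node absent from a displayed tree contributes only through
    the trees containing it (weights renormalised over those).
    """
    tip_states, order = _prepare(net, states, state_order)
    k = len(order)
    dts = net.displayed_trees()
    posts, logliks = [], []
    for dt in dts:
        post, ll = _tree_marginals(dt.tree, tip_states, k, alpha)
        posts.append(post)
        logliks.append(ll)
    logw = np.array(
        [np.log(dt.probability) if dt.probability > 0 else -np.inf for dt in dts]
    ) + np.array(logliks)
    m = logw.max()
    w = np.exp(logw - m)
    w /= w.sum()
    nodes = sorted(net.graph.nodes, key=str)
    table = np.zeros((len(nodes), k))
    for r, v in enumerate(nodes):
        mass = 0.0
        for dt, wt, post in zip(dts, w, posts):
            tn = dt.node_map.get(v, -1)
            if tn < 0:
                continue
            table[r] += wt * post[tn]
            mass += wt
        if mass > 0:
            table[r] /= mass
        else:  # pragma: no cover - defensive; every node persists somewhere
            table[r] = 1.0 / k
    total_ll = float(m + np.log(np.exp(logw - m).sum()))
    return ASRResult(
        posteriors=pd.DataFrame(table, index=nodes, columns=order),
        alpha=alpha,
        loglik=total_ll,
        tree_weights=[(dt.choices, float(wt)) for dt, wt in zip(dts, w)],
        states=order,
    )


def reconstruct_all(
    net: SpeciesNetwork,
    traits: TraitTable,
    trait_names=None,
    drop_missing: bool = False,
) -> dict:
    """Fit alpha and reconstruct marginals per trait on one network.

    Returns {trait name: ASRResult}. The leaf set is fixed by the
    network, so a leaf without a state is an error; with `drop_missing`
    the affected trait is skipped (with no entry in the result) instead.
    """
    if trait_names is None:
        trait_names = [c for c in traits.data.columns]
    out = {}
    for name in trait_names:
        states = traits.states(name)
        missing = [t for t in net.leaves if t not in states]
        if missing:
            if drop_missing:
                continue
            raise ValueError(f"trait {name!r}: no state for {missing}")
        order = list(TraitTable.STATES.get(name, sorted(set(states.values()))))
        order = [s for s in order if s in set(states.values())] or None
        fit = fit_ersm(net, states, state_order=order)
        out[name] = marginal_asr(net, states, fit["alpha"], state_order=order)
    return out


# ----------------------------------------------------------------------
def simulate_discrete_trait(
    net: SpeciesNetwork,
    alpha: float,
    n_traits: int,
    seed: int,
    k: int = 2,
    state_names=None,
) -> tuple[pd.DataFrame, list]:
    """Simulate trait histories on the network under the equal-rates model.

    Per trait, one displayed tree is drawn by its gamma-product
    probability, a root state from the uniform prior, and states evolve
    down the tree. Returns (taxon x trait state table, per-trait truth:
    (displayed-tree choices, node state map)).
    """
    if state_names is None:
        state_names = [f"s{i}" for i in range(k)]
    rng = np.random.default_rng(seed)
    dts = net.displayed_trees()
    probs = np.array([dt.probability for dt in dts])
    probs = probs / probs.sum()
    cols = {}
    truth = []
    for j in range(n_traits):
        dt = dts[rng.choice(len(dts), p=probs)]
        tree = dt.tree
        state = np.zeros(tree.n_nodes, dtype=int)
        state[tree.root] = rng.integers(k)
        for v in tree.topo_order():
            if v == tree.root:
                continue
            P = ersm_transition_matrix(k, alpha, float(tree.length[v]))
            state[v] = rng.choice(k, p=P[state[int(tree.parent[v])]])
        col = {
            tree.label[v]: state_names[state[v]]
            for v in range(tree.n_nodes)
            if tree.is_leaf(v)
        }
        cols[f"trait{j}"] = col
        truth.append((dt.choices, {int(v): int(s) for v, s in enumerate(state)}))
    return pd.DataFrame(cols), truth
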