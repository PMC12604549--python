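"""Candidate-network scoring, ranking and prevailing-network selection.

Under the multispecies coalescent, an unrooted 4-taxon set whose species
tree has internal branch length t (coalescent units) resolves as the
matching topology with probability 1 - (2/3) e^{-t} and as each of the two
alternatives with probability (1/3) e^{-t}. On a network, expected
concordance factors (CFs) are computed as the gamma-weighted mixture of
the displayed trees' CFs — exact whenever, restricted to the quartet, at
most one lineage enters each reticulation, and a documented approximation
otherwise (the simulator quantifies the error for any configuration).

Candidates are scored against observed gene-tree CFs with a multinomial
composite log-likelihood; score *differences* in natural-log units drive
the published ranking rules (strong <= 10 < moderate <= 20 < poor < 30 <=
excluded) and the majority-rule selection of a prevailing network across
resamplings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize

from .network import SpeciesNetwork
from .trees import Tree

__all__ = [
    "expected_quartet_cf",
    "observed_quartet_cf",
    "cf_table_from_coal_times",
    "pseudo_loglik",
    "classify_support",
    "exclude_outgroup_reticulations",
    "select_prevailing",
    "fit_gamma",
    "CandidateEvaluation",
]

CF_FLOOR = 1e-12

STRONG, MODERATE, POOR = "strong", "moderate", "poor"
EXCLUDED_DELTA, EXCLUDED_OUTGROUP = "excluded_delta", "excluded_outgroup"


# ----------------------------------------------------------------------
def _quartet_cf_tree(tree: Tree, quartet) -> np.ndarray:
    """CF triple of one displayed tree for a quartet (a,b,c,d).

    Index order: 0 = ab|cd, 1 = ac|bd, 2 = ad|bc. Uses the four-point
    condition on patristic distances; a zero internal branch gives the
    star CFs (1/3, 1/3, 1/3).
    """
    a, b, c, d = quartet
    dm = tree.patristic_matrix([a, b, c, d])
    # internal branch length for pairing ab|cd etc.
    sums = np.array(
        [dm[0, 1] + dm[2, 3], dm[0, 2] + dm[1, 3], dm[0, 3] + dm[1, 2]]
    )
    topo = int(np.argmin(sums))
    others = [s for i, s in enumerate(sums) if i != topo]
    t = (min(others) - sums[topo]) / 2.0
    cf = np.full(3, np.exp(-t) / 3.0)
    cf[topo] = 1.0 - 2.0 / 3.0 * np.exp(-t)
    return cf


def _mixture_cf(displayed, quartet) -> np.ndarray:
    cf = np.zeros(3)
    total = 0.0
    for dt in displayed:
        if not all(dt.tree.has_leaf(x) for x in quartet):
            continue  # a resolution that dropped one of the four taxa
        cf += dt.probability * _quartet_cf_tree(dt.tree, quartet)
        total += dt.probability
    if total <= 0:
        raise ValueError(f"no displayed tree contains all of {quartet}")
    return cf / total


def expected_quartet_cf(net: SpeciesNetwork, quartet) -> np.ndarray:
    """Expected CF triple for four taxa under the displayed-tree mixture."""
    net.require_lengths()
    return _mixture_cf(net.displayed_trees(), quartet)


# ----------------------------------------------------------------------
@dataclass
class QuartetCFTable:
    quartets: list  # list of 4-tuples of taxon names
    cf: np.ndarray  # (n_quartets, 3) observed proportions
    n: np.ndarray  # informative gene trees per quartet

    def __post_init__(self):
        self.cf = np.asarray(self.cf, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if len(self.cf) and not np.allclose(self.cf.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("CF triples must sum to 1")


def observed_quartet_cf(
    trees,
    taxa,
    max_quartets: int | None = None,
    seed: int = 0,
) -> QuartetCFTable:
    """Observed CFs over gene trees for all (or a seeded subsample of)
    4-taxon sets. A tree is informative for a quartet iff it contains all
    four taxa and resolves them; quartets informative in no tree are
    dropped."""
    quartets = list(itertools.combinations(sorted(taxa), 4))
    if max_quartets is not None and len(quartets) > max_quartets:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(quartets), size=max_quartets, replace=False)
        quartets = [quartets[i] for i in sorted(idx)]
    counts = np.zeros((len(quartets), 3))
    for tree in trees:
        present = set(tree.leaf_labels)
        for qi, q in enumerate(quartets):
            if not present.issuperset(q):
                continue
            topo = tree.quartet_split(*q)
            if topo >= 0:
                counts[qi, topo] += 1
    n = counts.sum(axis=1)
    keep = n > 0
    cf = counts[keep] / n[keep, None]
    return QuartetCFTable(
        quartets=[q for q, k in zip(quartets, keep) if k], cf=cf, n=n[keep]
    )


def cf_table_from_coal_times(coal_times, taxa) -> QuartetCFTable:
    """Observed CFs directly from simulator pairwise coalescence times.

    For an ultrametric genealogy the quartet topology is the pairing of
    the two tips with the smallest pairwise MRCA time; this avoids
    re-walking each gene tree and is the fast path for large simulations.
    """
    taxa = sorted(taxa)
    quartets = list(itertools.combinations(taxa, 4))
    counts = np.zeros((len(quartets), 3))
    uniform = len(coal_times) > 0 and all(
        labels == coal_times[0][0] for labels, _ in coal_times
    )
    if uniform and set(coal_times[0][0]) >= set(taxa):
        labels = coal_times[0][0]
        idx = {l: i for i, l in enumerate(labels)}
        stack = np.stack([T for _, T in coal_times])  # (loci, n, n)
        for qi, (a, b, c, d) in enumerate(quartets):
            ia, ib, ic, id_ = idx[a], idx[b], idx[c], idx[d]
            cols = np.stack(
                [
                    np.minimum(stack[:, ia, ib], stack[:, ic, id_]),
                    np.minimum(stack[:, ia, ic], stack[:, ib, id_]),
                    np.minimum(stack[:, ia, id_], stack[:, ib, ic]),
                ],
                axis=1,
            )
            counts[qi] = np.bincount(np.argmin(cols, axis=1), minlength=3)
        n = counts.sum(axis=1)
        keep = n > 0
        return QuartetCFTable(
            quartets=[q for q, k in zip(quartets, keep) if k],
            cf=counts[keep] / n[keep, None],
            n=n[keep],
        )
    for labels, T in coal_times:
        idx = {l: i for i, l in enumerate(labels)}
        for qi, (a, b, c, d) in enumerate(quartets):
            if a not in idx or b not in idx or c not in idx or d not in idx:
                continue
            ia, ib, ic, id_ = idx[a], idx[b], idx[c], idx[d]
            pairs = (
                (T[ia, ib], 0), (T[ic, id_], 0),
                (T[ia, ic], 1), (T[ib, id_], 1),
                (T[ia, id_], 2), (T[ib, ic], 2),
            )
            counts[qi, min(pairs)[1]] += 1
    n = counts.sum(axis=1)
    keep = n > 0
    return QuartetCFTable(
        quartets=[q for q, k in zip(quartets, keep) if k],
        cf=counts[keep] / n[keep, None],
        n=n[keep],
    )


# ----------------------------------------------------------------------
def pseudo_loglik(net: SpeciesNetwork, table: QuartetCFTable) -> float:
    """Multinomial composite log-likelihood of observed CFs.

    score = sum_q n_q * sum_topologies obsCF * log(expCF), expected CFs
    floored at 1e-12; linear in the per-quartet gene-tree counts, so
    score differences between candidates are in natural-log units.
    """
    net.require_lengths()
    displayed = net.displayed_trees()
    score = 0.0
    for q, obs, n_q in zip(table.quartets, table.cf, table.n):
        exp_cf = np.maximum(_mixture_cf(displayed, q), CF_FLOOR)
        score += n_q * float(obs @ np.log(exp_cf))
    return score


def fit_gamma(
    net: SpeciesNetwork, table: QuartetCFTable, hybrid: str | None = None
) -> tuple[float, float]:
    """Maximum-pseudolikelihood gamma for one hybrid node, topology and
    branch lengths held fixed. Returns (gamma_hat, score)."""
    hybrids = net.hybrid_nodes
    if not hybrids:
        raise ValueError("network has no hybrid node")
    hybrid = hybrid or hybrids[0]
    parents = sorted(net.graph.predecessors(hybrid))

    def set_gamma(g):
        work = net.copy()
        work.graph.edges[parents[0], hybrid]["gamma"] = g
        work.graph.edges[parents[1], hybrid]["gamma"] = 1.0 - g
        return work

    res = optimize.minimize_scalar(
        lambda g: -pseudo_loglik(set_gamma(g), table),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), float(-res.fun)


# ----------------------------------------------------------------------
@dataclass
class CandidateEvaluation:
    network: SpeciesNetwork
    score: float
    delta: float
    support_class: str
    h: int = field(init=False)

    def __post_init__(self):
        self.h = self.network.n_hybrids


def classify_support(candidate_score: float, reference_score: float) -> str:
    """Published thresholds on Delta = reference - candidate (natural-log
    pseudolikelihood units); boundaries go to the better class. A
    candidate better than its reference is simply strong."""
    delta = reference_score - candidate_score
    if delta <= 10:
        return STRONG
    if delta <= 20:
        return MODERATE
    if delta < 30:
        return POOR
    return EXCLUDED_DELTA


def exclude_outgroup_reticulations(candidates, outgroup: str):
    """Partition candidates into (retained, excluded) by the rule that no
    reticulation may involve the outgroup: excluded when the outgroup
    descends from a hybrid node or the outgroup's stem attaches inside a
    reticulation cycle."""
    retained, excluded = [], []
    for net in candidates:
        g = net.graph
        if outgroup not in g or g.out_degree(outgroup) != 0:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the candidate")
        (parent,) = g.predecessors(outgroup)
        bad = False
        for h in net.hybrid_nodes:
            cycle = net.reticulation_cycle_nodes(h)
            if parent in cycle:
                bad = True
                break
            if outgroup in nx.descendants(g, h):
                bad = True
                break
        (excluded if bad else retained).append(net)
    return retained, excluded


def evaluate_candidates(
    candidates, table: QuartetCFTable, outgroup: str | None = None
) -> list:
    """Score candidates (grouped by reticulation count), classify against
    the per-h best score, applying the outgroup-reticulation exclusion
    first when an outgroup is given."""
    if outgroup is not None:
        retained, excluded = exclude_outgroup_reticulations(candidates, outgroup)
    else:
        retained, excluded = list(candidates), []
    evals = []
    scored = [(net, pseudo_loglik(net, table)) for net in retained]
    by_h: dict[int, float] = {}
    for net, s in scored:
        by_h[net.n_hybrids] = max(by_h.get(net.n_hybrids, -np.inf), s)
    for net, s in scored:
        ref = by_h[net.n_hybrids]
        evals.append(
            CandidateEvaluation(
                network=net,
                score=s,
                delta=ref - s,
                support_class=classify_support(s, ref),
            )
        )
    for net in excluded:
        evals.append(
            CandidateEvaluation(
                network=net, score=np.nan, delta=np.nan,
                support_class=EXCLUDED_OUTGROUP,
            )
        )
    return evals


# ----------------------------------------------------------------------
def _topology_key(net: SpeciesNetwork) -> str:
    """Canonical string for grouping the same network topology across
    resamplings: lengths stripped, gammas rounded away."""
    work = net.copy()
    for u, v in work.graph.edges:
        work.graph.edges[u, v]["length"] = None
        if work.graph.edges[u, v].get("gamma") is not None:
            work.graph.edges[u, v]["gamma"] = 0.5
    return work.to_extended_newick(precision=1)


def select_prevailing(evaluations_by_resampling: dict, min_resamplings: int = 2):
    """Majority-rule selection of the prevailing network topology.

    `evaluations_by_resampling` maps a resampling id to its list of
    :class:`CandidateEvaluation`. Among reticulation counts where some
    topology has strong-or-moderate support in a majority of resamplings,
    the highest count wins; within it all topologies supported in at
    least `min_resamplings` resamplings are returned, ordered by number
    of supporting resamplings then mean score. Falls back to the best
    h = 0 candidate (with a warning flag) when nothing qualifies.
    """
    n_resamplings = len(evaluations_by_resampling)
    if n_resamplings == 0:
        raise ValueError("no resamplings given")
    support: dict[tuple, dict] = {}
    for rs, evals in evaluations_by_resampling.items():
        seen: set = set()
        for ev in evals:
            if ev.support_class not in (STRONG, MODERATE):
                continue
            key = (ev.h, _topology_key(ev.network))
            if key in seen:
                continue  # one vote per resampling per topology
            seen.add(key)
            rec = support.setdefault(
                key, {"resamplings": 0, "scores": [], "example": ev.network}
            )
            rec["resamplings"] += 1
            rec["scores"].append(ev.score)
    majority = n_resamplings // 2 + 1
    hs = [h for (h, _), rec in support.items() if rec["resamplings"] >= majority]
    if not hs:
        # fall back: best-scoring h=0 candidate anywhere
        best = None
        for evals in evaluations_by_resampling.values():
            for ev in evals:
                if ev.h == 0 and (best is None or ev.score > best.score):
                    best = ev
        return {
            "selected": [best.network] if best else [],
            "h": 0,
            "fallback": True,
            "details": [],
        }
    h_sel = max(hs)
    rows = [
        {
            "network": rec["example"],
            "n_resamplings": rec["resamplings"],
            "mean_score": float(np.mean(rec["scores"])),
        }
        for (h, _), rec in support.items()
        if h == h_sel and rec["resamplings"] >= min_resamplings
    ]
    rows.sort(key=lambda r: (-r["n_resamplings"], -r["mean_score"]))
    return {
        "selected": [r["network"] for r in rows],
        "h": h_sel,
        "fallback": False,
        "details": rows,
    }
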