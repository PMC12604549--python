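"""Built-in synthetic study system.

A fully specified 18-taxon, level-1 network (17 ingroup taxa in two
ladder-shaped clades plus one outgroup) with two reticulations confined to
separate clades, emulating the shape of the empirical system this pipeline
targets: ~18 sampled taxa, two introgression events with inheritance
probabilities around 0.25 and 0.33, and roughly a thousand nuclear loci.
Branch lengths are in coalescent units and the network is time-consistent
(every node has a well-defined age), which the simulator requires.

These objects are synthetic stand-ins constructed for validation — they
are not the empirical taxa, groupings or trait codings, which ship with
the original study's supplementary material and enter real analyses as
user configuration.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .network import SpeciesNetwork
from .snp import GroupingConfig, TraitTable

__all__ = [
    "study_network",
    "study_backbone_tree",
    "study_grouping_event1",
    "study_traits",
    "random_ultrametric_network",
]

GAMMA1 = 0.25  # minor-edge inheritance, clade-A event (donor T4 -> T6)
GAMMA2 = 0.33  # minor-edge inheritance, clade-B event (donor T12 -> T15)


def random_ultrametric_network(rng, n_taxa: int, n_hybrids: int = 0):
    """Random coalescent-shaped ultrametric tree, optionally with hybrid
    edges inserted between contemporaneous branches (time-consistent).
    Rebuilds when a random insertion violates the level-1 condition; used
    by property tests and validation experiments."""
    from .network import NetworkValidationError

    for _ in range(50):
        net = _try_random_network(rng, n_taxa, n_hybrids)
        if net is not None:
            return net
    if n_hybrids > 0:
        return random_ultrametric_network(rng, n_taxa, n_hybrids - 1)
    raise RuntimeError("could not build a random network")


def _try_random_network(rng, n_taxa, n_hybrids):
    import networkx as nx

    from .network import NetworkValidationError

    g = nx.DiGraph()
    active = []
    for i in range(n_taxa):
        name = f"t{i}"
        g.add_node(name, age=0.0)
        active.append(name)
    age = 0.0
    k = 0
    while len(active) > 1:
        m = len(active)
        age += float(rng.exponential(2.0 / (m * (m - 1)))) + 0.02
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        node = f"n{k}"
        k += 1
        g.add_node(node, age=age)
        g.add_edge(node, a)
        g.add_edge(node, b)
        active = [x for x in active if x not in (a, b)] + [node]
    added = 0
    tries = 0
    while added < n_hybrids and tries < 200:
        tries += 1
        edges = list(g.edges)
        ei, ej = rng.choice(len(edges), size=2, replace=False)
        (u1, v1), (u2, v2) = edges[ei], edges[ej]
        if {u1, v1} & {u2, v2}:
            continue
        lo = max(g.nodes[v1]["age"], g.nodes[v2]["age"])
        hi = min(g.nodes[u1]["age"], g.nodes[u2]["age"])
        if hi <= lo:
            continue
        t = float(rng.uniform(lo, hi))
        d_node, h_node = f"d{added}", f"h{added}"
        for (u, v, mid) in [(u1, v1, d_node), (u2, v2, h_node)]:
            g.remove_edge(u, v)
            g.add_node(mid, age=t)
            g.add_edge(u, mid)
            g.add_edge(mid, v)
        g.add_edge(d_node, h_node, gamma=float(rng.uniform(0.1, 0.9)))
        added += 1
    if added < n_hybrids:
        return None
    for u, v in g.edges:
        g.edges[u, v]["length"] = g.nodes[u]["age"] - g.nodes[v]["age"]
        g.edges[u, v].setdefault("gamma", None)
    net = SpeciesNetwork(g)
    try:
        net.require_level1()
    except NetworkValidationError:
        return None
    return net


def _ladder(g: nx.DiGraph, ages: list, tips: list, prefix: str) -> str:
    """Pectinate clade: internal node i at ages[i] splits tips[i] off."""
    nodes = [f"{prefix}{i}" for i in range(len(ages))]
    for i, (node, age) in enumerate(zip(nodes, ages)):
        g.add_node(node, age=age)
    for tip in tips:
        g.add_node(tip, age=0.0)
    for i in range(len(nodes) - 1):
        g.add_edge(nodes[i], tips[i])
        g.add_edge(nodes[i], nodes[i + 1])
    g.add_edge(nodes[-1], tips[-2])
    g.add_edge(nodes[-1], tips[-1])
    return nodes[0]


def _with_lengths(g: nx.DiGraph) -> SpeciesNetwork:
    for u, v in g.edges:
        g.edges[u, v]["length"] = g.nodes[u]["age"] - g.nodes[v]["age"]
        g.edges[u, v].setdefault("gamma", None)
    return SpeciesNetwork(g)


def _insert_on_edge(g: nx.DiGraph, u, v, node, age, gamma=None):
    """Subdivide edge u->v with `node` at `age`."""
    g.remove_edge(u, v)
    g.add_node(node, age=age)
    g.add_edge(u, node)
    g.add_edge(node, v)


def study_network(gamma1: float = GAMMA1, gamma2: float = GAMMA2) -> SpeciesNetwork:
    """The default two-reticulation study network (h = 2, 18 taxa)."""
    g = nx.DiGraph()
    a_tips = [f"T{i}" for i in range(1, 9)]
    b_tips = [f"T{i}" for i in range(9, 18)]
    a_root = _ladder(g, [3.0, 2.6, 2.2, 1.8, 1.4, 1.0, 0.6], a_tips, "A")
    b_root = _ladder(g, [4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5], b_tips, "B")
    g.add_node("I0", age=5.0)
    g.add_node("R", age=6.0)
    g.add_node("O", age=0.0)
    g.add_edge("I0", a_root)
    g.add_edge("I0", b_root)
    g.add_edge("R", "I0")
    g.add_edge("R", "O")
    # event 1: donor lineage T4, recipient lineage T6, hybrid at age 0.8
    _insert_on_edge(g, "A3", "T4", "D1", 0.8)
    _insert_on_edge(g, "A5", "T6", "H1", 0.8)
    g.add_edge("D1", "H1", gamma=gamma1)
    g.edges["A5", "H1"]["gamma"] = 1.0 - gamma1
    # event 2: donor lineage T12, recipient lineage T15, hybrid at age 0.7
    _insert_on_edge(g, "B3", "T12", "D2", 0.7)
    _insert_on_edge(g, "B6", "T15", "H2", 0.7)
    g.add_edge("D2", "H2", gamma=gamma2)
    g.edges["B6", "H2"]["gamma"] = 1.0 - gamma2
    net = _with_lengths(g)
    net.require_level1()
    return net


def study_backbone_tree() -> SpeciesNetwork:
    """The h = 0 backbone (the network with both minor edges removed)."""
    net = study_network()
    g = net.graph.copy()
    g.remove_edge("D1", "H1")
    g.remove_edge("D2", "H2")
    for u, v in list(g.edges):
        g.edges[u, v]["gamma"] = None
    # suppress the now degree-2 nodes
    for v in ["D1", "H1", "D2", "H2"]:
        (p,) = g.predecessors(v)
        (c,) = g.successors(v)
        ln = g.edges[p, v]["length"] + g.edges[v, c]["length"]
        g.remove_node(v)
        g.add_edge(p, c, length=ln, gamma=None)
    return SpeciesNetwork(g)


def study_grouping_event1() -> GroupingConfig:
    """Four-group configuration testing the clade-A reticulation.

    P2 is the recipient lineage (T6), P3 the donor (T4), P1 a lineage
    sister to the recipient and P4 an ingroup lineage outside the cycle.
    Under the species tree the major topology is P1P2|P3P4 (index 0); the
    reticulation pairs P2 with P3 (index 2 minor), leaving index 1
    contradictory.
    """
    return GroupingConfig(
        groups={"P1": ["T7", "T8"], "P2": ["T6"], "P3": ["T4"], "P4": ["T1", "T2"]},
        outgroup=["O"],
    )


EVENT1_DESIGNATION = {"major": 0, "minor": 2, "contra": 1}


def study_traits(seed: int = 0) -> TraitTable:
    """Synthetic binary trait states for the 18 taxa (clade-structured
    with a few discordant taxa, so rates are finite and identifiable)."""
    taxa = [f"T{i}" for i in range(1, 18)] + ["O"]
    longevity = {
        t: ("semelparous" if t in {"T1", "T2", "T3", "T4", "T5", "T6", "T13"}
            else "iteroparous")
        for t in taxa
    }
    fruit = {
        t: ("heterocarpic" if t in {"T9", "T10", "T11", "T12", "T3", "T4"}
            else "homocarpic")
        for t in taxa
    }
    environment = {
        t: ("unpredictable" if t in {"T5", "T6", "T7", "T8", "T14", "T15",
                                     "T16", "T17"}
            else "predictable")
        for t in taxa
    }
    df = pd.DataFrame(
        {"longevity": longevity, "fruit": fruit, "environment": environment}
    )
    return TraitTable(df.loc[taxa])
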