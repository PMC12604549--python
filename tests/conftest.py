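"""Shared fixtures and synthetic-object builders for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from netadmix.network import NetworkValidationError, SpeciesNetwork
from netadmix.trees import Tree, parse_newick


# ----------------------------------------------------------------------
def make_network(edges, ages=None) -> SpeciesNetwork:
    """Build a network from (parent, child, length[, gamma]) tuples."""
    g = nx.DiGraph()
    for e in edges:
        u, v, ln = e[0], e[1], e[2]
        gm = e[3] if len(e) > 3 else None
        g.add_edge(u, v, length=ln, gamma=gm)
    return SpeciesNetwork(g)


from netadmix.datasets import random_ultrametric_network  # noqa: E402,F401


def random_topology_tree(rng: np.random.Generator, n_tips: int,
                         polytomy_prob: float = 0.2) -> Tree:
    """Random tree with occasional polytomies and random lengths."""
    parent: list[int] = []
    length: list[float] = []
    label: list[str | None] = []
    active = []
    for i in range(n_tips):
        parent.append(-1)
        length.append(float(rng.uniform(0.1, 2.0)))
        label.append(f"t{i}")
        active.append(i)
    while len(active) > 1:
        size = 2
        if len(active) > 2 and rng.random() < polytomy_prob:
            size = int(rng.integers(3, min(len(active), 4) + 1))
        pick = rng.choice(len(active), size=size, replace=False)
        kids = [active[p] for p in pick]
        node = len(parent)
        parent.append(-1)
        length.append(float(rng.uniform(0.1, 2.0)))
        label.append(None)
        for c in kids:
            parent[c] = node
        active = [x for x in active if x not in kids] + [node]
    length[active[0]] = float("nan")
    return Tree(parent, length, label)


# ----------------------------------------------------------------------
@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def balanced_quartet_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def one_hybrid_net():
    """Terminal-lineage introgression B -> C with gamma = 0.3, exact for
    the displayed-tree CF mixture (one lineage enters the hybrid node)."""
    return make_network(
        [
            ("R", "I", 1.0),
            ("R", "D", 3.0),
            ("I", "AB", 1.0),
            ("I", "CH", 1.5),
            ("AB", "A", 1.0),
            ("AB", "BD", 0.5),
            ("BD", "B", 0.5),
            ("CH", "C", 0.5),
            ("BD", "CH", 0.0, 0.3),
        ]
    )
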