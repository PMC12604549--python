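"""Rooted phylogenetic networks with inheritance probabilities.

A :class:`SpeciesNetwork` is a rooted DAG in which *tree nodes* have
in-degree <= 1 and *hybrid nodes* have in-degree 2. Each hybrid node's two
parent edges carry inheritance probabilities gamma that sum to 1 — the
probability that a lineage (or a unit of genome) traces back through that
edge. Resolving every hybrid node to a single parent yields one of the
2^h *displayed trees*, whose probability is the product of the chosen
gammas; most network-level quantities in this package (pairwise distances,
expected quartet concordance factors, trait likelihoods) are expectations
over that displayed-tree mixture.

The serialisation dialect is extended newick: a hybrid node appears twice,
once with its subtree and once as a bare ``#Hk`` reference, and hybrid
edges carry ``:length:support:gamma`` fields (support is accepted and
ignored on read, written empty).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .trees import Tree, NewickParseError

__all__ = [
    "SpeciesNetwork",
    "DisplayedTree",
    "parse_extended_newick",
    "network_pairwise_distances",
    "NetworkValidationError",
]

GAMMA_TOL = 1e-6


class NetworkValidationError(ValueError):
    pass


@dataclass
class DisplayedTree:
    """One resolution of every hybrid node, with its mixture probability.

    ``node_map`` sends every node of the source network to its surviving
    representative in the displayed tree: a suppressed degree-2 node maps to
    the child node of its surviving edge, and nodes pruned entirely (only
    possible for unused hybrid-edge sources that become childless) map to -1.
    """

    tree: Tree
    probability: float
    choices: tuple[tuple[str, str], ...]  # (hybrid node, chosen parent) pairs
    node_map: dict = field(default_factory=dict)


class SpeciesNetwork:
    """Level-1 rooted phylogenetic network.

    Wraps a :class:`networkx.DiGraph`; edge attributes are ``length``
    (nonnegative float or None) and ``gamma`` (float in [0, 1] on hybrid
    edges, None elsewhere). Leaves are nodes with out-degree 0 and carry a
    ``label`` attribute equal to their node key.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph
        roots = [v for v in graph if graph.in_degree(v) == 0]
        if len(roots) != 1:
            raise NetworkValidationError(f"expected one root, found {len(roots)}")
        self.root = roots[0]
        self.validate()

    # ------------------------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        return sorted(v for v in self.graph if self.graph.out_degree(v) == 0)

    @property
    def hybrid_nodes(self) -> list[str]:
        return sorted(v for v in self.graph if self.graph.in_degree(v) == 2)

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_nodes)

    def edge_length(self, u, v) -> float | None:
        return self.graph.edges[u, v].get("length")

    def gamma(self, u, v) -> float | None:
        return self.graph.edges[u, v].get("gamma")

    def copy(self) -> "SpeciesNetwork":
        return SpeciesNetwork(self.graph.copy())

    # ------------------------------------------------------------------
    def validate(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkValidationError("network graph contains a directed cycle")
        for v in g:
            indeg = g.in_degree(v)
            if indeg > 2:
                raise NetworkValidationError(f"node {v!r} has in-degree {indeg} > 2")
            if indeg == 2:
                gammas = [g.edges[u, v].get("gamma") for u in g.predecessors(v)]
                known = [x for x in gammas if x is not None]
                if not known:
                    raise NetworkValidationError(
                        f"hybrid node {v!r} has no gamma on either parent edge"
                    )
                if len(known) == 2 and abs(sum(known) - 1.0) > GAMMA_TOL:
                    raise NetworkValidationError(
                        f"gamma values at hybrid node {v!r} sum to {sum(known)}, not 1"
                    )
                if len(known) == 1:
                    # infer the missing one
                    for u in g.predecessors(v):
                        if g.edges[u, v].get("gamma") is None:
                            g.edges[u, v]["gamma"] = 1.0 - known[0]
                for u in g.predecessors(v):
                    gm = g.edges[u, v]["gamma"]
                    if not (0.0 <= gm <= 1.0):
                        raise NetworkValidationError(
                            f"gamma {gm} outside [0,1] on edge ({u!r},{v!r})"
                        )
        for u, v, data in g.edges(data=True):
            ln = data.get("length")
            if ln is not None and ln < 0:
                raise NetworkValidationError(f"negative length on edge ({u!r},{v!r})")

    def require_level1(self) -> None:
        """Check that no two reticulation cycles share an edge."""
        seen: dict[tuple, str] = {}
        for h in self.hybrid_nodes:
            for e in self._cycle_edges(h):
                if e in seen and seen[e] != h:
                    raise NetworkValidationError(
                        f"edge {e!r} shared by reticulation cycles of {seen[e]!r} and {h!r}"
                    )
                seen[e] = h

    def _cycle_edges(self, hybrid) -> set[tuple]:
        """Edges of the reticulation cycle associated with one hybrid node."""
        p1, p2 = sorted(self.graph.predecessors(hybrid))
        up1 = self._path_to_root(p1)
        up2 = self._path_to_root(p2)
        common = [v for v in up1 if v in set(up2)]
        top = common[0]  # lowest common ancestor of the two parents
        edges = {(p1, hybrid), (p2, hybrid)}
        for path in (up1, up2):
            prev = path[0]
            if prev == top:
                continue
            for v in path[1:]:
                edges.add((v, prev))
                if v == top:
                    break
                prev = v
        return edges

    def _path_to_root(self, v) -> list:
        """One tree-path up to the root (first parent at each step)."""
        path = [v]
        while self.graph.in_degree(path[-1]) > 0:
            path.append(next(iter(self.graph.predecessors(path[-1]))))
        return path

    def reticulation_cycle_nodes(self, hybrid) -> set:
        return {u for e in self._cycle_edges(hybrid) for u in e}

    # ------------------------------------------------------------------
    def require_lengths(self) -> None:
        missing = [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d.get("length") is None
        ]
        if missing:
            raise NetworkValidationError(f"edges without length: {missing}")

    def node_ages(self, tol: float = 1e-6) -> dict:
        """Node ages assuming a time-consistent network with leaves at age 0.

        Every directed path from a node down to a leaf must have the same
        total length (within `tol`); raises otherwise. Needed by the
        coalescent simulator and the calibration checks.
        """
        self.require_lengths()
        ages: dict = {}
        for v in reversed(list(nx.topological_sort(self.graph))):
            if self.graph.out_degree(v) == 0:
                ages[v] = 0.0
                continue
            cand = [
                ages[c] + self.graph.edges[v, c]["length"]
                for c in self.graph.successors(v)
            ]
            # also: hybrid children constrain via both parents; checked on edges below
            if max(cand) - min(cand) > tol:
                raise NetworkValidationError(
                    f"node {v!r} has inconsistent ages via different children: {cand}"
                )
            ages[v] = float(np.mean(cand))
        for u, v, d in self.graph.edges(data=True):
            if abs(ages[u] - ages[v] - d["length"]) > max(tol, tol * ages[u]):
                raise NetworkValidationError(
                    f"edge ({u!r},{v!r}) length {d['length']} inconsistent with "
                    f"ages {ages[u]} -> {ages[v]}"
                )
        return ages

    # ------------------------------------------------------------------
    def displayed_trees(self, max_hybrids: int = 12) -> list[DisplayedTree]:
        """All 2^h displayed trees with probabilities and node maps."""
        hybrids = self.hybrid_nodes
        if len(hybrids) > max_hybrids:
            raise NetworkValidationError(
                f"{len(hybrids)} hybrid nodes exceeds the combinatorial guard "
                f"({max_hybrids})"
            )
        out = []
        parent_sets = [sorted(self.graph.predecessors(h)) for h in hybrids]
        for combo in itertools.product(*parent_sets):
            prob = 1.0
            for h, chosen in zip(hybrids, combo):
                prob *= self.graph.edges[chosen, h]["gamma"]
            tree, node_map = self._resolve(dict(zip(hybrids, combo)))
            out.append(
                DisplayedTree(
                    tree=tree,
                    probability=prob,
                    choices=tuple(zip(hybrids, combo)),
                    node_map=node_map,
                )
            )
        return out

    def _resolve(self, choice: dict) -> tuple[Tree, dict]:
        g = self.graph.copy()
        for h, keep in choice.items():
            for u in list(g.predecessors(h)):
                if u != keep:
                    g.remove_edge(u, h)
        # prune nodes that lost all descendants (non-leaf, out-degree 0)
        changed = True
        while changed:
            changed = False
            for v in list(g.nodes):
                if g.out_degree(v) == 0 and self.graph.out_degree(v) > 0:
                    g.remove_node(v)
                    changed = True
        # suppress degree-2 nodes (in 1 / out 1) and a root with out-degree 1
        node_map = {v: v for v in self.graph.nodes}
        removed_to: dict = {}
        changed = True
        while changed:
            changed = False
            for v in list(g.nodes):
                indeg, outdeg = g.in_degree(v), g.out_degree(v)
                if indeg == 1 and outdeg == 1:
                    (p,) = g.predecessors(v)
                    (c,) = g.successors(v)
                    l1 = g.edges[p, v].get("length")
                    l2 = g.edges[v, c].get("length")
                    ln = None if (l1 is None or l2 is None) else l1 + l2
                    g.remove_node(v)
                    g.add_edge(p, c, length=ln)
                    removed_to[v] = c
                    changed = True
                elif indeg == 0 and outdeg == 1:
                    (c,) = g.successors(v)
                    g.remove_node(v)
                    removed_to[v] = c
                    changed = True
        for v in self.graph.nodes:
            t = v
            while t in removed_to:
                t = removed_to[t]
            node_map[v] = t if t in g else -1
        # convert to Tree
        nodes = list(nx.topological_sort(g))
        idx = {v: i for i, v in enumerate(nodes)}
        parent = [-1] * len(nodes)
        length = [math.nan] * len(nodes)
        label: list[str | None] = [None] * len(nodes)
        for u, v, d in g.edges(data=True):
            parent[idx[v]] = idx[u]
            if d.get("length") is not None:
                length[idx[v]] = d["length"]
        for v in g.nodes:
            if g.out_degree(v) == 0:
                label[idx[v]] = str(v)
        tree = Tree(parent, length, label)
        node_map = {v: (idx[t] if t != -1 else -1) for v, t in node_map.items()}
        return tree, node_map

    # ------------------------------------------------------------------
    def pairwise_distances(self, labels=None) -> tuple[np.ndarray, list[str]]:
        """gamma-weighted expected patristic distances between leaves.

        Defined as the expectation of the displayed-tree patristic distance
        under the displayed-tree mixture; reduces to the plain patristic
        matrix when the network has no hybrid nodes.
        """
        self.require_lengths()
        if labels is None:
            labels = self.leaves
        n = len(labels)
        out = np.zeros((n, n))
        for dt in self.displayed_trees():
            out += dt.probability * dt.tree.patristic_matrix(labels)
        return out, list(labels)

    # ------------------------------------------------------------------
    def to_extended_newick(self, precision: int = 12) -> str:
        g = self.graph
        hybrid_id = {h: i + 1 for i, h in enumerate(self.hybrid_nodes)}
        written: set = set()

        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def edge_suffix(u, v) -> str:
            d = g.edges[u, v]
            ln, gm = d.get("length"), d.get("gamma")
            if gm is not None:
                return f":{fmt(ln) if ln is not None else ''}::{fmt(gm)}"
            if ln is not None:
                return f":{fmt(ln)}"
            return ""

        def rec(v, parent) -> str:
            if v in hybrid_id:
                tag = f"#H{hybrid_id[v]}"
                if v in written:
                    return tag + (edge_suffix(parent, v) if parent is not None else "")
                written.add(v)
                inner = rec_plain(v)
                return inner + tag + (
                    edge_suffix(parent, v) if parent is not None else ""
                )
            return rec_plain(v) + (
                str(v) if g.out_degree(v) == 0 else ""
            ) + (edge_suffix(parent, v) if parent is not None else "")

        def rec_plain(v) -> str:
            if g.out_degree(v) == 0:
                return ""
            return "(" + ",".join(rec(c, v) for c in sorted(g.successors(v))) + ")"

        return rec(self.root, None) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpeciesNetwork(n_leaves={len(self.leaves)}, "
            f"h={self.n_hybrids})"
        )


# ----------------------------------------------------------------------
def network_pairwise_distances(net: SpeciesNetwork, labels=None):
    """gamma-weighted expected patristic distance matrix between leaves;
    thin wrapper over :meth:`SpeciesNetwork.pairwise_distances`."""
    return net.pairwise_distances(labels)


# ----------------------------------------------------------------------
def parse_extended_newick(text: str) -> SpeciesNetwork:
    """Parse extended newick with ``#Hk`` hybrid tags into a network.

    Hybrid edges carry ``:length:support:gamma``; a gamma missing on one of
    the two parent edges is inferred as 1 - gamma of the other. Unpaired
    ``#H`` tags and gamma pairs not summing to 1 (tolerance 1e-6) raise.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickParseError("extended newick must end with ';'", len(text))
    s = s[:-1]
    g = nx.DiGraph()
    counter = itertools.count()

    def new_internal():
        return f"_n{next(counter)}"

    pos = 0
    n = len(s)

    def parse_fields(start: int) -> tuple[list[float | None], int]:
        """Parse up to 3 ':'-separated numeric fields at `start`."""
        fields: list[float | None] = []
        p = start
        while p < n and s[p] == ":" and len(fields) < 3:
            p += 1
            q = p
            while q < n and s[q] not in ",():;":
                q += 1
            tok = s[p:q].strip()
            fields.append(float(tok) if tok else None)
            p = q
        return fields, p

    hybrid_seen: dict[str, str] = {}  # #H tag -> node key

    def parse_subtree(p: int) -> tuple[str, int]:
        children: list[str] = []
        if p < n and s[p] == "(":
            p += 1
            while True:
                child, p = parse_subtree(p)
                children.append(child)
                if p >= n:
                    raise NewickParseError("unbalanced '('", p)
                if s[p] == ",":
                    p += 1
                    continue
                if s[p] == ")":
                    p += 1
                    break
                raise NewickParseError(f"unexpected character {s[p]!r}", p)
        # label (may contain a #H tag)
        q = p
        while q < n and s[q] not in ",():;":
            q += 1
        raw_label = s[p:q].strip()
        p = q
        fields, p = parse_fields(p)
        length = fields[0] if len(fields) >= 1 else None
        gamma = fields[2] if len(fields) >= 3 else None

        tag = None
        plain = raw_label
        if "#" in raw_label:
            i = raw_label.index("#")
            plain, tag = raw_label[:i], raw_label[i:]
            if not tag.startswith("#H"):
                raise NewickParseError(f"unsupported hybrid tag {tag!r}", q)

        if tag is not None:
            if tag in hybrid_seen:
                node = hybrid_seen[tag]
                if children:
                    if g.out_degree(node) > 0:
                        raise NewickParseError(
                            f"hybrid tag {tag!r} given a subtree twice", q
                        )
                    for c in children:
                        _attach(node, c)
            else:
                node = tag if not plain else plain + tag
                g.add_node(node)
                hybrid_seen[tag] = node
                for c in children:
                    _attach(node, c)
        else:
            if children:
                node = new_internal()
                g.add_node(node)
                for c in children:
                    _attach(node, c)
                if plain:
                    g.nodes[node]["name"] = plain
            else:
                if not plain:
                    raise NewickParseError("leaf without a label", q)
                node = plain
                g.add_node(node)
        edge_attrs[node] = edge_attrs.get(node, [])
        edge_attrs[node].append({"length": length, "gamma": gamma})
        return node, p

    # child -> stack of pending edge attributes (consumed by _attach)
    edge_attrs: dict[str, list[dict]] = {}

    def _attach(parent: str, child: str) -> None:
        attrs = edge_attrs[child].pop()
        if g.has_edge(parent, child):
            raise NewickParseError(f"duplicate edge {parent!r}->{child!r}", 0)
        g.add_edge(parent, child, length=attrs["length"], gamma=attrs["gamma"])

    root, pos = parse_subtree(pos)
    if pos != n:
        raise NewickParseError("trailing characters after root", pos)
    # the root's own attr entry is unused
    # check all hybrid tags resolved to in-degree-2 nodes with a subtree
    for tag, node in hybrid_seen.items():
        if g.in_degree(node) != 2:
            raise NewickParseError(
                f"hybrid tag {tag!r} appears with in-degree {g.in_degree(node)}, "
                "expected 2 (unpaired #H label)",
                0,
            )
    net = SpeciesNetwork(g)
    return net


def read_extended_newick_file(path) -> list[SpeciesNetwork]:
    nets = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                nets.append(parse_extended_newick(line))
    return nets


def write_extended_newick_file(path, nets) -> None:
    with open(path, "w") as fh:
        for net in nets:
            fh.write(net.to_extended_newick() + "\n")
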