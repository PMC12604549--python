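"""Lightweight rooted trees with branch lengths.

This class backs the hot loops of the package (coalescent simulation at
10^5-10^6 loci, exhaustive topology weighting). dendropy handles file IO and
serves as an independent cross-check in the test-suite; inside the library a
small array-backed structure keeps per-tree costs in the microsecond range.

Nodes are integer ids ``0..n_nodes-1``. Leaves carry taxon labels; branch
lengths are stored per node as the length of the edge above it (``nan`` on
the root).
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tree", "parse_newick", "NewickParseError"]


class NewickParseError(ValueError):
    """Malformed newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Tree:
    """Rooted tree; polytomies allowed; branch lengths optional.

    Parameters
    ----------
    parent
        Parent id per node, ``-1`` for the root.
    length
        Branch length above each node (``nan`` when absent / root).
    label
        Taxon label per node, ``None`` on unlabelled internals.
    """

    __slots__ = ("parent", "length", "label", "children", "root", "_leaf_ids")

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        label: Sequence[str | None],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.label = list(label)
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                self.children[p].append(i)
        if root < 0:
            raise ValueError("tree has no root")
        self.root = root
        self._leaf_ids: dict[str, int] = {}
        for i in range(n):
            if not self.children[i]:
                lab = self.label[i]
                if lab is None:
                    raise ValueError(f"leaf node {i} has no label")
                if lab in self._leaf_ids:
                    raise ValueError(f"duplicate leaf label {lab!r}")
                self._leaf_ids[lab] = i

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaf_ids)

    def leaf_id(self, label: str) -> int:
        return self._leaf_ids[label]

    def has_leaf(self, label: str) -> bool:
        return label in self._leaf_ids

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    # ------------------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (missing lengths treated as 0)."""
        d = np.zeros(self.n_nodes)
        order = self.topo_order()
        for v in order:
            p = self.parent[v]
            if p >= 0:
                ln = self.length[v]
                d[v] = d[p] + (0.0 if np.isnan(ln) else ln)
        return d

    def topo_order(self) -> list[int]:
        """Nodes in preorder (parents before children), iterative."""
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order

    def ancestors(self, node: int) -> list[int]:
        """Path from node up to and including the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, a: int, b: int) -> int:
        anc = set(self.ancestors(a))
        v = b
        while v not in anc:
            v = int(self.parent[v])
        return v

    def path_nodes(self, a: int, b: int) -> set[int]:
        """All nodes on the path between leaves/nodes a and b (inclusive)."""
        anc_a = self.ancestors(a)
        pos = {v: i for i, v in enumerate(anc_a)}
        path_b = []
        v = b
        while v not in pos:
            path_b.append(v)
            v = int(self.parent[v])
        return set(anc_a[: pos[v] + 1]) | set(path_b)

    # ------------------------------------------------------------------
    def patristic_distance(self, label_a: str, label_b: str) -> float:
        a, b = self._leaf_ids[label_a], self._leaf_ids[label_b]
        m = self.mrca(a, b)
        d = 0.0
        for v in (a, b):
            while v != m:
                ln = self.length[v]
                d += 0.0 if np.isnan(ln) else ln
                v = int(self.parent[v])
        return d

    def patristic_matrix(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise leaf distances; order follows `labels` (default: leaf_labels)."""
        if labels is None:
            labels = self.leaf_labels
        ids = [self._leaf_ids[x] for x in labels]
        depth = self.depths()
        n = len(ids)
        out = np.zeros((n, n))
        for i in range(n):
            anc_i = {v: depth[ids[i]] - depth[v] for v in self.ancestors(ids[i])}
            for j in range(i + 1, n):
                v = ids[j]
                while v not in anc_i:
                    v = int(self.parent[v])
                out[i, j] = out[j, i] = anc_i[v] + depth[ids[j]] - depth[v]
        return out

    # ------------------------------------------------------------------
    def quartet_split(self, a: str, b: str, c: str, d: str) -> int:
        """Resolved unrooted quartet topology among four leaf labels.

        Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, and -1 when the
        quartet is unresolved (star) in this tree. A pairing is realised
        iff the two within-pair paths are node-disjoint.
        """
        ia, ib, ic, id_ = (self._leaf_ids[x] for x in (a, b, c, d))
        p_ab = self.path_nodes(ia, ib)
        if not (p_ab & self.path_nodes(ic, id_)):
            return 0
        p_ac = self.path_nodes(ia, ic)
        if not (p_ac & self.path_nodes(ib, id_)):
            return 1
        if not (self.path_nodes(ia, id_) & self.path_nodes(ib, ic)):
            return 2
        return -1

    # ------------------------------------------------------------------
    def scaled(self, factor: float) -> "Tree":
        """Copy with all branch lengths multiplied by `factor`."""
        t = Tree(self.parent, self.length * factor, self.label)
        return t

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.length.copy(), list(self.label))

    # ------------------------------------------------------------------
    def to_newick(self, precision: int = 12) -> str:
        buf = io.StringIO()

        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def rec(node: int) -> None:
            if not self.is_leaf(node):
                buf.write("(")
                for i, k in enumerate(self.children[node]):
                    if i:
                        buf.write(",")
                    rec(k)
                buf.write(")")
            if self.label[node] is not None:
                buf.write(self.label[node])
            ln = self.length[node]
            if not np.isnan(ln):
                buf.write(f":{fmt(ln)}")

        rec(self.root)
        buf.write(";")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_leaves={len(self._leaf_ids)}, n_nodes={self.n_nodes})"


# ----------------------------------------------------------------------
def parse_newick(text: str) -> Tree:
    """Parse a single newick tree into a :class:`Tree`.

    Branch lengths are optional; quoted labels are not supported (taxon
    names in this package are plain identifiers). Errors report the
    character offset of the offending token.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickParseError("newick string must end with ';'", len(text))
    s = s[:-1]
    parent: list[int] = []
    length: list[float] = []
    label: list[str | None] = []

    def new_node(p: int) -> int:
        parent.append(p)
        length.append(np.nan)
        label.append(None)
        return len(parent) - 1

    pos = 0
    n = len(s)
    root = new_node(-1)
    cur = root
    depth = 0
    while pos < n:
        ch = s[pos]
        if ch == "(":
            depth += 1
            cur = new_node(cur)
            pos += 1
        elif ch == ",":
            if parent[cur] < 0:
                raise NewickParseError("comma outside parentheses", pos)
            cur = new_node(parent[cur])
            pos += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", pos)
            cur = parent[cur]
            pos += 1
        elif ch == ":":
            pos += 1
            start = pos
            while pos < n and s[pos] not in ",():;":
                pos += 1
            try:
                length[cur] = float(s[start:pos])
            except ValueError:
                raise NewickParseError("invalid branch length", start) from None
        elif ch.isspace():
            pos += 1
        else:
            start = pos
            while pos < n and s[pos] not in ",():;":
                pos += 1
            label[cur] = s[start:pos].strip()
    if depth != 0:
        raise NewickParseError("unbalanced '('", n)
    return Tree(parent, length, label)


def read_newick_file(path) -> list[Tree]:
    """Read a file with one newick tree per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(path, trees: Iterable[Tree]) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")
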