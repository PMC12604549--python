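"""Multispecies coalescent simulation on a species network.

Gene trees are generated backward in time: within each network edge, the
``k`` lineages present coalesce at rate ``k(k-1)/2`` per coalescent unit;
at a hybrid node every lineage independently chooses a parent edge with
probability gamma; above the root, coalescence continues until a single
lineage remains. Output gene trees are ultrametric in coalescent units;
among-locus rate variation is then emulated by multiplying each tree by an
i.i.d. lognormal draw, which is exactly the nuisance the downstream QC
normalisation is designed to remove.

SNP matrices follow the infinite-sites model: per locus a mutation is
dropped on a branch chosen with probability proportional to its length and
every tip below it carries the derived allele. Genotypes are haploid 0/1
by default; taxa listed in ``diploid_taxa`` get two sampled lineages and
0/1/2 genotypes.

Randomness contract: one root seed; the stream for locus ``i`` is derived
as ``default_rng([seed, i, stage])`` so any locus is reproducible
independently of ``n_loci``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SpeciesNetwork
from .snp import SNPMatrix
from .trees import Tree

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_gene_trees",
    "scale_to_substitutions",
    "simulate_snp_matrix",
]

_COAL_STAGE, _RATE_STAGE, _SNP_STAGE = 0, 1, 2


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the shape of the empirical dataset the pipeline is
    meant for: 18 taxa sampled one individual each, ~10^3 nuclear loci of a
    few hundred bp, moderate among-locus rate variation, and some taxa
    missing from some gene trees.
    """

    network: SpeciesNetwork
    n_loci: int = 964
    rate_sigma: float = 0.5  # sd of log rate multipliers (lognormal, median 1)
    m_tax: float = 0.05  # per-locus, per-taxon missing probability
    m_gt: float = 0.05  # per-genotype missing rate in SNP matrices
    locus_length: int = 400  # bp, for SNP positioning
    snps_per_locus: int = 1
    diploid_taxa: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self):
        if self.rate_sigma < 0:
            raise ValueError("rate_sigma must be >= 0")
        if not (0 <= self.m_tax < 1):
            raise ValueError("m_tax must be in [0, 1)")
        if not (0 <= self.m_gt < 1):
            raise ValueError("m_gt must be in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.diploid_taxa = frozenset(self.diploid_taxa)


@dataclass
class SimResult:
    taxa: list
    trees_coal: list  # ultrametric gene trees, coalescent units
    trees_subst: list  # after lognormal rate scaling
    rate_multipliers: np.ndarray
    lineage_choices: list  # per locus: list of (hybrid, tip_tuple, parent)
    coal_times: list  # per locus: (labels, pairwise MRCA-time matrix)
    snp_matrix: SNPMatrix | None
    truth: dict


class _CompiledNetwork:
    """Event-ordered view of a time-consistent network for fast simulation."""

    def __init__(self, net: SpeciesNetwork):
        g = net.graph
        self.ages = net.node_ages()
        for h in net.hybrid_nodes:
            for u in g.predecessors(h):
                if g.edges[u, h].get("gamma") is None:
                    raise ValueError(f"gamma missing on hybrid edge ({u!r},{h!r})")
        self.net = net
        self.leaves = net.leaves
        # non-leaf nodes in increasing age order; ties (zero-length hybrid
        # edges) broken topologically so a node is processed only after
        # every node feeding lineages into it
        import networkx as nx

        topo_rank = {
            v: i for i, v in enumerate(reversed(list(nx.topological_sort(g))))
        }
        self.internal = sorted(
            (v for v in g if g.out_degree(v) > 0),
            key=lambda v: (self.ages[v], topo_rank[v]),
        )
        self.root = net.root
        self.parents = {
            v: sorted(g.predecessors(v)) for v in g
        }
        self.children = {v: sorted(g.successors(v)) for v in g}
        self.gamma = {
            (u, v): g.edges[u, v].get("gamma") for u, v in g.edges
        }


def _coalesce_in_edge(lineages, a0, a1, rng, heights, parent, children, tips):
    """Coalesce `lineages` (gene-tree node ids) between ages a0 and a1.

    a1 = inf runs to a single lineage. Mutates the growing gene-tree arrays
    and the per-lineage tip sets; returns surviving lineage ids and the
    pairwise-coalescence-time entries recorded.
    """
    t = a0
    lins = list(lineages)
    pairs = []
    while len(lins) > 1:
        k = len(lins)
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t >= a1:
            break
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = lins[i], lins[j]
        node = len(heights)
        heights.append(t)
        parent.append(-1)
        children.append([a, b])
        parent[a] = node
        parent[b] = node
        tips.append(tips[a] | tips[b])
        pairs.append((tips[a], tips[b], t))
        lins[min(i, j)] = node
        lins.pop(max(i, j))
    return lins, pairs


def _simulate_locus(cn: _CompiledNetwork, rng, sampled: list) -> tuple:
    """One genealogy. `sampled` is a list of (taxon, label) tip samples.

    Returns (Tree, choices, labels, coal_time_matrix).
    """
    heights: list[float] = []
    parent: list[int] = []
    children: list[list[int]] = []
    tipsets: list[frozenset] = []
    labels = [lab for _, lab in sampled]
    lab_index = {lab: i for i, lab in enumerate(labels)}
    n_tips = len(labels)
    T = np.zeros((n_tips, n_tips))

    on_edge: dict = {}
    for taxon, lab in sampled:
        tip = len(heights)
        heights.append(0.0)
        parent.append(-1)
        children.append([])
        tipsets.append(frozenset([lab_index[lab]]))
        (p,) = cn.parents[taxon] if len(cn.parents[taxon]) == 1 else (None,)
        if p is None:
            raise ValueError(f"leaf {taxon!r} must have exactly one parent")
        on_edge.setdefault((taxon, p), []).append(tip)

    choices = []
    for v in cn.internal:
        av = cn.ages[v]
        incoming = []
        for c in cn.children[v]:
            key = (c, v)
            lins = on_edge.pop(key, [])
            if len(lins) > 1:
                lins, pairs = _coalesce_in_edge(
                    lins, cn.ages[c], av, rng, heights, parent, children, tipsets
                )
                for sa, sb, t in pairs:
                    for x in sa:
                        for y in sb:
                            T[x, y] = T[y, x] = t
            incoming.extend(lins)
        if v == cn.root:
            lins, pairs = _coalesce_in_edge(
                incoming, av, math.inf, rng, heights, parent, children, tipsets
            )
            for sa, sb, t in pairs:
                for x in sa:
                    for y in sb:
                        T[x, y] = T[y, x] = t
            root_lin = lins[0] if lins else None
        elif len(cn.parents[v]) == 2:
            p1, p2 = cn.parents[v]
            g1 = cn.gamma[(p1, v)]
            for lin in incoming:
                chosen = p1 if rng.random() < g1 else p2
                on_edge.setdefault((v, chosen), []).append(lin)
                choices.append(
                    (v, tuple(sorted(labels[i] for i in tipsets[lin])), chosen)
                )
        else:
            (p,) = cn.parents[v]
            on_edge.setdefault((v, p), []).extend(incoming)

    if any(on_edge.values()):
        raise RuntimeError(f"stranded lineages on edges {list(on_edge)}")
    # build the Tree: lengths from heights
    length = [math.nan] * len(heights)
    node_label: list[str | None] = [None] * len(heights)
    for i in range(n_tips):
        node_label[i] = labels[i]
    for i, p in enumerate(parent):
        if p >= 0:
            length[i] = heights[p] - heights[i]
    tree = Tree(parent, length, node_label)
    return tree, choices, labels, T


def simulate_gene_trees(cfg: SimConfig) -> SimResult:
    """Simulate `cfg.n_loci` gene trees under the network MSC.

    Each locus gets its own counter-derived random stream; taxa are dropped
    i.i.d. with probability ``m_tax`` before simulation (gene trees of
    unequal size). Trees come out ultrametric in coalescent units and are
    additionally returned scaled by lognormal rate multipliers.
    """
    cn = _CompiledNetwork(cfg.network)
    taxa = cn.leaves
    trees, all_choices, all_times = [], [], []
    for locus in range(cfg.n_loci):
        rng = np.random.default_rng([cfg.seed, locus, _COAL_STAGE])
        keep = [t for t in taxa if cfg.m_tax == 0 or rng.random() >= cfg.m_tax]
        if not keep:
            keep = list(taxa)  # never emit an empty tree
        sampled = [(t, t) for t in keep]
        tree, choices, labels, T = _simulate_locus(cn, rng, sampled)
        trees.append(tree)
        all_choices.append(choices)
        all_times.append((labels, T))
    trees_subst, mult = scale_to_substitutions(trees, cfg.rate_sigma, cfg.seed)
    truth = {
        "network": cfg.network.to_extended_newick(),
        "gamma": {
            f"{u}->{v}": cfg.network.gamma(u, v)
            for u, v in cfg.network.graph.edges
            if cfg.network.gamma(u, v) is not None
        },
        "seed": cfg.seed,
        "n_loci": cfg.n_loci,
        "rate_sigma": cfg.rate_sigma,
        "m_tax": cfg.m_tax,
        "m_gt": cfg.m_gt,
        "locus_length": cfg.locus_length,
        "snps_per_locus": cfg.snps_per_locus,
    }
    return SimResult(
        taxa=taxa,
        trees_coal=trees,
        trees_subst=trees_subst,
        rate_multipliers=mult,
        lineage_choices=all_choices,
        coal_times=all_times,
        snp_matrix=None,
        truth=truth,
    )


def scale_to_substitutions(trees, rate_sigma: float, seed: int):
    """Multiply each tree's lengths by an i.i.d. lognormal draw (median 1).

    Returns (scaled trees, multipliers). ``rate_sigma = 0`` leaves every
    tree unchanged (multiplier exactly 1).
    """
    if rate_sigma < 0:
        raise ValueError("rate_sigma must be >= 0")
    mult = np.empty(len(trees))
    out = []
    for i, t in enumerate(trees):
        rng = np.random.default_rng([seed, i, _RATE_STAGE])
        m = 1.0 if rate_sigma == 0 else float(np.exp(rng.normal(0.0, rate_sigma)))
        mult[i] = m
        out.append(t.scaled(m))
    return out, mult


def simulate_snp_matrix(cfg: SimConfig) -> SNPMatrix:
    """Infinite-sites SNPs, `snps_per_locus` biallelic sites per locus.

    Genealogies are simulated afresh (own random stream) so diploid taxa
    can carry two lineages. Loci whose genealogy has zero total branch
    length (a single surviving lineage) are skipped with a warning.
    """
    cn = _CompiledNetwork(cfg.network)
    taxa = cn.leaves
    individuals = list(taxa)
    n_ind = len(individuals)
    ind_index = {t: i for i, t in enumerate(individuals)}
    loci, positions, genos = [], [], []
    skipped = 0
    for locus in range(cfg.n_loci):
        rng = np.random.default_rng([cfg.seed, locus, _SNP_STAGE])
        keep = [t for t in taxa if cfg.m_tax == 0 or rng.random() >= cfg.m_tax]
        if len(keep) < 2:
            skipped += 1
            continue
        sampled = []
        for t in keep:
            if t in cfg.diploid_taxa:
                sampled.append((t, f"{t}|1"))
                sampled.append((t, f"{t}|2"))
            else:
                sampled.append((t, t))
        tree, _, labels, _ = _simulate_locus(cn, rng, sampled)
        lens = np.nan_to_num(tree.length, nan=0.0)
        total = lens.sum()
        if total <= 0:
            skipped += 1
            continue
        k = min(cfg.snps_per_locus, cfg.locus_length)
        pos = np.sort(rng.choice(cfg.locus_length, size=k, replace=False)) + 1
        # tip sets below each node, for carrier lookup
        below: list[set] = [set() for _ in range(tree.n_nodes)]
        for v in reversed(tree.topo_order()):
            if tree.is_leaf(v):
                below[v] = {tree.label[v]}
            else:
                for c in tree.children[v]:
                    below[v] |= below[c]
        prob = lens / total
        for p in pos:
            branch = int(rng.choice(tree.n_nodes, p=prob))
            carriers = below[branch]
            row = np.full(n_ind, -1, dtype=np.int8)
            for t in keep:
                if t in cfg.diploid_taxa:
                    cnt = (f"{t}|1" in carriers) + (f"{t}|2" in carriers)
                    row[ind_index[t]] = cnt
                else:
                    row[ind_index[t]] = 1 if t in carriers else 0
            if cfg.m_gt > 0:
                mask = rng.random(n_ind) < cfg.m_gt
                row[mask] = -1
            loci.append(f"L{locus:05d}")
            positions.append(int(p))
            genos.append(row)
    if skipped:
        warnings.warn(f"skipped {skipped} loci with degenerate genealogies")
    sites = pd.DataFrame(
        {
            "locus": loci,
            "pos": positions,
            "ref": "A",
            "alt": "T",
        }
    )
    gmat = (
        np.vstack(genos) if genos else np.empty((0, n_ind), dtype=np.int8)
    )
    return SNPMatrix(individuals=individuals, sites=sites, genotypes=gmat)
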