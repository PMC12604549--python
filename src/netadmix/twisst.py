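"""Topology weighting over four taxon groups, with an ILS null test.

For four groups P1..P4 a gene tree is summarised by the weight of each of
the three unrooted quartet topologies, obtained by exact enumeration over
all combinations of one tip per group (a seeded sampling fallback engages
above 10^6 combinations). Trees missing a whole group are flagged unusable
— this is the "gene trees of unequal size" handling. A majority rule then
assigns each tree's support to its highest-weight topology, splitting ties
equally, and the counts of the two non-major topologies are compared with
a chi-square test: under incomplete lineage sorting alone the minor and
contradictory topologies are expected at equal frequency, while
introgression inflates the minor one.

Topology indexing throughout: 0 = P1P2|P3P4, 1 = P1P3|P2P4, 2 = P1P4|P2P3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .snp import GroupingConfig
from .trees import Tree

__all__ = [
    "quartet_topology_weights",
    "assign_support",
    "twisst_counts",
    "ils_chisq_test",
    "WeightRecord",
    "TOPOLOGY_NAMES",
]

TOPOLOGY_NAMES = ("P1P2|P3P4", "P1P3|P2P4", "P1P4|P2P3")
MAX_EXACT_COMBINATIONS = 1_000_000


@dataclass
class WeightRecord:
    weights: np.ndarray  # length 3, sums to 1 when usable
    usable: bool
    n_combinations: int
    sampled: bool = False


def quartet_topology_weights(
    tree: Tree,
    grouping: GroupingConfig,
    seed: int = 0,
    max_exact: int = MAX_EXACT_COMBINATIONS,
    n_samples: int = 100_000,
) -> WeightRecord:
    """Weights of the three quartet topologies by exact tip enumeration.

    Each combination of one tip per group casts one vote for the induced
    unrooted quartet topology; an unresolved (polytomous) combination
    splits its vote equally over all three. Weights are votes divided by
    the number of combinations.
    """
    members = [
        [t for t in grp if tree.has_leaf(t)] for grp in grouping.quartet_groups
    ]
    if any(not m for m in members):
        return WeightRecord(
            weights=np.full(3, np.nan), usable=False, n_combinations=0
        )
    total = 1
    for m in members:
        total *= len(m)
    votes = np.zeros(3)
    if total <= max_exact:
        for a, b, c, d in itertools.product(*members):
            topo = tree.quartet_split(a, b, c, d)
            if topo < 0:
                votes += 1.0 / 3.0
            else:
                votes[topo] += 1.0
        weights = votes / total
        sampled = False
    else:  # pragma: no cover - engaged only on very large groups
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            combo = [m[rng.integers(len(m))] for m in members]
            topo = tree.quartet_split(*combo)
            if topo < 0:
                votes += 1.0 / 3.0
            else:
                votes[topo] += 1.0
        weights = votes / n_samples
        sampled = True
    return WeightRecord(
        weights=weights, usable=True, n_combinations=total, sampled=sampled
    )


def assign_support(weights: np.ndarray) -> np.ndarray:
    """Majority rule: the strictly largest weight takes support 1;
    k-way ties split it 1/k each. Values land in {0, 1/3, 1/2, 1}."""
    w = np.asarray(weights, dtype=float)
    best = w.max()
    top = np.isclose(w, best, rtol=0, atol=1e-12)
    out = np.zeros(3)
    out[top] = 1.0 / top.sum()
    return out


def twisst_counts(
    trees,
    grouping: GroupingConfig,
    designation: dict | None = None,
    seed: int = 0,
) -> dict:
    """Sum per-tree supports into (major, minor, contra) counts.

    `designation` maps the roles ``major``/``minor``/``contra`` to
    topology indices (relative to the reference network's reticulation);
    default is the identity (0, 1, 2). Returns the counts, the per-tree
    table, and integer-rounded minor/contra counts ready for the
    chi-square test (rounding preserves their total and is flagged).
    """
    if designation is None:
        designation = {"major": 0, "minor": 1, "contra": 2}
    rows = []
    support_sum = np.zeros(3)
    n_usable = 0
    for i, tree in enumerate(trees):
        rec = quartet_topology_weights(tree, grouping, seed=seed)
        if rec.usable:
            sup = assign_support(rec.weights)
            support_sum += sup
            n_usable += 1
        else:
            sup = np.full(3, np.nan)
        rows.append(
            {
                "tree": i,
                "usable": rec.usable,
                "n_combinations": rec.n_combinations,
                **{f"weight_{n}": w for n, w in zip(TOPOLOGY_NAMES, rec.weights)},
                **{f"support_{n}": s for n, s in zip(TOPOLOGY_NAMES, sup)},
            }
        )
    if n_usable == 0:
        raise ValueError("no usable gene trees (every tree misses a group)")
    counts = {
        role: float(support_sum[idx]) for role, idx in designation.items()
    }
    minor, contra = counts["minor"], counts["contra"]
    tot = int(round(minor + contra))
    minor_r = int(round(minor))
    contra_r = tot - minor_r
    rounded = not (
        np.isclose(minor_r, minor, atol=1e-9) and np.isclose(contra_r, contra, atol=1e-9)
    )
    return {
        "counts": counts,
        "n_usable": n_usable,
        "minor_count": minor_r,
        "contra_count": contra_r,
        "rounding_applied": rounded,
        "table": pd.DataFrame(rows).set_index("tree"),
    }


def ils_chisq_test(minor: int, contra: int) -> dict:
    """Chi-square test of minor == contra (the pure-ILS expectation).

    One degree of freedom; the p-value is the two-sided upper tail of the
    chi-square statistic, and the signed direction (minor minus contra) is
    reported alongside so a one-sided reading remains possible.
    """
    if minor + contra <= 0:
        raise ValueError("chi-square test undefined: minor + contra == 0")
    e = (minor + contra) / 2.0
    chi2 = (minor - e) ** 2 / e + (contra - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "chi2": float(chi2),
        "p": p,
        "df": 1,
        "direction": int(np.sign(minor - contra)),
        "minor": minor,
        "contra": contra,
    }
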