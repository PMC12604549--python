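"""Gene-tree quality control: outlier filtering and branch normalisation.

Two filters guard the downstream network analyses against misrooted or
rate-pathological loci, both phrased in tip-to-tip (patristic) distances,
which are independent of the rooting:

1. ratio criterion — the maximum distance among ingroup taxa may not
   exceed ``ratio`` (default 1.5) times the maximum ingroup-outgroup
   distance; long ingroup branches relative to the outgroup flag paralogy
   or alignment trouble;
2. floor criterion — the minimum ingroup-outgroup distance must be at
   least ``min_outdist`` (default 1e-4); an outgroup sitting inside the
   ingroup cloud cannot root the locus.

Passing trees are then normalised by dividing every branch length by the
tree's mean outgroup-ingroup distance, so that mean becomes exactly 1 and
among-locus rate variation cancels before distances are averaged.
Boundaries are inclusive: a tree exactly at either threshold passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Tree

__all__ = ["filter_gene_tree", "normalize_tree", "qc_batch", "QCReport"]

DEFAULT_RATIO = 1.5
DEFAULT_MIN_OUTDIST = 1e-4

PASS = "pass"
FAIL_RATIO = "fail_ratio"
FAIL_MINDIST = "fail_mindist"
FAIL_MISSING_OUTGROUP = "fail_missing_outgroup"


@dataclass
class QCReport:
    table: pd.DataFrame  # per-tree measured quantities and verdict
    counts: dict  # verdict -> number of trees

    @property
    def n_pass(self) -> int:
        return self.counts.get(PASS, 0)


def _distances(tree: Tree, ingroup, outgroup):
    present = [t for t in ingroup if tree.has_leaf(t)]
    labels = present + [outgroup]
    d = tree.patristic_matrix(labels)
    k = len(present)
    max_in = float(d[:k, :k].max()) if k >= 2 else 0.0
    out_col = d[:k, k]
    return max_in, float(out_col.max()), float(out_col.min()), present


def filter_gene_tree(
    tree: Tree,
    ingroup,
    outgroup: str,
    ratio: float = DEFAULT_RATIO,
    min_outdist: float = DEFAULT_MIN_OUTDIST,
) -> dict:
    """Apply both filters to one tree; returns verdict plus measurements.

    A tree lacking the outgroup is excluded (verdict
    ``fail_missing_outgroup``) rather than raising, so batches run
    unattended.
    """
    if not tree.has_leaf(outgroup):
        return {
            "verdict": FAIL_MISSING_OUTGROUP,
            "max_in": np.nan,
            "max_in_out": np.nan,
            "min_in_out": np.nan,
            "n_ingroup": sum(tree.has_leaf(t) for t in ingroup),
        }
    max_in, max_io, min_io, present = _distances(tree, ingroup, outgroup)
    if len(present) < 2:
        verdict = FAIL_MISSING_OUTGROUP  # too few ingroup tips to measure
    elif max_in > ratio * max_io:
        verdict = FAIL_RATIO
    elif min_io < min_outdist:
        verdict = FAIL_MINDIST
    else:
        verdict = PASS
    return {
        "verdict": verdict,
        "max_in": max_in,
        "max_in_out": max_io,
        "min_in_out": min_io,
        "n_ingroup": len(present),
    }


def normalize_tree(tree: Tree, ingroup, outgroup: str) -> Tree:
    """Divide all branch lengths by the mean outgroup-ingroup distance.

    After normalisation that mean equals 1 exactly, making the operation
    idempotent; distance ratios are untouched.
    """
    _, max_io, min_io, present = _distances(tree, ingroup, outgroup)
    k = len(present)
    labels = present + [outgroup]
    d = tree.patristic_matrix(labels)
    mean_io = float(d[:k, k].mean())
    if mean_io <= 0:
        raise ValueError("mean outgroup-ingroup distance is zero; cannot normalize")
    return tree.scaled(1.0 / mean_io)


def qc_batch(
    trees,
    ingroup,
    outgroup: str,
    ratio: float = DEFAULT_RATIO,
    min_outdist: float = DEFAULT_MIN_OUTDIST,
) -> tuple[QCReport, list]:
    """Filter then normalise a batch; retained trees keep input order."""
    if not trees:
        warnings.warn("qc_batch called with no trees")
        return QCReport(table=pd.DataFrame(), counts={}), []
    rows, retained = [], []
    for i, tree in enumerate(trees):
        rec = filter_gene_tree(tree, ingroup, outgroup, ratio, min_outdist)
        rec["tree"] = i
        rows.append(rec)
        if rec["verdict"] == PASS:
            retained.append(normalize_tree(tree, ingroup, outgroup))
    table = pd.DataFrame(rows).set_index("tree")
    counts = table["verdict"].value_counts().to_dict()
    return QCReport(table=table, counts=counts), retained
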