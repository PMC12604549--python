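"""Site-pattern introgression statistics on SNP matrices.

Implements the allele-frequency forms of Patterson's D and the f4-ratio,
an f-branch summary over a reference species tree, Benjamini-Hochberg FDR
adjustment, simple-matching similarity, and the SNP filtering/thinning
steps that precede them (biallelic sites, strict missing-data cutoff, one
SNP per window, one SNP per locus).

With populations (P1, P2, P3, O) and per-site derived-allele frequencies
p1, p2, p3, pO:

    D  = sum[(1-p1) p2 p3 (1-pO) - p1 (1-p2) p3 (1-pO)] / sum[... + ...]
    f4 = same numerator / numerator with P3 substituted for P2

Significance comes from an m-block jackknife over sites (default 20 equal
blocks) with a two-sided normal p-value. The f-branch statistic for a tree
branch b and candidate donor C is the median over descendants a of b of
the minimum over representatives A of b's sister clade of f4(A, a; C, O),
negative contributions floored at zero — the semantics of the Dsuite
statistic this module mirrors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .snp import MISSING, SNPMatrix
from .trees import Tree

__all__ = [
    "filter_snps",
    "one_snp_per_locus",
    "population_frequencies",
    "patterson_D",
    "f4_ratio",
    "f_branch",
    "fdr_adjust",
    "simple_matching_similarity",
]

DEFAULT_BLOCKS = 20


# ----------------------------------------------------------------------
def filter_snps(
    matrix: SNPMatrix,
    max_missing: float = 0.2,
    thin_bp: int = 100,
    drop_monomorphic: bool = False,
) -> SNPMatrix:
    """Missing-data filter (strict: fraction must be < `max_missing`)
    followed by greedy left-to-right thinning to one site per `thin_bp`
    window within each locus."""
    keep = matrix.missing_fraction() < max_missing
    if drop_monomorphic:
        g = np.where(matrix.genotypes == MISSING, np.nan, matrix.genotypes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mono = np.nanmax(g, axis=1) == np.nanmin(g, axis=1)
        keep &= ~mono
    m = matrix.subset_sites(keep)
    if thin_bp > 1:
        keep2 = np.zeros(m.n_sites, dtype=bool)
        last: dict = {}
        for i, (locus, pos) in enumerate(zip(m.sites["locus"], m.sites["pos"])):
            if locus not in last or pos - last[locus] >= thin_bp:
                keep2[i] = True
                last[locus] = pos
        m = m.subset_sites(keep2)
    if m.n_sites == 0:
        warnings.warn("filter_snps retained no sites")
    return m


def one_snp_per_locus(
    matrix: SNPMatrix, seed: int | None = None
) -> SNPMatrix:
    """Retain one site per locus: the first, or a seeded random choice."""
    keep = np.zeros(matrix.n_sites, dtype=bool)
    rng = np.random.default_rng(seed) if seed is not None else None
    for locus, sub in matrix.sites.groupby("locus", sort=False):
        idx = sub.index.to_numpy()
        keep[idx[0] if rng is None else rng.choice(idx)] = True
    return matrix.subset_sites(keep)


# ----------------------------------------------------------------------
def population_frequencies(
    matrix: SNPMatrix,
    populations: dict,
    ploidy: int = 1,
) -> pd.DataFrame:
    """Per-site derived-allele frequency per population (NaN if no data).

    `populations` maps population name -> list of individual IDs; `ploidy`
    is the number of allele copies a genotype code counts out of (1 for
    the simulator's haploid 0/1 calls, 2 for diploid VCF genotypes).
    """
    ind_idx = {ind: j for j, ind in enumerate(matrix.individuals)}
    out = {}
    g = matrix.genotypes
    for pop, members in populations.items():
        cols = [ind_idx[m] for m in members if m in ind_idx]
        if not cols:
            raise ValueError(f"population {pop!r} has no individuals in the matrix")
        sub = g[:, cols].astype(float)
        sub[sub == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[pop] = np.nanmean(sub, axis=1) / ploidy
    return pd.DataFrame(out, index=matrix.sites.index)


def _block_edges(n: int, blocks: int) -> np.ndarray:
    return np.linspace(0, n, min(blocks, n) + 1).astype(int)


def _jackknife_ratio(num: np.ndarray, den: np.ndarray, blocks: int):
    """Ratio statistic sum(num)/sum(den) with m-block jackknife Z and p."""
    n = len(num)
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        return np.nan, np.nan, np.nan, True
    est = tot_n / tot_d
    edges = _block_edges(n, blocks)
    m = len(edges) - 1
    if m < 2:
        return est, np.nan, np.nan, False
    loo = np.empty(m)
    for k in range(m):
        s = slice(edges[k], edges[k + 1])
        d = tot_d - den[s].sum()
        loo[k] = (tot_n - num[s].sum()) / d if d != 0 else est
    se = np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum())
    if se == 0:
        z = 0.0 if est == 0 else np.inf * np.sign(est)
    else:
        z = est / se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(est), float(z), p, False


@dataclass
class SitePatternResult:
    value: float
    z: float
    p: float
    n_sites: int
    undefined: bool


def _abba_baba_terms(p1, p2, p3, pO):
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


def patterson_D(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    pO: np.ndarray,
    blocks: int = DEFAULT_BLOCKS,
) -> SitePatternResult:
    """Patterson's D from population allele frequencies.

    Sites with a missing frequency in any population are skipped; the
    jackknife runs over the informative sites in matrix order.
    """
    p1, p2, p3, pO = map(np.asarray, (p1, p2, p3, pO))
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
    abba, baba = _abba_baba_terms(p1[ok], p2[ok], p3[ok], pO[ok])
    est, z, p, undef = _jackknife_ratio(abba - baba, abba + baba, blocks)
    return SitePatternResult(est, z, p, int(ok.sum()), undef)


def f4_ratio(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    pO: np.ndarray,
    blocks: int = DEFAULT_BLOCKS,
) -> SitePatternResult:
    """Admixture-fraction estimator: D's numerator over the same
    expression with the donor P3 in P2's place. The reported value is the
    raw ratio; consumers may clip to [-1, 1] for display."""
    p1, p2, p3, pO = map(np.asarray, (p1, p2, p3, pO))
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
    abba, baba = _abba_baba_terms(p1[ok], p2[ok], p3[ok], pO[ok])
    abba_d, baba_d = _abba_baba_terms(p1[ok], p3[ok], p3[ok], pO[ok])
    est, z, p, undef = _jackknife_ratio(abba - baba, abba_d - baba_d, blocks)
    return SitePatternResult(est, z, p, int(ok.sum()), undef)


# ----------------------------------------------------------------------
def _clades(tree: Tree):
    """Yield (branch_node, descendant_leaves, sister_leaves) per non-root branch."""
    for v in tree.topo_order():
        p = tree.parent[v]
        if p < 0:
            continue
        below = _leaves_below(tree, v)
        sister: list = []
        for s in tree.children[p]:
            if s != v:
                sister.extend(_leaves_below(tree, s))
        yield v, below, sister


def _leaves_below(tree: Tree, v: int) -> list:
    out = []
    stack = [v]
    while stack:
        u = stack.pop()
        if tree.is_leaf(u):
            out.append(tree.label[u])
        else:
            stack.extend(tree.children[u])
    return out


def f_branch(
    species_tree: Tree,
    freqs: pd.DataFrame,
    outgroup: str,
    blocks: int = DEFAULT_BLOCKS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """f-branch matrix over the branches of a rooted reference tree.

    Rows are branches (named by a representative descendant set), columns
    candidate donor taxa C. Cells where C descends from the branch or its
    sister are undefined (left NaN). Each defined cell carries the
    statistic, a block-jackknife Z, a two-sided p, and the BH-adjusted q
    computed across all defined cells.
    """
    pops = [c for c in freqs.columns if c != outgroup]
    if outgroup not in freqs.columns:
        raise ValueError(f"outgroup {outgroup!r} missing from frequency table")
    tips = set(species_tree.leaf_labels)
    if not tips.issuperset(pops):
        raise ValueError("species tree lacks some populations")
    F = {c: freqs[c].to_numpy() for c in freqs.columns}
    pO = F[outgroup]

    def f4_site_terms(A, a, C):
        p1, p2, p3 = F[A], F[a], F[C]
        ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
        abba, baba = _abba_baba_terms(p1, p2, p3, pO)
        abba_d, baba_d = _abba_baba_terms(p1, p3, p3, pO)
        num = np.where(ok, abba - baba, 0.0)
        den = np.where(ok, abba_d - baba_d, 0.0)
        return num, den

    n_sites = len(freqs)
    edges = _block_edges(n_sites, blocks)
    m = len(edges) - 1
    rows = []
    for v, desc, sister in _clades(species_tree):
        desc = [d for d in desc if d != outgroup]
        sister = [s for s in sister if s != outgroup]
        if not desc or not sister:
            continue
        branch_name = "+".join(sorted(desc))
        for C in pops:
            if C in desc or C in sister:
                continue
            # full-data statistic and per-block leave-one-out versions
            full_and_loo = np.empty((len(desc), m + 1))
            for ia, a in enumerate(desc):
                mins = np.full(m + 1, np.inf)
                for A in sister:
                    num, den = f4_site_terms(A, a, C)
                    tn, td = num.sum(), den.sum()
                    vals = np.empty(m + 1)
                    vals[0] = tn / td if td != 0 else np.nan
                    for k in range(m):
                        s = slice(edges[k], edges[k + 1])
                        d = td - den[s].sum()
                        vals[k + 1] = (tn - num[s].sum()) / d if d != 0 else vals[0]
                    mins = np.fmin(mins, vals)
                full_and_loo[ia] = np.maximum(mins, 0.0)  # negatives floored
            fb_all = np.median(full_and_loo, axis=0)
            fb, loo = fb_all[0], fb_all[1:]
            if np.isnan(fb):
                continue
            se = np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum())
            z = fb / se if se > 0 else (0.0 if fb == 0 else np.inf)
            p = float(2 * stats.norm.sf(abs(z)))
            rows.append(
                {"branch": branch_name, "C": C, "f_b": float(fb), "z": float(z), "p": p}
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = fdr_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] <= alpha
    return table


# ----------------------------------------------------------------------
def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
def simple_matching_similarity(matrix: SNPMatrix) -> pd.DataFrame:
    """Pairwise simple-matching coefficients between individuals.

    s(i, j) = (sites with equal genotypes) / (sites where both are
    non-missing); the diagonal is 1 and pairs with no comparable sites are
    NaN. Site order is irrelevant by construction.
    """
    if len(matrix.individuals) < 2:
        raise ValueError("need at least two individuals")
    g = matrix.genotypes
    n = len(matrix.individuals)
    out = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = (g[:, i] != MISSING) & (g[:, j] != MISSING)
        if not ok.any():
            out[i, j] = out[j, i] = np.nan
            continue
        s = float((g[ok, i] == g[ok, j]).mean())
        out[i, j] = out[j, i] = s
    return pd.DataFrame(out, index=matrix.individuals, columns=matrix.individuals)
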