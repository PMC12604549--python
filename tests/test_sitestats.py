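"""SNP filtering and site-pattern statistics."""

import numpy as np
import pandas as pd
import pytest

from netadmix.sitestats import (
    f4_ratio,
    f_branch,
    fdr_adjust,
    filter_snps,
    one_snp_per_locus,
    patterson_D,
    population_frequencies,
    simple_matching_similarity,
)
from netadmix.snp import SNPMatrix
from netadmix.trees import parse_newick


def make_matrix(genotypes, loci=None, positions=None, individuals=None):
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = g.shape
    if individuals is None:
        individuals = [f"i{k}" for k in range(n_ind)]
    if loci is None:
        loci = ["L0"] * n_sites
    if positions is None:
        positions = list(range(1, n_sites + 1))
    sites = pd.DataFrame(
        {"locus": loci, "pos": positions, "ref": "A", "alt": "T"}
    )
    return SNPMatrix(individuals=individuals, sites=sites, genotypes=g)


class TestFiltering:
    def test_exact_boundary_dropped(self):
        # 1 of 5 genotypes missing = 20%, strict < 0.2 drops it
        m = make_matrix([[0, 1, 0, 1, -1], [0, 1, 0, 1, 1]])
        out = filter_snps(m, max_missing=0.2, thin_bp=1)
        assert out.n_sites == 1

    def test_greedy_thinning(self):
        m = make_matrix([[0, 1]] * 3, positions=[1, 50, 101])
        out = filter_snps(m, max_missing=1.0, thin_bp=100)
        assert list(out.sites["pos"]) == [1, 101]

    def test_noop_when_spaced(self):
        m = make_matrix([[0, 1]] * 3, positions=[1, 200, 400])
        out = filter_snps(m, max_missing=0.5, thin_bp=100)
        assert out.n_sites == 3

    def test_thinning_per_locus(self):
        m = make_matrix(
            [[0, 1]] * 4, loci=["L0", "L0", "L1", "L1"],
            positions=[1, 50, 1, 50],
        )
        out = filter_snps(m, max_missing=1.0, thin_bp=100)
        assert list(out.sites["locus"]) == ["L0", "L1"]

    def test_one_snp_per_locus(self):
        m = make_matrix(
            [[0, 1]] * 5, loci=["L0"] * 3 + ["L1"] * 2, positions=[1, 2, 3, 1, 2]
        )
        out = one_snp_per_locus(m)
        assert out.n_sites == 2
        assert list(out.sites["pos"]) == [1, 1]

    def test_one_snp_per_locus_seeded_deterministic(self):
        m = make_matrix(
            [[0, 1]] * 6, loci=["L0"] * 3 + ["L1"] * 3, positions=[1, 2, 3] * 2
        )
        a = one_snp_per_locus(m, seed=5)
        b = one_snp_per_locus(m, seed=5)
        assert a.sites.equals(b.sites)


class TestPattersonD:
    def _freqs(self, abba, baba, extra_zero=0):
        """Haploid fixed-pattern frequency arrays: ABBA = (0,1,1,0)."""
        p1 = [0] * abba + [1] * baba + [0] * extra_zero
        p2 = [1] * abba + [0] * baba + [0] * extra_zero
        p3 = [1] * (abba + baba) + [0] * extra_zero
        pO = [0] * (abba + baba + extra_zero)
        return map(np.array, (p1, p2, p3, pO))

    def test_symmetric_counts_zero(self):
        res = patterson_D(*self._freqs(10, 10))
        assert res.value == pytest.approx(0.0)

    def test_fifteen_five(self):
        res = patterson_D(*self._freqs(15, 5))
        assert res.value == pytest.approx(0.5)
        assert res.n_sites == 20

    def test_antisymmetry(self):
        p1, p2, p3, pO = self._freqs(13, 6)
        a = patterson_D(p1, p2, p3, pO)
        b = patterson_D(p2, p1, p3, pO)
        assert a.value == pytest.approx(-b.value)

    def test_zero_denominator_flagged(self):
        z = np.zeros(10)
        res = patterson_D(z, z, z, z)
        assert res.undefined


class TestF4Ratio:
    def test_complete_sharing_is_one(self, rng):
        p1 = rng.random(50)
        p3 = rng.random(50)
        res = f4_ratio(p1, p3.copy(), p3, np.zeros(50))
        assert res.value == pytest.approx(1.0)

    def test_no_introgression_near_zero(self, rng):
        # P2 independent of P3: expectation of numerator is 0
        n = 20000
        anc = rng.random(n) * 0.5
        p1 = np.clip(anc + rng.normal(0, 0.1, n), 0, 1)
        p2 = np.clip(anc + rng.normal(0, 0.1, n), 0, 1)
        p3 = np.clip(rng.random(n) * 0.5 + rng.normal(0, 0.1, n), 0, 1)
        res = f4_ratio(p1, p2, p3, np.zeros(n))
        assert abs(res.value) < 3 * abs(res.value / res.z)


class TestFBranch:
    def test_singleton_clades_reduce_to_f4(self, rng):
        """With single-taxon clades the median and min vanish and f_b
        equals the plain (floored) f4-ratio."""
        tree = parse_newick("(((P1:1,P2:1):1,P3:2):1,O:3);")
        n = 400
        freqs = pd.DataFrame(
            {
                "P1": rng.random(n),
                "P2": rng.random(n),
                "P3": rng.random(n),
                "O": np.zeros(n),
            }
        )
        fb = f_branch(tree, freqs, outgroup="O", blocks=10)
        cell = fb[(fb["branch"] == "P2") & (fb["C"] == "P3")]
        assert len(cell) == 1
        direct = f4_ratio(
            freqs["P1"], freqs["P2"], freqs["P3"], freqs["O"], blocks=10
        )
        assert cell["f_b"].iloc[0] == pytest.approx(max(direct.value, 0.0))

    def test_undefined_cells_masked(self, rng):
        tree = parse_newick("((((P1:1,P2:1):1,P3:2):1,P4:3):1,O:4);")
        n = 100
        freqs = pd.DataFrame(
            {p: rng.random(n) for p in ["P1", "P2", "P3", "P4"]}
            | {"O": np.zeros(n)}
        )
        fb = f_branch(tree, freqs, outgroup="O", blocks=5)
        # C descending from the branch or its sister must be absent
        branch_p1p2 = fb[fb["branch"] == "P1+P2"]
        assert set(branch_p1p2["C"]) <= {"P4"}


class TestFDR:
    def test_hand_computed_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_identity(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_reorder_equivariance(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestSimilarity:
    def test_identical_rows(self):
        m = make_matrix([[0, 0], [1, 1], [2, 2], [0, 0]])
        s = simple_matching_similarity(m)
        assert s.iloc[0, 1] == pytest.approx(1.0)

    def test_all_different(self):
        m = make_matrix([[0, 1], [1, 0], [0, 2]])
        s = simple_matching_similarity(m)
        assert s.iloc[0, 1] == pytest.approx(0.0)

    def test_three_of_four(self):
        m = make_matrix([[0, 0], [1, 1], [0, 0], [1, 0], [0, -1]])
        s = simple_matching_similarity(m)
        # comparable sites: first four; three match
        assert s.iloc[0, 1] == pytest.approx(0.75)

    def test_site_order_invariant(self, rng):
        g = rng.integers(0, 3, size=(40, 5))
        m1 = make_matrix(g)
        m2 = make_matrix(g[::-1], positions=list(range(1, 41)))
        pd.testing.assert_frame_equal(
            simple_matching_similarity(m1), simple_matching_similarity(m2)
        )

    def test_symmetric_unit_diagonal(self, rng):
        m = make_matrix(rng.integers(-1, 3, size=(30, 4)))
        s = simple_matching_similarity(m).to_numpy()
        np.testing.assert_allclose(s, s.T)
        np.testing.assert_allclose(np.diag(s), 1.0)


class TestPopulationFrequencies:
    def test_haploid_mean_with_missing(self):
        m = make_matrix([[0, 1, -1], [1, 1, 1]])
        f = population_frequencies(m, {"pop": ["i0", "i1", "i2"]})
        assert f["pop"].iloc[0] == pytest.approx(0.5)
        assert f["pop"].iloc[1] == pytest.approx(1.0)

    def test_diploid_ploidy(self):
        m = make_matrix([[2, 1, 0, -1]])
        f = population_frequencies(
            m, {"pop": ["i0", "i1", "i2", "i3"]}, ploidy=2
        )
        assert f["pop"].iloc[0] == pytest.approx(0.5)
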