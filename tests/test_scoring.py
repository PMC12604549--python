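"""Expected/observed concordance factors, pseudolikelihood and ranking."""

import numpy as np
import pytest

from netadmix.network import parse_extended_newick
from netadmix.scoring import (
    EXCLUDED_DELTA,
    EXCLUDED_OUTGROUP,
    MODERATE,
    POOR,
    STRONG,
    CandidateEvaluation,
    QuartetCFTable,
    classify_support,
    evaluate_candidates,
    exclude_outgroup_reticulations,
    expected_quartet_cf,
    observed_quartet_cf,
    pseudo_loglik,
    select_prevailing,
)
from netadmix.trees import parse_newick

from conftest import make_network

QUARTET_TREE = "(((A:1,B:1):1,C:2):1,D:3);"


class TestExpectedCF:
    def test_star_limit(self):
        net = parse_extended_newick("(((A:1,B:1):0,C:1):1,D:2);")
        cf = expected_quartet_cf(net, ("A", "B", "C", "D"))
        np.testing.assert_allclose(cf, [1 / 3] * 3, atol=1e-12)

    def test_long_branch_asymptote(self):
        net = parse_extended_newick("(((A:1,B:1):10,C:11):1,D:12);")
        cf = expected_quartet_cf(net, ("A", "B", "C", "D"))
        assert cf[0] > 0.9999

    def test_internal_t_one(self):
        net = parse_extended_newick(QUARTET_TREE)
        cf = expected_quartet_cf(net, ("A", "B", "C", "D"))
        assert cf[0] == pytest.approx(1 - 2 / 3 * np.exp(-1), abs=1e-12)
        assert cf.sum() == pytest.approx(1.0)

    def test_hybrid_mixture_weights(self, one_hybrid_net):
        """CF triple is the gamma mixture of the two displayed trees."""
        dts = one_hybrid_net.displayed_trees()
        q = ("A", "B", "C", "D")
        from netadmix.scoring import _quartet_cf_tree

        manual = sum(
            dt.probability * _quartet_cf_tree(dt.tree, q) for dt in dts
        )
        np.testing.assert_allclose(
            expected_quartet_cf(one_hybrid_net, q), manual, atol=1e-12
        )


class TestObservedCF:
    def test_unanimous(self):
        trees = [parse_newick(QUARTET_TREE)] * 10
        table = observed_quartet_cf(trees, ["A", "B", "C", "D"])
        assert len(table.quartets) == 1
        np.testing.assert_allclose(table.cf[0], [1, 0, 0])
        assert table.n[0] == 10

    def test_tree_missing_taxon_uninformative(self):
        trees = [parse_newick(QUARTET_TREE), parse_newick("((A:1,B:1):1,C:2);")]
        table = observed_quartet_cf(trees, ["A", "B", "C", "D"])
        assert table.n[0] == 1

    def test_proportions_sum_to_one(self, rng):
        from conftest import random_topology_tree

        trees = [random_topology_tree(rng, 8) for _ in range(20)]
        taxa = trees[0].leaf_labels
        table = observed_quartet_cf(trees, taxa)
        np.testing.assert_allclose(table.cf.sum(axis=1), 1.0)


class TestPseudoLoglik:
    def _table(self):
        net = parse_extended_newick(QUARTET_TREE)
        cf = expected_quartet_cf(net, ("A", "B", "C", "D"))
        return net, QuartetCFTable(
            quartets=[("A", "B", "C", "D")], cf=cf[None, :], n=[100]
        )

    def test_true_network_is_local_maximum(self):
        """Perturbing a branch length away from truth lowers the score
        when observed CFs equal the expected CFs."""
        net, table = self._table()
        base = pseudo_loglik(net, table)
        for delta in (-0.2, 0.2):
            pert = net.copy()
            # internal edge: parent of A,B cherry
            for u, v in pert.graph.edges:
                if pert.graph.out_degree(v) == 2 and all(
                    pert.graph.out_degree(c) == 0
                    for c in pert.graph.successors(v)
                ):
                    pert.graph.edges[u, v]["length"] += delta
                    break
            assert pseudo_loglik(pert, table) < base

    def test_linear_in_counts(self):
        net, table = self._table()
        double = QuartetCFTable(
            quartets=table.quartets, cf=table.cf, n=table.n * 2
        )
        assert pseudo_loglik(net, double) == pytest.approx(
            2 * pseudo_loglik(net, table)
        )

    def test_quartet_order_invariant(self, rng):
        net = parse_extended_newick(
            "((((A:1,B:1):1,C:2):1,D:3):1,E:4);"
        )
        taxa = ["A", "B", "C", "D", "E"]
        import itertools

        quartets = list(itertools.combinations(taxa, 4))
        cf = np.vstack([expected_quartet_cf(net, q) for q in quartets])
        n = rng.integers(10, 50, size=len(quartets))
        t1 = QuartetCFTable(quartets=quartets, cf=cf, n=n)
        perm = rng.permutation(len(quartets))
        t2 = QuartetCFTable(
            quartets=[quartets[i] for i in perm], cf=cf[perm], n=n[perm]
        )
        assert pseudo_loglik(net, t1) == pytest.approx(pseudo_loglik(net, t2))


class TestClassification:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (5, STRONG),
            (10, STRONG),
            (15, MODERATE),
            (20, MODERATE),
            (25, POOR),
            (29.999, POOR),
            (30, EXCLUDED_DELTA),
            (50, EXCLUDED_DELTA),
            (-3, STRONG),
        ],
    )
    def test_thresholds(self, delta, expected):
        assert classify_support(100 - delta, 100) == expected


class TestOutgroupExclusion:
    def test_hybrid_on_outgroup_stem_excluded(self):
        # reticulation cycle touches the outgroup pendant edge's parent
        net = make_network(
            [
                ("R", "X", 1.0),
                ("X", "O", 1.0),
                ("X", "H", 0.5, 0.4),
                ("R", "I", 0.5),
                ("I", "H", 0.5, 0.6),
                ("I", "A", 1.5),
                ("H", "B", 1.0),
            ]
        )
        retained, excluded = exclude_outgroup_reticulations([net], "O")
        assert excluded == [net]

    def test_tree_never_excluded(self):
        net = parse_extended_newick(QUARTET_TREE)
        retained, excluded = exclude_outgroup_reticulations([net], "D")
        assert retained == [net]

    def test_internal_reticulation_retained(self, one_hybrid_net):
        retained, excluded = exclude_outgroup_reticulations(
            [one_hybrid_net], "D"
        )
        assert retained == [one_hybrid_net]

    def test_outgroup_not_leaf_raises(self):
        net = parse_extended_newick(QUARTET_TREE)
        with pytest.raises(ValueError):
            exclude_outgroup_reticulations([net], "Z")


class TestSelection:
    def _ev(self, net, score, ref):
        return CandidateEvaluation(
            network=net,
            score=score,
            delta=ref - score,
            support_class=classify_support(score, ref),
        )

    def test_clear_majority(self, one_hybrid_net):
        evals = {
            rs: [self._ev(one_hybrid_net, -100, -100)] for rs in range(4)
        }
        evals[4] = [self._ev(one_hybrid_net, -140, -100)]  # excluded_delta
        sel = select_prevailing(evals)
        assert len(sel["selected"]) == 1
        assert sel["h"] == 1 and not sel["fallback"]

    def test_prevailing_plus_alternative_pair(self, one_hybrid_net):
        """Two same-h topologies with strong support in 3 and 2 of 5
        resamplings are both returned, in that order."""
        alt = one_hybrid_net.copy()
        # different topology: rename leaves to change the topology key
        import networkx as nx

        alt.graph = nx.relabel_nodes(
            alt.graph, {"A": "B", "B": "A"}, copy=True
        )
        alt = type(one_hybrid_net)(alt.graph)
        evals = {}
        for rs in range(5):
            lst = []
            if rs < 3:
                lst.append(self._ev(one_hybrid_net, -100, -100))
            if rs >= 3:
                lst.append(self._ev(alt, -101, -100))
            if rs == 0:
                lst.append(self._ev(alt, -150, -100))  # excluded
            evals[rs] = lst
        sel = select_prevailing(evals)
        assert len(sel["selected"]) == 2
        # the 3-resampling topology leads
        assert sel["details"][0]["n_resamplings"] == 3
        assert sel["details"][1]["n_resamplings"] == 2

    def test_single_resampling_support_not_selected(self, one_hybrid_net):
        tree = parse_extended_newick(QUARTET_TREE)
        evals = {
            0: [self._ev(one_hybrid_net, -100, -100),
                self._ev(tree, -90, -90)],
            1: [self._ev(tree, -91, -91)],
            2: [self._ev(tree, -92, -92)],
        }
        sel = select_prevailing(evals)
        # h=1 supported in only 1 of 3 resamplings: falls to h=0 topology
        assert sel["h"] == 0

    def test_fallback_when_nothing_qualifies(self, one_hybrid_net):
        tree = parse_extended_newick(QUARTET_TREE)
        evals = {
            0: [self._ev(tree, -90, -80)],  # poor/excluded only
        }
        evals[0][0].support_class = POOR
        sel = select_prevailing(evals)
        assert sel["fallback"] and sel["h"] == 0


class TestEvaluateCandidates:
    def test_classes_and_outgroup_rule(self, one_hybrid_net):
        tree = parse_extended_newick(QUARTET_TREE)
        cf = np.array(
            [expected_quartet_cf(one_hybrid_net, ("A", "B", "C", "D"))]
        )
        table = QuartetCFTable(
            quartets=[("A", "B", "C", "D")], cf=cf, n=[500]
        )
        evals = evaluate_candidates([one_hybrid_net, tree], table, outgroup="D")
        classes = {ev.h: ev.support_class for ev in evals}
        assert classes[1] == STRONG and classes[0] == STRONG
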