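"""Clade-quartet aggregation and exhaustive rooted clade-tree ranking."""

import itertools
from dataclasses import replace

import dendropy
import numpy as np
import pytest

from quartetpol.filtering import RETAINED, REJECTED_RISK
from quartetpol.quartets import CladeQuartet, TOPOLOGY_IDS
from quartetpol.supertree import (
    CladeQuartetSummary,
    aggregate_clade_quartet,
    canonical,
    clades,
    compare_topologies,
    enumerate_rooted_clade_trees,
    from_newick,
    induced_quartet_topology,
    leaves,
    rank_trees,
    to_newick,
    total_tree_support,
)
from test_filtering import scored


class TestAggregation:
    def test_median_of_retained_supports(self):
        scores = [scored((2, 6, 2), "a"), scored((6, 4, 0), "b"), scored((7, 3, 0), "c")]
        # normalized x1 supports: 0.2, 0.6, 0.7 -> median 0.6
        summ = aggregate_clade_quartet(scores)
        assert summ.medians["x1"] == pytest.approx(0.6)
        assert summ.n_retained == 3 and summ.n_total == 3

    def test_single_retained_quartet_is_identity(self):
        sc = scored((6, 3, 1))
        summ = aggregate_clade_quartet([sc])
        assert summ.medians == pytest.approx(sc.s)

    def test_medians_not_renormalized(self):
        scores = [scored((8, 1, 1), "a"), scored((1, 8, 1), "b"), scored((1, 1, 8), "c")]
        summ = aggregate_clade_quartet(scores)
        assert summ.medians == pytest.approx({t: 0.1 for t in TOPOLOGY_IDS})
        assert sum(summ.medians.values()) != pytest.approx(1.0)

    def test_empty_retained_set_flagged(self):
        sc = replace(scored((6, 3, 1)), status=REJECTED_RISK)
        summ = aggregate_clade_quartet([sc])
        assert summ.empty and summ.n_retained == 0


DOUBLE_FACTORIALS = {2: 1, 3: 3, 4: 15, 5: 105, 6: 945, 7: 10395}


class TestEnumeration:
    @pytest.mark.parametrize("n,count", sorted(DOUBLE_FACTORIALS.items()))
    def test_counts_match_double_factorial(self, n, count):
        labels = [f"C{i}" for i in range(n)]
        trees = enumerate_rooted_clade_trees(labels)
        assert len(trees) == count
        assert len({to_newick(t) for t in trees}) == count
        for t in trees:
            assert leaves(t) == set(labels)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_rooted_clade_trees(["A"])
        with pytest.raises(ValueError):
            enumerate_rooted_clade_trees([f"C{i}" for i in range(9)])


TINAMOU_FIRST = from_newick("(S,(T,(E,(K,R))));")


class TestInducedTopology:
    def cq(self, trip):
        return CladeQuartet(outgroup="O", ingroups=tuple(trip))

    def grouped(self, tree, trip):
        topo = induced_quartet_topology(tree, self.cq(trip))
        return tuple(sorted(self.cq(trip).grouped_clades(topo)))

    def test_printed_tree_restrictions(self):
        assert self.grouped(TINAMOU_FIRST, ("E", "K", "R")) == ("K", "R")
        assert self.grouped(TINAMOU_FIRST, ("E", "K", "T")) == ("E", "K")
        assert self.grouped(TINAMOU_FIRST, ("K", "S", "T")) == ("K", "T")

    def test_cherry_plus_outlier(self):
        for trip in itertools.combinations("ABCDE", 3):
            a, b, c = trip
            tree = from_newick(f"({c},({a},{b}));")
            assert self.grouped(tree, trip) == tuple(sorted((a, b)))

    def test_missing_clade_raises(self):
        with pytest.raises(KeyError):
            induced_quartet_topology(TINAMOU_FIRST, self.cq(("E", "K", "Z")))

    def test_total_function_on_all_trees(self):
        trees = enumerate_rooted_clade_trees(list("EKRST"))
        cq = self.cq(("E", "K", "T"))
        for t in trees:
            assert induced_quartet_topology(t, cq) in TOPOLOGY_IDS


def summaries_from(support_map, clade_labels="EKRST"):
    """Build summaries for all clade triplets from {triplet: {topo: support}}."""
    out = {}
    for trip in itertools.combinations(sorted(clade_labels), 3):
        cq = CladeQuartet(outgroup="O", ingroups=trip)
        med = support_map(cq)
        out[cq.id] = CladeQuartetSummary(cq, med, n_retained=1, n_total=1)
    return out


def dendropy_induced_pair(newick, trip):
    """Independent triplet restriction via dendropy MRCA queries."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    tree.encode_bipartitions()
    taxa = {l.taxon.label: l.taxon for l in tree.leaf_node_iter()}
    all_mrca = tree.mrca(taxa=[taxa[x] for x in trip])
    for pair in itertools.combinations(trip, 2):
        if tree.mrca(taxa=[taxa[x] for x in pair]) is not all_mrca:
            return tuple(sorted(pair))
    raise AssertionError("no grouped pair found")


class TestScoring:
    def test_perfect_summaries_score_tree_count(self):
        target = TINAMOU_FIRST

        def support(cq):
            topo = induced_quartet_topology(target, cq)
            return {t: 1.0 if t == topo else 0.0 for t in TOPOLOGY_IDS}

        summaries = summaries_from(support)
        assert total_tree_support(target, summaries) == pytest.approx(10.0)
        ranking = rank_trees(summaries, list("EKRST"))
        assert ranking.best == canonical(target)
        assert ranking.supports[0] == pytest.approx(10.0)
        assert ranking.distances()[0] == 0.0

    def test_uniform_summaries_tie_all_trees(self):
        summaries = summaries_from(lambda cq: {t: 1 / 3 for t in TOPOLOGY_IDS})
        ranking = rank_trees(summaries, list("EKRST"))
        assert len(ranking.trees) == 105
        assert np.allclose(ranking.supports, ranking.supports[0])

    def test_agrees_with_independent_dendropy_scorer(self):
        rng = np.random.default_rng(13)

        def support(cq):
            w = rng.dirichlet([1, 1, 1])
            return {t: float(v) for t, v in zip(TOPOLOGY_IDS, w)}

        summaries = summaries_from(support)
        ranking = rank_trees(summaries, list("EKRST"))
        for tree, sup in list(zip(ranking.trees, ranking.supports))[::10]:
            newick = to_newick(tree, ";")
            total = 0.0
            for summ in summaries.values():
                pair = dendropy_induced_pair(newick, summ.clade_quartet.ingroups)
                topo = next(
                    t
                    for t in TOPOLOGY_IDS
                    if tuple(sorted(summ.clade_quartet.grouped_clades(t))) == pair
                )
                total += summ.medians[topo]
            assert total == pytest.approx(sup, abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(14)
        weights = {}

        def support(cq):
            key = cq.ingroups
            if key not in weights:
                weights[key] = rng.dirichlet([2, 2, 2])
            return {t: float(v) for t, v in zip(TOPOLOGY_IDS, weights[key])}

        summaries = summaries_from(support)
        ranking = rank_trees(summaries, list("EKRST"))
        # permute labels consistently
        perm = dict(zip("EKRST", "KRSTE"))
        perm_summaries = {}
        for summ in summaries.values():
            new_trip = tuple(sorted(perm[c] for c in summ.clade_quartet.ingroups))
            new_cq = CladeQuartet(outgroup="O", ingroups=new_trip)
            # remap topology ids: topology grouping pair (p,q) -> (perm p, perm q)
            med = {}
            for t in TOPOLOGY_IDS:
                pair = tuple(sorted(perm[c] for c in summ.clade_quartet.grouped_clades(t)))
                nt = next(
                    u
                    for u in TOPOLOGY_IDS
                    if tuple(sorted(new_cq.grouped_clades(u))) == pair
                )
                med[nt] = summ.medians[t]
            perm_summaries[new_cq.id] = CladeQuartetSummary(new_cq, med, 1, 1)
        perm_ranking = rank_trees(perm_summaries, list("EKRST"))
        assert np.allclose(sorted(ranking.supports), sorted(perm_ranking.supports))

    def test_empty_summary_equivalent_to_dropping_it(self):
        rng = np.random.default_rng(15)

        def support(cq):
            w = rng.dirichlet([1, 1, 1])
            return {t: float(v) for t, v in zip(TOPOLOGY_IDS, w)}

        summaries = summaries_from(support)
        key = sorted(summaries)[0]
        emptied = dict(summaries)
        emptied[key] = CladeQuartetSummary(
            summaries[key].clade_quartet, None, 0, 5
        )
        dropped = {k: v for k, v in summaries.items() if k != key}
        r1 = rank_trees(emptied, list("EKRST"))
        r2 = rank_trees(dropped, list("EKRST"))
        assert r1.newicks == r2.newicks
        assert np.allclose(r1.supports, r2.supports)


class TestCompare:
    def test_tree_vs_itself(self):
        assert compare_topologies(TINAMOU_FIRST, TINAMOU_FIRST)["same"]

    def test_nni_neighbour_shares_all_but_one_clade(self):
        t1 = from_newick("(S,(T,(E,(K,R))));")
        t2 = from_newick("(S,(T,(K,(E,R))));")
        cmp = compare_topologies(t1, t2)
        assert not cmp["same"]
        assert len(cmp["conflicting_clades_1"]) == 1
        assert len(cmp["conflicting_clades_2"]) == 1

    def test_leafset_mismatch_raises(self):
        with pytest.raises(ValueError):
            compare_topologies(from_newick("(A,(B,C));"), from_newick("(A,(B,D));"))

    def test_distinct_published_topologies_differ(self):
        tinamou_last = from_newick("(S,(E,(K,(R,T))));")
        assert not compare_topologies(TINAMOU_FIRST, tinamou_last)["same"]
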