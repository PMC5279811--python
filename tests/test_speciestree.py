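import itertools
import math

import dendropy
import numpy as np
import pytest

from gbscoal import simulate, speciestree as st, treeutils


def _trees(newicks, rooted=True):
    return [treeutils.tree_from_newick(nw, rooted=rooted) for nw in newicks]


def _identity_map(labels):
    return {l: l for l in labels}


class TestAverageInternodeMatrix:
    def test_single_tree_equals_its_internode_distances(self):
        tree = treeutils.tree_from_newick("(((A,B),C),D);")
        D = st.average_internode_matrix([tree], _identity_map("ABCD"))
        idx = {l: i for i, l in enumerate(D.labels)}
        assert D.values[idx["A"], idx["B"]] == 1
        assert D.values[idx["A"], idx["C"]] == 2
        assert D.values[idx["C"], idx["D"]] == 1

    def test_duplicated_input_unchanged(self):
        tree = treeutils.tree_from_newick("(((A,B),C),D);")
        D1 = st.average_internode_matrix([tree], _identity_map("ABCD"))
        D2 = st.average_internode_matrix([tree] * 3, _identity_map("ABCD"))
        assert np.array_equal(D1.values, D2.values)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(8)]
        trees = []
        all_t = list(treeutils.enumerate_rooted_topologies(labels[:6]))
        for i in rng.choice(len(all_t), 5, replace=False):
            trees.append(all_t[i])
        D = st.average_internode_matrix(trees, _identity_map(labels[:6]))
        idx = {l: i for i, l in enumerate(D.labels)}
        for a, b in itertools.combinations(labels[:6], 2):
            vals = []
            for t in trees:
                labs, E = treeutils.path_edge_counts(t)
                j = {l: i for i, l in enumerate(labs)}
                vals.append(E[j[a], j[b]] - 1)
            assert D.values[idx[a], idx[b]] == pytest.approx(np.mean(vals))

    def test_never_coobserved_pair_rejected(self):
        t1 = treeutils.tree_from_newick("((A,B),C);")
        with pytest.raises(ValueError, match="co-observed"):
            st.average_internode_matrix([t1], {"A": "A", "B": "B", "C": "C",
                                               "D": "D"})

    def test_multi_sample_species_averaging(self):
        tree = treeutils.tree_from_newick("(((a1,a2),b1),c1);")
        tmap = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        D = st.average_internode_matrix([tree], tmap)
        idx = {l: i for i, l in enumerate(D.labels)}
        # d(a1,b1)=2, d(a2,b1)=2 -> mean 2 ; d(a1,c1)=d(a2,c1)=2... wait
        labs, E = treeutils.path_edge_counts(tree)
        j = {l: i for i, l in enumerate(labs)}
        expected_ab = np.mean([E[j["a1"], j["b1"]] - 1, E[j["a2"], j["b1"]] - 1])
        assert D.values[idx["A"], idx["B"]] == pytest.approx(expected_ab)


class TestDistanceSpeciesTree:
    def test_identical_gene_trees_return_common_topology(self):
        trees = _trees(["((A,B),(C,D));"] * 10, rooted=True)
        est = st.distance_species_tree(
            st.average_internode_matrix(trees, _identity_map("ABCD")))
        assert treeutils.same_unrooted_topology(
            est.tree, treeutils.tree_from_newick("((A,B),(C,D));",
                                                 rooted=False))

    def test_three_species_trivial(self):
        trees = _trees(["((A,B),C);"] * 3)
        est = st.distance_species_tree(
            st.average_internode_matrix(trees, _identity_map("ABC")))
        assert set(treeutils.leaf_labels(est.tree)) == {"A", "B", "C"}


class TestTripletCounts:
    def test_identical_trees_counted(self):
        trees = _trees(["((a,b),c);"] * 10)
        tab = st.triplet_counts(trees, _identity_map("abc"))
        triple = frozenset("abc")
        assert tab.counts[triple] == {frozenset("ab"): 10}

    def test_star_tree_unresolved(self):
        trees = _trees(["(a,b,c);"] * 5)
        tab = st.triplet_counts(trees, _identity_map("abc"))
        assert tab.total(frozenset("abc")) == 0

    def test_unrooted_input_rejected(self):
        trees = _trees(["((a,b),c);"], rooted=False)
        with pytest.raises(ValueError, match="rooted"):
            st.triplet_counts(trees, _identity_map("abc"))

    def test_multi_sample_combinations_match_brute_force(self):
        rng = np.random.default_rng(1)
        tips = ["a1", "a2", "b1", "c1", "d1"]
        tmap = {"a1": "A", "a2": "A", "b1": "B", "c1": "C", "d1": "D"}
        all_trees = list(treeutils.enumerate_rooted_topologies(tips))
        trees = [all_trees[i] for i in rng.choice(len(all_trees), 12)]
        tab = st.triplet_counts(trees, tmap)
        # brute force: enumerate tip triples with distinct species
        expect: dict = {}
        for t in trees:
            for x, y, z in itertools.combinations(tips, 3):
                sp = {tmap[x], tmap[y], tmap[z]}
                if len(sp) != 3:
                    continue
                pair = treeutils.induced_triplet(t, x, y, z)
                if pair is None:
                    continue
                spair = frozenset(tmap[v] for v in pair)
                key = frozenset(sp)
                expect.setdefault(key, {})
                expect[key][spair] = expect[key].get(spair, 0) + 1
        assert tab.counts == expect


class TestTripletPseudoLikelihood:
    @pytest.mark.parametrize("p_hat", [0.4, 0.6, 0.9])
    def test_three_species_closed_form(self, p_hat):
        N = 10000
        n_match = int(round(p_hat * N))
        tab = st.TripletCountTable()
        tab.add(frozenset("ABC"), frozenset("AB"), n_match)
        tab.add(frozenset("ABC"), frozenset("AC"), (N - n_match) // 2)
        tab.add(frozenset("ABC"), frozenset("BC"),
                N - n_match - (N - n_match) // 2)
        topo = treeutils.tree_from_newick("((A,B),C);")
        fitted, logL = st.triplet_pseudo_likelihood(topo, tab)
        internal = [e.length for e in fitted.preorder_edge_iter()
                    if e.head_node is not fitted.seed_node
                    and not e.head_node.is_leaf()]
        expected = -math.log(3 * (1 - p_hat) / 2)
        assert internal[0] == pytest.approx(expected, abs=1e-6)
        assert logL <= 0

    def test_uniform_counts_give_zero_branch(self):
        tab = st.TripletCountTable()
        for pair in ("AB", "AC", "BC"):
            tab.add(frozenset("ABC"), frozenset(pair), 100)
        fitted, _ = st.triplet_pseudo_likelihood(
            treeutils.tree_from_newick("((A,B),C);"), tab)
        internal = [e.length for e in fitted.preorder_edge_iter()
                    if e.head_node is not fitted.seed_node
                    and not e.head_node.is_leaf()]
        assert internal[0] == pytest.approx(0.0, abs=1e-6)

    def test_all_matching_hits_cap(self):
        tab = st.TripletCountTable()
        tab.add(frozenset("ABC"), frozenset("AB"), 500)
        fitted, _ = st.triplet_pseudo_likelihood(
            treeutils.tree_from_newick("((A,B),C);"), tab)
        internal = [e.length for e in fitted.preorder_edge_iter()
                    if e.head_node is not fitted.seed_node
                    and not e.head_node.is_leaf()]
        assert internal[0] == pytest.approx(st.T_MAX)

    def test_unknown_species_rejected(self):
        tab = st.TripletCountTable()
        tab.add(frozenset("ABX"), frozenset("AB"), 5)
        with pytest.raises(ValueError, match="X"):
            st.triplet_pseudo_likelihood(
                treeutils.tree_from_newick("((A,B),C);"), tab)


class TestTripletSearch:
    def _counts_from_truth(self, newick, n=500, seed=0):
        model = simulate.SpeciesTreeModel.from_newick(newick,
                                                      samples_per_species=1,
                                                      ploidy=2)
        cfg = simulate.SimulationConfig(n_loci=n, seed=seed)
        truth = simulate.simulate_gene_trees(model, cfg)
        tmap = {f"{s}_h{i}": sp for s, sp in model.samples.items()
                for i in range(2)}
        return st.triplet_counts(truth.gene_trees, tmap)

    def test_truth_is_local_optimum(self):
        newick = "(((A:1,B:1):1,C:2):1,D:3);"
        counts = self._counts_from_truth(newick)
        start = treeutils.tree_from_newick("(((A,B),C),D);")
        est = st.triplet_search(counts, start, n_runs=1, seed=0)
        assert treeutils.same_rooted_topology(est.tree, start)

    def test_truth_is_global_optimum_among_all_rooted_trees(self):
        newick = "(((A:1,B:1):1,C:2):1,D:3);"
        counts = self._counts_from_truth(newick, n=800, seed=3)
        best_ll, best_tree = -np.inf, None
        for cand in treeutils.enumerate_rooted_topologies(list("ABCD")):
            _, ll = st.triplet_pseudo_likelihood(cand, counts)
            if ll > best_ll:
                best_ll, best_tree = ll, cand
        assert treeutils.same_rooted_topology(
            best_tree, treeutils.tree_from_newick("(((A,B),C),D);"))
        est = st.triplet_search(counts,
                                treeutils.tree_from_newick("(((A,D),C),B);"),
                                n_runs=3, seed=1)
        assert est.log_pseudo_likelihood == pytest.approx(best_ll, abs=1e-6)

    def test_deterministic_given_seed(self):
        counts = self._counts_from_truth("(((A:1,B:1):1,C:2):1,D:3);")
        start = treeutils.tree_from_newick("(((A,B),C),D);")
        e1 = st.triplet_search(counts, start, n_runs=3, seed=7)
        e2 = st.triplet_search(counts, start, n_runs=3, seed=7)
        assert e1.per_run_log_likelihoods == e2.per_run_log_likelihoods
        assert treeutils.same_rooted_topology(e1.tree, e2.tree)


class TestQuartetScore:
    def test_identical_gene_trees_combinatorics(self):
        L, n = 7, 6
        newick = "(((A,B),(C,D)),(E,F));"
        trees = _trees([newick] * L)
        cand = treeutils.tree_from_newick(newick, rooted=False)
        sc = st.quartet_score(cand, trees, _identity_map("ABCDEF"))
        assert sc["raw"] == L * math.comb(n, 4)
        assert sc["normalised"] == 1.0

    def test_disjoint_quartets_zero(self):
        trees = _trees(["((A,B),(C,D));"] * 5, rooted=True)
        cand = treeutils.tree_from_newick("((A,C),(B,D));", rooted=False)
        sc = st.quartet_score(cand, trees, _identity_map("ABCD"))
        assert sc["normalised"] == 0.0

    def test_random_gene_trees_near_one_third(self):
        rng = np.random.default_rng(5)
        alts = ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
        trees = _trees([alts[i] for i in rng.integers(0, 3, 900)])
        cand = treeutils.tree_from_newick(alts[0], rooted=False)
        sc = st.quartet_score(cand, trees, _identity_map("ABCD"))
        assert sc["normalised"] == pytest.approx(1 / 3, abs=0.05)

    def test_missing_species_rejected(self):
        trees = _trees(["((A,B),(C,D));"])
        cand = treeutils.tree_from_newick("((A,B),C);", rooted=False)
        with pytest.raises(ValueError, match="lacks"):
            st.quartet_score(cand, trees, _identity_map("ABCD"))

    def test_exhaustive_search_size_guard(self):
        trees = _trees(["((A,B),(C,D));"])
        with pytest.raises(ValueError, match="exhaustive"):
            st.exhaustive_quartet_search([f"s{i}" for i in range(10)], trees,
                                         _identity_map("ABCD"))


class TestMLBS:
    def _pools(self, locus_ids, B, label="x"):
        pools = {}
        for lid in locus_ids:
            pools[lid] = _trees(["((A,B),(C,D));"] * B)
        return pools

    def test_single_locus_single_tree_per_replicate(self):
        pools = self._pools([0], B=150)
        reps = st.mlbs_replicates(pools, st.MLBSConfig(n_replicates=10, seed=0))
        assert len(reps) == 10
        assert all(len(r) == 1 for r in reps)

    def test_replicate_count_default(self):
        pools = self._pools([0, 1, 2], B=20)
        reps = st.mlbs_replicates(pools, st.MLBSConfig(seed=1, B=20))
        assert len(reps) == 100
        assert all(len(r) == 3 for r in reps)

    def test_within_replicate_draws_are_distinct_pool_members(self):
        pools = {0: _trees([f"((A:{i},B:1),(C:1,D:1));" for i in range(50)]),
                 1: _trees([f"((A:{i},B:2),(C:1,D:1));" for i in range(50)])}
        reps = st.mlbs_replicates(pools, st.MLBSConfig(n_replicates=30, B=50,
                                                       seed=2))
        for rep in reps:
            ids = [id(t) for t in rep]
            assert len(ids) == len(set(ids))

    def test_pool_exhaustion_raises(self):
        pools = {0: _trees(["((A,B),(C,D));"]), 1: _trees(["((A,B),(C,D));"])}
        with pytest.raises(RuntimeError, match="increase B"):
            st.mlbs_replicates(pools, st.MLBSConfig(n_replicates=50, B=1,
                                                    seed=3))


class TestSummarizeSupport:
    def test_identical_bootstraps_full_support(self):
        est = st.SpeciesTreeEstimate(
            tree=treeutils.tree_from_newick("((A,B),(C,D),E);", rooted=False),
            method="distance", rooted=False)
        boots = _trees(["((A,B),(C,D),E);"] * 20, rooted=False)
        out = st.summarize_support(est, boots)
        assert set(out.supports.values()) == {100.0}

    def test_absent_branch_zero_and_counts(self):
        est = st.SpeciesTreeEstimate(
            tree=treeutils.tree_from_newick("((A,B),(C,D),E);", rooted=False),
            method="distance", rooted=False)
        boots = _trees(["((A,B),(C,D),E);"] * 87 +
                       ["((A,C),(B,D),E);"] * 13, rooted=False)
        out = st.summarize_support(est, boots)
        assert out.supports[frozenset({"A", "B"})] == pytest.approx(87.0)
        boots = _trees(["((A,C),(B,D),E);"] * 10, rooted=False)
        out = st.summarize_support(est, boots)
        assert set(out.supports.values()) == {0.0}

    def test_label_mismatch_rejected(self):
        est = st.SpeciesTreeEstimate(
            tree=treeutils.tree_from_newick("((A,B),(C,D));", rooted=False),
            method="distance", rooted=False)
        boots = _trees(["((A,B),(C,E));"], rooted=False)
        with pytest.raises(ValueError, match="same species"):
            st.summarize_support(est, boots)
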