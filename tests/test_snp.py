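import math

import numpy as np
import pytest

from gbscoal import assembly, snp, treeutils
from gbscoal.assembly import Locus, LocusSet, SampleLocus


def _locus(idx, genos_by_pos, samples, length=30, seq_base="A"):
    locus = Locus(id=idx, length=length)
    for s in samples:
        locus.samples[s] = SampleLocus([seq_base * length], seq_base * length, 9)
    locus.snps = genos_by_pos
    return locus


class TestBuildMatrix:
    def test_low_coverage_site_removed(self):
        samples = [f"s{i}" for i in range(100)]
        genos_ok = {0: {s: ("A",) if i % 2 else ("C",)
                        for i, s in enumerate(samples[:50])}}
        genos_low = {1: {s: ("A",) if i % 2 else ("C",)
                         for i, s in enumerate(samples[:49])}}
        ls = LocusSet(loci=[_locus(0, {**genos_ok, **genos_low}, samples)],
                      samples=samples)
        m = snp.build_and_filter_snp_matrix([ls], min_site_coverage=0.5)
        assert [pos for _, _, pos in m.sites] == [0]

    def test_invariant_site_removed(self):
        samples = ["a", "b", "c", "d"]
        genos = {0: {"a": ("A",), "b": ("A",), "c": ("A",)},
                 1: {"a": ("A",), "b": ("G",), "c": ("A",), "d": ("A",)}}
        ls = LocusSet(loci=[_locus(0, genos, samples)], samples=samples)
        m = snp.build_and_filter_snp_matrix([ls], min_site_coverage=0.0)
        assert [pos for _, _, pos in m.sites] == [1]

    def test_disjoint_sets_block_union(self):
        g1 = {0: {"a": ("A",), "b": ("C",)}}
        g2 = {0: {"c": ("G",), "d": ("T",)}}
        ls1 = LocusSet(loci=[_locus(0, g1, ["a", "b"])], samples=["a", "b"],
                       provenance="merged")
        ls2 = LocusSet(loci=[_locus(0, g2, ["c", "d"])], samples=["c", "d"],
                       provenance="unmerged")
        m = snp.build_and_filter_snp_matrix([ls1, ls2], min_site_coverage=0.0)
        assert m.samples == ["a", "b", "c", "d"]
        assert m.n_sites == 2
        df = m.to_frame()
        assert (df.loc["a", "unmerged:0:0"], df.loc["c", "merged:0:0"]) == ("-", "-")

    def test_replicates_excludable(self):
        g = {0: {"a": ("A",), "a.rep": ("A",), "b": ("C",)}}
        ls = LocusSet(loci=[_locus(0, g, ["a", "a.rep", "b"])],
                      samples=["a", "a.rep", "b"])
        m = snp.build_and_filter_snp_matrix([ls], min_site_coverage=0.0,
                                            exclude_samples=("a.rep",))
        assert m.samples == ["a", "b"]


class TestK80:
    def test_closed_form_value(self):
        # 400 sites: 40 transitions (A<->G), 20 transversions (A<->C)
        a = "A" * 400
        b = "G" * 40 + "C" * 20 + "A" * 340
        dm = snp.k80_distances({"x": a, "y": b})
        expected = 0.5 * math.log(1 / 0.75) + 0.25 * math.log(1 / 0.9)
        assert dm.values[0, 1] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.1702, abs=1e-4)

    def test_identical_sequences_zero(self):
        dm = snp.k80_distances({"x": "ACGTACGT", "y": "ACGTACGT"})
        assert dm.values[0, 1] == 0.0

    def test_proportion_scale_invariance(self):
        d1 = snp.k80_distances({"x": "AAAA", "y": "CAAA"}).values[0, 1]
        d2 = snp.k80_distances({"x": "A" * 400, "y": "C" * 100 + "A" * 300}
                               ).values[0, 1]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_pairwise_deletion_of_ambiguity(self):
        # N/IUPAC sites are excluded pair-by-pair
        dm = snp.k80_distances({"x": "ANRA", "y": "AGGA"})
        assert dm.values[0, 1] == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        chars = np.array(list("ACGT-N"))
        seqs = {f"s{i}": "".join(rng.choice(chars, size=60, p=[.22, .22, .22, .22, .06, .06]))
                for i in range(8)}
        dm = snp.k80_distances(seqs)
        labels = dm.labels
        for i in range(8):
            for j in range(i + 1, 8):
                x, y = seqs[labels[i]], seqs[labels[j]]
                n = ti = tv = 0
                for cx, cy in zip(x, y):
                    if cx not in "ACGT" or cy not in "ACGT":
                        continue
                    n += 1
                    if cx != cy:
                        if {cx, cy} in ({"A", "G"}, {"C", "T"}):
                            ti += 1
                        else:
                            tv += 1
                P, Q = ti / n, tv / n
                arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
                if arg1 <= 0 or arg2 <= 0:
                    assert np.isnan(dm.values[i, j])
                else:
                    expected = -0.5 * math.log(arg1 * math.sqrt(arg2))
                    assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_undefined_and_nj_rejects(self):
        dm = snp.k80_distances({"x": "AC--", "y": "--GT", "z": "ACGT"})
        assert ("x", "y") in dm.undefined_pairs()
        with pytest.raises(ValueError, match="x"):
            snp.nj_tree(dm)


def _leaf_distances(tree):
    """Independent patristic distances by BFS with edge lengths."""
    adj = {}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            w = ch.edge.length or 0.0
            adj.setdefault(node, []).append((ch, w))
            adj.setdefault(ch, []).append((node, w))
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    D = np.zeros((len(leaves), len(leaves)))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        nxt.append(v)
            frontier = nxt
        for j, l in enumerate(leaves):
            D[i, j] = dist[l]
    return labels, D


class TestNJ:
    def test_four_taxon_split_recovered(self):
        # additive distances with split AB|CD
        tree = treeutils.tree_from_newick(
            "((A:0.3,B:0.4):0.5,(C:0.2,D:0.6):0.1);", rooted=False)
        labels, D = _leaf_distances(tree)
        est = snp.nj_tree(snp.DistanceMatrix(labels=labels, values=D))
        assert treeutils.same_unrooted_topology(est, tree)

    @pytest.mark.parametrize("n", [5, 6])
    def test_exhaustive_recovery_small(self, n):
        rng = np.random.default_rng(n)
        labels = [f"t{i}" for i in range(n)]
        for tree in treeutils.enumerate_unrooted_topologies(labels):
            for e in tree.preorder_edge_iter():
                if e.head_node is not tree.seed_node:
                    e.length = float(rng.uniform(0.1, 1.0))
            labs, D = _leaf_distances(tree)
            est = snp.nj_tree(snp.DistanceMatrix(labels=labs, values=D))
            assert treeutils.same_unrooted_topology(est, tree)

    def test_label_order_invariance(self):
        tree = treeutils.tree_from_newick(
            "((A:0.3,B:0.4):0.5,(C:0.2,D:0.6):0.1);", rooted=False)
        labels, D = _leaf_distances(tree)
        perm = [2, 0, 3, 1]
        est1 = snp.nj_tree(snp.DistanceMatrix(labels=labels, values=D))
        est2 = snp.nj_tree(snp.DistanceMatrix(
            labels=[labels[i] for i in perm], values=D[np.ix_(perm, perm)]))
        assert treeutils.same_unrooted_topology(est1, est2)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.5, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        ord_ = snp.pcoa(snp.DistanceMatrix(labels=list("abcde"), values=D))
        assert len(ord_.eigenvalues) == 1
        coords = ord_.coordinates[:, 0]
        rec = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(rec, D, atol=1e-9)

    def test_planted_2d_configuration_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ord_ = snp.pcoa(snp.DistanceMatrix(
            labels=[f"p{i}" for i in range(10)], values=D), n_axes=2)
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts, ord_.coordinates)
        assert disparity < 1e-9

    def test_identical_samples_identical_coordinates(self):
        D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        ord_ = snp.pcoa(snp.DistanceMatrix(labels=list("abc"), values=D))
        assert np.allclose(ord_.coordinates[0], ord_.coordinates[1])

    def test_eigenvalues_bound_coordinate_norms(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ord_ = snp.pcoa(snp.DistanceMatrix(
            labels=[f"p{i}" for i in range(8)], values=D))
        assert np.all(np.diff(ord_.eigenvalues) <= 1e-9)
        assert ord_.eigenvalues.sum() == pytest.approx(
            (ord_.coordinates ** 2).sum(), abs=1e-9)
        assert np.allclose(ord_.coordinates.mean(axis=0), 0, atol=1e-9)


class TestUnlinkedSelection:
    def _matrix(self):
        samples = [f"s{i}" for i in range(8)]
        sites = []
        cols = []
        # locus 0: one singleton site, one site with minor count 3
        sites.append(("merged", 0, 2))
        cols.append(list("CAAAAAAA"))
        sites.append(("merged", 0, 7))
        cols.append(list("GGGAAAAA"))
        # locus 1: two singleton sites
        sites.append(("merged", 1, 0))
        cols.append(list("TAAAAAAA"))
        sites.append(("merged", 1, 4))
        cols.append(list("ATAAAAAA"))
        geno = np.array([[ord(c) for c in col] for col in cols],
                        dtype=np.uint8).T
        return snp.SNPMatrix(samples=samples, sites=sites, genotypes=geno)

    def test_biased_prefers_multi_occurrence_minor(self):
        m = self._matrix()
        sub, stats = snp.select_unlinked_snps(m, mode="biased", seed=0)
        assert ("merged", 0, 7) in sub.sites        # minor count 3 beats 1
        assert stats["n_selected"] == 2
        assert stats["singleton_fraction"] == pytest.approx(0.5)  # locus 1 fallback

    def test_one_site_per_locus(self):
        m = self._matrix()
        for mode in ("random", "biased"):
            sub, _ = snp.select_unlinked_snps(m, mode=mode, seed=3)
            loci = [(p, l) for p, l, _ in sub.sites]
            assert len(loci) == len(set(loci)) == 2

    def test_per_taxon_presence_filter(self):
        samples = ["x1", "x2", "y1"]
        sites = [("merged", 0, 0), ("merged", 1, 0)]
        geno = np.array([[ord("A"), ord("C")],
                         [ord("C"), ord("A")],
                         [ord("-"), ord("C")]], dtype=np.uint8)
        m = snp.SNPMatrix(samples=samples, sites=sites, genotypes=geno)
        tmap = {"x1": "X", "x2": "X", "y1": "Y"}
        sub, _ = snp.select_unlinked_snps(m, taxon_map=tmap,
                                          require_per_taxon_presence=True,
                                          seed=0)
        assert sub.sites == [("merged", 1, 0)]  # site 0 has no Y genotype

    def test_biased_lowers_singleton_fraction(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(12)]
        sites, cols = [], []
        for locus in range(60):
            for k, pos in (((1, 0)), (3, 1)):
                col = ["A"] * 12
                for idx in rng.choice(12, k, replace=False):
                    col[idx] = "C"
                sites.append(("merged", locus, pos))
                cols.append(col)
        geno = np.array([[ord(c) for c in col] for col in cols],
                        dtype=np.uint8).T
        m = snp.SNPMatrix(samples=samples, sites=sites, genotypes=geno)
        _, s_rand = snp.select_unlinked_snps(m, mode="random", seed=7)
        _, s_bias = snp.select_unlinked_snps(m, mode="biased", seed=7)
        assert s_bias["singleton_fraction"] < s_rand["singleton_fraction"]
        assert s_bias["singleton_fraction"] == 0.0
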