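"""Summary species-tree estimation from gene trees.

Three complementary summaries of a set of per-locus trees:

* an averaged internode-distance matrix over gene trees, turned into a
  species tree by neighbour-joining (topology only);
* a rooted-triplet pseudo-likelihood: under the multispecies coalescent a
  species triplet with internal path length T (coalescent units) matches the
  species topology with probability 1 - (2/3)e^{-T}, each alternative having
  probability (1/3)e^{-T}; the product of per-triple multinomials is
  maximised over internal branch lengths and, via NNI hill climbing, over
  rooted topologies;
* a quartet score: the number of resolved cross-species quartets in the gene
  trees that agree with a candidate species tree (exhaustive search provided
  for small species counts).

Branch support comes from multi-locus bootstrapping (MLBS): loci resampled
with replacement, and per-locus site resampling emulated by drawing
precomputed bootstrap trees without replacement within each replicate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize

from . import treeutils
from .snp import DistanceMatrix, nj_tree

__all__ = ["TripletCountTable", "SpeciesTreeEstimate", "MLBSConfig",
           "average_internode_matrix", "distance_species_tree",
           "triplet_counts", "triplet_pseudo_likelihood", "triplet_search",
           "quartet_tally", "quartet_score", "exhaustive_quartet_search",
           "mlbs_replicates", "summarize_support"]

T_MAX = 10.0


@dataclass
class TripletCountTable:
    """Rooted-triplet topology counts per unordered species triple.

    ``counts[{X,Y,Z}][{X,Y}]`` is the number of (gene tree x tip combination)
    units in which the tree put X and Y together below Z.
    """

    counts: dict = field(default_factory=dict)

    def add(self, triple: frozenset, pair: frozenset, n: int = 1) -> None:
        tab = self.counts.setdefault(triple, {})
        tab[pair] = tab.get(pair, 0) + n

    def species(self) -> set[str]:
        return {sp for triple in self.counts for sp in triple}

    def total(self, triple: frozenset) -> int:
        return sum(self.counts.get(triple, {}).values())


@dataclass
class SpeciesTreeEstimate:
    tree: dendropy.Tree
    method: str
    rooted: bool
    log_pseudo_likelihood: float | None = None
    quartet_score_raw: int | None = None
    quartet_score_normalised: float | None = None
    per_run_log_likelihoods: list[float] = field(default_factory=list)
    supports: dict = field(default_factory=dict)


@dataclass
class MLBSConfig:
    n_replicates: int = 100
    B: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.B < 1:
            raise ValueError("n_replicates and B must be >= 1")


# ---------------------------------------------------------------------------
# distance summary

def average_internode_matrix(gene_trees, taxon_map: dict[str, str]
                             ) -> DistanceMatrix:
    """Species-pair internode distances averaged over gene trees.

    The internode distance between two tips is the number of internal nodes
    on the unrooted path between them; all cross-species tip pairs of all
    trees containing both species contribute to the average.
    """
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    species = sorted(set(taxon_map.values()))
    for tree in gene_trees:
        if tree is None:
            continue
        labels, D = treeutils.path_edge_counts(tree)
        sp = [taxon_map.get(lbl) for lbl in labels]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = sp[i], sp[j]
                if a is None or b is None or a == b:
                    continue
                key = (a, b) if a < b else (b, a)
                sums[key] = sums.get(key, 0.0) + (int(D[i, j]) - 1)
                counts[key] = counts.get(key, 0) + 1
    n = len(species)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (species[i], species[j])
            if key not in counts:
                raise ValueError(f"species pair never co-observed: {key}")
            M[i, j] = M[j, i] = sums[key] / counts[key]
    return DistanceMatrix(labels=species, values=M, model="internode",
                          deletion="none")


def distance_species_tree(D: DistanceMatrix) -> SpeciesTreeEstimate:
    """Neighbour-joining on the averaged matrix; topology only."""
    tree = nj_tree(D)
    treeutils.strip_branch_lengths(tree)
    return SpeciesTreeEstimate(tree=tree, method="internode-distance",
                               rooted=False)


# ---------------------------------------------------------------------------
# rooted triplets

def triplet_counts(gene_trees, taxon_map: dict[str, str]) -> TripletCountTable:
    """Aggregate rooted-triplet topologies over trees and tip combinations.

    Every cross-species tip triple (one tip from each of three distinct
    species) of every rooted gene tree contributes one count; triples left
    unresolved by a polytomy are counted in none of the three topologies.
    A map sending each tip to itself reproduces the samples-as-species
    configuration.
    """
    table = TripletCountTable()
    for tree in gene_trees:
        if tree is None:
            continue
        if not tree.is_rooted:
            raise ValueError("triplet counting requires rooted gene trees")
        total: dict[str, int] = {}
        for lf in tree.leaf_node_iter():
            sp = taxon_map.get(lf.taxon.label)
            if sp is not None:
                total[sp] = total.get(sp, 0) + 1
        subtree: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                sp = taxon_map.get(node.taxon.label)
                subtree[node] = {sp: 1} if sp is not None else {}
                continue
            child_counts = [subtree[c] for c in node.child_nodes()]
            merged: dict[str, int] = {}
            for cc in child_counts:
                for sp, k in cc.items():
                    merged[sp] = merged.get(sp, 0) + k
            subtree[node] = merged
            outside = {sp: total[sp] - merged.get(sp, 0) for sp in total
                       if total[sp] - merged.get(sp, 0) > 0}
            if not outside:
                continue
            for ci in range(len(child_counts)):
                for cj in range(ci + 1, len(child_counts)):
                    for X, nx in child_counts[ci].items():
                        for Y, ny in child_counts[cj].items():
                            if X == Y:
                                continue
                            m = nx * ny
                            for Z, nz in outside.items():
                                if Z == X or Z == Y:
                                    continue
                                table.add(frozenset((X, Y, Z)),
                                          frozenset((X, Y)), m * nz)
    return table


def _internal_edges(tree: dendropy.Tree) -> list:
    return [e for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node and not e.head_node.is_leaf()]


def _triple_paths(tree: dendropy.Tree, triples) -> tuple[list, np.ndarray, dict]:
    """Edge-incidence matrix of triplet internal paths in a rooted tree."""
    edges = _internal_edges(tree)
    eidx = {id(e): k for k, e in enumerate(edges)}
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    rows = []
    info = []
    for triple in triples:
        trip = sorted(triple)
        pair = treeutils.induced_triplet(tree, *trip)
        if pair is None:
            raise ValueError("species topology must be binary")
        # ancestors of the cherry mrca up to the three-way mrca
        a, b = sorted(pair)
        (c,) = set(trip) - set(pair)

        def mrca(x, y):
            anc_x = []
            node = leaves[x]
            while node is not None:
                anc_x.append(node)
                node = node.parent_node
            anc = set(id(n) for n in anc_x)
            node = leaves[y]
            while id(node) not in anc:
                node = node.parent_node
            return node

        lower = mrca(a, b)
        upper = mrca(a, c)
        row = np.zeros(len(edges))
        node = lower
        while node is not upper:
            if id(node.edge) in eidx:
                row[eidx[id(node.edge)]] = 1.0
            node = node.parent_node
        rows.append(row)
        info.append((frozenset(triple), pair))
    M = np.stack(rows) if rows else np.zeros((0, len(edges)))
    return edges, M, dict(info)


def triplet_pseudo_likelihood(species_topology: dendropy.Tree,
                              counts: TripletCountTable
                              ) -> tuple[dendropy.Tree, float]:
    """MLE internal branch lengths (coalescent units) and pseudo-log-likelihood.

    For each triple with species-tree internal path length T the matching
    topology has probability 1 - (2/3)e^{-T} and each alternative
    (1/3)e^{-T}.  Lengths are maximised jointly (bounded at T_MAX = 10);
    terminal branches are not estimated and are set to a nominal 1.0.
    """
    tip_species = set(treeutils.leaf_labels(species_topology))
    extra = counts.species() - tip_species
    if extra:
        raise ValueError(f"counts reference species not in topology: {sorted(extra)}")
    triples = [t for t in counts.counts if counts.total(t) > 0
               and t <= tip_species]
    work = treeutils.tree_from_newick(
        species_topology.as_string(schema="newick"), rooted=True)
    edges, M, match_pair = _triple_paths(work, triples)
    n_match = np.array([counts.counts[t].get(match_pair[t], 0) for t in triples],
                       dtype=float)
    n_tot = np.array([counts.total(t) for t in triples], dtype=float)

    if not edges:
        return work, 0.0

    log13 = math.log(1.0 / 3.0)

    def neg_loglik(x):
        T = M @ x
        p = 1.0 - (2.0 / 3.0) * np.exp(-T)
        p = np.clip(p, 1e-300, 1.0)
        ll = n_match * np.log(p) + (n_tot - n_match) * (log13 - T)
        return -float(ll.sum())

    def grad(x):
        T = M @ x
        eT = np.exp(-T)
        p = np.clip(1.0 - (2.0 / 3.0) * eT, 1e-300, 1.0)
        dll_dT = n_match * ((2.0 / 3.0) * eT / p) - (n_tot - n_match)
        return -(M.T @ dll_dT)

    x0 = np.full(len(edges), 1.0)
    res = minimize(neg_loglik, x0, jac=grad, method="L-BFGS-B",
                   bounds=[(0.0, T_MAX)] * len(edges),
                   options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500})
    for e, length in zip(edges, res.x):
        e.length = float(length)
    for e in work.preorder_edge_iter():
        if e.head_node.is_leaf():
            e.length = 1.0  # terminal branches are not estimated
    return work, -float(res.fun)


def triplet_search(counts: TripletCountTable,
                   start_topology: dendropy.Tree,
                   n_runs: int = 3, seed: int = 0) -> SpeciesTreeEstimate:
    """NNI hill climbing over rooted topologies on the pseudo-likelihood.

    Run 1 starts from ``start_topology``; later runs perturb the start by two
    random NNI moves.  The best run's tree (with MLE branch lengths) wins.
    """
    rng = np.random.default_rng(seed)

    def climb(tree):
        cur_tree, cur_ll = triplet_pseudo_likelihood(tree, counts)
        while True:
            best = None
            for nb in treeutils.rooted_nni_neighbors(cur_tree):
                t2, ll2 = triplet_pseudo_likelihood(nb, counts)
                if best is None or ll2 > best[1]:
                    best = (t2, ll2)
            if best is not None and best[1] > cur_ll + 1e-10:
                cur_tree, cur_ll = best
            else:
                return cur_tree, cur_ll

    runs = []
    for r in range(n_runs):
        start = start_topology
        if r > 0:
            start = start_topology
            for _ in range(2):
                nbs = treeutils.rooted_nni_neighbors(start)
                if not nbs:
                    break
                start = nbs[int(rng.integers(0, len(nbs)))]
        runs.append(climb(start))
    lls = [ll for _, ll in runs]
    best_tree, best_ll = max(runs, key=lambda x: x[1])
    return SpeciesTreeEstimate(tree=best_tree, method="rooted-triplet",
                               rooted=True, log_pseudo_likelihood=best_ll,
                               per_run_log_likelihoods=lls)


# ---------------------------------------------------------------------------
# quartets

def quartet_tally(gene_trees, taxon_map: dict[str, str]):
    """Counts of resolved cross-species quartet topologies in the gene trees."""
    tally: dict[frozenset, dict[frozenset, int]] = {}
    n_resolved = 0
    for tree in gene_trees:
        if tree is None:
            continue
        labels, D = treeutils.path_edge_counts(tree)
        sp = [taxon_map.get(lbl) for lbl in labels]
        for i, j, k, l in itertools.combinations(range(len(labels)), 4):
            quad = {sp[i], sp[j], sp[k], sp[l]}
            if None in quad or len(quad) != 4:
                continue
            q = treeutils.induced_quartet(D, i, j, k, l)
            if q is None:
                continue
            pairing = frozenset(frozenset(sp[x] for x in part) for part in q)
            key = frozenset(quad)
            tally.setdefault(key, {})
            tally[key][pairing] = tally[key].get(pairing, 0) + 1
            n_resolved += 1
    return tally, n_resolved


def _candidate_pairings(candidate: dendropy.Tree) -> dict:
    labels, D = treeutils.path_edge_counts(candidate)
    out = {}
    for i, j, k, l in itertools.combinations(range(len(labels)), 4):
        q = treeutils.induced_quartet(D, i, j, k, l)
        key = frozenset({labels[i], labels[j], labels[k], labels[l]})
        if q is None:
            out[key] = None
        else:
            out[key] = frozenset(frozenset(labels[x] for x in part)
                                 for part in q)
    return out


def quartet_score(candidate: dendropy.Tree, gene_trees,
                  taxon_map: dict[str, str]) -> dict:
    """Share of resolved gene-tree quartets induced by the candidate tree.

    Brute-force enumeration over 4-tip subsets with four distinct species;
    ``normalised`` divides by the number of resolved quartets examined.
    """
    cand_species = set(treeutils.leaf_labels(candidate))
    missing = set(taxon_map.values()) - cand_species
    if missing:
        raise ValueError(f"candidate lacks species: {sorted(missing)}")
    tally, n_resolved = quartet_tally(gene_trees, taxon_map)
    return score_from_tally(candidate, tally, n_resolved)


def score_from_tally(candidate: dendropy.Tree, tally, n_resolved: int) -> dict:
    pairings = _candidate_pairings(candidate)
    raw = 0
    for key, counts in tally.items():
        cp = pairings.get(key)
        if cp is not None:
            raw += counts.get(cp, 0)
    return {"raw": raw,
            "normalised": (raw / n_resolved) if n_resolved else float("nan"),
            "n_resolved_examined": n_resolved}


def exhaustive_quartet_search(species: list[str], gene_trees,
                              taxon_map: dict[str, str],
                              max_species: int = 9) -> SpeciesTreeEstimate:
    """Best-scoring unrooted species tree by exhaustive enumeration.

    Intended for small species counts; the number of topologies grows as
    (2n-5)!!, so calls beyond ``max_species`` species are refused.
    """
    if len(species) > max_species:
        raise ValueError("exhaustive search limited to "
                         f"{max_species} species (got {len(species)})")
    tally, n_resolved = quartet_tally(gene_trees, taxon_map)
    best = None
    for cand in treeutils.enumerate_unrooted_topologies(sorted(species)):
        sc = score_from_tally(cand, tally, n_resolved)
        if best is None or sc["raw"] > best[1]["raw"]:
            best = (cand, sc)
    tree, sc = best
    return SpeciesTreeEstimate(tree=tree, method="quartet-score", rooted=False,
                               quartet_score_raw=sc["raw"],
                               quartet_score_normalised=sc["normalised"])


# ---------------------------------------------------------------------------
# multi-locus bootstrap

def mlbs_replicates(pools: dict, config: MLBSConfig):
    """MLBS input sets: loci drawn with replacement, pool trees without.

    ``pools`` maps locus id -> list of B bootstrap trees.  Each replicate
    draws L = len(pools) loci with replacement; every draw consumes a
    distinct (seeded, shuffled) tree from that locus's pool.  Drawing a locus
    more than B times in one replicate is a hard error (increase B).
    """
    rng = np.random.default_rng(config.seed)
    locus_ids = sorted(pools)
    L = len(locus_ids)
    replicates = []
    for _ in range(config.n_replicates):
        order = {lid: rng.permutation(len(pools[lid])) for lid in locus_ids}
        used = {lid: 0 for lid in locus_ids}
        draws = rng.integers(0, L, size=L)
        trees = []
        for d in draws:
            lid = locus_ids[int(d)]
            if used[lid] >= len(pools[lid]):
                raise RuntimeError(
                    f"bootstrap pool exhausted for locus {lid}: drawn more than "
                    f"{len(pools[lid])} times in one replicate; increase B")
            trees.append(pools[lid][int(order[lid][used[lid]])])
            used[lid] += 1
        replicates.append(trees)
    return replicates


def summarize_support(point_estimate: SpeciesTreeEstimate,
                      bootstrap_trees: list) -> SpeciesTreeEstimate:
    """Percentage of bootstrap trees containing each internal branch.

    Rooted estimates are compared on clades, unrooted on bipartitions;
    supports land on internal node labels of (a copy of) the point estimate.
    """
    est_tree = treeutils.tree_from_newick(
        point_estimate.tree.as_string(schema="newick"),
        rooted=point_estimate.rooted)
    tips = set(treeutils.leaf_labels(est_tree))
    for bt in bootstrap_trees:
        t = bt.tree if isinstance(bt, SpeciesTreeEstimate) else bt
        if set(treeutils.leaf_labels(t)) != tips:
            raise ValueError("bootstrap trees must cover the same species")

    def keys_of(tree):
        if point_estimate.rooted:
            return treeutils.clade_set(tree)
        return treeutils.bipartition_set(tree)

    boot_keys = []
    for bt in bootstrap_trees:
        t = bt.tree if isinstance(bt, SpeciesTreeEstimate) else bt
        boot_keys.append(keys_of(t))
    supports = {}
    n = len(boot_keys)
    for node in est_tree.preorder_internal_node_iter():
        if node is est_tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if point_estimate.rooted:
            key = below
            if len(below) < 2:
                continue
        else:
            other = frozenset(tips) - below
            if len(below) < 2 or len(other) < 2:
                continue
            key = frozenset({below, other})
        pct = 100.0 * sum(1 for ks in boot_keys if key in ks) / n if n else 0.0
        node.label = f"{pct:.0f}"
        supports[below] = pct
    out = SpeciesTreeEstimate(
        tree=est_tree, method=point_estimate.method,
        rooted=point_estimate.rooted,
        log_pseudo_likelihood=point_estimate.log_pseudo_likelihood,
        quartet_score_raw=point_estimate.quartet_score_raw,
        quartet_score_normalised=point_estimate.quartet_score_normalised,
        per_run_log_likelihoods=list(point_estimate.per_run_log_likelihoods),
        supports=supports)
    return out
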