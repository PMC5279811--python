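"""Per-locus alignments, distance-based gene trees, and outgroup rooting.

Gene trees here are K80 + neighbour-joining topologies (summary species-tree
methods consume topologies only); near-zero internal branches are collapsed
into polytomies, which the downstream summaries tolerate.  An import path for
externally estimated trees (a directory of Newick files) is provided so
likelihood-based gene trees can be substituted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import dendropy
import numpy as np

from . import snp as snpmod
from . import treeutils
from .assembly import Locus, LocusSet

__all__ = ["OutgroupHierarchy", "locus_alignment", "export_alignments",
           "estimate_gene_tree", "bootstrap_gene_trees", "root_or_discard",
           "load_gene_trees"]

POLYTOMY_EPS = 1e-8


@dataclass
class OutgroupHierarchy:
    """Ordered outgroup preference: earlier groups take priority.

    Each group is a set of taxon names; any present sample of the
    highest-priority represented group roots the tree, and trees containing
    no member of any group are discarded.
    """

    groups: list[frozenset]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("hierarchy must be non-empty")
        self.groups = [frozenset(g) for g in self.groups]
        seen: set = set()
        for g in self.groups:
            if g & seen:
                raise ValueError("hierarchy groups must be disjoint")
            seen |= g

    @classmethod
    def from_ranks(cls, outgroup_ranks: dict[str, int]) -> "OutgroupHierarchy":
        by_rank: dict[int, set] = {}
        for taxon, rank in outgroup_ranks.items():
            by_rank.setdefault(int(rank), set()).add(taxon)
        return cls([frozenset(by_rank[r]) for r in sorted(by_rank)])


def locus_alignment(locus: Locus) -> dict[str, str]:
    """Per-sample IUPAC consensus rows, padded with N to the locus length."""
    out = {}
    for s, sl in locus.samples.items():
        seq = sl.consensus[:locus.length]
        out[s] = seq + "N" * (locus.length - len(seq))
    return out


def export_alignments(locus_sets: list[LocusSet], out_dir: str
                      ) -> tuple[list[str], str, str]:
    """Write one relaxed-PHYLIP per locus plus a concatenated alignment.

    The combined file spans the union of samples; missing data are N.  A
    partition table maps each locus to its 1-based column range.  Locus names
    are ``{provenance}_{id}``; duplicates raise.
    """
    os.makedirs(out_dir, exist_ok=True)
    seen: set[str] = set()
    samples = sorted({s for ls in locus_sets for s in ls.samples})
    per_locus_paths = []
    blocks: list[tuple[str, dict[str, str], int]] = []
    for ls in locus_sets:
        for locus in ls.loci:
            name = f"{ls.provenance}_{locus.id}"
            if name in seen:
                raise ValueError(f"locus name collision: {name}")
            seen.add(name)
            aln = locus_alignment(locus)
            path = os.path.join(out_dir, f"{name}.phy")
            _write_phylip(path, aln)
            per_locus_paths.append(path)
            blocks.append((name, aln, locus.length))
    width = sum(b[2] for b in blocks)
    combined = {s: [] for s in samples}
    partitions = []
    start = 1
    for name, aln, L in blocks:
        for s in samples:
            combined[s].append(aln.get(s, "N" * L))
        partitions.append((name, start, start + L - 1))
        start += L
    combined_path = os.path.join(out_dir, "combined.phy")
    _write_phylip(combined_path, {s: "".join(v) for s, v in combined.items()})
    part_path = os.path.join(out_dir, "partitions.tsv")
    with open(part_path, "w") as fh:
        fh.write("locus\tstart\tend\n")
        for name, a, b in partitions:
            fh.write(f"{name}\t{a}\t{b}\n")
    assert width == start - 1
    return per_locus_paths, combined_path, part_path


def _write_phylip(path: str, alignment: dict[str, str]) -> None:
    names = list(alignment)
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    L = len(next(iter(alignment.values()))) if alignment else 0
    with open(path, "w") as fh:
        fh.write(f" {len(alignment)} {L}\n")
        for s in names:
            fh.write(f"{s}  {alignment[s]}\n")


def estimate_gene_tree(alignment: dict[str, str], eps: float = POLYTOMY_EPS):
    """Unrooted K80 + NJ tree for one locus; None when fewer than 3 usable rows.

    Samples without defined distances to the rest (no overlapping unambiguous
    sites, or saturation) are dropped from this locus's tree.
    """
    usable = {s: seq for s, seq in alignment.items()}
    while len(usable) >= 3:
        dm = snpmod.k80_distances(usable)
        nan_counts = np.isnan(dm.values).sum(axis=1)
        if nan_counts.max() == 0:
            break
        worst = int(np.argmax(nan_counts))
        usable.pop(dm.labels[worst])
    if len(usable) < 3:
        return None
    dm = snpmod.k80_distances(usable)
    if np.isnan(dm.values).any():
        return None
    tree = snpmod.nj_tree(dm)
    treeutils.collapse_short_branches(tree, eps)
    return tree


def bootstrap_gene_trees(alignment: dict[str, str], B: int = 150,
                         seed: int = 0) -> list:
    """B site-resampled NJ trees (columns drawn with replacement), in order."""
    rng = np.random.default_rng(seed)
    samples = list(alignment)
    arr = np.stack([np.frombuffer(alignment[s].encode(), dtype=np.uint8)
                    for s in samples])
    L = arr.shape[1]
    trees = []
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        res = arr[:, cols]
        aln = {s: res[i].tobytes().decode() for i, s in enumerate(samples)}
        trees.append(estimate_gene_tree(aln))
    return trees


def _canonical_edges(tree: dendropy.Tree) -> list:
    return [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]


def root_or_discard(tree: dendropy.Tree, hierarchy: OutgroupHierarchy,
                    taxon_map: dict[str, str]):
    """Root on the best available outgroup, or discard the tree.

    The hierarchy is scanned in priority order for a represented group; the
    tree is rooted on that group's pendant edge (single tip), on the edge
    making it monophyletic when one exists, else on the edge maximising the
    group's bipartition purity (Jaccard overlap; ties to the first edge in
    preorder).  Returns (rooted tree, None) or (None, reason).
    """
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    chosen: frozenset | None = None
    for group in hierarchy.groups:
        present = {t for t in tips if taxon_map.get(t) in group}
        if present:
            chosen = frozenset(present)
            break
    if chosen is None:
        return None, "no outgroup present"
    if chosen == tips:
        return None, "no ingroup tips"

    work = treeutils.tree_from_newick(
        tree.as_string(schema="newick"), rooted=False)
    work_tips = {lf.taxon.label: lf for lf in work.leaf_node_iter()}
    if len(chosen) == 1:
        (tip,) = chosen
        edge = work_tips[tip].edge
    else:
        edge = None
        best_score = -1.0
        for cand in _canonical_edges(work):
            below = frozenset(lf.taxon.label for lf in cand.head_node.leaf_iter())
            for side in (below, frozenset(tips) - below):
                score = len(side & chosen) / len(side | chosen)
                if score > best_score + 1e-12:
                    best_score = score
                    edge = cand
        if edge is None:
            return None, "no internal structure"
    half = (edge.length or 0.0) / 2.0
    work.reroot_at_edge(edge, length1=half, length2=half)
    work.is_rooted = True
    return work, None


def load_gene_trees(path: str) -> list[dendropy.Tree]:
    """Import externally estimated gene trees (file or directory of Newick)."""
    files = [path]
    if os.path.isdir(path):
        files = sorted(os.path.join(path, f) for f in os.listdir(path)
                       if f.endswith((".nwk", ".tre", ".newick", ".tree")))
    trees: list[dendropy.Tree] = []
    for f in files:
        trees.extend(dendropy.TreeList.get(path=f, schema="newick",
                                           preserve_underscores=True))
    return trees
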