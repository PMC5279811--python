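"""End-to-end orchestration: reads -> loci -> gene trees -> species trees."""

from __future__ import annotations

import dendropy

from . import assembly, genetrees, readprep, simulate, snp, speciestree
from .assembly import AssemblyParams, LocusSet

__all__ = ["prepare_read_sets", "assemble_read_sets", "locus_tree_set",
           "rooted_tree_pools", "summary_species_trees", "haplotype_taxon_map"]


def prepare_read_sets(reads_by_sample: dict[str, list],
                      min_overlap: int = readprep.DEFAULT_MIN_OVERLAP
                      ) -> tuple[dict, dict, dict]:
    """Filter and merge every sample's pairs.

    Returns (merged, unmerged_joined, stats): both read dicts map sample ->
    [(seq, qual)]; unmerged pairs are joined read1 + revcomp(read2) for the
    paired-GBS assembly path.
    """
    merged_out: dict[str, list] = {}
    unmerged_out: dict[str, list] = {}
    n_pairs = n_merged = 0
    for s, rows in sorted(reads_by_sample.items()):
        pairs = [readprep.ReadPair(*r) if not isinstance(r, readprep.ReadPair)
                 else r for r in rows]
        pairs = readprep.filter_reads(pairs)
        merged, unmerged = readprep.merge_pairs(pairs, min_overlap=min_overlap)
        merged_out[s] = [(m.seq, m.qual) for m in merged]
        unmerged_out[s] = assembly.join_unmerged(unmerged)
        n_pairs += len(pairs)
        n_merged += len(merged)
    stats = {"n_pairs": n_pairs, "n_merged": n_merged,
             "merged_fraction": (n_merged / n_pairs) if n_pairs else 0.0}
    return merged_out, unmerged_out, stats


def assemble_read_sets(merged: dict, unmerged: dict,
                       params_merged: AssemblyParams,
                       params_unmerged: AssemblyParams | None = None
                       ) -> list[LocusSet]:
    """Assemble the merged and unmerged read sets separately."""
    out = [assembly.assemble(merged, params_merged, provenance="merged")]
    if any(len(v) for v in unmerged.values()):
        out.append(assembly.assemble(unmerged,
                                     params_unmerged or params_merged,
                                     provenance="unmerged"))
    return out


def locus_tree_set(locus_sets: list[LocusSet], B: int | None = None,
                   seed: int = 0) -> tuple[dict, dict]:
    """Per-locus NJ gene trees (and optional bootstrap pools).

    Returns (trees, pools) keyed by locus name; loci yielding no tree (fewer
    than three usable samples) are absent.
    """
    trees: dict[str, dendropy.Tree] = {}
    pools: dict[str, list] = {}
    for ls in locus_sets:
        for locus in ls.loci:
            name = f"{ls.provenance}_{locus.id}"
            aln = genetrees.locus_alignment(locus)
            tree = genetrees.estimate_gene_tree(aln)
            if tree is None:
                continue
            trees[name] = tree
            if B:
                import zlib
                locus_seed = seed + zlib.crc32(name.encode()) % (2 ** 20)
                boots = [t for t in genetrees.bootstrap_gene_trees(
                    aln, B=B, seed=locus_seed) if t is not None]
                if boots:
                    pools[name] = boots
    return trees, pools


def rooted_tree_pools(trees: dict, pools: dict,
                      hierarchy: genetrees.OutgroupHierarchy,
                      taxon_map: dict[str, str]) -> tuple[list, dict, int]:
    """Root every tree (and its pool) on the outgroup hierarchy.

    Loci without any outgroup are discarded; bootstrap pools keep only
    rootable members.  Returns (rooted point trees, rooted pools, n_discarded).
    """
    rooted = []
    rooted_pools = {}
    discarded = 0
    for name in sorted(trees):
        rt, _ = genetrees.root_or_discard(trees[name], hierarchy, taxon_map)
        if rt is None:
            discarded += 1
            continue
        rooted.append(rt)
        if name in pools:
            rp = []
            for bt in pools[name]:
                rbt, _ = genetrees.root_or_discard(bt, hierarchy, taxon_map)
                if rbt is not None:
                    rp.append(rbt)
            if rp:
                rooted_pools[name] = rp
    return rooted, rooted_pools, discarded


def haplotype_taxon_map(model: simulate.SpeciesTreeModel) -> dict[str, str]:
    """Map every haplotype tip label of a truth set to its species."""
    out = {}
    for s, sp in model.samples.items():
        for i in range(model.ploidy[s]):
            out[f"{s}_h{i}"] = sp
    return out


def summary_species_trees(rooted_trees: list, taxon_map: dict[str, str],
                          seed: int = 0, quartet_exhaustive: bool = True
                          ) -> dict[str, speciestree.SpeciesTreeEstimate]:
    """The three summary estimates from one set of rooted gene trees."""
    species = sorted(set(taxon_map.values()))
    out: dict[str, speciestree.SpeciesTreeEstimate] = {}
    D = speciestree.average_internode_matrix(rooted_trees, taxon_map)
    out["distance"] = speciestree.distance_species_tree(D)

    counts = speciestree.triplet_counts(rooted_trees, taxon_map)
    start = _rooted_start(out["distance"].tree, species)
    out["triplet"] = speciestree.triplet_search(counts, start, seed=seed)

    if quartet_exhaustive and len(species) <= 9:
        out["quartet"] = speciestree.exhaustive_quartet_search(
            species, rooted_trees, taxon_map)
    return out


def _rooted_start(unrooted: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Root an unrooted topology arbitrarily on its first-listed tip."""
    from . import treeutils
    t = treeutils.tree_from_newick(unrooted.as_string(schema="newick"),
                                   rooted=False)
    tip = next(lf for lf in t.leaf_node_iter()
               if lf.taxon.label == sorted(species)[0])
    t.reroot_at_edge(tip.edge)
    t.is_rooted = True
    return t
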