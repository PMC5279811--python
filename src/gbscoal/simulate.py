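"""Synthetic paired-end GBS data with known truth.

The generator emulates the statistical features a de-novo GBS assembly has to
cope with: gene-tree/species-tree discordance from incomplete lineage sorting
(multispecies coalescent), K80 sequence evolution, restriction-site loss
(hereditary allelic dropout), interchangeable read orientations, short
fragments producing overlapping read pairs, uneven negative-binomial depth,
sequencing error, mixed diploid/tetraploid samples and technical replicates.

Tip naming: every chromosome copy of sample ``S`` is a haplotype tip
``S_h0 .. S_h{ploidy-1}`` in the per-locus gene trees.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import treeutils

__all__ = [
    "SpeciesTreeModel",
    "SimulationConfig",
    "TruthSet",
    "simulate_gene_trees",
    "evolve_sequences",
    "generate_reads",
    "make_replicates",
    "simulate_dataset",
    "write_dataset",
    "haplotype_sample",
    "revcomp",
]

_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)  # transitions: A<->G, C<->T
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMP[arr][::-1].tobytes().decode()


def haplotype_sample(tip_label: str) -> str:
    """Sample id of a haplotype tip label (``S01_h1`` -> ``S01``)."""
    return tip_label.rsplit("_h", 1)[0]


@dataclass
class SpeciesTreeModel:
    """Rooted binary species tree with branch lengths in coalescent units.

    ``samples`` maps sample id -> species; ``ploidy`` maps sample id -> 2 or 4
    (tetraploids are treated as autopolyploids: one coalescing lineage per
    chromosome copy).  ``outgroup_ranks`` assigns optional rooting priorities
    to species (1 = most preferred).  ``populations`` maps sample -> locality
    label; it defaults to the species name.
    """

    tree: dendropy.Tree
    samples: dict[str, str]
    ploidy: dict[str, int] = field(default_factory=dict)
    outgroup_ranks: dict[str, int] = field(default_factory=dict)
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        species = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 0.0
                if node.edge.length < 0:
                    raise ValueError("negative branch length in species tree")
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise ValueError("species tree must be binary")
        for s, sp in self.samples.items():
            if sp not in species:
                raise ValueError(f"sample {s} maps to unknown species {sp}")
        for s in self.samples:
            self.ploidy.setdefault(s, 2)
            if self.ploidy[s] not in (2, 4):
                raise ValueError("ploidy must be 2 or 4")
            self.populations.setdefault(s, self.samples[s])

    @classmethod
    def from_newick(cls, newick: str, samples_per_species: int | dict[str, int] = 1,
                    ploidy: int | dict[str, int] = 2,
                    outgroup_ranks: dict[str, int] | None = None) -> "SpeciesTreeModel":
        tree = treeutils.tree_from_newick(newick, rooted=True)
        species = [lf.taxon.label for lf in tree.leaf_node_iter()]
        samples: dict[str, str] = {}
        for sp in species:
            k = samples_per_species if isinstance(samples_per_species, int) \
                else samples_per_species.get(sp, 1)
            for i in range(k):
                samples[f"{sp}_{i}" if k > 1 else sp + "_0"] = sp
        pl = {s: (ploidy if isinstance(ploidy, int) else ploidy.get(s, 2))
              for s in samples}
        return cls(tree=tree, samples=samples, ploidy=pl,
                   outgroup_ranks=dict(outgroup_ranks or {}))

    @property
    def species(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def samples_of(self, species: str) -> list[str]:
        return sorted(s for s, sp in self.samples.items() if sp == species)

    def taxon_map(self) -> dict[str, str]:
        return dict(self.samples)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror a realistic paired-end GBS run.

    ``mut_rate`` converts coalescent-unit branch lengths into expected
    substitutions per site.  ``p_short`` is the probability that a fragment is
    short enough for its reads to overlap by at least ``min_overlap`` (the
    observed merged-pair fraction in real libraries is about 0.56, the
    default).  ``dropout_prob`` is the per-gene-tree-edge probability that a
    restriction site is lost; loss is hereditary.
    """

    n_loci: int = 200
    frag_min: int = 100
    frag_mode: int = 160
    frag_max: int = 450
    read_len: int = 100
    min_overlap: int = 16
    mut_rate: float = 0.01
    kappa: float = 2.0
    seq_error: float = 0.001
    depth_mean: float = 12.0
    depth_dispersion: float = 0.5
    p_short: float = 0.56
    p_flip: float = 0.5
    dropout_prob: float = 0.0
    replicates: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("seq_error", "p_short", "p_flip", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_loci < 1:
            raise ValueError("n_loci >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not self.frag_min <= self.frag_mode <= self.frag_max:
            raise ValueError("fragment distribution needs min <= mode <= max")


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    model: SpeciesTreeModel
    config: SimulationConfig
    gene_trees: list = field(default_factory=list)
    haplotypes: list = field(default_factory=list)   # per locus: tip -> seq
    dropout: list = field(default_factory=list)      # per locus: set of dropped tips
    dropout_clades: list = field(default_factory=list)  # per locus: mutated-edge leaf sets
    locus_lengths: list = field(default_factory=list)

    def tip_labels(self) -> list[str]:
        return [f"{s}_h{i}" for s in sorted(self.model.samples)
                for i in range(self.model.ploidy[s])]

    def sample_dropped(self, locus: int, sample: str) -> bool:
        tips = [f"{sample}_h{i}" for i in range(self.model.ploidy[sample])]
        return all(t in self.dropout[locus] for t in tips)

    def sample_alleles(self, locus: int, sample: str) -> list[str]:
        """Surviving (non-dropped) haplotype sequences of a sample at a locus."""
        out = []
        for i in range(self.model.ploidy[sample]):
            tip = f"{sample}_h{i}"
            if tip not in self.dropout[locus]:
                out.append(self.haplotypes[locus][tip])
        return out

    def genotype_table(self):
        """Long-format table: locus, sample, distinct allele sequences."""
        import pandas as pd
        rows = []
        for loc in range(len(self.haplotypes)):
            for s in sorted(self.model.samples):
                alleles = self.sample_alleles(loc, s)
                rows.append({"locus": loc, "sample": s,
                             "alleles": "/".join(sorted(set(alleles)))})
        return pd.DataFrame(rows)


def _node_ages(tree: dendropy.Tree) -> dict:
    ages = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            ages[node] = 0.0
        else:
            ages[node] = max(ages[c] + (c.edge.length or 0.0) for c in kids)
    return ages


def _simulate_one_gene_tree(model: SpeciesTreeModel, rng: np.random.Generator,
                            namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    ages = _node_ages(model.tree)
    active: dict = {}

    class _Lin:
        __slots__ = ("node", "height")

        def __init__(self, node, height):
            self.node = node
            self.height = height

    def coalesce(lineages: list, t0: float, t1: float) -> list:
        t = t0
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            w = rng.exponential(2.0 / (k * (k - 1)))
            if t + w > t1:
                break
            t += w
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a = lineages.pop(j)
            b = lineages.pop(i)
            parent = dendropy.Node()
            for lin in (a, b):
                lin.node.edge.length = t - lin.height
                parent.add_child(lin.node)
            lineages.append(_Lin(parent, t))
        return lineages

    for node in model.tree.postorder_node_iter():
        if node.is_leaf():
            sp = node.taxon.label
            lins = []
            for s in model.samples_of(sp):
                for i in range(model.ploidy[s]):
                    tip = dendropy.Node()
                    tip.taxon = namespace.require_taxon(label=f"{s}_h{i}")
                    lins.append(_Lin(tip, ages[node]))
        else:
            lins = []
            for c in node.child_nodes():
                lins.extend(active.pop(c))
        if node is model.tree.seed_node:
            lins = coalesce(lins, ages[node], np.inf)
        else:
            top = ages[node] + node.edge.length
            lins = coalesce(lins, ages[node], top)
        active[node] = lins

    (root_lin,) = active[model.tree.seed_node]
    gt = dendropy.Tree(taxon_namespace=namespace)
    gt.seed_node = root_lin.node
    gt.is_rooted = True
    return gt


def simulate_gene_trees(model: SpeciesTreeModel, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> TruthSet:
    """One rooted coalescent gene tree per locus, within the species tree.

    Within every species-tree branch, ``k`` lineages coalesce as a pure-death
    process with Exponential(k(k-1)/2) waiting times (coalescent units); all
    remaining lineages coalesce above the root.
    """
    rng = rng or np.random.default_rng(config.seed)
    namespace = dendropy.TaxonNamespace()
    truth = TruthSet(model=model, config=config)
    for _ in range(config.n_loci):
        truth.gene_trees.append(_simulate_one_gene_tree(model, rng, namespace))
    return truth


def _k80_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """K80 substitution probabilities for branch length d (subs/site).

    Base order A,G,C,T; transitions are A<->G and C<->T.
    """
    bt = d / (kappa + 2.0)       # beta * t
    at = kappa * bt              # alpha * t
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 1] = P[1, 0] = P[2, 3] = P[3, 2] = p_ti
    return P


def _draw_fragment_length(config: SimulationConfig, rng) -> int:
    boundary = 2 * config.read_len - config.min_overlap  # longest mergeable
    boundary = min(boundary, config.frag_max)
    if rng.random() < config.p_short and boundary > config.frag_min:
        mode = min(max(config.frag_mode, config.frag_min), boundary)
        return int(round(rng.triangular(config.frag_min, mode, boundary)))
    lo = min(boundary + 1, config.frag_max)
    if lo >= config.frag_max:
        return config.frag_max
    mode = min(max(config.frag_mode, lo), config.frag_max)
    return int(round(rng.triangular(lo, mode, config.frag_max)))


def evolve_sequences(truth: TruthSet, rng: np.random.Generator | None = None) -> TruthSet:
    """Fill per-tip haplotype sequences by K80 evolution along each gene tree."""
    config = truth.config
    rng = rng or np.random.default_rng(config.seed + 1)
    if config.kappa <= 0:
        raise ValueError("kappa must be positive")
    truth.haplotypes = []
    truth.locus_lengths = []
    truth.dropout = []
    truth.dropout_clades = []
    for gt in truth.gene_trees:
        L = _draw_fragment_length(config, rng)
        truth.locus_lengths.append(L)
        seqs: dict[str, str] = {}
        dropped: set[str] = set()
        root_state = rng.integers(0, 4, size=L)
        states = {id(gt.seed_node): root_state}
        drop_state = {id(gt.seed_node): False}
        mutated_clades: list[frozenset] = []
        for node in gt.preorder_node_iter():
            if node is gt.seed_node:
                continue
            parent_state = states[id(node.parent_node)]
            d = (node.edge.length or 0.0) * config.mut_rate
            if d <= 0:
                child_state = parent_state
            else:
                P = _k80_transition_matrix(d, config.kappa)
                cum = P.cumsum(axis=1)
                r = rng.random(L)
                child_state = (r[:, None] > cum[parent_state]).sum(axis=1)
            states[id(node)] = child_state
            mutated_here = (config.dropout_prob > 0
                            and rng.random() < config.dropout_prob)
            if mutated_here and not drop_state[id(node.parent_node)]:
                mutated_clades.append(frozenset(
                    lf.taxon.label for lf in node.leaf_iter()))
            lost = drop_state[id(node.parent_node)] or mutated_here
            drop_state[id(node)] = lost
            if node.is_leaf():
                seqs[node.taxon.label] = _BASES[child_state].tobytes().decode()
                if lost:
                    dropped.add(node.taxon.label)
        truth.haplotypes.append(seqs)
        truth.dropout.append(dropped)
        truth.dropout_clades.append(mutated_clades)
    return truth


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"AGCT"):
    _CODE[_b] = _i


def _error_batch(seq: str, depth: int, rng, err: float) -> list[tuple[str, str]]:
    """``depth`` copies of ``seq`` with per-base errors and Phred-33 qualities."""
    L = len(seq)
    base_qual = "I" * L  # Q40 baseline
    if err <= 0:
        return [(seq, base_qual)] * depth
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    M = np.tile(codes, (depth, 1))
    mask = rng.random((depth, L)) < err
    n_hits = int(mask.sum())
    out: list[tuple[str, str]] = []
    if n_hits:
        M[mask] = (M[mask] + rng.integers(1, 4, size=n_hits)) % 4
        Q = np.full((depth, L), 33 + 40, dtype=np.uint8)
        Q[mask] = 33 + rng.integers(5, 21, size=n_hits)
    seq_rows = _BASES[M]
    for r in range(depth):
        if mask[r].any():
            out.append((seq_rows[r].tobytes().decode(),
                        Q[r].tobytes().decode()))
        else:
            out.append((seq, base_qual))
    return out


def _reads_for_samples(truth: TruthSet, samples: list[str], rng,
                       id_suffix: str = "") -> dict[str, list]:
    """Paired reads per sample: list of (id, seq1, qual1, seq2, qual2)."""
    config = truth.config
    k = config.depth_dispersion
    m = config.depth_mean
    p_nb = k / (k + m)
    out: dict[str, list] = {s: [] for s in samples}
    for loc in range(len(truth.haplotypes)):
        for s in samples:
            for h in range(truth.model.ploidy[s]):
                tip = f"{s}_h{h}"
                if tip in truth.dropout[loc]:
                    continue
                frag = truth.haplotypes[loc][tip]
                depth = int(rng.negative_binomial(k, p_nb))
                if depth == 0:
                    continue
                fwd = frag[:config.read_len]
                rev = revcomp(frag)[:config.read_len]
                flips = rng.random(depth) < config.p_flip
                mates1 = _error_batch(fwd, depth, rng, config.seq_error)
                mates2 = _error_batch(rev, depth, rng, config.seq_error)
                for r in range(depth):
                    s1, q1 = mates1[r]
                    s2, q2 = mates2[r]
                    if flips[r]:
                        s1, q1, s2, q2 = s2, q2, s1, q1
                    rid = f"{s}{id_suffix}:L{loc}:h{h}:{r}"
                    out[s].append((rid, s1, q1, s2, q2))
    return out


def generate_reads(truth: TruthSet, rng: np.random.Generator | None = None) -> dict[str, list]:
    """Paired-end reads for every sample in the model.

    Per (sample, locus, chromosome copy): depth is negative-binomial per
    allele; dropped haplotypes emit nothing; each fragment emits one read pair
    per depth unit, flipped end-for-end with probability ``p_flip``;
    sequencing errors get Phred-consistent lowered qualities.
    """
    rng = rng or np.random.default_rng(truth.config.seed + 2)
    return _reads_for_samples(truth, sorted(truth.model.samples), rng)


def make_replicates(sample_ids: list[str], truth: TruthSet,
                    rng: np.random.Generator | None = None) -> dict[str, list]:
    """Technical replicates: same haplotypes and dropout, fresh depth/errors.

    Returns reads keyed by replicate id ``{sample}.rep``.
    """
    rng = rng or np.random.default_rng(truth.config.seed + 3)
    for s in sample_ids:
        if s not in truth.model.samples:
            raise KeyError(f"unknown sample id {s}")
    fresh = _reads_for_samples(truth, list(sample_ids), rng, id_suffix=".rep")
    return {f"{s}.rep": fresh[s] for s in sample_ids}


def simulate_dataset(model: SpeciesTreeModel, config: SimulationConfig):
    """Full generation: gene trees, haplotypes, reads and replicates.

    Returns ``(truth, reads_by_sample)`` where replicate samples are named
    ``{sample}.rep``.
    """
    rng = np.random.default_rng(config.seed)
    truth = simulate_gene_trees(model, config, rng)
    evolve_sequences(truth, rng)
    reads = _reads_for_samples(truth, sorted(model.samples), rng)
    if config.replicates:
        reads.update(make_replicates(list(config.replicates), truth, rng))
    return truth, reads


def sample_sheet(model: SpeciesTreeModel, config: SimulationConfig):
    """Sample sheet rows (one per physical library, replicates included)."""
    import pandas as pd
    rows = []
    for s in sorted(model.samples):
        rows.append({"sample": s, "population": model.populations[s],
                     "taxon": model.samples[s], "ploidy": model.ploidy[s],
                     "replicate_pair": s if s in config.replicates else "",
                     "outgroup_rank": model.outgroup_ranks.get(model.samples[s], "")})
    for s in config.replicates:
        rows.append({"sample": f"{s}.rep", "population": model.populations[s],
                     "taxon": model.samples[s], "ploidy": model.ploidy[s],
                     "replicate_pair": s,
                     "outgroup_rank": model.outgroup_ranks.get(model.samples[s], "")})
    return pd.DataFrame(rows)


def write_dataset(out_dir: str, model: SpeciesTreeModel, config: SimulationConfig,
                  truth: TruthSet, reads: dict[str, list]) -> None:
    """Write paired FASTQ (Phred+33), sample sheet TSV, truth Newick + genotypes."""
    os.makedirs(out_dir, exist_ok=True)
    for s, pairs in reads.items():
        with open(os.path.join(out_dir, f"{s}_R1.fastq"), "w") as f1, \
                open(os.path.join(out_dir, f"{s}_R2.fastq"), "w") as f2:
            for rid, s1, q1, s2, q2 in pairs:
                f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
    sample_sheet(model, config).to_csv(
        os.path.join(out_dir, "sample_sheet.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "true_gene_trees.nwk"), "w") as fh:
        for gt in truth.gene_trees:
            fh.write(gt.as_string(schema="newick"))
    truth.genotype_table().to_csv(
        os.path.join(out_dir, "true_genotypes.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "sim_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=list)
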