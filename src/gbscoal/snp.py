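"""SNP matrix construction, K80 distances, NJ, PCoA and unlinked-SNP selection.

Heterozygous genotypes enter the matrix as IUPAC ambiguity codes; distance
computation treats ambiguity as missing and deletes sites pairwise, matching
the usual ``dist.dna(..., model="K80", pairwise.deletion=TRUE)`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import IUPAC, LocusSet

__all__ = ["SNPMatrix", "DistanceMatrix", "Ordination",
           "build_and_filter_snp_matrix", "k80_distances", "nj_tree", "pcoa",
           "select_unlinked_snps"]

REV_IUPAC = {v: k for k, v in IUPAC.items()}
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class SNPMatrix:
    """Samples x variable sites; cells are IUPAC codes, '-' for missing."""

    samples: list[str]
    sites: list[tuple]            # (provenance, locus_id, pos_in_locus)
    genotypes: np.ndarray         # uint8, shape (n_samples, n_sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_coverage(self) -> np.ndarray:
        return (self.genotypes != ord("-")).mean(axis=0)

    def column(self, j: int) -> list[frozenset]:
        """Expanded base sets per sample at site j (empty set = missing)."""
        out = []
        for i in range(len(self.samples)):
            ch = chr(self.genotypes[i, j])
            out.append(REV_IUPAC.get(ch, frozenset()) if ch not in "-N"
                       else frozenset())
        return out

    def minor_allele_count(self, j: int) -> int:
        """Number of samples carrying the rarest allele at a biallelic site."""
        col = self.column(j)
        alleles = sorted({b for s in col for b in s})
        if len(alleles) != 2:
            return 0
        carriers = [sum(1 for s in col if a in s) for a in alleles]
        return min(carriers)

    def to_frame(self):
        import pandas as pd
        data = self.genotypes.view("S1").astype(str)
        cols = [f"{p}:{l}:{pos}" for p, l, pos in self.sites]
        return pd.DataFrame(data, index=self.samples, columns=cols)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    model: str = "K80"
    deletion: str = "pairwise"

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


@dataclass
class Ordination:
    coordinates: np.ndarray   # samples x axes, eigenvalue-ordered
    eigenvalues: np.ndarray   # positive eigenvalues, descending
    samples: list[str] = field(default_factory=list)


def _genotype_char(bases: tuple) -> str:
    return IUPAC.get(frozenset(bases), "N")


def build_and_filter_snp_matrix(locus_sets: list[LocusSet],
                                min_site_coverage: float = 0.5,
                                exclude_samples: tuple[str, ...] = ()
                                ) -> SNPMatrix:
    """Combine SNPs from several assemblies and drop low-coverage/invariant sites.

    Sites keep their (read-set provenance, locus, position) identity.  A site
    is removed when genotyped in fewer than ``min_site_coverage`` of the
    samples or when all non-missing genotypes are identical.
    """
    samples = sorted({s for ls in locus_sets for s in ls.samples
                      if s not in exclude_samples})
    if not samples:
        raise ValueError("no samples left after exclusions")
    index = {s: i for i, s in enumerate(samples)}
    sites: list[tuple] = []
    columns: list[np.ndarray] = []
    for ls in locus_sets:
        for locus in ls.loci:
            for pos, genos in sorted(locus.snps.items()):
                col = np.full(len(samples), ord("-"), dtype=np.uint8)
                vals = set()
                n_called = 0
                for s, bases in genos.items():
                    if s in index:
                        ch = _genotype_char(bases)
                        col[index[s]] = ord(ch)
                        vals.add(ch)
                        n_called += 1
                if n_called < min_site_coverage * len(samples):
                    continue
                if len(vals) <= 1:
                    continue
                sites.append((ls.provenance, locus.id, pos))
                columns.append(col)
    geno = np.stack(columns, axis=1) if columns else \
        np.zeros((len(samples), 0), dtype=np.uint8)
    return SNPMatrix(samples=samples, sites=sites, genotypes=geno)


def _sequences_from(matrix_or_sequences) -> tuple[list[str], np.ndarray]:
    if isinstance(matrix_or_sequences, SNPMatrix):
        return matrix_or_sequences.samples, matrix_or_sequences.genotypes
    seqs = dict(matrix_or_sequences)
    labels = list(seqs)
    arr = np.stack([np.frombuffer(seqs[k].encode(), dtype=np.uint8)
                    for k in labels])
    return labels, arr


def k80_distances(matrix_or_sequences, pairwise_deletion: bool = True
                  ) -> DistanceMatrix:
    """Kimura two-parameter distances with pairwise deletion of missing data.

    Per pair, over sites where both samples have an unambiguous base:
    P = transition proportion, Q = transversion proportion,
    d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).  Saturated pairs (non-positive
    argument) and pairs with no overlapping sites are flagged NaN, never 0.
    """
    labels, arr = _sequences_from(matrix_or_sequences)
    n = len(labels)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    if not pairwise_deletion:
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]
    purine = np.isin(arr, np.frombuffer(b"AG", dtype=np.uint8))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            diff = (arr[i] != arr[j]) & both
            ti = diff & (purine[i] == purine[j])
            P = float(ti.sum()) / m
            Q = float(diff.sum() - ti.sum()) / m
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            if a1 <= 0 or a2 <= 0:
                D[i, j] = D[j, i] = np.nan
                continue
            D[i, j] = D[j, i] = -0.5 * np.log(a1 * np.sqrt(a2))
    return DistanceMatrix(labels=labels, values=D)


def nj_tree(D: DistanceMatrix):
    """Neighbour-joining tree (dendropy, unrooted) from a distance matrix."""
    import dendropy
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    bad = D.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")
    vals = np.array(D.values, dtype=float)
    vals = (vals + vals.T) / 2.0  # guard against float asymmetry
    np.fill_diagonal(vals, 0.0)
    sk = skbio_nj(SkbioDM(vals, ids=D.labels))
    newick = str(sk)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             rooting="force-unrooted")
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return tree


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical metric scaling; axes for positive eigenvalues only."""
    import warnings
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.ordination import pcoa as skbio_pcoa

    bad = D.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = skbio_pcoa(SkbioDM(np.asarray(D.values, float), ids=D.labels))
    eig = res.eigvals.values
    pos = eig > 1e-12
    coords = res.samples.values[:, pos]
    eig = eig[pos]
    order = np.argsort(-eig)
    coords, eig = coords[:, order], eig[order]
    if n_axes is not None:
        n_axes = min(n_axes, coords.shape[1])
        coords, eig = coords[:, :n_axes], eig[:n_axes]
    coords = coords - coords.mean(axis=0, keepdims=True)
    return Ordination(coordinates=coords, eigenvalues=eig, samples=list(D.labels))


def select_unlinked_snps(matrix: SNPMatrix, mode: str = "random",
                         taxon_map: dict[str, str] | None = None,
                         require_per_taxon_presence: bool = False,
                         seed: int = 0):
    """One SNP per locus, uniformly or biased against singletons.

    Candidates are biallelic sites.  ``biased`` prefers sites whose rare
    allele occurs in at least two samples (largest minor-allele count first,
    ties random); singletons are a fallback only.  The optional filter demands
    each selected site be genotyped in at least one sample of every taxon.
    Returns ``(SNPMatrix, stats)`` where stats report the singleton fraction.
    """
    if mode not in ("random", "biased"):
        raise ValueError("mode must be 'random' or 'biased'")
    if require_per_taxon_presence and taxon_map is None:
        raise ValueError("taxon_map required for the per-taxon presence filter")
    rng = np.random.default_rng(seed)
    by_locus: dict[tuple, list[int]] = {}
    for j, (prov, locus_id, _pos) in enumerate(matrix.sites):
        by_locus.setdefault((prov, locus_id), []).append(j)
    taxa = sorted(set(taxon_map.values())) if taxon_map else []
    chosen: list[int] = []
    n_singleton = 0
    for key in sorted(by_locus):
        cand = [j for j in by_locus[key] if matrix.minor_allele_count(j) >= 1]
        if not cand:
            continue
        if mode == "random":
            j = int(rng.choice(cand))
        else:
            macs = {j: matrix.minor_allele_count(j) for j in cand}
            multi = [j for j in cand if macs[j] >= 2]
            pool = multi if multi else cand
            best = max(macs[j] for j in pool)
            ties = [j for j in pool if macs[j] == best]
            j = int(rng.choice(ties))
        if require_per_taxon_presence:
            col = matrix.column(j)
            present = {taxon_map[s] for s, bases in zip(matrix.samples, col)
                       if bases and s in taxon_map}
            if any(t not in present for t in taxa):
                continue
        chosen.append(j)
        if matrix.minor_allele_count(j) == 1:
            n_singleton += 1
    sub = SNPMatrix(samples=list(matrix.samples),
                    sites=[matrix.sites[j] for j in chosen],
                    genotypes=matrix.genotypes[:, chosen]
                    if chosen else np.zeros((len(matrix.samples), 0), np.uint8))
    stats = {"n_selected": len(chosen),
             "singleton_fraction": (n_singleton / len(chosen)) if chosen else np.nan}
    return sub, stats
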