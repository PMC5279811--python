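"""De-novo GBS locus assembly with six tunable parameters.

The pipeline per read set (merged or unmerged) is: per-sample quality
filtering of reads (``n``), dereplication in canonical orientation (``mr``),
greedy within-sample clustering at identity ``c``, statistical base calling
and allele phasing (``d``, ``pl``, consensus ``n``), greedy across-sample
clustering at identity ``c`` (reverse-complement aware), then locus-level
filters: shared-heterozygosity paralog filter ``h`` and minimum sample
coverage.

Because GBS adaptors bind either fragment end, a read and its reverse
complement are the same molecule; all clustering therefore scores both
orientations and merges them ("reverse complement clustering").

Comparisons are ungapped (the simulator emits indel-free loci); sequences of
unequal length are compared over the shorter length.  Greedy clustering scans
centroids of the query's own length first (in insertion order), then the
remaining centroids in insertion order, and joins the first with identity at
or above ``c`` — a deterministic rule given the documented input ordering
(descending depth, ties broken lexicographically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.stats import binom

from .simulate import revcomp

__all__ = ["AssemblyParams", "Locus", "LocusSet", "dereplicate",
           "cluster_within_sample", "call_alleles", "cluster_across_samples",
           "filter_loci", "assemble", "assemble_sample", "join_unmerged"]

IUPAC = {frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
         frozenset("T"): "T",
         frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
         frozenset("GT"): "K", frozenset("AT"): "W", frozenset("CG"): "S",
         frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
         frozenset("CGT"): "B", frozenset("ACGT"): "N"}

_LOWQ = 20  # Phred threshold for a "low quality" site (n filter)


@dataclass
class AssemblyParams:
    """The six assembly knobs plus the locus coverage filter.

    d: minimum depth for a statistical base call.
    n: maximum low-quality sites per read / ambiguous sites per consensus.
    c: clustering identity threshold, within and between samples.
    h: maximum individuals sharing a heterozygous site (int count, or a
       proportion of samples < 1, rounded up).
    pl: maximum alleles per locus per sample (ploidy filter).
    mr: minimum reads for a dereplicate within an individual.
    min_sample_coverage: minimum fraction of samples a locus must cover.
    error_rate: sequencing error for the base caller; None = estimate from
       within-cluster mismatches (fallback 0.001).
    """

    d: int = 6
    n: int = 4
    c: float = 0.88
    h: float = 3
    pl: int = 2
    mr: int = 1
    min_sample_coverage: float = 0.25
    error_rate: float | None = None

    def __post_init__(self):
        if not 0 < self.c <= 1:
            raise ValueError("c must be in (0, 1]")
        if self.d < 1 or self.mr < 1:
            raise ValueError("d and mr must be >= 1")
        if self.pl not in (2, 4, 8):
            raise ValueError("pl must be one of 2, 4, 8")
        if not 0 < self.min_sample_coverage <= 1:
            raise ValueError("min_sample_coverage in (0, 1]")

    def h_count(self, n_samples: int) -> int:
        if self.h < 1:
            return math.ceil(self.h * n_samples)
        return int(self.h)


@dataclass
class SampleLocus:
    """One sample's data at one locus."""
    alleles: list[str]
    consensus: str          # IUPAC at heterozygous sites
    depth: int


@dataclass
class Locus:
    id: int
    length: int
    samples: dict[str, SampleLocus] = field(default_factory=dict)
    snps: dict[int, dict[str, tuple]] = field(default_factory=dict)

    @property
    def coverage(self) -> int:
        return len(self.samples)


@dataclass
class LocusSet:
    loci: list[Locus]
    samples: list[str]
    provenance: str = "merged"
    params: AssemblyParams | None = None
    paralog_events: int = 0

    def heterozygosity(self) -> dict[str, float]:
        het = {s: 0 for s in self.samples}
        sites = {s: 0 for s in self.samples}
        for loc in self.loci:
            for s, sl in loc.samples.items():
                sites[s] += len(sl.consensus)
                het[s] += sum(1 for ch in sl.consensus if ch in "RYMKWSVHDB")
        return {s: (het[s] / sites[s] if sites[s] else 0.0) for s in self.samples}

    def n_snps(self) -> int:
        return sum(len(loc.snps) for loc in self.loci)


# ---------------------------------------------------------------------------
# sequence helpers

def _arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    L = min(a.size, b.size)
    if L == 0:
        return 0.0
    return float(np.count_nonzero(a[:L] == b[:L])) / L


def canonical(seq: str) -> tuple[str, bool]:
    """Lexicographic min of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return (seq, False) if seq <= rc else (rc, True)


class _GreedyClusterer:
    """Greedy centroid clustering with reverse-complement awareness.

    Queries must be presented in the documented deterministic order; each
    query joins the first sufficiently similar centroid (own-length centroids
    scanned before the rest), otherwise it seeds a new cluster.
    """

    def __init__(self, c: float):
        self.c = c
        self.centroids: list[np.ndarray] = []
        self.by_length: dict[int, list[int]] = {}

    def assign(self, seq: str) -> tuple[int, bool]:
        """Return (cluster index, flipped?) for a sequence; may open a cluster."""
        q = _arr(seq)
        qr = _arr(revcomp(seq))
        hit = self._scan(q, qr, self.by_length.get(q.size, ()))
        if hit is None:
            rest = [i for L, idxs in self.by_length.items() if L != q.size
                    for i in idxs]
            hit = self._scan(q, qr, sorted(rest))
        if hit is not None:
            return hit
        idx = len(self.centroids)
        self.centroids.append(q)
        self.by_length.setdefault(q.size, []).append(idx)
        return idx, False

    def _scan(self, q, qr, indices):
        for i in indices:
            cen = self.centroids[i]
            fwd = _identity(q, cen)
            rev = _identity(qr, cen)
            if max(fwd, rev) >= self.c:
                return i, rev > fwd
        return None


# ---------------------------------------------------------------------------
# per-sample steps

def quality_trim_reads(reads: Iterable[tuple[str, str]], n: int) -> list[tuple[str, str]]:
    """Drop reads with more than ``n`` low-quality (Q<20) sites."""
    kept = []
    for seq, qual in reads:
        q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
        if int((q < _LOWQ).sum()) <= n:
            kept.append((seq, qual))
    return kept


def dereplicate(reads: Iterable[tuple[str, str] | str], mr: int = 1
                ) -> list[tuple[str, int]]:
    """Collapse identical reads (canonical orientation) into counted uniques.

    Returns (sequence, count) sorted by descending count, ties broken by
    sequence; dereplicates with fewer than ``mr`` reads are discarded.
    """
    counts: dict[str, int] = {}
    for item in reads:
        seq = item if isinstance(item, str) else item[0]
        can, _ = canonical(seq)
        counts[can] = counts.get(can, 0) + 1
    out = [(s, c) for s, c in counts.items() if c >= mr]
    out.sort(key=lambda sc: (-sc[1], sc[0]))
    return out


def cluster_within_sample(dereps: list[tuple[str, int]], c: float
                          ) -> list[list[tuple[str, int, bool]]]:
    """Greedy clustering of one sample's dereplicates at identity ``c``.

    Input must be sorted by descending count (ties lexicographic), the order
    :func:`dereplicate` produces.  Members are (sequence, count, flipped
    relative to centroid).
    """
    clusterer = _GreedyClusterer(c)
    clusters: list[list[tuple[str, int, bool]]] = []
    for seq, count in dereps:
        idx, flipped = clusterer.assign(seq)
        if idx == len(clusters):
            clusters.append([])
        clusters[idx].append((revcomp(seq) if flipped else seq, count, flipped))
    return clusters


def estimate_error_rate(clusters: list[list[tuple[str, int, bool]]],
                        fallback: float = 0.001) -> float:
    """Per-base error from near-identical dereplicates (<=2 mismatches)."""
    errors = 0
    bases = 0
    for members in clusters:
        cen = _arr(members[0][0])
        for seq, count, *_flip in members:
            a = _arr(seq)
            if a.size != cen.size:
                continue
            mm = int(np.count_nonzero(a != cen))
            if mm <= 2:
                errors += mm * count
                bases += a.size * count
    if bases == 0:
        return fallback
    return max(errors / bases, 1e-4)


def call_alleles(members: list[tuple[str, int, bool]], d: int,
                 sequencing_error_estimate: float, pl: int, n: int
                 ) -> SampleLocus | None:
    """Statistical base calls and allele phasing for one within-sample cluster.

    Per column with depth >= ``d``, the two most frequent bases are compared
    under an error-only (homozygote) and a 50:50 (heterozygote) binomial
    model; columns below ``d`` become N.  Heterozygous columns are phased into
    alleles by read co-occurrence (patterns need at least two supporting
    reads; unsupported minor bases are demoted).  Returns None when the
    sample's data are discarded (> ``pl`` alleles, > ``n`` ambiguous consensus
    sites, or nothing callable).
    """
    if not members:
        return None
    L = len(members[0][0])
    code = np.full((len(members), L), 4, dtype=np.int8)
    w = np.zeros(len(members), dtype=np.int64)
    base_of = {65: 0, 67: 1, 71: 2, 84: 3}
    for i, (seq, count, *_flip) in enumerate(members):
        a = _arr(seq)[:L]
        row = np.full(L, 4, dtype=np.int8)
        for b, k in base_of.items():
            row[a == b] = k
        code[i, :a.size] = row
        w[i] = count
    counts = np.zeros((4, L), dtype=np.int64)
    for b in range(4):
        counts[b] = w @ (code == b)
    depth_col = counts.sum(axis=0)
    order = np.argsort(-counts, axis=0, kind="stable")
    n1 = counts[order[0], np.arange(L)]
    n2 = counts[order[1], np.arange(L)]
    e = max(sequencing_error_estimate, 1e-6)
    consensus = np.full(L, 4, dtype=np.int8)
    het = np.zeros(L, dtype=bool)
    callable_col = depth_col >= d
    tot = n1 + n2
    with np.errstate(all="ignore"):
        l_hom = binom.pmf(n2, tot, e)
        l_het = binom.pmf(n2, tot, 0.5)
    het_call = callable_col & (n2 > 0) & (l_het > l_hom)
    hom_call = callable_col & ~het_call
    consensus[hom_call] = order[0][hom_call]
    het[het_call] = True
    consensus[het_call] = order[0][het_call]

    het_idx = np.nonzero(het)[0]
    alleles_codes: list[np.ndarray]
    if het_idx.size:
        patterns: dict[tuple, int] = {}
        sub = code[:, het_idx]
        for i in range(len(members)):
            pat = tuple(int(x) for x in sub[i])
            if 4 in pat:
                continue
            patterns[pat] = patterns.get(pat, 0) + int(w[i])
        supported = {p: cnt for p, cnt in patterns.items() if cnt >= 2}
        # demote het columns whose minor base has no supported pattern
        keep_cols = []
        for j, col in enumerate(het_idx):
            bases_seen = {p[j] for p in supported}
            if len(bases_seen) >= 2:
                keep_cols.append(j)
            else:
                het[col] = False
                if len(bases_seen) == 1:
                    consensus[col] = next(iter(bases_seen))
        if keep_cols:
            proj: dict[tuple, int] = {}
            for p, cnt in supported.items():
                key = tuple(p[j] for j in keep_cols)
                proj[key] = proj.get(key, 0) + cnt
            if len(proj) > pl:
                return None
            cols = het_idx[keep_cols]
            alleles_codes = []
            for key in sorted(proj, key=lambda k: (-proj[k], k)):
                al = consensus.copy()
                al[cols] = key
                alleles_codes.append(al)
        else:
            alleles_codes = [consensus.copy()]
    else:
        alleles_codes = [consensus.copy()]

    def decode(codes: np.ndarray) -> str:
        return "".join("ACGTN"[int(k)] for k in codes)

    cons_chars = list(decode(consensus))
    for col in np.nonzero(het)[0]:
        bset = frozenset("ACGTN"[int(a[col])] for a in alleles_codes) - {"N"}
        cons_chars[col] = IUPAC.get(bset, "N") if bset else "N"
    cons_str = "".join(cons_chars)
    if cons_str.count("N") > n:
        return None
    if np.all(consensus == 4):
        return None
    alleles = [decode(a) for a in alleles_codes]
    return SampleLocus(alleles=alleles, consensus=cons_str, depth=int(w.sum()))


def join_unmerged(pairs) -> list[tuple[str, str]]:
    """Join unmerged pairs into single sequences (read1 + revcomp(read2)).

    With fixed-length reads the joined sequences from one locus align without
    gaps; an orientation-flipped pair joins to the exact reverse complement,
    which reverse-complement clustering reunites.
    """
    out = []
    for p in pairs:
        out.append((p.seq1 + revcomp(p.seq2), p.qual1 + p.qual2[::-1]))
    return out


def assemble_sample(reads: list[tuple[str, str]], params: AssemblyParams
                    ) -> list[SampleLocus]:
    """Per-sample pipeline: n filter, dereplication, clustering, allele calls."""
    reads = quality_trim_reads(reads, params.n)
    dereps = dereplicate(reads, params.mr)
    clusters = cluster_within_sample(dereps, params.c)
    err = params.error_rate if params.error_rate is not None \
        else estimate_error_rate(clusters)
    out = []
    for members in clusters:
        called = call_alleles(members, params.d, err, params.pl, params.n)
        if called is not None:
            out.append(called)
    return out


def cluster_across_samples(per_sample: dict[str, list[SampleLocus]], c: float
                           ) -> LocusSet:
    """Cluster per-sample consensuses into candidate loci at identity ``c``.

    At most one within-sample cluster per sample enters a locus; when two
    collide the deeper one is kept and the event counted as a potential
    paralog.
    """
    units = []
    for sample, sls in per_sample.items():
        for sl in sls:
            units.append((sl.depth, sl.consensus, sample, sl))
    units.sort(key=lambda u: (-u[0], u[1], u[2]))
    clusterer = _GreedyClusterer(c)
    loci: list[Locus] = []
    paralogs = 0
    for depth, consensus, sample, sl in units:
        idx, flipped = clusterer.assign(consensus)
        if idx == len(loci):
            loci.append(Locus(id=idx, length=len(consensus)))
        locus = loci[idx]
        oriented = sl if not flipped else SampleLocus(
            alleles=[revcomp(a) for a in sl.alleles],
            consensus=revcomp(sl.consensus), depth=sl.depth)
        prev = locus.samples.get(sample)
        if prev is None or oriented.depth > prev.depth:
            if prev is not None:
                paralogs += 1
            locus.samples[sample] = oriented
        elif prev is not None:
            paralogs += 1
    for locus in loci:
        compute_locus_snps(locus)
    return LocusSet(loci=loci, samples=sorted(per_sample), paralog_events=paralogs)


def compute_locus_snps(locus: Locus) -> None:
    """Recompute SNP positions/genotypes across the locus's retained samples."""
    locus.snps = {}
    L = locus.length
    per_sample_bases: dict[str, list] = {}
    for s, sl in locus.samples.items():
        mats = []
        for al in sl.alleles:
            a = _arr(al[:L])
            if a.size < L:
                a = np.concatenate([a, np.full(L - a.size, ord("N"), np.uint8)])
            mats.append(a)
        per_sample_bases[s] = mats
    for pos in range(L):
        seen: set[int] = set()
        genos: dict[str, tuple] = {}
        for s, mats in per_sample_bases.items():
            bases = tuple(sorted({chr(m[pos]) for m in mats} - {"N"}))
            if bases:
                genos[s] = bases
                seen.update(ord(b) for b in bases)
        if len(seen) >= 2:
            locus.snps[pos] = genos


def filter_loci(locus_set: LocusSet, h: float | None = None,
                min_sample_coverage: float | None = None,
                params: AssemblyParams | None = None) -> LocusSet:
    """Apply the shared-heterozygosity (paralog) and coverage filters.

    A locus is dropped when any site is heterozygous in more than ``h``
    individuals, or when fewer than ``ceil(min_sample_coverage * n_samples)``
    samples carry it.  SNP lists are recomputed on the survivors.
    """
    params = params or locus_set.params or AssemblyParams()
    if h is None:
        h = params.h
    if min_sample_coverage is None:
        min_sample_coverage = params.min_sample_coverage
    n_samples = len(locus_set.samples)
    h_count = AssemblyParams.h_count(replace(params, h=h), n_samples)
    min_cov = math.ceil(min_sample_coverage * n_samples)
    kept = []
    for locus in locus_set.loci:
        if locus.coverage < min_cov:
            continue
        bad = False
        for pos, genos in locus.snps.items():
            n_het = sum(1 for g in genos.values() if len(g) >= 2)
            if n_het > h_count:
                bad = True
                break
        if bad:
            continue
        compute_locus_snps(locus)
        kept.append(locus)
    out_params = replace(params, h=h, min_sample_coverage=min_sample_coverage)
    return LocusSet(loci=kept, samples=locus_set.samples,
                    provenance=locus_set.provenance, params=out_params,
                    paralog_events=locus_set.paralog_events)


def assemble(reads_by_sample: dict[str, list[tuple[str, str]]],
             params: AssemblyParams | None = None,
             provenance: str = "merged") -> LocusSet:
    """Full assembly of one read set across samples; returns filtered loci."""
    params = params or AssemblyParams()
    per_sample = {s: assemble_sample(reads, params)
                  for s, reads in sorted(reads_by_sample.items())}
    unfiltered = cluster_across_samples(per_sample, params.c)
    unfiltered.provenance = provenance
    unfiltered.params = params
    return filter_loci(unfiltered, params.h, params.min_sample_coverage, params)
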