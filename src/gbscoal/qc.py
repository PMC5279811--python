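"""Replicate-based assembly quality control and parameter optimisation.

Technical replicate pairs (two libraries from the same DNA) quantify assembly
noise: *locus error* is the fraction of loci recovered in only one replicate
(relative to the union of the pair's loci), *allele error* the fraction of
shared loci whose allele sequences differ, and *SNP error* the fraction of
genotype calls differing at shared loci.  A one-parameter-at-a-time sweep over
the assembly knobs, scored on loci/SNPs recovered, the three error rates and
intra-population distances, guides parameter choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import AssemblyParams, LocusSet, assemble
from . import snp as snpmod

__all__ = ["ErrorReport", "SweepResult", "replicate_error_rates",
           "intra_population_distances", "sweep_parameters",
           "select_parameters", "DEFAULT_GRID", "DEFAULT_PARAMS"]

# standard one-at-a-time sweep grid (defaults included in each list)
DEFAULT_GRID: dict[str, list] = {
    "d": [2, 3, 4, 6, 8, 10],
    "n": [2, 4, 8],
    "c": [0.82, 0.85, 0.88, 0.91, 0.94, 0.97],
    "h": [3, 5, 10],
    "pl": [2, 4, 8],
    "mr": [1, 2, 4, 8, 10],
}
DEFAULT_PARAMS = AssemblyParams(d=6, n=4, c=0.88, h=3, pl=2, mr=1)


@dataclass
class ErrorReport:
    pair: tuple[str, str]
    locus_error: float | None
    allele_error: float | None
    snp_error: float | None
    n_loci_a: int = 0
    n_loci_b: int = 0
    n_union: int = 0
    n_shared: int = 0
    n_shared_differing: int = 0
    n_shared_snp_calls: int = 0
    n_differing_snp_calls: int = 0


@dataclass
class SweepResult:
    parameter: str
    value: float
    provenance: str
    n_loci: int
    n_snps: int
    error_reports: list[ErrorReport]
    intra_population: dict[str, dict]
    failed: str | None = None


def replicate_error_rates(locus_set: LocusSet, pair: tuple[str, str]) -> ErrorReport:
    """Locus/allele/SNP error rates for one replicate pair.

    Locus identity is cluster membership: the two replicates share a locus
    when both were clustered into it.  With no shared loci, allele and SNP
    error are undefined (None), never 0.
    """
    a, b = pair
    if a not in locus_set.samples or b not in locus_set.samples:
        raise KeyError(f"replicate pair {pair} not in locus set samples")
    with_a = [loc for loc in locus_set.loci if a in loc.samples]
    with_b = [loc for loc in locus_set.loci if b in loc.samples]
    shared = [loc for loc in with_a if b in loc.samples]
    n_union = len(with_a) + len(with_b) - len(shared)
    locus_error = ((n_union - len(shared)) / n_union) if n_union else None

    n_diff = 0
    snp_total = 0
    snp_diff = 0
    for loc in shared:
        if sorted(loc.samples[a].alleles) != sorted(loc.samples[b].alleles):
            n_diff += 1
        for pos, genos in loc.snps.items():
            if a in genos and b in genos:
                snp_total += 1
                if genos[a] != genos[b]:
                    snp_diff += 1
    allele_error = (n_diff / len(shared)) if shared else None
    # with shared loci but no overlapping SNP calls there is zero observable
    # SNP discordance; only a pair sharing nothing has undefined rates
    snp_error = ((snp_diff / snp_total) if snp_total else 0.0) if shared else None
    return ErrorReport(pair=pair, locus_error=locus_error,
                       allele_error=allele_error, snp_error=snp_error,
                       n_loci_a=len(with_a), n_loci_b=len(with_b),
                       n_union=n_union, n_shared=len(shared),
                       n_shared_differing=n_diff,
                       n_shared_snp_calls=snp_total,
                       n_differing_snp_calls=snp_diff)


def intra_population_distances(locus_set_or_matrix, populations: dict[str, str],
                               exclude_samples: tuple[str, ...] = ()
                               ) -> dict[str, dict]:
    """Pairwise K80 distances among same-population samples, summarised.

    Accepts a LocusSet (a SNP matrix is built from it) or a prebuilt
    SNPMatrix.  Populations with fewer than two genotyped samples are skipped.
    """
    if isinstance(locus_set_or_matrix, LocusSet):
        matrix = snpmod.build_and_filter_snp_matrix(
            [locus_set_or_matrix], min_site_coverage=0.0,
            exclude_samples=exclude_samples)
    else:
        matrix = locus_set_or_matrix
    dm = snpmod.k80_distances(matrix)
    idx = {s: i for i, s in enumerate(dm.labels)}
    by_pop: dict[str, list[float]] = {}
    for s, pop in populations.items():
        if s in idx:
            by_pop.setdefault(pop, [])
    out: dict[str, dict] = {}
    for pop in sorted(by_pop):
        members = [s for s, p in populations.items() if p == pop and s in idx]
        dists = []
        for i, s1 in enumerate(members):
            for s2 in members[i + 1:]:
                v = dm.values[idx[s1], idx[s2]]
                if np.isfinite(v):
                    dists.append(float(v))
        if len(members) < 2 or not dists:
            continue
        out[pop] = {"mean": float(np.mean(dists)), "max": float(np.max(dists)),
                    "n_pairs": len(dists)}
    return out


def sweep_parameters(reads_by_sample: dict[str, list],
                     defaults: AssemblyParams | None = None,
                     grid: dict[str, list] | None = None,
                     replicate_pairs: list[tuple[str, str]] = (),
                     populations: dict[str, str] | None = None,
                     provenance: str = "merged") -> list[SweepResult]:
    """One assembly + QC per (parameter, value), other parameters at default."""
    defaults = defaults or DEFAULT_PARAMS
    grid = grid or DEFAULT_GRID
    populations = populations or {}
    replicate_samples = tuple(s for pair in replicate_pairs for s in pair)
    results: list[SweepResult] = []
    cache: dict[tuple, LocusSet] = {}
    for parameter, values in grid.items():
        for value in values:
            params = replace(defaults, **{parameter: value})
            key = (params.d, params.n, params.c, params.h, params.pl,
                   params.mr, params.min_sample_coverage)
            try:
                if key in cache:
                    ls = cache[key]
                else:
                    ls = assemble(reads_by_sample, params, provenance)
                    cache[key] = ls
                reports = [replicate_error_rates(ls, p) for p in replicate_pairs]
                intra = intra_population_distances(
                    ls, populations, exclude_samples=tuple(
                        s for s in replicate_samples if s.endswith(".rep")))
                results.append(SweepResult(
                    parameter=parameter, value=value, provenance=provenance,
                    n_loci=len(ls.loci), n_snps=ls.n_snps(),
                    error_reports=reports, intra_population=intra))
            except Exception as exc:  # record, keep sweeping
                results.append(SweepResult(
                    parameter=parameter, value=value, provenance=provenance,
                    n_loci=0, n_snps=0, error_reports=[], intra_population={},
                    failed=str(exc)))
    return results


def _criteria(res: SweepResult) -> list[float]:
    reports = [r for r in res.error_reports if r.locus_error is not None]
    mean_or = lambda vals, d: float(np.mean(vals)) if vals else d
    locus_err = mean_or([r.locus_error for r in reports
                         if r.locus_error is not None], 1.0)
    allele_err = mean_or([r.allele_error for r in res.error_reports
                          if r.allele_error is not None], 1.0)
    snp_err = mean_or([r.snp_error for r in res.error_reports
                       if r.snp_error is not None], 1.0)
    intra = mean_or([v["mean"] for v in res.intra_population.values()], 0.0)
    return [-res.n_loci, -res.n_snps, locus_err, allele_err, snp_err, intra]


def select_parameters(results: list[SweepResult],
                      weights: list[float] | None = None,
                      defaults: AssemblyParams | None = None
                      ) -> tuple[AssemblyParams, dict]:
    """Advisory per-parameter choice by weighted rank over the sweep criteria.

    Criteria (all minimised): -loci, -SNPs, locus error, allele error, SNP
    error, mean intra-population distance.  Ranks are averaged for ties; the
    value with the lowest weighted rank sum wins, ties broken toward the
    default.  The choice is a compromise and user override is expected.
    """
    from scipy.stats import rankdata

    defaults = defaults or DEFAULT_PARAMS
    weights = weights or [1.0] * 6
    if not results:
        raise ValueError("empty sweep")
    chosen: dict[str, float] = {}
    report: dict[str, list] = {}
    for parameter in sorted({r.parameter for r in results}):
        rows = [r for r in results if r.parameter == parameter and not r.failed]
        if not rows:
            continue
        crit = np.array([_criteria(r) for r in rows])
        ranks = np.column_stack([rankdata(crit[:, k]) for k in range(crit.shape[1])])
        scores = ranks @ np.asarray(weights, float)
        best = np.min(scores)
        default_value = getattr(defaults, parameter)
        ties = [rows[i].value for i in range(len(rows))
                if scores[i] <= best + 1e-12]
        pick = min(ties, key=lambda v: (abs(v - default_value), v))
        chosen[parameter] = pick
        report[parameter] = [
            {"value": rows[i].value, "score": float(scores[i]),
             "n_loci": rows[i].n_loci, "n_snps": rows[i].n_snps,
             "criteria": [float(x) for x in crit[i]]}
            for i in range(len(rows))]
    params = replace(defaults, **chosen)
    return params, report
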