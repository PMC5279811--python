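"""Flat-text output formats and LocusSet (de)serialisation."""

from __future__ import annotations

import json

from .assembly import AssemblyParams, Locus, LocusSet, SampleLocus

__all__ = ["write_loci_text", "write_vcf_lite", "write_coverage_tsv",
           "write_locus_fastas", "locus_set_to_json", "locus_set_from_json"]


def write_loci_text(locus_set: LocusSet, path: str) -> None:
    """PyRAD-style flat text: aligned sample rows per locus, then a SNP line."""
    with open(path, "w") as fh:
        for locus in locus_set.loci:
            width = max((len(s) for s in locus.samples), default=0) + 2
            for s in sorted(locus.samples):
                sl = locus.samples[s]
                fh.write(f"{s:<{width}}{sl.consensus}\n")
            marks = ["-"] * locus.length
            for pos in locus.snps:
                marks[pos] = "*"
            fh.write(f"{'//':<{width}}{''.join(marks)}|{locus.id}\n")


def write_vcf_lite(locus_set: LocusSet, path: str) -> None:
    """Minimal VCF: one record per SNP, GT field only, positions 1-based in-locus."""
    samples = locus_set.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2-lite\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for locus in locus_set.loci:
            for pos, genos in sorted(locus.snps.items()):
                alleles = sorted({b for g in genos.values() for b in g})
                ref, alts = alleles[0], alleles[1:]
                code = {a: i for i, a in enumerate(alleles)}
                cells = []
                for s in samples:
                    g = genos.get(s)
                    if g is None:
                        cells.append("./.")
                    else:
                        idxs = sorted(code[b] for b in g)
                        if len(idxs) == 1:
                            idxs = idxs * 2
                        cells.append("/".join(str(i) for i in idxs))
                fh.write(f"{locus_set.provenance}_{locus.id}\t{pos + 1}\t.\t"
                         f"{ref}\t{','.join(alts) or '.'}\t.\tPASS\t.\tGT\t"
                         + "\t".join(cells) + "\n")


def write_coverage_tsv(locus_set: LocusSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tlength\tcoverage\tn_snps\n")
        for locus in locus_set.loci:
            fh.write(f"{locus_set.provenance}_{locus.id}\t{locus.length}\t"
                     f"{locus.coverage}\t{len(locus.snps)}\n")


def write_locus_fastas(locus_set: LocusSet, out_dir: str) -> None:
    import os
    os.makedirs(out_dir, exist_ok=True)
    for locus in locus_set.loci:
        with open(os.path.join(out_dir,
                               f"{locus_set.provenance}_{locus.id}.fasta"),
                  "w") as fh:
            for s in sorted(locus.samples):
                for i, al in enumerate(locus.samples[s].alleles):
                    fh.write(f">{s}_allele{i}\n{al}\n")


def locus_set_to_json(locus_set: LocusSet, path: str) -> None:
    doc = {
        "samples": locus_set.samples,
        "provenance": locus_set.provenance,
        "paralog_events": locus_set.paralog_events,
        "params": vars(locus_set.params) if locus_set.params else None,
        "loci": [{
            "id": loc.id, "length": loc.length,
            "samples": {s: {"alleles": sl.alleles, "consensus": sl.consensus,
                            "depth": sl.depth}
                        for s, sl in loc.samples.items()},
            "snps": {str(pos): {s: list(g) for s, g in genos.items()}
                     for pos, genos in loc.snps.items()},
        } for loc in locus_set.loci],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def locus_set_from_json(path: str) -> LocusSet:
    with open(path) as fh:
        doc = json.load(fh)
    loci = []
    for rec in doc["loci"]:
        loc = Locus(id=rec["id"], length=rec["length"])
        for s, d in rec["samples"].items():
            loc.samples[s] = SampleLocus(alleles=list(d["alleles"]),
                                         consensus=d["consensus"],
                                         depth=int(d["depth"]))
        loc.snps = {int(pos): {s: tuple(g) for s, g in genos.items()}
                    for pos, genos in rec["snps"].items()}
        loci.append(loc)
    params = AssemblyParams(**doc["params"]) if doc.get("params") else None
    return LocusSet(loci=loci, samples=list(doc["samples"]),
                    provenance=doc["provenance"], params=params,
                    paralog_events=int(doc.get("paralog_events", 0)))
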