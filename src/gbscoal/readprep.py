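"""Quality filtering and overlap-merging of paired GBS reads.

Short restriction fragments sequenced from both ends yield overlapping read
pairs; those are merged into a single fragment-length sequence and analysed
separately from the unmerged pairs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .simulate import revcomp

__all__ = ["ReadPair", "MergedRead", "filter_reads", "merge_pairs",
           "read_fastq_pairs", "write_merged", "write_unmerged"]

DEFAULT_MIN_OVERLAP = 16
DEFAULT_MAX_MISMATCH = 0.1


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_length: int
    source: str  # "merged" | "unmerged-pair"


def read_fastq_pairs(r1_path: str, r2_path: str) -> list[ReadPair]:
    """Load a pair of Phred+33 FASTQ files into ReadPair records."""
    from Bio import SeqIO
    pairs = []
    it1 = SeqIO.parse(r1_path, "fastq")
    it2 = SeqIO.parse(r2_path, "fastq")
    for idx, (a, b) in enumerate(zip(it1, it2)):
        q1 = "".join(chr(33 + q) for q in a.letter_annotations["phred_quality"])
        q2 = "".join(chr(33 + q) for q in b.letter_annotations["phred_quality"])
        try:
            pairs.append(ReadPair(a.id, str(a.seq), q1, str(b.seq), q2))
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {idx}: {exc}") from exc
    return pairs


def filter_reads(pairs: Iterable[ReadPair], max_fraction_low_quality: float = 0.25,
                 quality_floor: int = 10) -> list[ReadPair]:
    """Discard pairs with uncalled bases or too many low-quality bases.

    A pair is dropped when either mate contains an N, or when the fraction of
    bases below ``quality_floor`` in either mate exceeds
    ``max_fraction_low_quality``.  Input order is preserved.
    """
    kept = []
    for p in pairs:
        if "N" in p.seq1 or "N" in p.seq2:
            continue
        bad = False
        for seq, qual in ((p.seq1, p.qual1), (p.seq2, p.qual2)):
            if not seq:
                continue
            q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
            if (q < quality_floor).sum() > max_fraction_low_quality * len(seq):
                bad = True
                break
        if not bad:
            kept.append(p)
    return kept


def _best_overlap(s1: np.ndarray, s2: np.ndarray, min_overlap: int,
                  max_mismatch_fraction: float):
    """Best suffix(seq1)/prefix(seq2rc) overlap by matches - mismatches.

    Ties go to the longest overlap.  Returns (overlap, n_mismatch) or None.
    """
    best = None
    max_o = min(s1.size, s2.size)
    for o in range(min_overlap, max_o + 1):
        eq = int(np.count_nonzero(s1[-o:] == s2[:o]))
        mm = o - eq
        if mm > max_mismatch_fraction * o:
            continue
        score = eq - mm
        if best is None or score >= best[0]:
            best = (score, o, mm)
    if best is None:
        return None
    return best[1], best[2]


def merge_pairs(pairs: Iterable[ReadPair], min_overlap: int = DEFAULT_MIN_OVERLAP,
                max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH,
                ) -> tuple[list[MergedRead], list[ReadPair]]:
    """Partition pairs into merged single reads and unmerged pairs.

    Mate 2 is reverse-complemented, the best overlap of at least
    ``min_overlap`` bases with mismatch fraction within tolerance is merged;
    at overlap conflicts the higher-quality base wins.  Every input pair lands
    in exactly one output set.
    """
    merged: list[MergedRead] = []
    unmerged: list[ReadPair] = []
    cache: dict = {}
    for p in pairs:
        key = (p.seq1, p.seq2, p.qual1, p.qual2)
        hit = cache.get(key)
        if hit is not None:
            ok, seq, qual, o = hit
            if ok:
                merged.append(MergedRead(p.id, seq, qual, o, "merged"))
            else:
                unmerged.append(p)
            continue
        result = _merge_one(p, min_overlap, max_mismatch_fraction)
        if result is None:
            cache[key] = (False, None, None, 0)
            unmerged.append(p)
        else:
            seq, qual, o = result
            cache[key] = (True, seq, qual, o)
            merged.append(MergedRead(p.id, seq, qual, o, "merged"))
    return merged, unmerged


def _merge_one(p: ReadPair, min_overlap: int, max_mismatch_fraction: float):
    if not p.seq1 or not p.seq2:
        return None
    r2rc = revcomp(p.seq2)
    q2r = p.qual2[::-1]
    a1 = np.frombuffer(p.seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(r2rc.encode(), dtype=np.uint8)
    found = _best_overlap(a1, a2, min_overlap, max_mismatch_fraction)
    if found is None:
        return None
    o, _ = found
    q1 = np.frombuffer(p.qual1.encode(), dtype=np.uint8)
    q2 = np.frombuffer(q2r.encode(), dtype=np.uint8)
    left = a1[:a1.size - o]
    ov1, ov2 = a1[a1.size - o:], a2[:o]
    qv1, qv2 = q1[q1.size - o:], q2[:o]
    agree = ov1 == ov2
    take2 = (~agree) & (qv2 > qv1)
    ov = np.where(take2, ov2, ov1)
    qov = np.where(agree, np.maximum(qv1, qv2), np.where(take2, qv2, qv1))
    seq = left.tobytes().decode() + ov.tobytes().decode() + r2rc[o:]
    qual = p.qual1[:a1.size - o] + qov.tobytes().decode() + q2r[o:]
    return seq, qual, o


def write_merged(path: str, merged: list[MergedRead]) -> None:
    with open(path, "w") as fh:
        for m in merged:
            fh.write(f"@{m.id}\n{m.seq}\n+\n{m.qual}\n")


def write_unmerged(path1: str, path2: str, pairs: list[ReadPair]) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")
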