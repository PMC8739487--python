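"""Paired-read merging and quality filtering.

The filtering contract, applied in this fixed order to each merged read:

1. reads with an arithmetic-mean Phred quality < 30 are removed
   (mean exactly 30.0 is kept);
2. remaining bases with quality < 30 are masked with ``N`` (Q30 untouched);
3. reads with more than 10 ``N``s after masking are removed
   (exactly 10 is kept).

Pre-existing ``N``s in the input count toward the 10-N limit.  Masking never
changes sequence length and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

MEAN_Q_MIN = 30.0
MASK_Q_MIN = 30
MAX_N = 10

_RC = str.maketrans("ACGTN", "TGCAN")


class QCStatus(str, Enum):
    KEPT = "kept"
    REMOVED_LOW_MEAN_Q = "removed_low_mean_q"
    REMOVED_EXCESS_N = "removed_excess_n"
    REMOVED_NO_OVERLAP = "removed_no_overlap"


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read; mate 2 is reverse-complement oriented."""

    id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: tuple[int, ...]
    n_masked: int = 0
    status: QCStatus = QCStatus.KEPT


def merge_pair(
    pair: ReadPair, min_overlap: int = 20, max_mismatch_frac: float = 0.1
) -> MergedRead:
    """Merge a read pair over its best ungapped overlap.

    Scans all overlap lengths of mate 1 against the reverse-complemented
    mate 2 and keeps the highest-scoring one (match +1, mismatch −1, ``N``
    neutral; ties broken toward the longer overlap) with length
    ``>= min_overlap`` and mismatch fraction ``<= max_mismatch_frac``.
    Within the overlap each base is taken from the mate with the higher
    quality, which is also the quality retained.
    """
    s1 = np.frombuffer(pair.seq1.encode(), dtype="S1")
    s2 = np.frombuffer(pair.seq2.translate(_RC)[::-1].encode(), dtype="S1")
    q1 = np.asarray(pair.qual1, dtype=np.int32)
    q2 = np.asarray(pair.qual2, dtype=np.int32)[::-1]
    n1, n2 = len(s1), len(s2)

    best: tuple[int, int] | None = None  # (score, overlap)
    for o in range(min(n1, n2), min_overlap - 1, -1):
        a, b = s1[n1 - o :], s2[:o]
        informative = (a != b"N") & (b != b"N")
        matches = int(np.sum((a == b) & informative))
        mismatches = int(np.sum((a != b) & informative))
        if o and mismatches / o > max_mismatch_frac:
            continue
        score = matches - mismatches
        if best is None or score > best[0]:
            best = (score, o)
    if best is None:
        return MergedRead(
            pair.id, "", (), status=QCStatus.REMOVED_NO_OVERLAP
        )

    o = best[1]
    left_s, left_q = s1[: n1 - o], q1[: n1 - o]
    right_s, right_q = s2[o:], q2[o:]
    a, b = s1[n1 - o :].copy(), s2[:o]
    qa, qb = q1[n1 - o :].copy(), q2[:o]
    take2 = qb > qa  # ties favour mate 1
    a[take2] = b[take2]
    qa = np.maximum(qa, qb)
    seq = (left_s.tobytes() + a.tobytes() + right_s.tobytes()).decode()
    qual = tuple(int(x) for x in np.concatenate([left_q, qa, right_q]))
    return MergedRead(pair.id, seq, qual, status=QCStatus.KEPT)


def quality_filter(read: MergedRead) -> MergedRead:
    """Apply the mean-quality, masking, and N-count rules in fixed order."""
    if read.status is not QCStatus.KEPT:
        return read
    qual = np.asarray(read.qual, dtype=np.int32)
    if len(qual) == 0 or float(qual.mean()) < MEAN_Q_MIN:
        return replace(read, status=QCStatus.REMOVED_LOW_MEAN_Q)
    seq = np.frombuffer(read.seq.encode(), dtype="S1").copy()
    to_mask = (qual < MASK_Q_MIN) & (seq != b"N")
    seq[to_mask] = b"N"
    n_masked = read.n_masked + int(to_mask.sum())
    n_total = int(np.sum(seq == b"N"))
    status = QCStatus.REMOVED_EXCESS_N if n_total > MAX_N else QCStatus.KEPT
    return MergedRead(read.id, seq.tobytes().decode(), read.qual, n_masked, status)


def process_pair(
    pair: ReadPair, min_overlap: int = 20, max_mismatch_frac: float = 0.1
) -> MergedRead:
    """Merge then quality-filter one pair."""
    return quality_filter(merge_pair(pair, min_overlap, max_mismatch_frac))


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized mates from two FASTQ files (Phred+33)."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        yield ReadPair(
            id=r1.id,
            seq1=str(r1.seq).upper(),
            qual1=tuple(r1.letter_annotations["phred_quality"]),
            seq2=str(r2.seq).upper(),
            qual2=tuple(r2.letter_annotations["phred_quality"]),
        )


def qc_fastq(
    path1: str | Path,
    path2: str | Path,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[MergedRead], "pd.DataFrame"]:
    """QC a FASTQ pair; returns kept merged reads and a per-read status table."""
    import pandas as pd

    kept: list[MergedRead] = []
    status_rows = []
    for pair in read_fastq_pairs(path1, path2):
        merged = process_pair(pair, min_overlap, max_mismatch_frac)
        status_rows.append(
            {
                "sequence_id": merged.id,
                "status": merged.status.value,
                "n_masked": merged.n_masked,
            }
        )
        if merged.status is QCStatus.KEPT:
            kept.append(merged)
    return kept, pd.DataFrame(
        status_rows, columns=["sequence_id", "status", "n_masked"]
    )
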