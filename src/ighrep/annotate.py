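"""V/J germline assignment, CDR3 extraction, SHM computation, and copy collapse.

Gene assignment uses semi-global (overlap) alignment with free end gaps,
scored match +1, mismatch −1, gap open −4, gap extend −1; ``N`` is neutral
(neither match nor mismatch) everywhere, since masked bases carry no
evidence.  The best-scoring gene wins, ties broken by lexicographic name;
a best score below ``min_score`` leaves the sequence unassignable.

SHM is the percentage of mismatched positions over the aligned V region from
the FR1 boundary (the FR1 / primer-binding region is trimmed off) up to the
CDR3 anchor, with ``N`` positions excluded from both numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .germline import GermlineGene, GermlineSet

DEFAULT_MIN_SCORE = 40.0

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def translate_nt(nt: str) -> str:
    """Translate full codons; codons containing ``N`` become ``X``,
    stop codons become ``*``.  Trailing partial codons are dropped."""
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aa.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aa)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = 1.0 if a == b else -1.0
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    # affine gap cost 4 + k for a gap of length k
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aligner.end_gap_score = 0.0  # free end gaps on both sequences
    return aligner


@dataclass(frozen=True)
class GeneAssignment:
    """Best-gene call with the germline→query coordinate map of its alignment."""

    gene: GermlineGene
    score: float
    identity: float
    germline_to_query: dict[int, int]


def _align_map(
    germline_seq: str, query: str
) -> tuple[float, dict[int, int], float]:
    """Align germline (target) vs query; return (score, germline→query map,
    identity over aligned non-N positions)."""
    aln = _aligner().align(germline_seq, query)[0]
    g2q: dict[int, int] = {}
    matches = compared = 0
    tb, qb = aln.aligned
    for (t0, t1), (q0, q1) in zip(tb, qb):
        for off in range(t1 - t0):
            t, q = t0 + off, q0 + off
            g2q[t] = q
            gc, qc = germline_seq[t], query[q]
            if gc == "N" or qc == "N":
                continue
            compared += 1
            if gc == qc:
                matches += 1
    identity = matches / compared if compared else 0.0
    return float(aln.score), g2q, identity


def assign_gene(
    sequence: str,
    genes: Sequence[GermlineGene],
    min_score: float = DEFAULT_MIN_SCORE,
) -> GeneAssignment | None:
    """Assign the best-matching germline gene, or ``None`` if unassignable."""
    if not sequence or not genes:
        raise ValueError("need a non-empty sequence and gene collection")
    aligner = _aligner()
    best_gene: GermlineGene | None = None
    best_score = -np.inf
    for gene in sorted(genes, key=lambda g: g.name):
        score = aligner.score(gene.sequence, sequence)
        if score > best_score:
            best_gene, best_score = gene, score
    assert best_gene is not None
    if best_score < min_score:
        return None
    score, g2q, identity = _align_map(best_gene.sequence, sequence)
    return GeneAssignment(best_gene, score, identity, g2q)


def compute_shm(v_assignment: GeneAssignment, v_gene: GermlineGene, sequence: str) -> float | None:
    """Percent mismatched positions over the FR1-trimmed aligned V region.

    Returns ``None`` (undefined) when no position can be compared, e.g. when
    every aligned base in the window is masked.
    """
    mismatches = compared = 0
    for p in range(v_gene.fr1_end, v_gene.cdr3_anchor):
        q = v_assignment.germline_to_query.get(p)
        if q is None:
            continue
        qc = sequence[q]
        if qc == "N":
            continue
        compared += 1
        if qc != v_gene.sequence[p]:
            mismatches += 1
    if compared == 0:
        return None
    return 100.0 * mismatches / compared


def _anchor_query_span(
    assignment: GeneAssignment, anchor: int
) -> tuple[int, int] | None:
    """Query span of the anchor codon, or None if not aligned contiguously."""
    g2q = assignment.germline_to_query
    qs = [g2q.get(anchor + k) for k in range(3)]
    if any(q is None for q in qs):
        return None
    if qs[1] != qs[0] + 1 or qs[2] != qs[1] + 1:
        return None
    return qs[0], qs[2] + 1


def extract_cdr3(
    sequence: str,
    v_assignment: GeneAssignment,
    j_assignment: GeneAssignment,
) -> tuple[str, str, bool] | None:
    """Extract the CDR3 between the V and J anchor codons (anchors excluded).

    Returns ``(cdr3_nt, cdr3_aa, productive)`` or ``None`` when an anchor
    codon is not contiguously covered by its alignment.  ``productive``
    requires an in-frame junction with no stop codon.
    """
    v_span = _anchor_query_span(v_assignment, v_assignment.gene.cdr3_anchor)
    j_span = _anchor_query_span(j_assignment, j_assignment.gene.cdr3_anchor)
    if v_span is None or j_span is None:
        return None
    start, end = v_span[1], j_span[0]
    if end < start:
        return None
    cdr3_nt = sequence[start:end]
    in_frame = len(cdr3_nt) % 3 == 0
    cdr3_aa = translate_nt(cdr3_nt) if in_frame else ""
    productive = in_frame and "*" not in cdr3_aa
    return cdr3_nt, cdr3_aa, productive


def _fr1_trim_position(assignment: GeneAssignment, v_gene: GermlineGene) -> int | None:
    """First query position aligned at or beyond the FR1 boundary."""
    for p in range(v_gene.fr1_end, v_gene.cdr3_anchor + 3):
        q = assignment.germline_to_query.get(p)
        if q is not None:
            return q
    return None


REARRANGEMENT_COLUMNS = [
    "sequence_id",
    "subject_id",
    "sample_id",
    "sequence",
    "v_call",
    "j_call",
    "v_identity",
    "cdr3",
    "cdr3_aa",
    "productive",
    "shm_percent",
    "duplicate_count",
]


def annotate_sample(
    reads: Iterable[tuple[str, str]],
    germline: GermlineSet,
    subject_id: str,
    sample_id: str,
    min_score: float = DEFAULT_MIN_SCORE,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate one sample's merged reads into unique rearrangements.

    ``reads`` yields ``(read_id, sequence)``.  Identical input strings are
    deduplicated before alignment (identical strings receive identical
    annotations), FR1 is trimmed using the V alignment, and records identical
    after trimming collapse into one rearrangement whose ``duplicate_count``
    is the number of input reads it absorbed.  Returns the rearrangement
    table and a counter dict accounting for every input read.
    """
    counts = {
        "input": 0,
        "unassignable": 0,
        "cdr3_failure": 0,
        "undefined_shm": 0,
        "annotated": 0,
    }
    groups: dict[str, list[str]] = {}
    for rid, seq in reads:
        counts["input"] += 1
        groups.setdefault(seq, []).append(rid)

    rows = []
    for seq in sorted(groups):
        ids = sorted(groups[seq])
        n = len(ids)
        v = assign_gene(seq, germline.v_genes, min_score)
        j = assign_gene(seq, germline.j_genes, min_score)
        if v is None or j is None:
            counts["unassignable"] += n
            continue
        cdr3 = extract_cdr3(seq, v, j)
        if cdr3 is None:
            counts["cdr3_failure"] += n
            continue
        shm = compute_shm(v, v.gene, seq)
        if shm is None:
            counts["undefined_shm"] += n
            continue
        trim = _fr1_trim_position(v, v.gene)
        trimmed = seq[trim:] if trim is not None else seq
        counts["annotated"] += n
        rows.append(
            {
                "sequence_id": ids[0],
                "subject_id": subject_id,
                "sample_id": sample_id,
                "sequence": trimmed,
                "v_call": v.gene.name,
                "j_call": j.gene.name,
                "v_identity": v.identity,
                "cdr3": cdr3[0],
                "cdr3_aa": cdr3[1],
                "productive": cdr3[2],
                "shm_percent": shm,
                "duplicate_count": n,
            }
        )
    df = pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS)
    return collapse_copies(df), counts


def collapse_copies(rearrangements: pd.DataFrame) -> pd.DataFrame:
    """Collapse rearrangements with identical (subject, sample, sequence)
    into one record, summing ``duplicate_count``.  Conserves total copies."""
    if rearrangements.empty:
        return rearrangements.copy()
    df = rearrangements.sort_values("sequence_id", kind="stable")
    keys = ["subject_id", "sample_id", "sequence"]
    agg = {c: "first" for c in df.columns if c not in keys + ["duplicate_count"]}
    agg["duplicate_count"] = "sum"
    out = df.groupby(keys, as_index=False, sort=True).agg(agg)
    return out[REARRANGEMENT_COLUMNS].reset_index(drop=True)
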