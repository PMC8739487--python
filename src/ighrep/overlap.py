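"""Clone-size filtering, tissue-overlap statistics, and SHM summaries.

The 50% mcf (mean copy-number frequency) filter excludes, within each
subject, clones whose total copy number is strictly less than half the mean
clone copy number of that subject; because the threshold is relative, using
copy *frequencies* (copies / total copies) instead of raw copies yields the
identical filtered set.

Clonal overlap between two samples is the Jaccard index over clone presence
sets — each clone counts once, disregarding size.  Within-subject pairs use
the subject's own clones; between-subject pairs pool the two subjects'
filtered rearrangements and re-cluster them jointly, so one consistent clone
definition underlies both relation types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .clones import Clone, infer_clones

SampleKey = tuple[str, str]  # (subject_id, sample_id)


@dataclass(frozen=True)
class OverlapResult:
    sample_a: SampleKey
    sample_b: SampleKey
    n_shared: int
    n_union: int
    jaccard: float
    relation: str  # "within_subject" | "between_subject"
    degenerate: bool = False  # n_union == 0

    def __post_init__(self) -> None:
        if self.n_union > 0 and not np.isclose(
            self.jaccard, self.n_shared / self.n_union
        ):
            raise ValueError("jaccard inconsistent with counts")


@dataclass
class SHMHistogram:
    tissue: str
    bin_edges: np.ndarray  # percent SHM
    counts: np.ndarray
    n_clones: int
    values: np.ndarray  # per-clone SHM values underlying the counts
    weighting: str = "per-clone copy-weighted mean SHM, per-tissue members only"

    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)

    def mean(self) -> float:
        """Mean of the per-clone SHM values underlying the histogram."""
        return float(self.values.mean()) if len(self.values) else 0.0


def filter_clones_mcf(
    clones: Sequence[Clone], fraction: float = 0.5
) -> list[Clone]:
    """Remove clones with total copies strictly below ``fraction`` × the mean
    clone copy number of their subject (equality is kept; fraction=0 is the
    identity)."""
    out: list[Clone] = []
    by_subject: dict[str, list[Clone]] = {}
    for c in clones:
        by_subject.setdefault(c.subject_id, []).append(c)
    for subject in sorted(by_subject):
        group = by_subject[subject]
        threshold = fraction * float(
            np.mean([c.total_copies for c in group])
        )
        out.extend(c for c in group if not c.total_copies < threshold)
    return out


def _presence(clones: Iterable[Clone], key: SampleKey) -> set[str]:
    return {
        c.clone_id for c in clones if c.copies_by_sample.get(key, 0) > 0
    }


def jaccard_overlap(
    clones: Sequence[Clone], sample_a: SampleKey, sample_b: SampleKey
) -> OverlapResult:
    """Clone-presence Jaccard index between two (subject, sample) labels."""
    known = {k for c in clones for k in c.copies_by_sample}
    for key in (sample_a, sample_b):
        if key not in known:
            raise ValueError(f"unknown sample label {key}")
    a, b = _presence(clones, sample_a), _presence(clones, sample_b)
    n_shared, n_union = len(a & b), len(a | b)
    return OverlapResult(
        sample_a=sample_a,
        sample_b=sample_b,
        n_shared=n_shared,
        n_union=n_union,
        jaccard=n_shared / n_union if n_union else 0.0,
        relation=(
            "within_subject"
            if sample_a[0] == sample_b[0]
            else "between_subject"
        ),
        degenerate=n_union == 0,
    )


def presence_matrix(
    clones: Sequence[Clone], samples: Sequence[SampleKey], mode: str = "clone"
) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean presence matrix of multi-sample clones.

    Rows are clones (or exact CDR3 amino-acid strings with ``mode="cdr3"``)
    present in at least two samples, ordered by descending sample support
    then total copies; returns the matrix and the per-sample total clone
    counts reported alongside it.
    """
    cols = [f"{s}_{t}" for s, t in samples]
    totals = pd.Series(
        {f"{s}_{t}": len(_presence(clones, (s, t))) for s, t in samples}
    )
    if mode == "clone":
        units: dict[str, dict] = {
            c.clone_id: {
                "keys": set(c.copies_by_sample),
                "copies": c.total_copies,
            }
            for c in clones
        }
    elif mode == "cdr3":
        units = {}
        for c in clones:
            u = units.setdefault(
                c.representative_cdr3_aa, {"keys": set(), "copies": 0}
            )
            u["keys"] |= set(c.copies_by_sample)
            u["copies"] += c.total_copies
    else:
        raise ValueError(f"unknown presence mode {mode!r}")
    rows = {
        name: u for name, u in units.items() if len(u["keys"] & set(samples)) >= 2
    }
    order = sorted(
        rows,
        key=lambda n: (-len(rows[n]["keys"]), -rows[n]["copies"], n),
    )
    data = [
        [key in rows[name]["keys"] for key in samples] for name in order
    ]
    matrix = pd.DataFrame(data, index=order, columns=cols, dtype=bool)
    return matrix, totals


def shm_histogram(
    rearrangements: pd.DataFrame,
    membership: pd.DataFrame,
    clones: Sequence[Clone],
    bin_width: float = 1.0,
    max_percent: float | None = None,
) -> dict[str, SHMHistogram]:
    """Per-tissue histogram of per-clone SHM.

    Each clone contributes to a tissue the copy-weighted mean SHM of its
    members *in that tissue only*, so tissue-spanning clones are recomputed
    per tissue rather than double-counting a global mean.
    """
    keep = {c.clone_id for c in clones}
    df = rearrangements.merge(membership, on="sequence_id")
    df = df[df["clone_id"].isin(keep)]
    if df.empty:
        return {}
    per = (
        df.assign(w=df["shm_percent"] * df["duplicate_count"])
        .groupby(["sample_id", "clone_id"])
        .agg(w=("w", "sum"), copies=("duplicate_count", "sum"))
        .reset_index()
    )
    per["clone_tissue_shm"] = per["w"] / per["copies"]
    hi = max_percent
    if hi is None:
        hi = max(bin_width, float(np.ceil(per["clone_tissue_shm"].max() + 1e-9)))
    edges = np.arange(0.0, hi + bin_width, bin_width)
    out: dict[str, SHMHistogram] = {}
    for tissue, sub in per.groupby("sample_id", sort=True):
        vals = sub["clone_tissue_shm"].to_numpy()
        counts, _ = np.histogram(np.clip(vals, 0, edges[-1] - 1e-12), bins=edges)
        out[str(tissue)] = SHMHistogram(
            tissue=str(tissue),
            bin_edges=edges,
            counts=counts,
            n_clones=len(vals),
            values=vals,
        )
    return out


def overlap_report(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """Tabulate pairwise Jaccard results with relation labels."""
    rows = [
        {
            "subject_a": r.sample_a[0],
            "sample_a": r.sample_a[1],
            "subject_b": r.sample_b[0],
            "sample_b": r.sample_b[1],
            "n_shared": r.n_shared,
            "n_union": r.n_union,
            "jaccard": r.jaccard,
            "relation": r.relation,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_a",
            "sample_a",
            "subject_b",
            "sample_b",
            "n_shared",
            "n_union",
            "jaccard",
            "relation",
        ],
    )


def overlap_analysis(
    rearrangements: pd.DataFrame,
    threshold: float = 0.85,
    mcf_fraction: float = 0.5,
    method: str = "single",
) -> dict:
    """Full Fig-style overlap analysis of an annotated rearrangement table.

    Per subject: infer clones, apply the mcf filter, and compute the
    within-subject (tissue vs tissue) Jaccard.  Between-subject pairs pool
    the two subjects' filtered rearrangements, re-cluster jointly, and
    compare each cross-subject sample pair.  Returns clones, membership,
    overlap results/report, per-sample included-clone counts, and summary
    counters.
    """
    clones, membership, counts = infer_clones(
        rearrangements, threshold=threshold, method=method
    )
    filtered = filter_clones_mcf(clones, mcf_fraction)
    kept_ids = {c.clone_id for c in filtered}
    kept_members = {
        m for c in filtered for m in c.members
    }
    filtered_rearr = rearrangements[
        rearrangements["sequence_id"].isin(kept_members)
    ]

    samples: list[SampleKey] = sorted(
        map(
            tuple,
            rearrangements[["subject_id", "sample_id"]]
            .drop_duplicates()
            .itertuples(index=False),
        )
    )
    results: list[OverlapResult] = []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            if a[0] == b[0]:
                results.append(jaccard_overlap(filtered, a, b))
    subjects = sorted({s for s, _ in samples})
    for i, sa in enumerate(subjects):
        for sb in subjects[i + 1 :]:
            pooled = filtered_rearr[
                filtered_rearr["subject_id"].isin([sa, sb])
            ]
            pooled_clones, _, _ = infer_clones(
                pooled, threshold=threshold, method=method, subject_scoped=False
            )
            for a in [s for s in samples if s[0] == sa]:
                for b in [s for s in samples if s[0] == sb]:
                    results.append(jaccard_overlap(pooled_clones, a, b))

    report = overlap_report(results)
    matrix, sample_totals = presence_matrix(filtered, samples)
    summary = {
        "rearrangements": int(len(rearrangements)),
        "non_productive": int(counts["non_productive"]),
        "clones_total": len(clones),
        "clones_after_mcf": len(filtered),
        "included_clones_per_sample": sample_totals.to_dict(),
        "jaccard_mean_within": (
            float(report[report.relation == "within_subject"].jaccard.mean())
            if (report.relation == "within_subject").any()
            else float("nan")
        ),
        "jaccard_mean_between": (
            float(report[report.relation == "between_subject"].jaccard.mean())
            if (report.relation == "between_subject").any()
            else float("nan")
        ),
    }
    return {
        "clones": clones,
        "filtered_clones": filtered,
        "membership": membership,
        "results": results,
        "report": report,
        "presence_matrix": matrix,
        "sample_totals": sample_totals,
        "summary": summary,
    }
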