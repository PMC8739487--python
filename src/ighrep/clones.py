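"""Clonal inference: bin by (V, J, CDR3 length), cluster by CDR3 identity.

A clone is the set of a subject's rearrangements sharing the same V gene,
J gene and CDR3 amino-acid length whose CDR3s link at >= 85% amino-acid
identity (1 − normalized Hamming distance; the boundary value links).
Clustering is single-linkage agglomeration — equivalently, connected
components of the pairwise-identity graph — which merges the mutational
ladder of a lineage; complete linkage is available as an alternative.
Clones are inferred per subject across that subject's samples jointly, so a
clone may span tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_THRESHOLD = 0.85


def cdr3_identity(a: str, b: str) -> float:
    """1 − normalized Hamming distance between equal-length CDR3s."""
    if len(a) != len(b):
        raise ValueError("CDR3 identity requires equal lengths")
    if not a:
        raise ValueError("empty CDR3")
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class Clone:
    clone_id: str
    subject_id: str
    v_call: str
    j_call: str
    cdr3_length: int
    members: tuple[str, ...]  # sequence_ids
    representative_cdr3_aa: str
    total_copies: int
    copies_by_sample: dict[Hashable, int]
    clone_shm_percent: float

    def __post_init__(self) -> None:
        if self.total_copies != sum(self.copies_by_sample.values()):
            raise ValueError(f"{self.clone_id}: copy totals inconsistent")


def partition_bins(
    rearrangements: pd.DataFrame,
) -> tuple[dict[tuple[str, str, int], pd.DataFrame], dict[str, int]]:
    """Partition one subject's rearrangements by (v_call, j_call, CDR3 length).

    Non-productive records are excluded and counted; the partition is exact
    over the remainder.
    """
    counts = {"input": len(rearrangements), "non_productive": 0, "binned": 0}
    if rearrangements.empty:
        return {}, counts
    prod = rearrangements[rearrangements["productive"].astype(bool)]
    counts["non_productive"] = counts["input"] - len(prod)
    counts["binned"] = len(prod)
    bins: dict[tuple[str, str, int], pd.DataFrame] = {}
    if prod.empty:
        return bins, counts
    prod = prod.assign(_cdr3_length=prod["cdr3_aa"].str.len())
    for key, sub in prod.groupby(["v_call", "j_call", "_cdr3_length"], sort=True):
        bins[(key[0], key[1], int(key[2]))] = sub.drop(columns="_cdr3_length")
    return bins, counts


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_bin(
    members: Sequence[tuple[str, str]],
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "single",
) -> list[list[str]]:
    """Cluster one bin's ``(sequence_id, cdr3_aa)`` members into clones.

    Single linkage is computed as the transitive closure of the graph linking
    pairs with identity >= threshold; complete linkage cuts a hierarchical
    dendrogram at distance 1 − threshold.  Members are sorted by sequence_id
    first, so the partition is independent of input order.
    """
    members = sorted(members)
    lengths = {len(cdr3) for _, cdr3 in members}
    if len(lengths) > 1:
        raise RuntimeError("mixed CDR3 lengths in one bin (partition violated)")
    n = len(members)
    if n == 0:
        return []
    if n == 1:
        return [[members[0][0]]]
    if method == "single":
        uf = _UnionFind(n)
        for i in range(n):
            for j in range(i + 1, n):
                if cdr3_identity(members[i][1], members[j][1]) >= threshold:
                    uf.union(i, j)
        groups: dict[int, list[str]] = {}
        for i, (sid, _) in enumerate(members):
            groups.setdefault(uf.find(i), []).append(sid)
        return [groups[r] for r in sorted(groups)]
    if method == "complete":
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - cdr3_identity(members[i][1], members[j][1])
                dist[i, j] = dist[j, i] = d
        labels = fcluster(
            linkage(squareform(dist), method="complete"),
            t=(1.0 - threshold) + 1e-9,
            criterion="distance",
        )
        groups = {}
        for i, (sid, _) in enumerate(members):
            groups.setdefault(int(labels[i]), []).append(sid)
        return [sorted(g) for _, g in sorted(groups.items())]
    raise ValueError(f"unknown linkage method {method!r}")


def clone_shm(
    shm_percents: Sequence[float], copy_numbers: Sequence[int]
) -> float:
    """Copy-weighted mean SHM over a clone's unique members."""
    w = np.asarray(copy_numbers, dtype=float)
    s = np.asarray(shm_percents, dtype=float)
    if w.sum() <= 0:
        raise ValueError("clone with zero total copies")
    return float(np.sum(s * w) / np.sum(w))


def infer_clones(
    rearrangements: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "single",
    subject_scoped: bool = True,
) -> tuple[list[Clone], pd.DataFrame, dict[str, int]]:
    """Infer clones for a rearrangement table.

    When ``subject_scoped`` (the default) each subject is clustered
    independently; otherwise all records are pooled and clustered jointly
    (used for between-subject overlap, where one consistent clone definition
    must span two subjects).  Returns (clones, membership table mapping
    sequence_id → clone_id, exclusion counts).
    """
    totals = {"input": len(rearrangements), "non_productive": 0, "binned": 0}
    proto: list[dict] = []
    scopes = (
        rearrangements.groupby("subject_id", sort=True)
        if subject_scoped and not rearrangements.empty
        else [("pooled", rearrangements)]
    )
    for scope_id, sub in scopes:
        bins, counts = partition_bins(sub)
        totals["non_productive"] += counts["non_productive"]
        totals["binned"] += counts["binned"]
        for (v, j, length), bdf in sorted(bins.items()):
            by_id = bdf.set_index("sequence_id")
            pairs = list(zip(bdf["sequence_id"], bdf["cdr3_aa"]))
            for member_ids in cluster_bin(pairs, threshold, method):
                mdf = by_id.loc[member_ids]
                rep = mdf.sort_values(
                    ["duplicate_count", "cdr3_aa"],
                    ascending=[False, True],
                    kind="stable",
                )["cdr3_aa"].iloc[0]
                copies_by_sample = (
                    mdf.groupby(["subject_id", "sample_id"])["duplicate_count"]
                    .sum()
                    .to_dict()
                )
                proto.append(
                    {
                        "scope": str(scope_id),
                        "v_call": v,
                        "j_call": j,
                        "cdr3_length": length,
                        "rep": rep,
                        "members": tuple(member_ids),
                        "copies_by_sample": {
                            k: int(c) for k, c in copies_by_sample.items()
                        },
                        "total_copies": int(mdf["duplicate_count"].sum()),
                        "shm": clone_shm(
                            mdf["shm_percent"].to_numpy(),
                            mdf["duplicate_count"].to_numpy(),
                        ),
                    }
                )
    proto.sort(
        key=lambda p: (p["scope"], p["v_call"], p["j_call"], p["cdr3_length"], p["rep"])
    )
    clones: list[Clone] = []
    membership_rows = []
    for i, p in enumerate(proto):
        cid = f"{p['scope']}_c{i + 1:05d}"
        clones.append(
            Clone(
                clone_id=cid,
                subject_id=p["scope"],
                v_call=p["v_call"],
                j_call=p["j_call"],
                cdr3_length=p["cdr3_length"],
                members=p["members"],
                representative_cdr3_aa=p["rep"],
                total_copies=p["total_copies"],
                copies_by_sample=p["copies_by_sample"],
                clone_shm_percent=p["shm"],
            )
        )
        membership_rows.extend(
            {"sequence_id": sid, "clone_id": cid} for sid in p["members"]
        )
    membership = pd.DataFrame(membership_rows, columns=["sequence_id", "clone_id"])
    return clones, membership, totals


def clones_to_df(clones: Iterable[Clone]) -> pd.DataFrame:
    """Flatten clones to a table; per-sample copies become
    ``copies_<subject>_<sample>`` columns."""
    rows = []
    for c in clones:
        row = {
            "clone_id": c.clone_id,
            "subject_id": c.subject_id,
            "v_call": c.v_call,
            "j_call": c.j_call,
            "cdr3_length": c.cdr3_length,
            "representative_cdr3_aa": c.representative_cdr3_aa,
            "total_copies": c.total_copies,
            "clone_shm_percent": c.clone_shm_percent,
            "n_members": len(c.members),
        }
        for (subj, sample), n in sorted(c.copies_by_sample.items()):
            row[f"copies_{subj}_{sample}"] = n
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)
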