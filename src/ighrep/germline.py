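"""Germline V/J gene reference: types, FASTA I/O, and a toy set generator.

The reference dialect stores the CDR3 anchor and FR1 boundary directly in the
FASTA header as ``key=value`` tokens::

    >IGHV1-1 segment=V cdr3_anchor=288 fr1_end=75
    CAGGTGCAG...

``cdr3_anchor`` is the 0-based index of the first base of the conserved
anchor codon (Cys for V genes, Trp/Phe for J genes); ``fr1_end`` (V only) is
one past the last FR1 base.  All coordinates are 0-based, half-open, and the
anchor is a multiple-of-3 offset from the gene's reading-frame start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

_NT = frozenset("ACGT")
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


class GermlineError(ValueError):
    """Raised when a germline record or set violates the reference contract."""


@dataclass(frozen=True)
class GermlineGene:
    """One annotated germline V or J segment."""

    name: str
    segment: str  # "V" or "J"
    sequence: str
    cdr3_anchor: int
    fr1_end: int | None = None  # V genes only

    def __post_init__(self) -> None:
        if self.segment not in ("V", "J"):
            raise GermlineError(f"{self.name}: segment must be 'V' or 'J'")
        bad = set(self.sequence) - _NT
        if bad:
            raise GermlineError(f"{self.name}: non-ACGT characters {sorted(bad)}")
        if self.cdr3_anchor < 0 or self.cdr3_anchor % 3 != 0:
            raise GermlineError(
                f"{self.name}: cdr3_anchor={self.cdr3_anchor} must be a "
                "non-negative multiple of 3"
            )
        if len(self.sequence) < self.cdr3_anchor + 3:
            raise GermlineError(
                f"{self.name}: sequence too short to contain the anchor codon"
            )
        if self.segment == "V":
            if self.fr1_end is None:
                raise GermlineError(f"{self.name}: V gene requires fr1_end")
            if not 0 <= self.fr1_end <= self.cdr3_anchor:
                raise GermlineError(
                    f"{self.name}: fr1_end={self.fr1_end} outside "
                    f"[0, cdr3_anchor={self.cdr3_anchor}]"
                )
        elif self.fr1_end is not None:
            raise GermlineError(f"{self.name}: fr1_end is V-only")

    @property
    def anchor_codon(self) -> str:
        return self.sequence[self.cdr3_anchor : self.cdr3_anchor + 3]


@dataclass(frozen=True)
class GermlineSet:
    """A validated collection of V and J germline genes."""

    v_genes: tuple[GermlineGene, ...]
    j_genes: tuple[GermlineGene, ...]
    id: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.v_genes or not self.j_genes:
            raise GermlineError("germline set needs at least one V and one J gene")
        names = [g.name for g in self.v_genes + self.j_genes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GermlineError(f"duplicate gene names: {sorted(dupes)}")
        for g in self.v_genes:
            if g.segment != "V":
                raise GermlineError(f"{g.name}: non-V gene in v_genes")
        for g in self.j_genes:
            if g.segment != "J":
                raise GermlineError(f"{g.name}: non-J gene in j_genes")

    def __getitem__(self, name: str) -> GermlineGene:
        for g in self.v_genes + self.j_genes:
            if g.name == name:
                return g
        raise KeyError(name)


_HEADER_RE = re.compile(r"(\w+)=(\S+)")


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    parts = description.split()
    name = parts[0]
    tokens = dict(_HEADER_RE.findall(" ".join(parts[1:])))
    return name, tokens


def load_germline_set(path: str | Path, set_id: str | None = None) -> GermlineSet:
    """Load and validate a germline set from an annotated FASTA file.

    Raises :class:`GermlineError` naming the offending record on any
    malformed header, non-ACGT character, or out-of-range anchor.
    """
    path = Path(path)
    v_genes: list[GermlineGene] = []
    j_genes: list[GermlineGene] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, tokens = _parse_header(rec.description)
        if "segment" not in tokens or "cdr3_anchor" not in tokens:
            raise GermlineError(
                f"{name}: header must carry segment= and cdr3_anchor= tokens"
            )
        segment = tokens["segment"]
        try:
            anchor = int(tokens["cdr3_anchor"])
        except ValueError:
            raise GermlineError(f"{name}: cdr3_anchor is not an integer") from None
        fr1_end: int | None = None
        if segment == "V":
            if "fr1_end" not in tokens:
                raise GermlineError(f"{name}: V gene header missing fr1_end=")
            fr1_end = int(tokens["fr1_end"])
        gene = GermlineGene(
            name=name,
            segment=segment,
            sequence=str(rec.seq).upper(),
            cdr3_anchor=anchor,
            fr1_end=fr1_end,
        )
        (v_genes if segment == "V" else j_genes).append(gene)
    return GermlineSet(
        v_genes=tuple(v_genes),
        j_genes=tuple(j_genes),
        id=set_id or path.stem,
    )


def write_germline_set(gset: GermlineSet, path: str | Path) -> None:
    """Write a germline set in the annotated-FASTA dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for g in gset.v_genes + gset.j_genes:
            header = f">{g.name} segment={g.segment} cdr3_anchor={g.cdr3_anchor}"
            if g.segment == "V":
                header += f" fr1_end={g.fr1_end}"
            fh.write(header + "\n")
            fh.write(g.sequence + "\n")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions over the shorter of two sequences."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


# Toy set geometry: 25 FR1 codons, 71 further V codons, Cys anchor codon.
_V_FR1_CODONS = 25
_V_BODY_CODONS = 71
_J_TAIL_CODONS = 15


def make_toy_germline_set(
    n_v: int, n_j: int, seed: int, set_id: str = "toy"
) -> GermlineSet:
    """Generate a deterministic toy germline set for simulation and testing.

    V genes are 97 codons (291 nt) ending in a Cys anchor (TGT), with
    ``fr1_end=75`` and ``cdr3_anchor=288``; J genes start with a Trp anchor
    (TGG) followed by 15 codons.  Random codons exclude stops, and V genes are
    regenerated until all pairs are < 90% identical, so gene assignment is
    unambiguous at low mutation loads.
    """
    if n_v < 1 or n_j < 1:
        raise GermlineError("need n_v >= 1 and n_j >= 1")
    rng = np.random.default_rng(seed)

    def random_codons(n: int) -> str:
        return "".join(rng.choice(_CODONS) for _ in range(n))

    v_genes: list[GermlineGene] = []
    for i in range(n_v):
        for _attempt in range(100):
            seq = random_codons(_V_FR1_CODONS + _V_BODY_CODONS) + "TGT"
            if all(pairwise_identity(seq, g.sequence) < 0.90 for g in v_genes):
                break
        else:  # pragma: no cover - 100 random draws always suffice
            raise GermlineError("could not generate sufficiently distinct V genes")
        v_genes.append(
            GermlineGene(
                name=f"TOYV{i + 1}",
                segment="V",
                sequence=seq,
                cdr3_anchor=3 * (_V_FR1_CODONS + _V_BODY_CODONS),
                fr1_end=3 * _V_FR1_CODONS,
            )
        )
    j_genes = [
        GermlineGene(
            name=f"TOYJ{i + 1}",
            segment="J",
            sequence="TGG" + random_codons(_J_TAIL_CODONS),
            cdr3_anchor=0,
        )
        for i in range(n_j)
    ]
    return GermlineSet(tuple(v_genes), tuple(j_genes), id=set_id)


def toy_germline_path() -> Path:
    """Path of the packaged toy reference ``toy_igh_v1`` (8 V, 4 J genes)."""
    return Path(__file__).parent / "data" / "toy_igh_v1.fasta"


def load_toy_germline_set() -> GermlineSet:
    return load_germline_set(toy_germline_path(), set_id="toy_igh_v1")
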