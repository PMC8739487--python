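"""Ground-truth repertoire and paired-read simulator.

Emulates the study design the analysis assumes: several subjects (mice), two
tissue samples per subject (bone marrow ``BM`` and small-intestine lamina
propria ``siLP``), clonally expanded lineages with V/J/CDR3 structure, a
controllable fraction of clones shared between a subject's two tissues,
per-sequence somatic hypermutation (SHM) on the V segment, heavy-tailed
copy numbers, and a sequencing-error / quality model that exercises every
downstream QC rule.

With within-subject sharing fraction ``s`` and ``N`` clones per sample, the
number of tissue-shared clones per subject is Binomial(N, s), so each sample
holds exactly N clones, the union holds 2N − shared, and the expected
clone-level Jaccard index between the two tissues is s/(2 − s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .germline import _STOP_CODONS, GermlineGene, GermlineSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODONS_NOSTOP = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)

TRUTH_COLUMNS = [
    "seq_id",
    "subject_id",
    "sample_id",
    "clone_id",
    "v_call",
    "j_call",
    "cdr3",
    "cdr3_aa",
    "shm_percent",
    "copy_number",
    "sequence",
]


class SimConfigError(ValueError):
    """Raised for impossible or invalid simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated experiment.

    Defaults describe a plausible murine IgA plasma-cell experiment: a few
    subjects, BM and siLP sampled per subject, a measurable within-subject
    tissue-sharing fraction, SHM loads typical of gut-derived IgA lineages,
    and geometric (heavy-tailed) expansion of unique sequences and copies.
    """

    n_subjects: int = 4
    samples_per_subject: tuple[str, ...] = ("BM", "siLP")
    clones_per_sample: int = 100
    sharing_fraction: float = 0.2
    between_subject_sharing: float = 0.0
    shm_rate: float = 0.02
    seqs_per_clone: tuple[str, dict] = ("geometric", {"mean": 3.0})
    copies_per_seq: tuple[str, dict] = ("geometric", {"mean": 3.0})
    read_error_rate: float = 0.001
    frac_low_quality_reads: float = 0.02
    low_quality_base_rate: float = 0.002
    read_length: int = 300
    cdr3_codon_range: tuple[int, int] = (8, 22)
    mutate_cdr3: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "sharing_fraction": self.sharing_fraction,
            "between_subject_sharing": self.between_subject_sharing,
            "shm_rate": self.shm_rate,
            "read_error_rate": self.read_error_rate,
            "frac_low_quality_reads": self.frac_low_quality_reads,
            "low_quality_base_rate": self.low_quality_base_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name}={p} not in [0, 1]")
        if self.n_subjects < 1 or self.clones_per_sample < 1:
            raise SimConfigError("counts must be >= 1")
        if self.read_length < 50:
            raise SimConfigError("read_length must be >= 50")
        if len(self.samples_per_subject) < 2 and self.sharing_fraction > 0:
            raise SimConfigError(
                "sharing_fraction > 0 requires at least two samples per subject"
            )
        lo, hi = self.cdr3_codon_range
        if not 1 <= lo <= hi:
            raise SimConfigError("invalid cdr3_codon_range")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator: one record per unique sequence.

    ``records`` maps every emitted read id prefix (``subject|sample|clone|seq``)
    to its true clone, V/J genes, CDR3, SHM percent and copy number.
    """

    records: pd.DataFrame
    config: SimConfig

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path, config: SimConfig | None = None) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", dtype={"cdr3": str, "cdr3_aa": str})
        return SimTruth(records=df, config=config or SimConfig())


def _draw_count(rng: np.random.Generator, dist: tuple[str, dict]) -> int:
    name, params = dist
    if name == "geometric":
        mean = float(params.get("mean", 3.0))
        if mean < 1.0:
            raise SimConfigError("geometric mean must be >= 1")
        return int(rng.geometric(1.0 / mean))
    if name == "constant":
        return int(params["value"])
    raise SimConfigError(f"unknown count distribution {name!r}")


def _random_cdr3(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(
        _CODONS_NOSTOP[i]
        for i in rng.integers(0, len(_CODONS_NOSTOP), size=n_codons)
    )


def _translate(nt: str) -> str:
    from .annotate import translate_nt  # local import to avoid cycle

    return translate_nt(nt)


def _mutate_seq(
    rng: np.random.Generator, seq: str, positions: np.ndarray, rate: float
) -> tuple[str, np.ndarray]:
    """Substitute each listed position independently at `rate`; return
    the mutated sequence and the positions actually changed."""
    if rate <= 0 or len(positions) == 0:
        return seq, np.empty(0, dtype=int)
    hit = positions[rng.random(len(positions)) < rate]
    if len(hit) == 0:
        return seq, hit
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for p in hit:
        old = arr[p]
        choices = _BASES[_BASES != old]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode(), hit


@dataclass(frozen=True)
class _Founder:
    clone_id: str
    v: GermlineGene
    j: GermlineGene
    cdr3: str
    cdr3_aa: str


def _make_founder(
    rng: np.random.Generator, germline: GermlineSet, config: SimConfig, clone_id: str
) -> _Founder:
    lo, hi = config.cdr3_codon_range
    v = germline.v_genes[rng.integers(len(germline.v_genes))]
    j = germline.j_genes[rng.integers(len(germline.j_genes))]
    cdr3 = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
    return _Founder(clone_id, v, j, cdr3, _translate(cdr3))


def simulate_repertoire(
    config: SimConfig, germline: GermlineSet
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate unique rearranged sequences with full ground truth.

    Returns ``(records, truth)`` where ``records`` holds one row per unique
    sequence (annotation-level truth: V/J call, CDR3, SHM percent, copy
    number, full amplicon nucleotide sequence) and ``truth`` wraps the same
    table with the generating configuration.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    prior_founders: list[_Founder] = []

    for si in range(config.n_subjects):
        subject = f"M{si + 1}"
        n = config.clones_per_sample
        n_shared = int(rng.binomial(n, config.sharing_fraction))
        shared = [
            _make_founder(rng, germline, config, f"{subject}:S{k}")
            for k in range(n_shared)
        ]
        per_sample: dict[str, list[_Founder]] = {}
        new_founders: list[_Founder] = list(shared)
        for sample in config.samples_per_subject:
            private: list[_Founder] = []
            for k in range(n - n_shared):
                if (
                    prior_founders
                    and rng.random() < config.between_subject_sharing
                ):
                    donor = prior_founders[rng.integers(len(prior_founders))]
                    private.append(donor)
                else:
                    f = _make_founder(
                        rng, germline, config, f"{subject}:{sample}:P{k}"
                    )
                    private.append(f)
                    new_founders.append(f)
            per_sample[sample] = shared + private
        prior_founders.extend(new_founders)

        for sample in config.samples_per_subject:
            for founder in per_sample[sample]:
                n_seq = max(1, _draw_count(rng, config.seqs_per_clone))
                for k in range(n_seq):
                    v = founder.v
                    v_part = v.sequence[: v.cdr3_anchor + 3]
                    # SHM over the whole V (FR1 included, anchor codon spared)
                    v_positions = np.arange(v.cdr3_anchor)
                    v_mut, hit = _mutate_seq(
                        rng, v_part, v_positions, config.shm_rate
                    )
                    cdr3 = founder.cdr3
                    if config.mutate_cdr3:
                        cdr3, _ = _mutate_seq(
                            rng, cdr3, np.arange(len(cdr3)), config.shm_rate
                        )
                    window = v.cdr3_anchor - v.fr1_end
                    n_window = int(
                        np.sum((hit >= v.fr1_end) & (hit < v.cdr3_anchor))
                    )
                    shm = 100.0 * n_window / window if window else 0.0
                    amplicon = (
                        v_mut + cdr3 + founder.j.sequence[founder.j.cdr3_anchor :]
                    )
                    copies = max(1, _draw_count(rng, config.copies_per_seq))
                    seq_id = f"{subject}|{sample}|{founder.clone_id}|{k}"
                    rows.append(
                        {
                            "seq_id": seq_id,
                            "subject_id": subject,
                            "sample_id": sample,
                            "clone_id": founder.clone_id,
                            "v_call": v.name,
                            "j_call": founder.j.name,
                            "cdr3": cdr3,
                            "cdr3_aa": _translate(cdr3),
                            "shm_percent": shm,
                            "copy_number": copies,
                            "sequence": amplicon,
                        }
                    )

    records = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return records, SimTruth(records=records, config=config)


def _phred_string(quals: np.ndarray) -> str:
    return (quals.astype(np.uint8) + 33).tobytes().decode("ascii")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _read_qualities(
    rng: np.random.Generator, n: int, low_quality: bool, base_rate: float
) -> np.ndarray:
    if low_quality:
        return rng.integers(20, 30, size=n)
    q = rng.integers(35, 41, size=n)
    if base_rate > 0:
        drop = rng.random(n) < base_rate
        q[drop] = rng.integers(2, 30, size=int(drop.sum()))
    return q


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    mutated, _ = _mutate_seq(rng, seq, np.arange(len(seq)), rate)
    return mutated


def emit_reads(
    records: pd.DataFrame,
    config: SimConfig,
    out1: str | Path,
    out2: str | Path,
) -> int:
    """Write overlapping paired-end FASTQ reads (Phred+33) for every copy of
    every unique sequence.  Read ids encode the truth key as
    ``subject|sample|clone|seq/copy``.  Returns the number of pairs written.
    """
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    n_pairs = 0
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for row in records.itertuples(index=False):
            amplicon = row.sequence
            for c in range(int(row.copy_number)):
                rid = f"{row.seq_id}/c{c}"
                m1 = _apply_errors(rng, amplicon[:rl], config.read_error_rate)
                m2 = _apply_errors(
                    rng, _revcomp(amplicon[-rl:]), config.read_error_rate
                )
                low = rng.random() < config.frac_low_quality_reads
                q1 = _read_qualities(rng, len(m1), low, config.low_quality_base_rate)
                q2 = _read_qualities(rng, len(m2), low, config.low_quality_base_rate)
                f1.write(f"@{rid}\n{m1}\n+\n{_phred_string(q1)}\n")
                f2.write(f"@{rid}\n{m2}\n+\n{_phred_string(q2)}\n")
                n_pairs += 1
    return n_pairs


def emit_reads_per_sample(
    records: pd.DataFrame, config: SimConfig, outdir: str | Path
) -> pd.DataFrame:
    """Write one FASTQ pair per (subject, sample) and return a manifest
    DataFrame with columns fastq1, fastq2, subject_id, sample_id."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    keys = (
        records[["subject_id", "sample_id"]]
        .drop_duplicates()
        .sort_values(["subject_id", "sample_id"])
    )
    for i, (subject, sample) in enumerate(keys.itertuples(index=False)):
        sub = records[
            (records.subject_id == subject) & (records.sample_id == sample)
        ]
        f1 = outdir / f"{subject}_{sample}_R1.fastq"
        f2 = outdir / f"{subject}_{sample}_R2.fastq"
        per_cfg = replace(config, seed=config.seed + 1000 + i)
        emit_reads(sub, per_cfg, f1, f2)
        manifest_rows.append(
            {
                "fastq1": str(f1),
                "fastq2": str(f2),
                "subject_id": subject,
                "sample_id": sample,
            }
        )
    return pd.DataFrame(manifest_rows)
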