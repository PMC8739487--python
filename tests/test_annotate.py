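import numpy as np
import pandas as pd
import pytest

from conftest import truth_as_rearrangements
from ighrep.annotate import (
    annotate_sample,
    assign_gene,
    collapse_copies,
    compute_shm,
    extract_cdr3,
    translate_nt,
)

_OTHER = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = _OTHER[out[p]]
    return "".join(out)


def _amplicon(v, j, cdr3):
    return v.sequence[: v.cdr3_anchor + 3] + cdr3 + j.sequence[j.cdr3_anchor :]


def test_exact_germline_assigned_with_identity_one(toy_germline):
    v = toy_germline.v_genes[0]
    call = assign_gene(v.sequence, toy_germline.v_genes)
    assert call.gene.name == v.name
    assert call.identity == 1.0


def test_three_substitutions_keep_assignment_with_reduced_identity(toy_germline):
    v = toy_germline.v_genes[2]
    seq = _mutate(v.sequence, [10, 100, 200])
    call = assign_gene(seq, toy_germline.v_genes)
    assert call.gene.name == v.name
    assert call.identity == pytest.approx((len(v.sequence) - 3) / len(v.sequence))


def test_random_sequence_is_unassignable(toy_germline):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT")) for _ in range(300))
    assert assign_gene(seq, toy_germline.v_genes) is None


def test_cdr3_matches_simulator_truth(toy_germline, small_sim):
    records, _, _ = small_sim
    for row in records.head(40).itertuples(index=False):
        v_call = assign_gene(row.sequence, toy_germline.v_genes)
        j_call = assign_gene(row.sequence, toy_germline.j_genes)
        cdr3_nt, cdr3_aa, productive = extract_cdr3(row.sequence, v_call, j_call)
        assert cdr3_nt == row.cdr3
        assert cdr3_aa == row.cdr3_aa
        assert productive


def test_in_frame_stop_codon_marks_non_productive(toy_germline):
    v, j = toy_germline.v_genes[0], toy_germline.j_genes[0]
    seq = _amplicon(v, j, "TAA" + "GCA" * 9)
    vc = assign_gene(seq, toy_germline.v_genes)
    jc = assign_gene(seq, toy_germline.j_genes)
    _, aa, productive = extract_cdr3(seq, vc, jc)
    assert not productive
    assert "*" in aa


def test_out_of_frame_junction_marks_non_productive(toy_germline):
    v, j = toy_germline.v_genes[0], toy_germline.j_genes[0]
    seq = _amplicon(v, j, "GCAGC" * 6 + "GC")  # 32 nt, not divisible by 3
    vc = assign_gene(seq, toy_germline.v_genes)
    jc = assign_gene(seq, toy_germline.j_genes)
    result = extract_cdr3(seq, vc, jc)
    assert result is not None
    assert result[2] is False


def test_shm_percent_is_mismatches_over_compared_window(toy_germline):
    v, j = toy_germline.v_genes[1], toy_germline.j_genes[1]
    window = v.cdr3_anchor - v.fr1_end
    positions = [v.fr1_end + 3, v.fr1_end + 50, v.fr1_end + 101, v.fr1_end + 150]
    seq = _amplicon(v, j, "GCA" * 12)
    seq = _mutate(seq, positions)
    vc = assign_gene(seq, toy_germline.v_genes)
    assert compute_shm(vc, vc.gene, seq) == pytest.approx(100 * 4 / window)


def test_fr1_mutations_do_not_affect_shm(toy_germline):
    v, j = toy_germline.v_genes[1], toy_germline.j_genes[1]
    seq = _mutate(_amplicon(v, j, "GCA" * 12), [0, 10, 20, 30])  # FR1 only
    vc = assign_gene(seq, toy_germline.v_genes)
    assert compute_shm(vc, vc.gene, seq) == 0.0


def test_fully_masked_window_gives_undefined_shm(toy_germline):
    v, j = toy_germline.v_genes[1], toy_germline.j_genes[1]
    seq = _amplicon(v, j, "GCA" * 12)
    masked = seq[: v.fr1_end] + "N" * (v.cdr3_anchor - v.fr1_end) + seq[v.cdr3_anchor :]
    vc = assign_gene(masked, toy_germline.v_genes)
    assert compute_shm(vc, vc.gene, masked) is None


def test_masked_bases_excluded_from_shm_numerator_and_denominator(toy_germline):
    v, j = toy_germline.v_genes[1], toy_germline.j_genes[1]
    seq = _mutate(_amplicon(v, j, "GCA" * 12), [v.fr1_end + 10])
    # additionally mask 13 window positions
    s = list(seq)
    for p in range(v.fr1_end + 30, v.fr1_end + 43):
        s[p] = "N"
    seq = "".join(s)
    vc = assign_gene(seq, toy_germline.v_genes)
    window = v.cdr3_anchor - v.fr1_end
    assert compute_shm(vc, vc.gene, seq) == pytest.approx(100 * 1 / (window - 13))


def test_collapse_identical_and_distinct_sequences():
    base = {
        "subject_id": "M1",
        "sample_id": "BM",
        "v_call": "V",
        "j_call": "J",
        "v_identity": 1.0,
        "cdr3": "GCA",
        "cdr3_aa": "A",
        "productive": True,
        "shm_percent": 0.0,
        "duplicate_count": 1,
    }
    rows = [
        {**base, "sequence_id": f"r{i}", "sequence": "AAAA"} for i in range(5)
    ] + [
        {**base, "sequence_id": f"d{i}", "sequence": f"CCC{b}"}
        for i, b in enumerate("ACGTA")
    ]
    df = pd.DataFrame(rows)
    out = collapse_copies(df)
    assert out.duplicate_count.sum() == len(df)  # conservation
    collapsed = out[out.sequence == "AAAA"]
    assert len(collapsed) == 1 and collapsed.duplicate_count.iloc[0] == 5
    assert (out[out.sequence != "AAAA"].duplicate_count <= 2).all()


def test_annotate_sample_recovers_truth_calls_and_shm(toy_germline, small_sim):
    records, _, config = small_sim
    sub = records[(records.subject_id == "M1") & (records.sample_id == "BM")]
    reads = [(r.seq_id, r.sequence) for r in sub.itertuples(index=False)]
    rearr, counts = annotate_sample(reads, toy_germline, "M1", "BM")
    assert counts["unassignable"] == 0
    assert counts["input"] == len(sub)
    assert rearr.duplicate_count.sum() == len(sub)
    truth = truth_as_rearrangements(sub)
    merged = rearr.merge(
        truth, on="sequence_id", suffixes=("_obs", "_true")
    )
    assert (merged.v_call_obs == merged.v_call_true).all()
    assert (merged.j_call_obs == merged.j_call_true).all()
    assert (merged.cdr3_obs == merged.cdr3_true).all()
    assert np.allclose(merged.shm_percent_obs, merged.shm_percent_true)


def test_population_shm_mean_matches_simulated_rate(toy_germline):
    from ighrep.simulate import SimConfig, simulate_repertoire

    rate, window = 0.015, 213
    cfg = SimConfig(n_subjects=1, clones_per_sample=60, shm_rate=rate, seed=31)
    records, _ = simulate_repertoire(cfg, toy_germline)
    sub = records[records.sample_id == "BM"]
    reads = [(r.seq_id, r.sequence) for r in sub.itertuples(index=False)]
    rearr, _ = annotate_sample(reads, toy_germline, "M1", "BM")
    n = len(rearr)
    se = 100 * np.sqrt(rate * (1 - rate) / window / n)
    assert abs(rearr.shm_percent.mean() - 100 * rate) < 3 * se


def test_translate_nt_handles_ns_and_stops():
    assert translate_nt("GCTTAAGNA") == "A*X"
    assert translate_nt("GC") == ""
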