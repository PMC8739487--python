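import numpy as np
import pytest

from conftest import truth_as_rearrangements
from ighrep.clones import Clone
from ighrep.overlap import (
    filter_clones_mcf,
    jaccard_overlap,
    overlap_analysis,
    overlap_report,
    presence_matrix,
    shm_histogram,
)


def _clone(cid, copies_by_sample, subject="M1", shm=1.0, **kw):
    total = sum(copies_by_sample.values())
    return Clone(
        clone_id=cid,
        subject_id=subject,
        v_call=kw.get("v_call", "V1"),
        j_call=kw.get("j_call", "J1"),
        cdr3_length=12,
        members=(cid + "_m",),
        representative_cdr3_aa=kw.get("cdr3", "A" * 12),
        total_copies=total,
        copies_by_sample=copies_by_sample,
        clone_shm_percent=shm,
    )


BM, LP = ("M1", "BM"), ("M1", "siLP")


def test_mcf_filter_spec_fixture_retains_two_of_three():
    clones = [
        _clone("c1", {BM: 10}),
        _clone("c2", {BM: 10}),
        _clone("c3", {BM: 1}),
    ]
    kept = filter_clones_mcf(clones)  # mean 7, threshold 3.5
    assert [c.clone_id for c in kept] == ["c1", "c2"]


def test_mcf_filter_keeps_equal_copy_clones_and_singletons():
    clones = [_clone(f"c{i}", {BM: 4}) for i in range(5)]
    assert len(filter_clones_mcf(clones)) == 5
    assert len(filter_clones_mcf([_clone("only", {BM: 1})])) == 1


def test_mcf_filter_boundary_equality_is_kept():
    # copies [2, 2, 4]: mean 8/3, threshold 4/3; with fraction 0.75 the
    # threshold is exactly 2 and 'less than' is strict, so 2-copy clones stay
    clones = [
        _clone("a", {BM: 2}),
        _clone("b", {BM: 2}),
        _clone("c", {BM: 4}),
    ]
    kept = filter_clones_mcf(clones, fraction=0.75)
    assert [c.clone_id for c in kept] == ["a", "b", "c"]


def test_mcf_fraction_zero_is_identity():
    rng = np.random.default_rng(0)
    clones = [
        _clone(f"c{i}", {BM: int(n)})
        for i, n in enumerate(rng.integers(1, 50, size=30))
    ]
    assert filter_clones_mcf(clones, fraction=0.0) == clones


def test_mcf_filter_is_per_subject():
    clones = [
        _clone("a1", {BM: 100}, subject="M1"),
        _clone("a2", {BM: 1}, subject="M1"),
        _clone("b1", {("M2", "BM"): 1}, subject="M2"),
    ]
    kept = filter_clones_mcf(clones)
    # M2's singleton is its own mean and survives; M1's does not
    assert {c.clone_id for c in kept} == {"a1", "b1"}


def test_jaccard_identical_disjoint_and_partial_sets():
    both = [_clone(c, {BM: 1, LP: 1}) for c in "xyz"]
    assert jaccard_overlap(both, BM, LP).jaccard == 1.0

    split = [_clone("x", {BM: 1}), _clone("y", {LP: 1})]
    assert jaccard_overlap(split, BM, LP).jaccard == 0.0

    mixed = [
        _clone("a", {BM: 1}),
        _clone("b", {BM: 1, LP: 2}),
        _clone("c", {BM: 3, LP: 1}),
        _clone("d", {LP: 1}),
    ]
    res = jaccard_overlap(mixed, BM, LP)
    assert res.n_shared == 2 and res.n_union == 4
    assert res.jaccard == 0.5
    assert res.relation == "within_subject"


def test_jaccard_symmetric():
    mixed = [
        _clone("a", {BM: 1}),
        _clone("b", {BM: 1, LP: 2}),
        _clone("d", {LP: 1}),
    ]
    ab = jaccard_overlap(mixed, BM, LP)
    ba = jaccard_overlap(mixed, LP, BM)
    assert ab.jaccard == ba.jaccard
    assert ab.n_shared == ba.n_shared


def test_jaccard_unknown_sample_label_rejected():
    with pytest.raises(ValueError, match="unknown sample"):
        jaccard_overlap([_clone("a", {BM: 1})], BM, ("M1", "spleen"))


def test_presence_matrix_empty_and_single_row():
    singles = [_clone("a", {BM: 1}), _clone("b", {LP: 1})]
    matrix, totals = presence_matrix(singles, [BM, LP])
    assert matrix.empty
    assert totals.to_dict() == {"M1_BM": 1, "M1_siLP": 1}

    spanning = singles + [_clone("c", {BM: 2, LP: 1})]
    matrix, _ = presence_matrix(spanning, [BM, LP])
    assert list(matrix.index) == ["c"]
    assert matrix.loc["c"].all()


def test_presence_matrix_row_count_matches_direct_enumeration(small_sim):
    records, _, _ = small_sim
    analysis = overlap_analysis(truth_as_rearrangements(records))
    filtered = analysis["filtered_clones"]
    expected = sum(1 for c in filtered if len(c.copies_by_sample) >= 2)
    assert len(analysis["presence_matrix"]) == expected


def test_shm_histogram_all_zero_shm_in_first_bin(small_sim):
    records, _, _ = small_sim
    rearr = truth_as_rearrangements(records).assign(shm_percent=0.0)
    analysis = overlap_analysis(rearr)
    hists = shm_histogram(rearr, analysis["membership"], analysis["filtered_clones"])
    for h in hists.values():
        assert h.counts[0] == h.counts.sum() == h.n_clones


def test_shm_histogram_counts_sum_to_contributing_clones(small_sim):
    records, _, _ = small_sim
    rearr = truth_as_rearrangements(records)
    analysis = overlap_analysis(rearr)
    hists = shm_histogram(rearr, analysis["membership"], analysis["filtered_clones"])
    assert set(hists) == {"BM", "siLP"}
    for h in hists.values():
        assert h.counts.sum() == h.n_clones
        assert np.all(np.diff(h.bin_edges) > 0)


def test_within_subject_overlap_exceeds_between_when_sharing(toy_germline):
    from ighrep.simulate import SimConfig, simulate_repertoire

    cfg = SimConfig(
        n_subjects=3,
        clones_per_sample=60,
        sharing_fraction=0.4,
        between_subject_sharing=0.0,
        seed=19,
    )
    records, _ = simulate_repertoire(cfg, toy_germline)
    analysis = overlap_analysis(truth_as_rearrangements(records), mcf_fraction=0.0)
    report = analysis["report"]
    within = report[report.relation == "within_subject"].jaccard
    between = report[report.relation == "between_subject"].jaccard
    assert len(within) == 3 and len(between) > 0
    assert within.min() > between.max()
    assert between.max() <= 0.02


def test_no_sharing_anywhere_gives_zero_overlap(toy_germline):
    from ighrep.simulate import SimConfig, simulate_repertoire

    cfg = SimConfig(
        n_subjects=2, clones_per_sample=40, sharing_fraction=0.0, seed=21
    )
    records, _ = simulate_repertoire(cfg, toy_germline)
    analysis = overlap_analysis(truth_as_rearrangements(records), mcf_fraction=0.0)
    assert (analysis["report"].jaccard == 0.0).all()


def test_overlap_report_structure(small_sim):
    records, _, _ = small_sim
    analysis = overlap_analysis(truth_as_rearrangements(records))
    report = analysis["report"]
    assert set(report.relation) == {"within_subject", "between_subject"}
    assert (report.jaccard >= 0).all() and (report.jaccard <= 1).all()
    summary = analysis["summary"]
    assert summary["clones_after_mcf"] <= summary["clones_total"]
    assert set(summary["included_clones_per_sample"]) == {
        "M1_BM", "M1_siLP", "M2_BM", "M2_siLP",
    }
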