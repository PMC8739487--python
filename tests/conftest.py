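import pytest

from ighrep.germline import load_toy_germline_set
from ighrep.simulate import SimConfig, simulate_repertoire


@pytest.fixture(scope="session")
def toy_germline():
    return load_toy_germline_set()


@pytest.fixture(scope="session")
def small_sim(toy_germline):
    """A small, error-free simulated repertoire with known ground truth."""
    config = SimConfig(
        n_subjects=2,
        clones_per_sample=25,
        sharing_fraction=0.4,
        shm_rate=0.01,
        read_error_rate=0.0,
        frac_low_quality_reads=0.0,
        low_quality_base_rate=0.0,
        seed=11,
    )
    records, truth = simulate_repertoire(config, toy_germline)
    return records, truth, config


def truth_as_rearrangements(records):
    """Reshape simulator truth records into the rearrangement table schema,
    bypassing read emission / QC / annotation."""
    df = records.rename(
        columns={"seq_id": "sequence_id", "copy_number": "duplicate_count"}
    ).copy()
    df["productive"] = True
    df["v_identity"] = 1.0
    return df[
        [
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
    ]
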