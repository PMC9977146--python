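import numpy as np
import pytest

from shmclass import SimulationConfig, simulate_cohort
from shmclass.airr_io import RearrangementRecord, Repertoire


def make_record(
    sequence_id="seq1",
    germline="ATGCATGCA",
    observed=None,
    v_call="IGHV1-1*01",
    j_call="IGHJ1*01",
    junction="TGTGCGTGG",
    junction_aa="CAW",
    **kwargs,
):
    return RearrangementRecord(
        sequence_id=sequence_id,
        v_call=v_call,
        j_call=j_call,
        junction=junction,
        junction_aa=junction_aa,
        sequence_alignment=observed if observed is not None else germline,
        germline_alignment=germline,
        **kwargs,
    )


@pytest.fixture
def toy_repertoire():
    """Three records over two V families with distinct junctions."""
    recs = [
        make_record("a", junction="TGTGCGAAATGG", junction_aa="CAKW",
                    v_call="IGHV1-2*02", duplicate_count=2),
        make_record("b", junction="TGTGCGAAATGG", junction_aa="CAKW",
                    v_call="IGHV1-2*02", duplicate_count=7),
        make_record("c", junction="TGTTTTTTTTGG", junction_aa="CFFW",
                    v_call="IGHV3-23*01", j_call="IGHJ4*01"),
    ]
    return Repertoire("toy", recs)


@pytest.fixture(scope="session")
def small_cohort():
    """Null synthetic cohort: 3+3 subjects, 120 sequences each."""
    config = SimulationConfig(
        subjects_per_group=3, n_sequences=120, master_seed=11,
        record_mutations=False,
    )
    cohort, truth = simulate_cohort(config)
    return cohort, truth


@pytest.fixture
def rng():
    # function-scoped: every test sees the same fresh stream regardless of
    # which other tests ran before it
    return np.random.default_rng(2024)
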