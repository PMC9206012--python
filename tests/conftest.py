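import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from famscan import SequenceRecord
from famscan.synthetic import generate_expression_matrix, generate_protein_with_fingers


@pytest.fixture
def one_finger_protein():
    rec, truth = generate_protein_with_fingers(
        1, spacer_plan=[(2, 2, 12, 2)], linker_len=10, seed=11
    )
    return rec, truth


@pytest.fixture(scope="session")
def planted_module():
    """40-transcript family module at pairwise correlation 0.9 over 42
    genotype-shaped samples, plus an independent background pool."""
    fam, truth = generate_expression_matrix(
        40, 0, module_correlation=0.9, seed=101
    )
    bg, _ = generate_expression_matrix(0, 120, module_correlation=0.9, seed=102)
    return fam, bg, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_protein(seq: str, seq_id: str = "p") -> SequenceRecord:
    return SequenceRecord(seq_id, seq, "protein")
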