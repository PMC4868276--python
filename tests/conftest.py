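import pytest

from acetylsite.records import ProteinRecord, SubstitutionMatrix, extract_window
from acetylsite.simulate import make_worked_example


def window_from(seq: str, center: int, L: int = 6, pid: str = "p"):
    """Build a window from a raw sequence string (1-based centre)."""
    return extract_window(ProteinRecord(pid, seq), center, L)


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def worked_example():
    """One 40-residue protein, 2 positive + 2 negative lysines, full profiles."""
    return make_worked_example()
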