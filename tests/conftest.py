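import numpy as np
import pytest

from barcodekey.seq_panel import DnaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20211201)


@pytest.fixture
def write_text(tmp_path):
    def _write(name: str, content: str):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def toy_table():
    """Four closely related 60 bp sequences with one unique SNP in sp1."""
    base = "ATGGCGTACGTTAGCCTAGGCATCGATCGGATTACAGCTAGGCTTAACGGTCCATGCAAT"
    assert len(base) == 60 and base[30] == "A"
    mutated = base[:30] + "C" + base[31:]
    return {
        "sp1": DnaSequence("sp1", mutated),
        "sp2": DnaSequence("sp2", base),
        "sp3": DnaSequence("sp3", base),
        "sp4": DnaSequence("sp4", base),
    }
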