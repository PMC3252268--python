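import numpy as np
import pytest

from arescore import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20120105)


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "utrs.fa"
    path.write_text(
        ">utr1 first record\n"
        "AUUUAUUUAG\n"
        ">utr2\n"
        "GCGCGCGCGCGC\n"
        ">utr3\n"
        "AUUUAGCGCAUUUA\n"
    )
    return path


@pytest.fixture
def records():
    return [
        SequenceRecord("utr1", "AUUUAUUUAG"),
        SequenceRecord("utr2", "GCGCGCGCGCGC"),
        SequenceRecord("utr3", "AUUUAGCGCAUUUA"),
    ]
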