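import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from islepair.seq_io import build_alignment, write_codon_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20160630)


@pytest.fixture
def fasta_writer(tmp_path):
    """Write (id, seq) pairs to a temp FASTA and return the path."""

    def _write(pairs, name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in pairs:
                fh.write(f">{sid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def simple_alignment():
    """Two sequences, one synonymous difference (TTT/TTC), no masking."""
    return build_alignment(
        [("a", "ATGTTTGGA"), ("b", "ATGTTCGGA")], genetic_code="standard"
    )


def random_sense_sequence(rng, n_codons, code_name="standard"):
    from oracles import sense_codons

    codons = sense_codons(code_name)
    return "".join(rng.choice(codons) for _ in range(n_codons))
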