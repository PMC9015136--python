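from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import idpseq

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"


@pytest.fixture(scope="session")
def asyn() -> idpseq.ProteinSequence:
    """Canonical 140-residue alpha-synuclein (UniProt P37840), bundled."""
    return idpseq.read_fasta(EXAMPLES / "P37840_SNCA_HUMAN.fasta")[0]


@pytest.fixture
def random_sequences():
    """Reproducible uniform-composition sequences of assorted lengths."""

    def make(n: int, min_len: int = 9, max_len: int = 300, seed: int = 0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            residues = "".join(rng.choice(list(idpseq.STANDARD_AA), size=length))
            out.append(idpseq.ProteinSequence(f"rand{i}", residues))
        return out

    return make


@pytest.fixture
def fasta_file(tmp_path):
    def make(records, name="input.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, residues in records:
                fh.write(f">{rec_id}\n{residues}\n")
        return path

    return make
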