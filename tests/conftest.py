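import numpy as np
import pytest

import phoskit as pk


@pytest.fixture(scope="session")
def sim_proteome():
    """A small simulated annotated proteome shared across tests."""
    spec = pk.SimulationSpec(n_proteins=40, seed=7)
    return pk.simulate(spec)


@pytest.fixture(scope="session")
def balanced_sets(sim_proteome):
    proteins, _ = sim_proteome
    return pk.build_balanced_sets(proteins, "S", replicates=3, seed=11)


@pytest.fixture()
def fasta_file(tmp_path):
    """Factory writing FASTA text and returning its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture()
def tsv_file(tmp_path):
    def _write(text, name="sites.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
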