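import numpy as np
import pytest

from porethru import peptide as pep
from porethru import trace_synth as ts


@pytest.fixture(scope="session")
def ptm():
    return pep.load_ptm()


@pytest.fixture
def write_fasta(tmp_path):
    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for title, seq in entries:
                fh.write(f">{title}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def noiseless_trace():
    """A clean two-level trace with its ground-truth ledger."""
    gating = ts.GatingModel(k_on0=10.0, alpha_on=0.0, tau0=5e-3, alpha_off=0.0)
    config = ts.TraceConfig(
        duration=20.0, sampling_rate=50_000.0, noise_sd=0.0,
        filter_cutoff=None, seed=7,
    )
    trace, ledger = ts.simulate_trace(gating, config, concentration_uM=1.0, V_mV=0.0)
    return trace, ledger, config
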