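import numpy as np
import pytest

from nucbarrier.polymer import PolymerParams, TetherComposition
from nucbarrier.hopping import TrapModel


@pytest.fixture(scope="session")
def hopping_params():
    return PolymerParams.preset("hopping")


@pytest.fixture(scope="session")
def fitted_params():
    return PolymerParams.preset("fitted")


@pytest.fixture(scope="session")
def unzip_comp():
    return TetherComposition(n_ds_bp=1850)


@pytest.fixture(scope="session")
def hopping_comp():
    return TetherComposition(n_ds_bp=1848)


@pytest.fixture(scope="session")
def trap():
    return TrapModel()


@pytest.fixture(scope="session")
def linker_table():
    """Warm the (expensive) linker-energy cache once per session."""
    from nucbarrier.ratchet import linker_energy_table

    return linker_energy_table()


@pytest.fixture(scope="session")
def txn_trace_ensemble():
    """Shared ensemble of ratchet-model transcription traces (uniform phi)."""
    from nucbarrier.ratchet import InteractionProfile
    from nucbarrier.synth import gen_txn_trace

    phi = InteractionProfile(np.ones(147))
    return [gen_txn_trace(phi, seed=100 + i) for i in range(5)]


@pytest.fixture(scope="session")
def registered_ensemble(txn_trace_ensemble):
    """The shared ensemble registered with the consensus ruler period."""
    from nucbarrier.txn import register_ensemble

    return register_ensemble(txn_trace_ensemble)
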