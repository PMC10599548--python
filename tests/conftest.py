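import dataclasses

import numpy as np
import pytest

from oddnet import GenParams, ModelParams, Network, calibrate_epsp


@pytest.fixture(scope="session")
def calibrated_params() -> ModelParams:
    """Model parameters with the EPSP scale fitted once for the session."""
    _, scale = calibrate_epsp(ModelParams())
    return dataclasses.replace(ModelParams(), epsp_scale=scale)


@pytest.fixture(scope="session")
def small_gen_params() -> GenParams:
    """A scaled-down generator: same geometry, fewer neurons."""
    return GenParams(n_exc=120, n_inh=30, min_responders=60, seed=7)


def build_chain_network(n: int = 6, all_excitatory: bool = True) -> Network:
    """A hand-built feed-forward chain 0 -> 1 -> ... -> n-1 for oracles."""
    positions = np.column_stack([np.linspace(0, 1, n), np.zeros(n)])
    synapses = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    return Network(
        positions=positions,
        is_excitatory=np.full(n, all_excitatory),
        synapses=synapses,
        site_centers=np.zeros((1, 2)),
        stimulated_sets=np.array([[0]], dtype=np.int64),
        seed=0,
        gen_params=GenParams(n_exc=n, n_inh=0, n_sites=1, n_stimulated=1, min_responders=1),
    )
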