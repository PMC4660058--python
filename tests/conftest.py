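import numpy as np
import pytest

from bfckinetics import (
    BarbedEndState,
    FMNL2,
    FlowProtocol,
    SolutionCondition,
    simulate_population,
)

PA_CHASE = SolutionCondition(actin=1.0, profilin=4.0, label="chase")


@pytest.fixture(scope="session")
def fmnl2_decay_population():
    """1e5 filaments starting in the ternary state, profilin-actin chase.

    Shared by the distributional checks (exit-time law, branching
    probability, appearance-curve convergence) and the branch-fraction
    recovery test; expensive enough to simulate once per session.
    """
    protocol = FlowProtocol(((1500.0, PA_CHASE),))
    traces = simulate_population(
        100_000, protocol, FMNL2, initial_state=BarbedEndState.BFC, master_seed=2024
    )
    return protocol, traces


@pytest.fixture(scope="session")
def fmnl2_decay_exit_times(fmnl2_decay_population):
    _, traces = fmnl2_decay_population
    return np.array([tr.transitions[0][0] for tr in traces if tr.transitions])
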