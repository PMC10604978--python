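import numpy as np
import pytest

from dwgc.paradigm import Block, Paradigm, generate_paradigm
from dwgc.synthetic import SimulationConfig, simulate_roi_series


@pytest.fixture
def mi_paradigm():
    """TR 2 s, 10 s task blocks, 20 s rests, 4 blocks over MIL/MIR."""
    return generate_paradigm(2.0, 10.0, 20.0, ["MIL", "MIR"], 4, seed=7)


@pytest.fixture
def constant_task_paradigm():
    """A single 1200 s task block (constant coupling throughout)."""
    return Paradigm(
        tr_seconds=2.0,
        blocks=[Block("task", 0.0, 1200.0)],
        total_duration_s=1200.0,
    )


def coupled_config(n_nodes=2, coupling=0.8, conditions=("task",), seed=0, **kwargs):
    """One-way coupling node0 -> node1 active during the given conditions."""
    C = np.zeros((n_nodes, n_nodes))
    C[1, 0] = coupling
    return SimulationConfig(
        n_nodes=n_nodes,
        base_ar_coeffs=np.full(n_nodes, 0.3),
        coupling_schedule={c: C for c in conditions},
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def coupled_series(constant_task_paradigm):
    """HRF-convolved 2-node run with node0 -> node1 coupling 0.8."""
    series, truth = simulate_roi_series(
        coupled_config(seed=11), constant_task_paradigm
    )
    return series, truth
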