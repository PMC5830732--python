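import numpy as np
import pytest

from hillgrn.dynamics import simulate
from hillgrn.estimator import TimeSeriesData
from hillgrn.model import GeneNetwork, ParameterSet


@pytest.fixture(scope="session")
def two_gene_case():
    """Small negative-feedback loop with a rich, identifiable trajectory."""
    network = GeneNetwork(("g1", "g2"), [(0, 1, 1), (1, 0, -1)])
    truth = ParameterSet(P=[5.0, 4.0], S=[0.30, 0.25], Q=[6.0, 8.0], R=[2.0, 2.0])
    x0 = np.array([1.0, 1.0])
    times = np.linspace(0.0, 60.0, 25)
    traj = simulate(network, truth, x0, (0.0, 60.0), grid=times)
    data = TimeSeriesData(times, traj.states, gene_names=network.gene_names)
    return {"network": network, "truth": truth, "data": data, "trajectory": traj}


@pytest.fixture(scope="session")
def three_gene_case():
    """3-gene / 4-edge feedback instance used by the recovery harness.

    Thresholds sit inside the range each regulator sweeps, so synthesis,
    degradation and threshold parameters are all practically identifiable
    from one trajectory.
    """
    network = GeneNetwork(
        ("g1", "g2", "g3"), [(0, 1, 1), (1, 2, 1), (2, 0, -1), (2, 2, -1)]
    )
    truth = ParameterSet(
        P=[6.0, 4.0, 5.0],
        S=[0.35, 0.25, 0.30],
        Q=[4.0, 9.0, 6.0, 6.0],
        R=[1.9, 2.1, 1.95, 2.15],
    )
    x0 = np.array([2.0, 1.0, 1.0])
    times = np.linspace(0.0, 60.0, 25)
    traj = simulate(network, truth, x0, (0.0, 60.0), grid=times)
    data = TimeSeriesData(times, traj.states, gene_names=network.gene_names)
    return {"network": network, "truth": truth, "data": data, "trajectory": traj}
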