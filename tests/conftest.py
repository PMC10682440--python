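import numpy as np
import pytest

from bcgdose.model import ModelParameters, X0_DEFAULT
from bcgdose.regimen import CostWeights
from bcgdose import koopman as kp


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def x0():
    return X0_DEFAULT.copy()


@pytest.fixture(scope="session")
def weights(params, x0):
    """Cost weights with the untreated-maximum normalization precomputed."""
    return CostWeights.for_model(params, x0)


@pytest.fixture(scope="session")
def koopman_model(params):
    """Surrogate fitted on the full training design (100 runs, 100 days)."""
    ds = kp.generate_training_data(params, n_traj=100, seed=42)
    centers = kp.fit_centers(ds, k=10, seed=42)
    return kp.fit_koopman(ds, centers)


@pytest.fixture(scope="session")
def held_out_run(params):
    """One nominal trajectory from the training distribution, unseen seed."""
    ds = kp.generate_training_data(params, n_traj=1, seed=777)
    return ds.trajectories[0]


def make_arx_dataset(seed=3, n_traj=3, length=300):
    """Delay-embedded linear (ARX) process whose extended-state dynamics are
    exactly linear: y+ = a1*y + a2*y- + a3*y-- + b1*u + b2*u- + b3*u--.

    Returns (dataset, true A (5x5), true B (5,)) in the layout
    [y_k, y_{k-1}, y_{k-2}, u_{k-1}, u_{k-2}].
    """
    a1, a2, a3 = 0.6, 0.2, 0.1
    b1, b2, b3 = 0.5, 0.2, 0.1
    rng = np.random.default_rng(seed)
    trajs = []
    for _ in range(n_traj):
        y = np.zeros(length)
        u = rng.normal(size=length)
        y[:3] = rng.normal(size=3)
        for k in range(2, length - 1):
            y[k + 1] = (a1 * y[k] + a2 * y[k - 1] + a3 * y[k - 2]
                        + b1 * u[k] + b2 * u[k - 1] + b3 * u[k - 2])
        # define a full "state" as a fixed linear map of the extended state
        x = np.column_stack([y, np.roll(y, 1), np.roll(u, 1), np.roll(u, 2)])
        trajs.append(kp.TrajectoryData(y=y, x=x, u=u))
    a_true = np.array([
        [a1, a2, a3, b2, b3],
        [1.0, 0, 0, 0, 0],
        [0, 1.0, 0, 0, 0],
        [0, 0, 0, 0, 0],
        [0, 0, 0, 1.0, 0],
    ])
    b_true = np.array([b1, 0.0, 0.0, 1.0, 0.0])
    return kp.TrainingDataset(trajs, dt=1.0, seed=seed), a_true, b_true


@pytest.fixture(scope="session")
def arx_dataset():
    return make_arx_dataset()
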