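import numpy as np
import pytest

import mpcluster as mpc


def random_irreducible_counts(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dense positive count matrix — trivially irreducible."""
    return rng.integers(1, 50, size=(n, n)).astype(np.int64)


def random_model(rng: np.random.Generator, n: int) -> mpc.MicrostateModel:
    counts = random_irreducible_counts(rng, n)
    cm = mpc.CountMatrix(counts=counts, lag=1, populations=counts.sum(axis=1))
    T = mpc.transition_matrix(cm)
    pi = mpc.stationary_distribution(T)
    return mpc.MicrostateModel(
        T=T, pi=pi, E=mpc.free_energies(pi), populations=cm.populations
    )


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    X = rng.uniform(0, 10, size=(n, 2))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1) ** 2
    np.fill_diagonal(D, 0.0)
    return D


@pytest.fixture(scope="session")
def three_basin_dataset():
    spec = mpc.make_three_basin_landscape()
    return mpc.metropolis_trajectories(spec, n_traj=100, n_steps=2000, seed=1)


@pytest.fixture(scope="session")
def three_basin_result(three_basin_dataset):
    return mpc.run_pipeline(three_basin_dataset.trajectories, mpc.RunConfig(seed=1))


@pytest.fixture(scope="session")
def alanine_dataset():
    spec = mpc.make_alanine_like_landscape()
    return mpc.metropolis_trajectories(spec, n_traj=200, n_steps=5000, seed=1)


@pytest.fixture(scope="session")
def alanine_result(alanine_dataset):
    return mpc.run_pipeline(alanine_dataset.trajectories, mpc.RunConfig(seed=1))


def well_of_label(result, dataset, label: int) -> str:
    """Ground-truth well name of the basin a cluster label lives in."""
    spec = dataset.spec
    original_bin = result.model.state_map[label]
    return spec.well_names[dataset.ground_truth[original_bin]]
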