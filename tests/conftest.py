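import numpy as np
import pytest

import seqmvpa as sm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_separated_betas(k=4, n_runs=8, n_voxels=20, sep=10.0, noise=0.1, seed=0):
    """Well-separated class patterns with small run-wise noise."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0, sep, size=(k, n_voxels))
    return means[:, None, :] + rng.normal(0, noise, size=(k, n_runs, n_voxels))


def null_betas(n_voxels=160, n_runs=8, seed=0, v_common=1.0, v_run=0.1, v_trial=0.2):
    """Patterns with no condition-specific signal."""
    gt = sm.make_ground_truth(
        n_voxels, v_common, 0.0, v_run, v_trial, d=1, geometry="random", rng_seed=seed
    )
    return sm.simulate_betas(gt, n_runs, rng_seed=seed + 100_000)
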