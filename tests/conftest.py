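"""Shared fixtures: synthetic regions, baseline runs, and a fast step grid.

Expensive artefacts (the 28-year default run, the calibration refits) are
session-scoped so the invariant tests and the acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mhsd import (
    default_configs,
    default_params,
    simulate,
)

#: coarse step (days) used where a test checks structure, not convergence
FAST_DT = 3.5


@pytest.fixture(scope="session")
def configs():
    return default_configs()


@pytest.fixture(scope="session")
def hne_config(configs):
    return configs[0]


@pytest.fixture()
def params():
    return default_params()


@pytest.fixture(scope="session")
def baseline_traj_28y(configs):
    """Default 28-year run of the larger region at the canonical step."""
    return simulate(configs[0], default_params(), t_end=28.0)


@pytest.fixture(scope="session")
def baseline_traj_28y_half_dt(configs):
    return simulate(configs[0], default_params(), t_end=28.0, dt_days=0.21875)


@pytest.fixture(scope="session")
def recovery_bundle():
    """Noiseless and noisy Powell refits of the synthetic-truth fixture."""
    from mhsd import recovery_fixture
    from mhsd.calibration import fit

    fx = recovery_fixture(seed=1)
    cfg = fx.configs[0]
    noiseless = fit(
        cfg, fx.params, fx.targets_noiseless, fx.free, fx.bounds,
        seed=1, restarts=2, max_iter=40,
    )
    noisy = fit(
        cfg, fx.params, fx.targets_noisy, fx.free, fx.bounds,
        seed=1, restarts=2, max_iter=40,
    )
    return fx, noiseless, noisy


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
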