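import numpy as np
import pandas as pd
import pytest

from paeecal import RunConfig, generate_dataset, run_pipeline
from paeecal.synthetic import NoiseConfig


@pytest.fixture(scope="session")
def default_bundle():
    """Report bundle from one default (noisy) end-to-end run."""
    return run_pipeline(RunConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Report bundle from a fully deterministic (noiseless) run."""
    return run_pipeline(RunConfig(seed=7, noiseless=True))


@pytest.fixture(scope="session")
def small_dataset():
    """A 3-participant single-group dataset for fast I/O and plumbing tests."""
    from paeecal.synthetic import GroupSpec

    specs = [GroupSpec(label="control", n=3, rmr_mean=1846, rmr_sd=191,
                       rest_hr_mean=54, rest_hr_sd=4, body_mass_mean=80,
                       body_mass_sd=7)]
    return generate_dataset(seed=11, group_specs=specs, noise=NoiseConfig())


@pytest.fixture
def toy_records():
    """Four hand-checkable calibration records (one participant each)."""
    return pd.DataFrame(
        {
            "participant": ["a", "b", "c", "d"],
            "pac": [0.0, 2000.0, 4000.0, 6000.0],
            "hr": [60.0, 90.0, 100.0, 130.0],
            "criterion_paee": [0.1, 2.0, 3.9, 6.2],
        }
    )


def normal_equations(pac, hr, y):
    """Independent OLS oracle: solve the normal equations explicitly."""
    A = np.column_stack([np.ones(len(y)), pac, hr])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, float))
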