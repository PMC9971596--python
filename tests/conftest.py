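import numpy as np
import pandas as pd
import pytest

from psmcea import ArmSimSpec, EconomicInputs, simulate_arm
from psmcea.config import config_from_dict


@pytest.fixture(scope="session")
def base_inputs() -> EconomicInputs:
    return EconomicInputs()


@pytest.fixture(scope="session")
def medium_arm():
    """One simulated arm with mild dropout, shared by fitting tests.

    The OS endpoint carries the undistorted Weibull(1.3, 12) marginal; the
    PFS endpoint is constrained below it and is only used where the
    constraint itself is under test.
    """
    spec = ArmSimSpec(
        label="fit-fixture", n_subjects=1000,
        pfs_shape=1.3, pfs_scale=12.0, os_shape=1.3, os_scale=12.0,
        censor_rate=0.025, max_followup=60.0, seed=2024,
    )
    return simulate_arm(spec)


@pytest.fixture()
def toy_occupancy():
    """Hand-built three-cycle occupancy for economics arithmetic."""
    return pd.DataFrame(
        {
            "cycle": [0, 1, 2],
            "t_days": [0.0, 21.0, 42.0],
            "t_months": np.array([0, 1, 2]) * 21 / 30.4375,
            "pfs": [1.0, 0.6, 0.3],
            "pd": [0.0, 0.3, 0.4],
            "death": [0.0, 0.1, 0.3],
        }
    )


@pytest.fixture(scope="session")
def fast_config():
    """A small synthetic two-arm configuration for pipeline-level tests."""
    return config_from_dict(
        {
            "seed": 7,
            "digitize_points": 120,
            "arms": {
                "arm1": {
                    "label": "treat",
                    "km_cutoff_cycles": {"pfs": 20, "os": 20},
                    "simulate": {
                        "n_subjects": 120, "pfs_shape": 1.3, "pfs_scale": 18.0,
                        "os_shape": 1.5, "os_scale": 26.0, "censor_rate": 0.01,
                        "max_followup": 20.0, "seed": 1,
                    },
                },
                "arm0": {
                    "label": "control",
                    "km_cutoff_cycles": {"pfs": 20, "os": 20},
                    "simulate": {
                        "n_subjects": 120, "pfs_shape": 1.4, "pfs_scale": 12.0,
                        "os_shape": 1.5, "os_scale": 23.0, "censor_rate": 0.01,
                        "max_followup": 20.0, "seed": 2,
                    },
                },
            },
            "psa": {"n_draws": 60},
        }
    )
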