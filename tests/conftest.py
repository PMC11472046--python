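import numpy as np
import pandas as pd
import pytest

import hpdyn


@pytest.fixture(scope="session")
def chp2_like_data():
    """~1e4 steps of 2-state motion at the slow/fast regime of a chromatin
    reader (D = 0.007 / 0.13 um^2/s, ~92.5% slow), unconfined so the data
    match the free-diffusion emission model exactly."""
    cfg = hpdyn.SimConfig(
        K=2,
        D=(0.007, 0.13),
        T_frame=((0.99, 0.01), (0.1233, 0.8767)),
        sigma_loc=0.02,
        R_nuc=None,
        p_bleach=0.05,
        n_tracks=520,
        seed=42,
    )
    return hpdyn.simulate_trajectories(cfg)


@pytest.fixture(scope="session")
def single_state_data():
    cfg = hpdyn.SimConfig(
        K=1, D=(0.05,), T_frame=((1.0,),), sigma_loc=0.02, R_nuc=None,
        p_bleach=0.1, n_tracks=300, seed=7,
    )
    return hpdyn.simulate_trajectories(cfg)


@pytest.fixture
def tiny_tracks():
    """Hand-built 2-track TrajectorySet with one ROI."""
    df = pd.DataFrame(
        {
            "track_id": [0, 0, 0, 1, 1],
            "frame": [0, 1, 2, 0, 1],
            "x_um": [0.0, 0.1, 0.2, -0.1, -0.2],
            "y_um": [0.0, 0.0, 0.1, 0.0, 0.1],
            "cell_id": [0, 0, 0, 0, 0],
        }
    )
    rois = pd.DataFrame({"cell_id": [0], "cx_um": [0.0], "cy_um": [0.0], "r_um": [1.0]})
    return hpdyn.TrajectorySet(df=df, dt_frame=0.04, sigma_loc=0.02, rois=rois)
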