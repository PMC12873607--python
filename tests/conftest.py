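import pandas as pd
import pytest

from dnmt1spt.config import AcquisitionConfig, DetectionConfig, FitConfig
from dnmt1spt.simulate import GroundTruthModel, SimulatedDataset, simulate_trajectories


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def model():
    return GroundTruthModel()


@pytest.fixture(scope="session")
def three_state_dataset(model, acq):
    """Moderate-size mixture dataset shared across read-only tests."""
    return simulate_trajectories(model, acq, 3000, seed=1234)


@pytest.fixture()
def detection_cfg():
    return DetectionConfig()


@pytest.fixture()
def fit_cfg():
    return FitConfig()


def make_static_dataset(positions_um, n_frames, acq, cell_id="cell_0"):
    """Dataset of immobile ground-truth emitters at given (x, y) per frame,
    used as an injection oracle for rendering/localization tests."""
    rows = []
    tid = 0
    for f in range(n_frames):
        for (x, y) in positions_um:
            rows.append((tid, f, x, y))
            tid += 1
    df = pd.DataFrame(rows, columns=["trajectory_id", "frame",
                                     "x_true_um", "y_true_um"])
    df["x_um"] = df["x_true_um"]
    df["y_um"] = df["y_true_um"]
    df["cell_id"] = cell_id
    df["true_state"] = "bound"
    df["molecule_id"] = df["trajectory_id"]
    df["z_um"] = 0.0
    return SimulatedDataset(df, GroundTruthModel(), acq, 0)
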