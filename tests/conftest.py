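import numpy as np
import pandas as pd
import pytest

from mixsync import CellTrackSet


def make_track_set(positions: np.ndarray, dt_frame: float = 1.0) -> CellTrackSet:
    """Build a CellTrackSet from a (frames, cells, 3) position array."""
    F, N, _ = positions.shape
    df = pd.DataFrame({
        "track_id": np.tile(np.arange(N), F),
        "frame": np.repeat(np.arange(F), N),
        "x_um": positions[:, :, 0].ravel(),
        "y_um": positions[:, :, 1].ravel(),
        "z_um": positions[:, :, 2].ravel(),
    })
    return CellTrackSet(df, dt_frame=dt_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_track_toy() -> CellTrackSet:
    """Track 0 stays at the origin; track 1 walks in from x=30 to x=2."""
    frames = np.arange(8)
    pos = np.zeros((8, 2, 3))
    pos[:, 1, 0] = 30.0 - 4.0 * frames
    return make_track_set(pos)
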