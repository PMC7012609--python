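import numpy as np
import pandas as pd
import pytest

from cmekinetics import MovieMeta


@pytest.fixture
def movie():
    """Standard single-channel acquisition: 300x300 px, 601 frames, 1 fps."""
    return MovieMeta(width=300, height=300, n_frames=601, frame_rate=1.0)


@pytest.fixture
def small_movie():
    return MovieMeta(width=120, height=120, n_frames=150, frame_rate=1.0)


def make_track(track_id, frames, x, y, amplitude=1.0, channel="ch0"):
    """Build track-table rows for one track; scalars are broadcast."""
    frames = np.asarray(frames)
    n = frames.size
    return pd.DataFrame(
        {
            "track_id": track_id,
            "channel": channel,
            "frame": frames,
            "x": np.broadcast_to(np.asarray(x, float), n).copy(),
            "y": np.broadcast_to(np.asarray(y, float), n).copy(),
            "amplitude": np.broadcast_to(np.asarray(amplitude, float), n).copy(),
        }
    )


@pytest.fixture
def make_tracks():
    return make_track
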