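import numpy as np
import pytest

from gaitrisk import GaitSimParams, generate_walk, preprocess


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free symmetric walk, no turns; step time exactly 25 frames."""
    params = GaitSimParams(
        duration=60.0, cadence=120.0, step_time_asymmetry=1.0,
        noise_sd=0.0, turn_duration=0.0, seed=1,
    )
    rec, events = generate_walk(params)
    return preprocess(rec), events


@pytest.fixture(scope="session")
def noisy_walk():
    """Default-condition walk with sensor noise, asymmetry and turns."""
    rec, events = generate_walk(GaitSimParams(duration=120.0, seed=5))
    return preprocess(rec), events


@pytest.fixture(scope="session")
def step_table(noisy_walk):
    from gaitrisk import step_features

    rec, events = noisy_walk
    return step_features(rec, events)


def strike_offsets(pred_frames: np.ndarray, truth_frames: np.ndarray) -> np.ndarray:
    """Distance (frames) from each true strike to its nearest prediction."""
    if len(pred_frames) == 0:
        return np.full(len(truth_frames), np.inf)
    return np.min(np.abs(np.asarray(truth_frames)[:, None] - np.asarray(pred_frames)[None, :]), axis=1)
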