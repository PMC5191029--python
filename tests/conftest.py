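import numpy as np
import pandas as pd
import pytest

from hhtar import features, pamap2, synth


def make_raw_frame(
    n: int,
    activity: int | np.ndarray = 1,
    fs: float = 100.0,
    t0: float = 0.0,
    channel_values: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Raw 54-column records with unit accelerometer channels by default."""
    df = pd.DataFrame(np.nan, index=range(n), columns=list(pamap2.RAW_COLUMNS))
    df["timestamp"] = t0 + np.arange(n) / fs
    df["activity_id"] = np.broadcast_to(np.asarray(activity, dtype=int), (n,)).copy()
    for sensor in ("wrist", "chest", "ankle"):
        for axis in ("x", "y", "z"):
            col = f"{sensor}_acc16_{axis}"
            df[col] = 1.0
            if channel_values and f"{sensor}_{axis}" in channel_values:
                df[col] = channel_values[f"{sensor}_{axis}"]
    return df


@pytest.fixture(scope="session")
def demo_windows() -> pamap2.WindowSet:
    """Windows of the seeded 4-class synthetic recording."""
    stream = synth.generate_stream(synth.demo_config(seed=1))
    frames_df = pd.DataFrame(np.nan, index=range(stream.n_samples),
                             columns=list(pamap2.RAW_COLUMNS))
    frames_df["timestamp"] = stream.timestamps
    frames_df["activity_id"] = stream.activity_ids
    for c, col in enumerate(synth.ACC16_COLUMNS):
        frames_df[pamap2.RAW_COLUMNS[col]] = stream.channels[c]
    frames = pamap2.preprocess(frames_df, subject_id=1)
    return pamap2.segment(frames)


@pytest.fixture(scope="session")
def demo_features(demo_windows) -> features.FeatureMatrix:
    """Full IE-MS-IAIF feature matrix of the seeded 4-class recording.

    Session-scoped: the EMD of ~200 windows x 9 channels dominates the
    suite's runtime and is shared by the feature and end-to-end tests.
    """
    return features.extract_features(demo_windows, spec="ie-ms-iaif")
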