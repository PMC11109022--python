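import io

import numpy as np
import pytest

from audiencesync import (
    AudienceRecording,
    ExpressionTrack,
    ParticipantInfo,
)


def make_track(participant_id, values, frame_rate=50.0):
    """Track from an (n_frames, 8) array; NaN rows become invalid frames."""
    return ExpressionTrack(participant_id, frame_rate, np.asarray(values, float))


def make_recording(arrays, frame_rate=50.0, seats=None, info=None,
                   performance_id="test"):
    """Recording from a list of (n_frames, 8) arrays; seats default to row 0."""
    tracks = [make_track(f"p{i:02d}", a, frame_rate) for i, a in enumerate(arrays)]
    ids = [t.participant_id for t in tracks]
    if seats is None:
        seats = {pid: (0, i) for i, pid in enumerate(ids)}
    if info is None:
        info = {
            pid: ParticipantInfo(age=30.0, gender="female", empathy_total=20.0,
                                 questionnaires_complete=True)
            for pid in ids
        }
    return AudienceRecording(performance_id, tracks, seats, info)


def random_masked_arrays(rng, n_participants, n_frames, missing_frac=0.1):
    """Random valid tracks with randomly invalid frames."""
    arrays = []
    for _ in range(n_participants):
        x = rng.random((n_frames, 8))
        drop = rng.random(n_frames) < missing_frac
        x[drop] = np.nan
        arrays.append(x)
    return arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    return make_recording(random_masked_arrays(rng, 4, 400))


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")
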