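import numpy as np
import pytest

from cardiovoice import BeatSeries, FormantTrack


def make_beats(times, participant_id="p001", screen_index=1, rng=None):
    """BeatSeries with physiologically plausible filler measures."""
    times = np.asarray(times, dtype=float)
    n = times.size
    d = np.diff(times)
    ibi = np.concatenate([[d[0]], d])
    rng = rng or np.random.default_rng(0)
    with np.errstate(divide="ignore"):  # invalid ibi is exercised on purpose
        hr = 60.0 / ibi
    sbp = rng.normal(120, 5, n)
    dbp = sbp - rng.normal(45, 3, n)
    mp = dbp + (sbp - dbp) / 3
    sv = rng.normal(75, 5, n)
    co = hr * sv / 1000
    measures = np.column_stack(
        [hr, sbp, dbp, mp, ibi, sv, rng.normal(1.5, 0.1, n), co, mp / co, rng.normal(1000, 50, n)]
    )
    return BeatSeries(participant_id, screen_index, times, measures)


def make_track(duration_s=5.0, participant_id="p001", screen_index=1, rng=None, start=0.005):
    rng = rng or np.random.default_rng(1)
    t = np.arange(start, duration_s, 0.010)
    f = np.column_stack(
        [
            rng.normal(500, 30, t.size),
            rng.normal(1500, 60, t.size),
            rng.normal(2500, 80, t.size),
        ]
    )
    return FormantTrack(participant_id, screen_index, t, np.abs(f) + 1.0)


@pytest.fixture
def beats_07s():
    """Ten beats 0.7 s apart starting at 0.7 s."""
    return make_beats(0.7 * np.arange(1, 11))


@pytest.fixture
def track_8s():
    return make_track(8.0)
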