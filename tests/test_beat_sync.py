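import numpy as np
import pytest
from scipy import stats as sstats

from cardiovoice import (
    BeatFeatureMatrix,
    assign_frames,
    beat_formant_features,
    cardio_features,
    fuse,
    track_stats,
)
from cardiovoice.beat_sync import WindowError

from conftest import make_beats, make_track


def brute_stats(values, times, tau):
    """Naive-formula oracle: explicit normal equations + direct moments."""
    y = np.asarray(values, float)
    s = np.asarray(times, float) - tau
    A = np.column_stack([s**2, s, np.ones_like(s)])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    n = y.size
    mu = y.sum() / n
    m2 = ((y - mu) ** 2).sum() / n
    std = np.sqrt(((y - mu) ** 2).sum() / (n - 1))
    if m2 == 0:
        skew, kurt = 0.0, 3.0
    else:
        skew = (((y - mu) ** 3).sum() / n) / m2**1.5
        kurt = (((y - mu) ** 4).sum() / n) / m2**2
    return np.array(
        [coef[0], coef[1], coef[2], y.min(), y.max(), mu, np.median(y), std, skew, kurt]
    )


class TestAssignFrames:
    def test_windows_tile_and_own_each_frame_once(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            times = np.cumsum(rng.uniform(0.5, 1.1, size=rng.integers(3, 9)))
            beats = make_beats(times)
            track = make_track(times[-1] + 1.0)
            windows = assign_frames(beats, track)
            # tiling: consecutive edges shared
            for a, b in zip(windows[:-1], windows[1:]):
                assert a.right_s == b.left_s
            # exhaustive membership oracle: each frame in the covered span
            # belongs to exactly one window
            lo, hi = windows[0].left_s, windows[-1].right_s
            owner = np.zeros(track.n_frames, dtype=int)
            for w in windows:
                owner[w.frame_indices] += 1
            covered = (track.frame_times > lo) & (track.frame_times <= hi)
            assert np.all(owner[covered] == 1)
            assert np.all(owner[~covered] == 0)

    def test_hand_computed_middle_window(self):
        """Beats at 1.0/1.7/2.4 s: the middle window is (1.35, 2.05]."""
        beats = make_beats([1.0, 1.7, 2.4])
        track = make_track(3.2)
        windows = assign_frames(beats, track)
        mid = windows[1]
        assert mid.left_s == pytest.approx(1.35)
        assert mid.right_s == pytest.approx(2.05)
        brute = [
            l
            for l, t in enumerate(track.frame_times)
            if 1.35 < t <= 2.05
        ]
        np.testing.assert_array_equal(mid.frame_indices, brute)

    def test_700ms_beats_give_about_70_frames_per_window(self, beats_07s, track_8s):
        windows = assign_frames(beats_07s, track_8s)
        counts = [w.n_frames for w in windows]
        assert all(abs(c - 70) <= 1 for c in counts)
        assert np.mean(counts) == pytest.approx(70, abs=0.5)

    def test_edge_frame_belongs_to_earlier_window(self):
        # beats at 1/2/3 s put the first shared window edge at exactly 1.5 s;
        # pin one frame onto that edge (within the 1e-6 s grid tolerance)
        from cardiovoice import FormantTrack

        t = np.arange(0.500, 3.5, 0.010)
        edge_idx = int(np.argmin(np.abs(t - 1.5)))
        t[edge_idx] = 1.5
        track = FormantTrack("p", 1, t, np.full((t.size, 3), 500.0))
        beats = make_beats([1.0, 2.0, 3.0])
        windows = assign_frames(beats, track)
        assert windows[0].right_s == 1.5 == windows[1].left_s
        assert edge_idx in windows[0].frame_indices
        assert edge_idx not in windows[1].frame_indices

    def test_sparse_window_errors_unless_tolerant(self):
        beats = make_beats([0.5, 3.0, 3.5])  # long gap, then short
        from cardiovoice import FormantTrack

        t = np.arange(2.9, 3.9, 0.010)
        track = FormantTrack("p", 1, t, np.full((t.size, 3), 500.0))
        with pytest.raises(WindowError, match="fewer than"):
            assign_frames(beats, track)
        windows = assign_frames(beats, track, tolerant=True)
        assert len(windows) == 3


class TestTrackStats:
    def test_constant_window_convention(self):
        t = np.arange(0, 0.7, 0.01)
        out = track_stats(np.full(t.size, 500.0), t, 0.35)
        np.testing.assert_allclose(
            out, [0, 0, 500, 500, 500, 500, 500, 0, 0, 3], atol=1e-9
        )

    def test_exact_quadratic_recovery(self):
        tau = 1.0
        t = np.linspace(0.7, 1.3, 61)
        s = t - tau
        y = 2 * s**2 + 3 * s + 400
        out = track_stats(y, t, tau)
        np.testing.assert_allclose(out[:3], [2, 3, 400], atol=1e-6)

    def test_matches_naive_oracle_on_random_windows(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(3, 90))
            t = np.sort(rng.uniform(0, 1, n))
            tau = rng.uniform(0.3, 0.7)
            y = rng.normal(1500, 200, n)
            np.testing.assert_allclose(
                track_stats(y, t, tau), brute_stats(y, t, tau), atol=1e-9, rtol=1e-9
            )

    def test_moment_conventions_match_scipy(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=50)
        t = np.arange(50) * 0.01
        out = track_stats(y, t, 0.25)
        assert out[7] == pytest.approx(np.std(y, ddof=1))
        assert out[8] == pytest.approx(sstats.skew(y, bias=True))
        assert out[9] == pytest.approx(sstats.kurtosis(y, fisher=False, bias=True))


class TestBeatFeatures:
    def test_static_and_dynamic_dimensions(self, beats_07s, track_8s):
        phi = beat_formant_features(track_8s, beats_07s, with_dynamics=False)
        gamma = beat_formant_features(track_8s, beats_07s, with_dynamics=True)
        assert phi.values.shape == (10, 30)
        assert gamma.values.shape == (10, 90)
        assert phi.feature_set == "phi" and gamma.feature_set == "gamma"

    def test_constant_track_dynamics_statistics(self, beats_07s):
        from cardiovoice import FormantTrack

        t = np.arange(0.005, 8.0, 0.010)
        track = FormantTrack("p", 1, t, np.tile([500.0, 1500.0, 2500.0], (t.size, 1)))
        gamma = beat_formant_features(track, beats_07s, with_dynamics=True)
        # delta/acceleration tracks are identically zero: all their
        # statistics vanish except the kurtosis convention (=3)
        for block in range(3, 9):
            stats = gamma.values[:, 10 * block : 10 * (block + 1)]
            np.testing.assert_allclose(stats[:, :9], 0.0, atol=1e-9)
            np.testing.assert_allclose(stats[:, 9], 3.0)

    def test_cardio_dimensions(self, beats_07s):
        assert cardio_features(beats_07s).values.shape == (10, 10)
        assert cardio_features(beats_07s, with_dynamics=True).values.shape == (10, 30)


class TestFuse:
    @pytest.mark.parametrize(
        "formant,cardio,dim",
        [("phi", "c", 40), ("phi", "c_da", 60), ("gamma", "c", 100), ("gamma", "c_da", 120)],
    )
    def test_fused_dimensions(self, beats_07s, track_8s, formant, cardio, dim):
        f = beat_formant_features(track_8s, beats_07s, with_dynamics=(formant == "gamma"))
        c = cardio_features(beats_07s, with_dynamics=(cardio == "c_da"))
        fused = fuse(f, c)
        assert fused.values.shape == (10, dim)
        assert fused.feature_set == f"{formant}+{cardio}"

    def test_beat_count_mismatch_rejected(self, beats_07s, track_8s):
        f = beat_formant_features(track_8s, beats_07s, with_dynamics=True)
        other = cardio_features(make_beats(0.7 * np.arange(1, 9)))
        with pytest.raises(ValueError, match="mismatch"):
            fuse(f, other)

    def test_permuted_beats_rejected(self, beats_07s, track_8s):
        f = beat_formant_features(track_8s, beats_07s, with_dynamics=False)
        c = cardio_features(beats_07s)
        shuffled = BeatFeatureMatrix("c", c.values, c.beat_times + 0.1)
        with pytest.raises(ValueError, match="beat-time"):
            fuse(f, shuffled)

    def test_single_source_passthrough(self, beats_07s):
        c = cardio_features(beats_07s)
        assert fuse(None, c) is c
        assert fuse(c, None) is c
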