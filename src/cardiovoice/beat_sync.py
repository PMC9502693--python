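"""Heartbeat synchronization of formant frames and feature fusion.

Each heartbeat n at time tau_n with pulse interval D_n = tau_n - tau_{n-1}
owns the half-open time window

    (tau_n - D_n / 2,  tau_n + D_{n+1} / 2]

so that consecutive windows tile the recording and every frame has exactly
one owner.  For the first beat the missing left interval is taken as D_2
and for the last beat the missing right interval as D_N, both clamped to
the span of the formant track.  At a typical 0.7 s pulse interval and the
100 frames/s track this assigns about 70 frames per beat.

Ten summary statistics are computed per formant track and window: the
three coefficients of a least-squares quadratic in time (centered on the
beat), minimum, maximum, mean, median, sample standard deviation, skewness
and kurtosis.  Statistics over the three raw tracks give a 30-dimensional
beat vector; expanding the track to nine (adding frame-level delta and
acceleration tracks first) gives 90 dimensions.  Fusion is plain row-wise
concatenation [formant | cardio] of beat-aligned matrices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sstats

from .features import DynamicsConfig, expand_dynamics
from .io_formats import BeatSeries, FormantTrack

__all__ = [
    "BeatWindow",
    "BeatFeatureMatrix",
    "FEATURE_DIMS",
    "STAT_NAMES",
    "assign_frames",
    "track_stats",
    "beat_formant_features",
    "cardio_features",
    "fuse",
]

#: Expected column counts for each feature-set tag.
FEATURE_DIMS = {
    "phi": 30,
    "gamma": 90,
    "c": 10,
    "c_da": 30,
    "phi+c": 40,
    "phi+c_da": 60,
    "gamma+c": 100,
    "gamma+c_da": 120,
}

STAT_NAMES = (
    "poly2_a",
    "poly2_b",
    "poly2_c",
    "min",
    "max",
    "mean",
    "median",
    "std",
    "skewness",
    "kurtosis",
)


class WindowError(ValueError):
    """A beat window cannot support the per-beat statistics."""


@dataclasses.dataclass(frozen=True)
class BeatWindow:
    """Half-open time window (left_s, right_s] owned by one heartbeat."""

    beat_index: int
    left_s: float
    right_s: float
    frame_indices: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frame_indices.size


@dataclasses.dataclass(frozen=True)
class BeatFeatureMatrix:
    """Per-heartbeat feature rows with their source tag and beat times.

    ``beat_times`` are carried so fusion can verify that two matrices
    describe the same heartbeats, not merely the same number of them.
    ``level`` is the Stroop level when known, else 0.
    """

    feature_set: str
    values: np.ndarray
    beat_times: np.ndarray
    level: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        bt = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "beat_times", bt)
        if self.feature_set not in FEATURE_DIMS:
            raise ValueError(
                f"unknown feature set {self.feature_set!r}; "
                f"valid tags: {sorted(FEATURE_DIMS)}"
            )
        expected = FEATURE_DIMS[self.feature_set]
        if vals.ndim != 2 or vals.shape[1] != expected:
            raise ValueError(
                f"feature set {self.feature_set!r} requires {expected} columns, "
                f"got shape {vals.shape}"
            )
        if bt.shape != (vals.shape[0],):
            raise ValueError("beat_times length must equal feature row count")

    @property
    def n_beats(self) -> int:
        return self.values.shape[0]


def assign_frames(
    beats: BeatSeries,
    track: FormantTrack,
    min_frames: int = 3,
    tolerant: bool = False,
) -> list[BeatWindow]:
    """Partition the formant frames into per-heartbeat windows.

    Frames before the first window or after the last are dropped.  A window
    with fewer than ``min_frames`` frames raises :class:`WindowError`
    unless ``tolerant`` is set, in which case the window is emitted empty
    and downstream feature extraction copies the previous beat's row.
    """
    tau = beats.beat_times
    d = np.diff(tau)  # d[n-1] = interval ending at beat n (0-based)
    n = tau.size
    t = track.frame_times
    t_lo, t_hi = t[0], t[-1]
    if tau[-1] < t_lo or tau[0] > t_hi:
        raise WindowError("formant track does not overlap the beat span")

    # Half-interval to the left of beat i and to the right of beat i,
    # substituting the neighbouring interval at the edges.
    left_half = np.concatenate([[d[0]], d]) / 2.0
    right_half = np.concatenate([d, [d[-1]]]) / 2.0
    lefts = np.maximum(tau - left_half, t_lo - 1e-12)
    rights = np.minimum(tau + right_half, t_hi + 1e-12)
    # interior edges must agree exactly for the tiling invariant
    lefts[1:] = rights[:-1]

    windows: list[BeatWindow] = []
    short: list[int] = []
    for i in range(n):
        mask = (t > lefts[i]) & (t <= rights[i])
        idx = np.nonzero(mask)[0]
        if idx.size < min_frames:
            short.append(i)
            if not tolerant:
                continue
        windows.append(BeatWindow(i, float(lefts[i]), float(rights[i]), idx))
    if short and not tolerant:
        raise WindowError(
            f"beat window(s) with fewer than {min_frames} frames at beat "
            f"indices {short}; re-run with tolerant=True to copy the previous "
            f"beat's features"
        )
    return windows


def track_stats(values: np.ndarray, times: np.ndarray, tau: float) -> np.ndarray:
    """Ten summary statistics of one track segment around one heartbeat.

    Returns ``(a, b, c, min, max, mean, median, std, skew, kurt)`` where
    ``a*s**2 + b*s + c`` is the least-squares quadratic in s = time - tau
    (descending-degree coefficients, so ``c`` is the fitted level at the
    beat).  ``std`` uses the n-1 denominator; skewness is the biased moment
    estimator and kurtosis is non-excess (normal -> 3).  A zero-variance
    segment returns skewness 0 and kurtosis 3 by convention.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size < 3:
        raise WindowError(f"need >= 3 frames for per-beat statistics, got {y.size}")
    s = t - tau
    coeffs = np.polyfit(s, y, 2)
    std = float(np.std(y, ddof=1))
    if std == 0.0 or np.isclose(std, 0.0, atol=1e-12 * max(1.0, abs(float(y[0])))):
        skew, kurt = 0.0, 3.0
    else:
        skew = float(sstats.skew(y, bias=True))
        kurt = float(sstats.kurtosis(y, fisher=False, bias=True))
    return np.array(
        [
            coeffs[0],
            coeffs[1],
            coeffs[2],
            float(np.min(y)),
            float(np.max(y)),
            float(np.mean(y)),
            float(np.median(y)),
            std,
            skew,
            kurt,
        ]
    )


def _window_stats_all_tracks(values: np.ndarray, times: np.ndarray, tau: float) -> np.ndarray:
    """Vectorized :func:`track_stats` for all tracks of one window.

    ``values`` is (n_frames, n_tracks); returns (n_tracks, 10).  One
    shared least-squares solve serves every track since the design matrix
    depends only on the frame times.
    """
    y = np.asarray(values, dtype=float)
    s = np.asarray(times, dtype=float) - tau
    n = y.shape[0]
    design = np.column_stack([s**2, s, np.ones_like(s)])
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)  # (3, n_tracks)
    mean = y.mean(axis=0)
    centered = y - mean
    m2 = np.mean(centered**2, axis=0)
    std = np.sqrt(np.sum(centered**2, axis=0) / (n - 1))
    safe = m2 > 0
    skew = np.zeros_like(mean)
    kurt = np.full_like(mean, 3.0)
    skew[safe] = np.mean(centered[:, safe] ** 3, axis=0) / m2[safe] ** 1.5
    kurt[safe] = np.mean(centered[:, safe] ** 4, axis=0) / m2[safe] ** 2
    return np.column_stack(
        [
            coeffs[0],
            coeffs[1],
            coeffs[2],
            y.min(axis=0),
            y.max(axis=0),
            mean,
            np.median(y, axis=0),
            std,
            skew,
            kurt,
        ]
    )


def beat_formant_features(
    track: FormantTrack,
    beats: BeatSeries,
    with_dynamics: bool = False,
    config: DynamicsConfig = DynamicsConfig(),
    tolerant: bool = False,
    level: int = 0,
) -> BeatFeatureMatrix:
    """Per-heartbeat formant statistics matrix.

    Without dynamics, the 10 statistics of each of the three formant
    tracks give an N x 30 matrix (tag ``phi``), ordered F1 stats, F2
    stats, F3 stats.  With dynamics, the frame-level track is expanded to
    nine tracks (three static, three delta, three acceleration) *before*
    windowing and an N x 90 matrix results (tag ``gamma``).  Dynamics are
    never re-applied to the per-beat statistics themselves.
    """
    tracks = track.formants
    if with_dynamics:
        tracks = expand_dynamics(tracks, config)
    windows = assign_frames(beats, track, tolerant=tolerant)
    n_tracks = tracks.shape[1]
    rows = np.empty((len(windows), 10 * n_tracks))
    for w in windows:
        if w.n_frames < 3:
            # tolerant mode: copy the previous beat's feature row
            rows[w.beat_index] = rows[w.beat_index - 1] if w.beat_index > 0 else np.nan
            continue
        t = track.frame_times[w.frame_indices]
        tau = beats.beat_times[w.beat_index]
        rows[w.beat_index] = _window_stats_all_tracks(
            tracks[w.frame_indices], t, tau
        ).ravel()
    # a leading short window in tolerant mode copies the first complete row
    if np.any(np.isnan(rows[0])):
        first_ok = int(np.nonzero(~np.isnan(rows[:, 0]))[0][0])
        rows[:first_ok] = rows[first_ok]
    tag = "gamma" if with_dynamics else "phi"
    return BeatFeatureMatrix(tag, rows, beats.beat_times, level=level)


def cardio_features(
    beats: BeatSeries,
    with_dynamics: bool = False,
    config: DynamicsConfig = DynamicsConfig(),
    level: int = 0,
) -> BeatFeatureMatrix:
    """Cardiovascular beat matrix: raw measures (tag ``c``, N x 10) or the
    delta/acceleration expansion (tag ``c_da``, N x 30)."""
    vals = beats.measures
    tag = "c"
    if with_dynamics:
        vals = expand_dynamics(vals, config)
        tag = "c_da"
    return BeatFeatureMatrix(tag, vals, beats.beat_times, level=level)


def fuse(
    formant_feats: BeatFeatureMatrix | None,
    cardio_feats: BeatFeatureMatrix | None,
) -> BeatFeatureMatrix:
    """Feature-level fusion by row-wise concatenation [formant | cardio].

    Passing a single source returns it unchanged (the unfused baselines).
    Both sources must describe the same heartbeats: equal counts and equal
    beat times.
    """
    if formant_feats is None and cardio_feats is None:
        raise ValueError("fuse needs at least one feature matrix")
    if formant_feats is None:
        return cardio_feats
    if cardio_feats is None:
        return formant_feats
    if formant_feats.n_beats != cardio_feats.n_beats:
        raise ValueError(
            f"beat-count mismatch: formant features have {formant_feats.n_beats} "
            f"beats, cardio features have {cardio_feats.n_beats}"
        )
    if not np.allclose(formant_feats.beat_times, cardio_feats.beat_times):
        raise ValueError("beat-time mismatch: matrices describe different heartbeats")
    tag = f"{formant_feats.feature_set}+{cardio_feats.feature_set}"
    if tag not in FEATURE_DIMS:
        raise ValueError(f"unsupported fusion {tag!r}")
    level = formant_feats.level or cardio_feats.level
    return BeatFeatureMatrix(
        tag,
        np.hstack([formant_feats.values, cardio_feats.values]),
        formant_feats.beat_times,
        level=level,
    )
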