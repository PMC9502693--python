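"""High-level orchestration: feature extraction tags and cohort evaluation.

Glue between the signal-level modules and the evaluation protocol.  The
eight feature-set tags name what enters the classifier per heartbeat:

====================  ====  ==========================================
tag                   dim   contents
====================  ====  ==========================================
``phi``               30    formant statistics
``gamma``             90    formant + frame-level delta/accel statistics
``c``                 10    cardiovascular measures
``c_da``              30    cardiovascular + delta/accel
``phi+c``             40    fusion
``phi+c_da``          60    fusion
``gamma+c``           100   fusion
``gamma+c_da``        120   fusion (the headline configuration)
====================  ====  ==========================================
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .beat_sync import (
    BeatFeatureMatrix,
    FEATURE_DIMS,
    beat_formant_features,
    cardio_features,
    fuse,
)
from .classification import ClassifierConfig
from .evaluation import CohortSummary, LosoResult, ScreenFeatures, cohort_summary, loso_evaluate
from .features import DynamicsConfig
from .io_formats import BeatSeries, CohortManifest, FormantTrack, read_beat_series, read_formant_track
from .synthetic import ScreenRecord

__all__ = [
    "extract_features",
    "screen_features",
    "cohort_screen_features",
    "evaluate_cohort",
    "load_cohort",
]


def extract_features(
    beats: BeatSeries,
    track: FormantTrack | None,
    feature_set: str,
    dynamics: DynamicsConfig = DynamicsConfig(),
    tolerant: bool = False,
    level: int = 0,
) -> BeatFeatureMatrix:
    """Build the per-beat feature matrix for one screen and one tag."""
    if feature_set not in FEATURE_DIMS:
        raise ValueError(
            f"unknown feature set {feature_set!r}; valid tags: {sorted(FEATURE_DIMS)}"
        )
    parts = feature_set.split("+")
    formant_tag = next((p for p in parts if p in ("phi", "gamma")), None)
    cardio_tag = next((p for p in parts if p in ("c", "c_da")), None)
    formant = None
    if formant_tag is not None:
        if track is None:
            raise ValueError(f"feature set {feature_set!r} needs a formant track")
        formant = beat_formant_features(
            track,
            beats,
            with_dynamics=(formant_tag == "gamma"),
            config=dynamics,
            tolerant=tolerant,
            level=level,
        )
    cardio = None
    if cardio_tag is not None:
        cardio = cardio_features(
            beats, with_dynamics=(cardio_tag == "c_da"), config=dynamics, level=level
        )
    if formant is not None and cardio is not None:
        # fusion drops cardio rows for beats whose formant window was dropped
        if formant.n_beats != cardio.n_beats:
            raise ValueError(
                "formant and cardio beat counts diverged; use tolerant mode"
            )
        return fuse(formant, cardio)
    return formant if formant is not None else cardio


def screen_features(
    rec: ScreenRecord,
    feature_set: str,
    dynamics: DynamicsConfig = DynamicsConfig(),
    tolerant: bool = False,
) -> ScreenFeatures:
    return ScreenFeatures(
        screen_index=rec.screen_index,
        level=rec.level,
        features=extract_features(
            rec.beats, rec.track, feature_set, dynamics, tolerant, level=rec.level
        ),
    )


def cohort_screen_features(
    cohort: list[list[ScreenRecord]],
    feature_set: str,
    dynamics: DynamicsConfig = DynamicsConfig(),
    tolerant: bool = False,
) -> list[list[ScreenFeatures]]:
    return [
        [screen_features(rec, feature_set, dynamics, tolerant) for rec in screens]
        for screens in cohort
    ]


def evaluate_cohort(
    per_participant_screens: list[list[ScreenFeatures]],
    config: ClassifierConfig,
    allow_lenient: bool = False,
) -> tuple[CohortSummary, CohortSummary, list[LosoResult]]:
    """Leave-one-screen-out over every participant.

    Returns the sequence-level summary, the beat-level summary and the raw
    per-participant results.
    """
    results = []
    for p_index, screens in enumerate(per_participant_screens):
        pid = f"participant_{p_index + 1}"
        results.append(
            loso_evaluate(screens, config, participant_id=pid, allow_lenient=allow_lenient)
        )
    seq = cohort_summary([r.sequence_confusion for r in results])
    beat = cohort_summary([r.beat_confusion for r in results])
    return seq, beat, results


def load_cohort(manifest: CohortManifest, base_dir: str | Path) -> list[list[ScreenRecord]]:
    """Materialize every screen referenced by a manifest."""
    base = Path(base_dir)
    cohort = []
    for pid in manifest.participants:
        screens = []
        for row in manifest.screens_of(pid).itertuples(index=False):
            beats = read_beat_series(
                base / row.beat_file, participant_id=pid, screen_index=int(row.screen_index)
            )
            track = read_formant_track(
                base / row.formant_file, participant_id=pid, screen_index=int(row.screen_index)
            )
            screens.append(
                ScreenRecord(pid, int(row.screen_index), int(row.level), beats, track)
            )
        cohort.append(screens)
    return cohort
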