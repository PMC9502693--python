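"""Leave-one-screen-out evaluation, confusion tables and MCR/MTR metrics.

Classifiers are participant dependent: for each of a participant's 21
screens, a model is trained on the other 20 and the held-out screen is
scored, yielding one sequence decision per screen and one decision per
heartbeat.  Decisions accumulate into 3x3 actual-vs-classified confusion
tables from which per-class misclassification rates (MCR, row-wise),
per-class mistrust rates (MTR, column-wise) and the overall MCR
(off-diagonal over total) are derived.  Cohort aggregation reports both
the mean of per-participant MCRs with its standard error and the pooled
MCR of the summed tables; the two differ slightly because class counts
are unbalanced.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .beat_sync import BeatFeatureMatrix
from .classification import ClassifierConfig, classify_sequence, score_beats, train
from .io_formats import ConfusionTable

__all__ = [
    "ScreenFeatures",
    "LosoResult",
    "CohortSummary",
    "loso_evaluate",
    "mcr_per_class",
    "mtr_per_class",
    "overall_mcr",
    "cohort_summary",
]


@dataclasses.dataclass(frozen=True)
class ScreenFeatures:
    """One screen's precomputed beat-feature matrix and its Stroop level."""

    screen_index: int
    level: int
    features: BeatFeatureMatrix


@dataclasses.dataclass(frozen=True)
class LosoResult:
    """Per-participant leave-one-screen-out outcome."""

    participant_id: str
    screen_predictions: list[tuple[int, int, int]]  # (screen_index, actual, predicted)
    beat_predictions: list[tuple[int, int, int]]  # (screen_index, actual, predicted)
    sequence_confusion: ConfusionTable
    beat_confusion: ConfusionTable


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Average-over-participants and pooled misclassification aggregates."""

    per_participant_mcr: list[float]
    mean_mcr: float
    se_mcr: float  # NaN for a single participant
    pooled_mcr: float
    pooled_confusion: ConfusionTable


def loso_evaluate(
    screens: list[ScreenFeatures],
    config: ClassifierConfig,
    participant_id: str = "",
    allow_lenient: bool = False,
) -> LosoResult:
    """Leave-one-screen-out evaluation for one participant.

    Each fold trains on all screens but one and scores the held-out
    screen's beats; the fold seed is the configured seed XORed with the
    fold index so folds are independent but reproducible.  Strictly
    expects the full 21-screen design unless ``allow_lenient``.
    """
    levels = [s.level for s in screens]
    counts = tuple(levels.count(k) for k in (1, 2, 3))
    if not allow_lenient and counts != (7, 6, 8):
        raise ValueError(
            f"expected the 7/6/8 screen design (21 screens), got {counts}; "
            f"pass allow_lenient=True for other layouts"
        )
    if any(c < 2 for c in counts):
        raise ValueError(
            f"need >= 2 screens per level for leave-one-out, got {counts}"
        )
    screen_preds: list[tuple[int, int, int]] = []
    beat_preds: list[tuple[int, int, int]] = []
    seq_conf = np.zeros((3, 3), dtype=np.int64)
    beat_conf = np.zeros((3, 3), dtype=np.int64)
    for fold, held in enumerate(screens):
        train_screens = [s for s in screens if s is not held]
        x = np.vstack([s.features.values for s in train_screens])
        y = np.concatenate(
            [np.full(s.features.n_beats, s.level) for s in train_screens]
        )
        fold_config = dataclasses.replace(config, seed=config.seed ^ fold)
        stacked = dataclasses.replace(
            held.features,
            values=x,
            beat_times=np.arange(x.shape[0], dtype=float),
        )
        model = train(stacked, y, fold_config)
        scores = score_beats(model, held.features)
        seq_level, _ = classify_sequence(scores)
        screen_preds.append((held.screen_index, held.level, seq_level))
        seq_conf[held.level - 1, seq_level - 1] += 1
        beat_levels = np.argmax(scores.scores, axis=1) + 1
        for b in beat_levels:
            beat_preds.append((held.screen_index, held.level, int(b)))
        np.add.at(beat_conf[held.level - 1], beat_levels - 1, 1)
    return LosoResult(
        participant_id=participant_id,
        screen_predictions=screen_preds,
        beat_predictions=beat_preds,
        sequence_confusion=ConfusionTable(seq_conf),
        beat_confusion=ConfusionTable(beat_conf),
    )


def _rate(off_diag: np.ndarray, totals: np.ndarray, axis_name: str) -> np.ndarray:
    out = np.full(3, np.nan)
    for k in range(3):
        if totals[k] == 0:
            continue  # undefined entry stays NaN rather than a silent zero
        out[k] = 100.0 * off_diag[k] / totals[k]
    return out


def mcr_per_class(t: ConfusionTable) -> np.ndarray:
    """Per-actual-class misclassification rate in percent (row-wise).

    Entries with an empty row are NaN.
    """
    c = t.counts
    row_tot = c.sum(axis=1)
    off = row_tot - np.diag(c)
    return _rate(off, row_tot, "row")


def mtr_per_class(t: ConfusionTable) -> np.ndarray:
    """Per-classified-class mistrust rate in percent (column-wise)."""
    c = t.counts
    col_tot = c.sum(axis=0)
    off = col_tot - np.diag(c)
    return _rate(off, col_tot, "column")


def overall_mcr(t: ConfusionTable) -> float:
    """Overall misclassification: off-diagonal count over total, percent."""
    total = t.total
    if total == 0:
        raise ValueError("empty confusion table has no misclassification rate")
    return 100.0 * (total - int(np.trace(t.counts))) / total


def cohort_summary(per_participant: list[ConfusionTable]) -> CohortSummary:
    """Aggregate per-participant confusion tables.

    Reports the mean of per-participant overall MCRs with its standard
    error (sample std / sqrt(P); NaN for one participant) and the pooled
    MCR of the elementwise-summed table.  The two aggregates differ when
    participants contribute unequal class counts.
    """
    if not per_participant:
        raise ValueError("need at least one confusion table")
    mcrs = [overall_mcr(t) for t in per_participant]
    pooled = per_participant[0]
    for t in per_participant[1:]:
        pooled = pooled + t
    p = len(mcrs)
    mean = float(np.mean(mcrs))
    se = float(np.std(mcrs, ddof=1) / math.sqrt(p)) if p >= 2 else float("nan")
    return CohortSummary(
        per_participant_mcr=mcrs,
        mean_mcr=mean,
        se_mcr=se,
        pooled_mcr=overall_mcr(pooled),
        pooled_confusion=pooled,
    )
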