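"""Synthetic Stroop-style cohort generator.

Emulates the study design end-to-end so the whole pipeline is testable
without any recordings: each participant performs 21 screens (7 at level
1, 6 at level 2, 8 at level 3, in a participant-dependent order cycling
through the six permutations of the levels), and each screen yields

* a beat series — beat times from jittered pulse intervals around a
  participant baseline heart rate (default mean 86 bpm, i.e. ~0.7 s
  intervals) shifted additively by the workload level, plus the ten
  per-beat hemodynamic measures built from simulated primaries (heart
  rate, pressures, stroke volume, ...) with AR(1) within-screen drift and
  a random screen-to-screen offset; derived measures (mean pressure,
  cardiac output, total peripheral resistance) are computed from the
  primaries so the usual physiological couplings hold;
* a 100 frames/s three-formant track — a concatenation of vowel-like
  segments whose targets are drawn from five template vowels (standing in
  for the five colour words), with level-dependent mean shifts and, at
  level 3, the faster externally paced segment rate.

The generator makes no attempt at waveform-level realism: it produces the
per-beat measures directly, because that is the pipeline's input
contract.  Level effects are additive and monotone in level for heart
rate by default (higher workload, higher heart rate).  Setting every
effect to zero (``null_config``) yields three statistically identical
levels, the chance-level reference condition.
"""

from __future__ import annotations

import dataclasses
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BeatSeries,
    CohortManifest,
    FormantTrack,
    MANIFEST_COLUMNS,
    SCREENS_PER_LEVEL,
    write_beat_series,
    write_formant_track,
    write_manifest,
)

__all__ = [
    "SimulationConfig",
    "ParticipantParams",
    "ScreenRecord",
    "null_config",
    "simulate_screen",
    "simulate_cohort",
    "write_cohort",
]

#: Template (F1, F2, F3) targets in Hz for the five colour-word vowels.
#: Artifact constants spanning the vowel space; only their level-dependent
#: modulation matters for testing.
VOWEL_TEMPLATES = np.array(
    [
        [300.0, 2200.0, 2900.0],
        [390.0, 2100.0, 2850.0],
        [500.0, 1500.0, 2500.0],
        [620.0, 1100.0, 2400.0],
        [750.0, 1300.0, 2550.0],
    ]
)

LEVEL_ORDERS = list(permutations((1, 2, 3)))


def _arr(values) -> np.ndarray:
    return np.asarray(values, dtype=float)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All distributional parameters of the synthetic cohort.

    Level-effect arrays have one entry per level (level 1 first); entry 0
    is zero by convention so levels 2 and 3 are shifts relative to the
    congruent baseline.  Units follow the measure they modify (bpm, mmHg,
    ml, Hz, ...).
    """

    n_participants: int = 10
    screen_duration_s: float = 30.0
    frame_rate_hz: float = 100.0
    seed: int = 0

    # participant baselines (population mean, sd)
    base_hr_bpm: tuple[float, float] = (86.0, 8.0)
    base_sbp_mmhg: tuple[float, float] = (124.0, 9.0)
    base_dbp_mmhg: tuple[float, float] = (72.0, 7.0)
    base_sv_ml: tuple[float, float] = (75.0, 9.0)
    base_lvpe: tuple[float, float] = (1.5, 0.2)
    base_dpdt: tuple[float, float] = (1000.0, 120.0)

    # additive level effects on the primary cardio measures, per level.
    # profiles are deliberately heterogeneous across measures (some respond
    # early and saturate, others mostly between medium and high load), as
    # cardiovascular reactivity channels do; this also keeps the three
    # level centroids off a single line in feature space
    hr_effect_bpm: tuple[float, ...] = (0.0, 4.0, 8.0)
    sbp_effect_mmhg: tuple[float, ...] = (0.0, 7.0, 10.0)
    dbp_effect_mmhg: tuple[float, ...] = (0.0, 2.0, 6.0)
    sv_effect_ml: tuple[float, ...] = (0.0, -4.0, -5.0)
    lvpe_effect: tuple[float, ...] = (0.0, 0.03, 0.10)
    dpdt_effect: tuple[float, ...] = (0.0, 60.0, 80.0)

    # within-screen AR(1) drift of the primaries
    ar_coefficient: float = 0.8
    hr_noise_sd: float = 1.5
    sbp_noise_sd: float = 2.5
    dbp_noise_sd: float = 1.8
    sv_noise_sd: float = 2.0
    lvpe_noise_sd: float = 0.04
    dpdt_noise_sd: float = 30.0

    # screen-to-screen (between-screen) offsets of the primaries
    hr_screen_sd: float = 2.0
    sbp_screen_sd: float = 3.0
    dbp_screen_sd: float = 2.0
    sv_screen_sd: float = 2.0
    lvpe_screen_sd: float = 0.05
    dpdt_screen_sd: float = 30.0

    # multiplicative jitter of individual pulse intervals
    pulse_jitter_sd: float = 0.03

    # formant generation
    # formant shifts follow the same heterogeneous-profile principle
    formant_effect_hz: tuple[tuple[float, ...], ...] = (
        (0.0, 35.0, 50.0),  # F1 per level: early response
        (0.0, 25.0, 100.0),  # F2 per level: late response
        (0.0, 30.0, 40.0),  # F3 per level: early response
    )
    formant_segment_sd_hz: float = 25.0
    formant_frame_sd_hz: float = 6.0
    formant_screen_sd_hz: float = 8.0
    segment_duration_s: tuple[float, float] = (0.9, 0.15)  # levels 1-2 (mean, sd)
    paced_durations_s: tuple[float, float] = (0.75, 0.65)  # level 3 choices
    level3_paced: bool = True


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every level effect removed.

    Pacing is also made level independent so no feature carries workload
    information; the three levels are then statistically identical and any
    classifier operates at chance.
    """
    zero3 = (0.0, 0.0, 0.0)
    defaults = dict(
        hr_effect_bpm=zero3,
        sbp_effect_mmhg=zero3,
        dbp_effect_mmhg=zero3,
        sv_effect_ml=zero3,
        lvpe_effect=zero3,
        dpdt_effect=zero3,
        formant_effect_hz=(zero3, zero3, zero3),
        level3_paced=False,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclasses.dataclass(frozen=True)
class ParticipantParams:
    """Per-participant baselines drawn once from the population."""

    participant_id: str
    hr_bpm: float
    sbp_mmhg: float
    dbp_mmhg: float
    sv_ml: float
    lvpe: float
    dpdt: float


@dataclasses.dataclass(frozen=True)
class ScreenRecord:
    """One simulated screen: level plus the two signal objects."""

    participant_id: str
    screen_index: int
    level: int
    beats: BeatSeries
    track: FormantTrack


def _draw_participant(config: SimulationConfig, index: int, rng: np.random.Generator) -> ParticipantParams:
    return ParticipantParams(
        participant_id=f"p{index + 1:03d}",
        hr_bpm=rng.normal(*config.base_hr_bpm),
        sbp_mmhg=rng.normal(*config.base_sbp_mmhg),
        dbp_mmhg=rng.normal(*config.base_dbp_mmhg),
        sv_ml=rng.normal(*config.base_sv_ml),
        lvpe=rng.normal(*config.base_lvpe),
        dpdt=rng.normal(*config.base_dpdt),
    )


def _ar1(n: int, coeff: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - coeff**2, 1e-12))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = coeff * x[i - 1] + eps[i - 1]
    return x


def simulate_screen(
    participant: ParticipantParams,
    level: int,
    config: SimulationConfig,
    screen_index: int,
    rng: np.random.Generator,
) -> ScreenRecord:
    """Simulate one screen's beat series and formant track."""
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level}")
    duration = config.screen_duration_s
    k = level - 1
    phi = config.ar_coefficient

    # --- beats -----------------------------------------------------------
    hr_center = participant.hr_bpm + config.hr_effect_bpm[k]
    if duration < 2.5 * 60.0 / max(hr_center, 1.0):
        raise ValueError(
            f"screen duration {duration} s too short for two beats at "
            f"{hr_center:.0f} bpm"
        )
    # generous beat budget, trimmed to the duration afterwards
    n_max = int(np.ceil(duration * hr_center / 60.0 * 1.5)) + 4
    hr_screen_offset = rng.normal(0.0, config.hr_screen_sd)
    hr_drift = _ar1(n_max, phi, config.hr_noise_sd, rng)
    hr = hr_center + hr_screen_offset + hr_drift
    hr = np.clip(hr, 35.0, 200.0)
    jitter = rng.normal(1.0, config.pulse_jitter_sd, size=n_max)
    intervals = np.clip(60.0 / hr * jitter, 0.25, 2.2)
    times = np.cumsum(intervals)
    keep = times <= duration + 1e-9  # a beat exactly at the end belongs to the screen
    times = times[keep]
    intervals = intervals[keep]
    n = times.size

    hr_meas = 60.0 / intervals  # heart-rate measure consistent with the beat grid
    sbp = (
        participant.sbp_mmhg
        + config.sbp_effect_mmhg[k]
        + rng.normal(0.0, config.sbp_screen_sd)
        + _ar1(n, phi, config.sbp_noise_sd, rng)
    )
    dbp = (
        participant.dbp_mmhg
        + config.dbp_effect_mmhg[k]
        + rng.normal(0.0, config.dbp_screen_sd)
        + _ar1(n, phi, config.dbp_noise_sd, rng)
    )
    dbp = np.minimum(dbp, sbp - 10.0)
    sv = (
        participant.sv_ml
        + config.sv_effect_ml[k]
        + rng.normal(0.0, config.sv_screen_sd)
        + _ar1(n, phi, config.sv_noise_sd, rng)
    )
    sv = np.clip(sv, 20.0, 160.0)
    lvpe = (
        participant.lvpe
        + config.lvpe_effect[k]
        + rng.normal(0.0, config.lvpe_screen_sd)
        + _ar1(n, phi, config.lvpe_noise_sd, rng)
    )
    dpdt = (
        participant.dpdt
        + config.dpdt_effect[k]
        + rng.normal(0.0, config.dpdt_screen_sd)
        + _ar1(n, phi, config.dpdt_noise_sd, rng)
    )
    mean_p = dbp + (sbp - dbp) / 3.0
    co = hr_meas * sv / 1000.0  # l/min
    tpr = mean_p / co
    measures = np.column_stack(
        [hr_meas, sbp, dbp, mean_p, intervals, sv, lvpe, co, tpr, dpdt]
    )
    beats = BeatSeries(
        participant_id=participant.participant_id,
        screen_index=screen_index,
        beat_times=times,
        measures=measures,
    )

    # --- formant track ---------------------------------------------------
    step = 1.0 / config.frame_rate_hz
    frame_times = np.arange(step / 2.0, duration, step)
    n_frames = frame_times.size
    shifts = np.array([config.formant_effect_hz[i][k] for i in range(3)])
    screen_offset = rng.normal(0.0, config.formant_screen_sd_hz, size=3)
    formants = np.empty((n_frames, 3))
    # every screen shows the same five colour words in near-equal proportion,
    # so segments draw from a balanced, shuffled deck rather than i.i.d. —
    # screen-to-screen vowel composition is then as stable as in the task
    deck: list[int] = []
    pos = 0
    while pos < n_frames:
        if level == 3 and config.level3_paced:
            seg_dur = config.paced_durations_s[rng.integers(0, 2)]
        else:
            seg_dur = max(rng.normal(*config.segment_duration_s), 0.2)
        seg_len = max(int(round(seg_dur * config.frame_rate_hz)), 3)
        seg_len = min(seg_len, n_frames - pos)
        if not deck:
            deck = list(rng.permutation(len(VOWEL_TEMPLATES)))
        template = VOWEL_TEMPLATES[deck.pop()]
        target = (
            template
            + shifts
            + screen_offset
            + rng.normal(0.0, config.formant_segment_sd_hz, size=3)
        )
        # smooth onset/offset so segment joins are not step edges
        ramp = np.minimum(np.arange(seg_len), np.arange(seg_len)[::-1])
        shape = 1.0 - 0.15 * np.exp(-ramp / 3.0)
        for i in range(3):
            formants[pos : pos + seg_len, i] = target[i] * shape + _ar1(
                seg_len, 0.7, config.formant_frame_sd_hz, rng
            )
        pos += seg_len
    formants = np.maximum(formants, 50.0)
    track = FormantTrack(
        participant_id=participant.participant_id,
        screen_index=screen_index,
        frame_times=frame_times,
        formants=formants,
    )
    return ScreenRecord(participant.participant_id, screen_index, level, beats, track)


def _session_levels(participant_index: int) -> list[int]:
    """Level of each of the 21 screens, in presentation order.

    The three level blocks are presented in one of the six level orders,
    cycling across participants (a Latin-square-style rotation).
    """
    order = LEVEL_ORDERS[participant_index % len(LEVEL_ORDERS)]
    levels: list[int] = []
    for lv in order:
        levels.extend([lv] * SCREENS_PER_LEVEL[lv - 1])
    return levels


def simulate_cohort(config: SimulationConfig) -> list[list[ScreenRecord]]:
    """Simulate every participant's 21-screen session, in memory.

    Returns one list of :class:`ScreenRecord` per participant.  All
    randomness derives from ``config.seed`` through a seed tree, so equal
    configurations produce identical cohorts.
    """
    cohort: list[list[ScreenRecord]] = []
    for p in range(config.n_participants):
        p_seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(p,))
        participant = _draw_participant(config, p, np.random.default_rng(p_seq))
        levels = _session_levels(p)
        screens = []
        for j, level in enumerate(levels, start=1):
            s_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(p, j))
            )
            screens.append(simulate_screen(participant, level, config, j, s_rng))
        cohort.append(screens)
    return cohort


def write_cohort(
    cohort: list[list[ScreenRecord]],
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Write a simulated cohort to disk and return the manifest path."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for screens in cohort:
        for rec in screens:
            stem = f"{rec.participant_id}_s{rec.screen_index:02d}"
            beat_file = f"{stem}_beats.csv"
            formant_file = f"{stem}_formants.csv"
            write_beat_series(out_dir / beat_file, rec.beats)
            write_formant_track(out_dir / formant_file, rec.track)
            rows.append(
                (rec.participant_id, rec.screen_index, rec.level, beat_file, formant_file)
            )
    table = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    write_manifest(manifest_path, table)
    return manifest_path
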