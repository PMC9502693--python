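"""Reading, writing and validation of on-disk artifacts.

All files are plain CSV (comma delimiter, decimal point, UTF-8, mandatory
header row).  The three artifact kinds are

* beat-series files: one row per heartbeat carrying the beat time and the
  ten per-beat hemodynamic measures a Finometer-class monitor emits,
* formant-track files: one row per 10 ms analysis frame with the first
  three formant frequencies in Hz,
* cohort manifests: one row per (participant, screen) pair linking the
  Stroop level and the two signal files.

Validation is strict by design: a malformed file is rejected with a
message naming the offending column or row rather than silently coerced.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BeatSeries",
    "FormantTrack",
    "CohortManifest",
    "ConfusionTable",
    "FormatError",
    "ValidationError",
    "BEAT_COLUMNS",
    "FORMANT_COLUMNS",
    "MANIFEST_COLUMNS",
    "read_beat_series",
    "write_beat_series",
    "read_formant_track",
    "write_formant_track",
    "read_manifest",
    "write_manifest",
    "read_confusion",
    "write_confusion",
]


class FormatError(ValueError):
    """File structure (header, columns, labels) does not match the schema."""


class ValidationError(ValueError):
    """File parsed but the data violate a domain invariant."""


#: Canonical beat-file column order: beat time then the ten measures.
#: ``ibi_s`` (inter-beat/pulse interval) duplicates the successive
#: differences of ``time_s``; it is carried because the pulse interval is
#: one of the ten monitor measures, but ``time_s`` is authoritative for
#: synchronization.
BEAT_COLUMNS = (
    "time_s",
    "hr_bpm",
    "sbp_mmhg",
    "dbp_mmhg",
    "map_mmhg",
    "ibi_s",
    "sv_ml",
    "lvpe",
    "co_lmin",
    "tpr",
    "dpdt_max",
)

#: The ten measure columns (beat file minus the time column).
MEASURE_COLUMNS = BEAT_COLUMNS[1:]

FORMANT_COLUMNS = ("time_s", "f1_hz", "f2_hz", "f3_hz")

MANIFEST_COLUMNS = ("participant_id", "screen_index", "level", "beat_file", "formant_file")

#: Frame increment of formant tracks in seconds.
FRAME_STEP_S = 0.010
FRAME_STEP_TOL_S = 1e-6

#: Screens per Stroop level in the strict study design (levels 1, 2, 3).
SCREENS_PER_LEVEL = (7, 6, 8)
SCREENS_PER_PARTICIPANT = sum(SCREENS_PER_LEVEL)

LEVEL_LABELS = ("L1", "L2", "L3")


@dataclasses.dataclass(frozen=True)
class BeatSeries:
    """Per-heartbeat record of one screen.

    Attributes
    ----------
    participant_id : str
    screen_index : int
        1-based screen index within the participant's session.
    beat_times : (N,) float array, strictly increasing, seconds
    measures : (N, 10) float array
        Columns in the fixed order of :data:`MEASURE_COLUMNS`.
    """

    participant_id: str
    screen_index: int
    beat_times: np.ndarray
    measures: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        ms = np.asarray(self.measures, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "measures", ms)
        if bt.ndim != 1 or bt.size < 2:
            raise ValidationError("beat series needs at least 2 beats")
        if ms.shape != (bt.size, 10):
            raise ValidationError(
                f"measures shape {ms.shape} does not match ({bt.size}, 10)"
            )
        if not np.all(np.isfinite(bt)):
            raise ValidationError("beat series contains non-finite beat times")
        diffs = np.diff(bt)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(
                f"beat times not strictly increasing at row {row} "
                f"(t={bt[row]:.6f} after t={bt[row - 1]:.6f})"
            )
        if not np.all(np.isfinite(ms)):
            raise ValidationError("beat series contains non-finite measures")
        ibi = ms[:, MEASURE_COLUMNS.index("ibi_s")]
        if np.any(ibi <= 0):
            row = int(np.argmax(ibi <= 0))
            raise ValidationError(f"non-positive pulse interval at row {row}")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def pulse_intervals(self) -> np.ndarray:
        """Successive beat-time differences; entry 0 repeats entry 1.

        The interval of the first beat is undefined (no predecessor); it is
        filled with the second interval so the array aligns with beats.
        """
        d = np.diff(self.beat_times)
        return np.concatenate([[d[0]], d])


@dataclasses.dataclass(frozen=True)
class FormantTrack:
    """First three formant frequencies on a uniform 10 ms frame grid."""

    participant_id: str
    screen_index: int
    frame_times: np.ndarray
    formants: np.ndarray

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times, dtype=float)
        fm = np.asarray(self.formants, dtype=float)
        object.__setattr__(self, "frame_times", ft)
        object.__setattr__(self, "formants", fm)
        if ft.ndim != 1 or ft.size < 3:
            raise ValidationError("formant track needs at least 3 frames")
        if fm.shape != (ft.size, 3):
            raise ValidationError(
                f"formants shape {fm.shape} does not match ({ft.size}, 3)"
            )
        if not np.all(np.isfinite(ft)) or not np.all(np.isfinite(fm)):
            raise ValidationError("formant track contains non-finite values")
        if np.any(fm <= 0):
            row, col = np.unravel_index(int(np.argmax(fm <= 0)), fm.shape)
            raise ValidationError(
                f"non-positive formant value in column {FORMANT_COLUMNS[col + 1]} "
                f"at row {row}"
            )
        dev = np.abs(np.diff(ft) - FRAME_STEP_S)
        if dev.size and dev.max() > FRAME_STEP_TOL_S:
            raise ValidationError(
                f"non-uniform frame spacing: max deviation {dev.max():.3e} s "
                f"from {FRAME_STEP_S} s at row {int(np.argmax(dev)) + 1}"
            )

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclasses.dataclass(frozen=True)
class CohortManifest:
    """Table of (participant, screen, level, files) rows.

    ``strict`` records whether the manifest satisfied the full study
    design (21 screens per participant split 7/6/8 across levels) at read
    time.  Lenient manifests only guarantee >= 2 screens of each level per
    participant, the minimum for leave-one-screen-out training.
    """

    table: pd.DataFrame
    strict: bool

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.table["participant_id"]))

    def screens_of(self, participant_id: str) -> pd.DataFrame:
        sub = self.table[self.table["participant_id"] == participant_id]
        if sub.empty:
            raise KeyError(f"unknown participant {participant_id!r}")
        return sub.reset_index(drop=True)


@dataclasses.dataclass(frozen=True)
class ConfusionTable:
    """3x3 actual-vs-classified counts (rows actual, columns classified)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValidationError(f"confusion table must be 3x3, got {c.shape}")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValidationError("confusion counts must be integers")
            c = np.round(c).astype(np.int64)
        if np.any(c < 0):
            raise ValidationError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.counts + other.counts)


def _check_header(df: pd.DataFrame, expected: tuple[str, ...], path: Path) -> None:
    got = tuple(df.columns)
    missing = [c for c in expected if c not in got]
    extra = [c for c in got if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise FormatError(f"{path}: {'; '.join(parts)}; expected {list(expected)}")
    if got != expected:
        raise FormatError(f"{path}: columns out of order; expected {list(expected)}")


def _check_finite(df: pd.DataFrame, cols, path: Path) -> None:
    block = df[list(cols)].to_numpy(dtype=float)
    if not np.all(np.isfinite(block)):
        r, c = np.unravel_index(int(np.argmax(~np.isfinite(block))), block.shape)
        raise ValidationError(f"{path}: non-finite value in {list(cols)[c]} at data row {r}")


def _ids_from_name(path: Path) -> tuple[str, int]:
    # Fallback identification "<participant>_s<index>_*.csv"; readers accept
    # explicit ids too.
    stem = path.stem
    parts = stem.split("_")
    for part in parts:
        if part.startswith("s") and part[1:].isdigit():
            return parts[0], int(part[1:])
    return stem, 0


def read_beat_series(
    path: str | Path,
    participant_id: str | None = None,
    screen_index: int | None = None,
) -> BeatSeries:
    """Read and validate a beat-series CSV.

    Participant/screen identity is taken from the arguments when given,
    otherwise inferred from a ``<participant>_s<index>_...`` file name.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, BEAT_COLUMNS, path)
    _check_finite(df, BEAT_COLUMNS, path)
    pid, scr = _ids_from_name(path)
    return BeatSeries(
        participant_id=participant_id if participant_id is not None else pid,
        screen_index=screen_index if screen_index is not None else scr,
        beat_times=df["time_s"].to_numpy(dtype=float),
        measures=df[list(MEASURE_COLUMNS)].to_numpy(dtype=float),
    )


def write_beat_series(path: str | Path, series: BeatSeries) -> None:
    df = pd.DataFrame(
        np.column_stack([series.beat_times, series.measures]), columns=list(BEAT_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_formant_track(
    path: str | Path,
    participant_id: str | None = None,
    screen_index: int | None = None,
) -> FormantTrack:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, FORMANT_COLUMNS, path)
    _check_finite(df, FORMANT_COLUMNS, path)
    pid, scr = _ids_from_name(path)
    return FormantTrack(
        participant_id=participant_id if participant_id is not None else pid,
        screen_index=screen_index if screen_index is not None else scr,
        frame_times=df["time_s"].to_numpy(dtype=float),
        formants=df[["f1_hz", "f2_hz", "f3_hz"]].to_numpy(dtype=float),
    )


def write_formant_track(path: str | Path, track: FormantTrack) -> None:
    df = pd.DataFrame(
        np.column_stack([track.frame_times, track.formants]), columns=list(FORMANT_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_manifest(path: str | Path, strict: bool = True) -> CohortManifest:
    """Read a cohort manifest.

    In strict mode every participant must have exactly 21 screens split
    7/6/8 across levels 1/2/3.  Lenient mode (``strict=False``) only
    requires at least two screens of every level per participant.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_header(df, MANIFEST_COLUMNS, path)
    if not df["level"].isin([1, 2, 3]).all():
        bad = sorted(set(df["level"]) - {1, 2, 3})
        raise ValidationError(f"{path}: invalid Stroop level(s) {bad}; must be 1, 2 or 3")
    offenders = []
    for pid, sub in df.groupby("participant_id", sort=False):
        counts = tuple(int((sub["level"] == k).sum()) for k in (1, 2, 3))
        if strict and counts != SCREENS_PER_LEVEL:
            offenders.append((pid, counts))
        if not strict and any(c < 2 for c in counts):
            offenders.append((pid, counts))
    if offenders:
        mode = "strict 7/6/8" if strict else "lenient >=2 per level"
        detail = ", ".join(f"{pid}: {c}" for pid, c in offenders)
        raise ValidationError(f"{path}: participants violating {mode} screen counts: {detail}")
    return CohortManifest(table=df.reset_index(drop=True), strict=strict)


def write_manifest(path: str | Path, table: pd.DataFrame) -> None:
    table[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def write_confusion(path: str | Path, table: ConfusionTable) -> None:
    df = pd.DataFrame(table.counts, index=list(LEVEL_LABELS), columns=list(LEVEL_LABELS))
    df.index.name = "actual"
    df.to_csv(path)


def read_confusion(path: str | Path) -> ConfusionTable:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if tuple(df.columns) != LEVEL_LABELS or tuple(df.index) != LEVEL_LABELS:
        raise FormatError(
            f"{path}: confusion table must have rows/columns {list(LEVEL_LABELS)}"
        )
    return ConfusionTable(df.to_numpy())
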