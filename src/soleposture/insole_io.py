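"""Reading, validating, writing and resampling raw insole recordings.

A wireless pressure insole reports, for each foot, a timestamped series of
eight zone forces (big toe, smaller toes, two metatarsal groups, two arch
zones, two heel zones).  This module defines the in-memory containers for
those recordings, a long-format CSV dialect for exchanging them, and the
anti-alias down-sampling step that brings 50 Hz acquisitions onto the 12 Hz
analysis grid shared by all downstream posturography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial import ConvexHull

from .exceptions import FormatError, ParameterError, ValidationError

#: Task labels: three static balance tasks, three active balance tasks.
STATIC_TASKS = ("EO", "EC", "OF")
ACTIVE_TASKS = ("GAIT", "FR", "BO")
TASKS = STATIC_TASKS + ACTIVE_TASKS

TASK_SETS = {
    "static": STATIC_TASKS,
    "active": ACTIVE_TASKS,
    "static_active": TASKS,
}

FEET = ("left", "right")
GROUPS = ("young_control", "age_matched_control", "pd")

N_ZONES = 8

#: Sampling rates used by the insole hardware; other positive rates are
#: accepted with a warning.
CANONICAL_RATES = (50.0, 12.0)

CSV_COLUMNS = ["subject_id", "task", "foot", "time_s"] + [
    f"f{i}" for i in range(1, N_ZONES + 1)
] + ["sampling_rate_hz"]


@dataclass(frozen=True)
class ZoneGeometry:
    """Planar coordinates of the eight insole zones.

    Coordinates are per-insole: ML is measured from the medial edge of the
    insole (so larger ML = more lateral for either foot, because the right
    insole is physically mirrored), AP from the heel end.  Units are mm.
    """

    ml: np.ndarray
    ap: np.ndarray
    zone_names: tuple[str, ...] = (
        "big_toe",
        "smaller_toes",
        "metatarsal_1_2",
        "metatarsal_3_4",
        "medial_arch",
        "lateral_arch",
        "medial_heel",
        "lateral_heel",
    )

    def __post_init__(self) -> None:
        ml = np.asarray(self.ml, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "ap", ap)
        if ml.shape != (N_ZONES,) or ap.shape != (N_ZONES,):
            raise ValidationError("geometry must define exactly 8 (ml, ap) pairs")
        pts = np.column_stack([ml, ap])
        if len(np.unique(pts, axis=0)) != N_ZONES:
            raise ValidationError("zone coordinates must be pairwise distinct")
        if ConvexHull(pts).volume <= 0:  # 2-D: volume == area
            raise ValidationError("zone geometry must span a positive area")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.ml, self.ap])

    def hull(self) -> ConvexHull:
        return ConvexHull(self.points)


def default_geometry() -> ZoneGeometry:
    """An anatomically plausible 8-zone layout on a 100 x 250 mm insole.

    The hardware vendor does not publish physical zone coordinates, so this
    layout is a documented, configurable default: toes at the top, two
    metatarsal zones, medial/lateral arch, medial/lateral heel.
    """
    ml = np.array([35.0, 70.0, 35.0, 75.0, 30.0, 80.0, 35.0, 65.0])
    ap = np.array([235.0, 220.0, 180.0, 175.0, 110.0, 110.0, 30.0, 25.0])
    return ZoneGeometry(ml=ml, ap=ap)


@dataclass(frozen=True)
class SubjectMeta:
    """Group membership and fall history for one participant."""

    subject_id: str
    group: str  # young_control | age_matched_control | pd
    faller: bool | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.faller is True and self.group != "pd":
            raise ValidationError(
                "faller status is tracked only within the pd group"
            )


@dataclass
class InsoleRecording:
    """One foot's 8-zone force series for one task of one subject."""

    subject_id: str
    task: str
    foot: str
    timestamps: np.ndarray  # seconds, strictly increasing
    forces: np.ndarray  # (n_frames, 8), non-negative
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}; expected {TASKS}")
        if self.foot not in FEET:
            raise ValidationError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if self.forces.ndim != 2 or self.forces.shape[1] != N_ZONES:
            raise ValidationError(
                f"forces must have exactly {N_ZONES} columns, got shape "
                f"{self.forces.shape}"
            )
        if len(self.timestamps) != len(self.forces):
            raise ValidationError("timestamps and forces must have equal length")
        neg = np.argwhere(self.forces < 0)
        if neg.size:
            frame, zone = neg[0]
            raise ValidationError(
                f"negative force at frame {frame}, zone {zone + 1}"
            )
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                idx = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"timestamps not strictly increasing at frame {idx + 1}"
                )
            if self.sampling_rate <= 0:
                raise ValidationError("sampling_rate must be positive")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.sampling_rate) > 0.1 / self.sampling_rate:
                raise ValidationError(
                    f"median inter-sample interval {med:.4f}s deviates >10% "
                    f"from 1/{self.sampling_rate} Hz"
                )
        if not any(np.isclose(self.sampling_rate, r) for r in CANONICAL_RATES):
            warnings.warn(
                f"sampling rate {self.sampling_rate} Hz is not one of the "
                f"canonical insole rates {CANONICAL_RATES}",
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def total_force(self) -> np.ndarray:
        return self.forces.sum(axis=1)


# ---------------------------------------------------------------------------
# CSV dialect (long format, one row per frame per foot)
# ---------------------------------------------------------------------------

def recordings_to_frame(recordings: list[InsoleRecording]) -> pd.DataFrame:
    """Stack recordings into the long-format exchange table."""
    chunks = []
    for rec in recordings:
        df = pd.DataFrame(rec.forces, columns=[f"f{i}" for i in range(1, 9)])
        df.insert(0, "subject_id", rec.subject_id)
        df.insert(1, "task", rec.task)
        df.insert(2, "foot", rec.foot)
        df.insert(3, "time_s", rec.timestamps)
        df["sampling_rate_hz"] = rec.sampling_rate
        chunks.append(df)
    if not chunks:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(chunks, ignore_index=True)[CSV_COLUMNS]


def write_insole_csv(recordings: list[InsoleRecording], path) -> str:
    """Write recordings in the documented long CSV dialect.

    Rows are ordered deterministically: subject, canonical task order,
    left before right, then time.  Floats use the shortest round-trip
    representation so that :func:`read_insole_csv` inverts this exactly.
    """
    df = recordings_to_frame(recordings)
    if len(df):
        task_rank = {t: i for i, t in enumerate(TASKS)}
        foot_rank = {"left": 0, "right": 1}
        df = df.sort_values(
            by=["subject_id", "task", "foot", "time_s"],
            key=lambda col: (
                col.map(task_rank) if col.name == "task"
                else col.map(foot_rank) if col.name == "foot"
                else col
            ),
            kind="stable",
        )
    df.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))
    return str(path)


def read_insole_csv(path) -> list[InsoleRecording]:
    """Read the long CSV dialect back into per-(subject, task, foot) recordings.

    Raises :class:`FormatError` naming any missing column and
    :class:`ValidationError` for negative forces or non-monotone timestamps.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    recordings = []
    for (subject, task, foot), grp in df.groupby(
        ["subject_id", "task", "foot"], sort=False
    ):
        grp = grp.sort_values("time_s", kind="stable")
        rate = float(grp["sampling_rate_hz"].iloc[0])
        recordings.append(
            InsoleRecording(
                subject_id=str(subject),
                task=str(task),
                foot=str(foot),
                timestamps=grp["time_s"].to_numpy(),
                forces=grp[[f"f{i}" for i in range(1, 9)]].to_numpy(),
                sampling_rate=rate,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# Anti-alias down-sampling
# ---------------------------------------------------------------------------

def antialias_downsample(
    rec: InsoleRecording, target_rate: float = 12.0
) -> InsoleRecording:
    """Low-pass filter and down-sample a recording to ``target_rate``.

    Mirrors the acquisition chain in which 50 Hz recordings are brought to
    the common 12 Hz analysis rate: each of the eight force channels is
    first placed on a uniform grid (linear interpolation absorbs timestamp
    jitter), filtered with a zero-phase 8th-order Butterworth low-pass at
    0.4 x target_rate, then resampled onto the uniform target grid.
    Non-negativity is restored by clipping at zero.  A recording already at
    the target rate is returned unchanged.
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise ParameterError(
            f"target rate {target_rate} Hz exceeds recording rate "
            f"{rec.sampling_rate} Hz"
        )
    if np.isclose(target_rate, rec.sampling_rate):
        return rec
    t0, t1 = rec.timestamps[0], rec.timestamps[-1]
    n_in = rec.n_frames
    # uniform source grid (absorbs jitter before the IIR filter)
    t_uniform = t0 + np.arange(n_in) / rec.sampling_rate
    t_uniform = t_uniform[t_uniform <= t1 + 1e-12]
    forces_u = np.column_stack(
        [
            np.interp(t_uniform, rec.timestamps, rec.forces[:, j])
            for j in range(N_ZONES)
        ]
    )
    sos = signal.butter(
        8, 0.4 * target_rate, btype="low", fs=rec.sampling_rate, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, forces_u, axis=0)
    n_out = int(np.floor((t_uniform[-1] - t0) * target_rate)) + 1
    t_out = t0 + np.arange(n_out) / target_rate
    out = np.column_stack(
        [np.interp(t_out, t_uniform, filtered[:, j]) for j in range(N_ZONES)]
    )
    out = np.clip(out, 0.0, None)
    return replace(
        rec, timestamps=t_out, forces=out, sampling_rate=float(target_rate)
    )
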