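"""Center-of-pressure trajectories from zone forces, and stance segmentation.

The center of pressure (COP) under one foot is the force-weighted centroid
of the eight zone coordinates:

    COP_ML = sum_i F_i * D_ML,i / sum_i F_i
    COP_AP = sum_i F_i * D_AP,i / sum_i F_i

Frames whose total force falls below a threshold (swing phases during gait,
the lifted foot during single-leg stance) have an undefined COP and are
masked invalid rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyTrajectoryError, SegmentationError
from .insole_io import InsoleRecording, ZoneGeometry

#: Invalid-frame threshold as a fraction of the trial's median total force.
DEFAULT_THRESHOLD_FRACTION = 0.05

#: Minimum stance-segment length for single-leg segmentation, in seconds.
DEFAULT_MIN_SEGMENT_S = 0.25


@dataclass
class COPTrajectory:
    """Per-frame (ML, AP) COP coordinates with a valid-frame mask."""

    ml: np.ndarray  # mm; NaN where invalid
    ap: np.ndarray
    valid: np.ndarray  # bool per frame
    sampling_rate: float
    foot: str
    task: str

    @property
    def n_frames(self) -> int:
        return len(self.ml)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_points(self) -> np.ndarray:
        """(n_valid, 2) array of the valid (ML, AP) samples, in frame order."""
        return np.column_stack([self.ml[self.valid], self.ap[self.valid]])

    def valid_runs(self) -> list[slice]:
        """Maximal runs of consecutive valid frames, as slices."""
        return _mask_runs(self.valid)

    def restrict(self, frame_slice: slice) -> "COPTrajectory":
        return COPTrajectory(
            ml=self.ml[frame_slice],
            ap=self.ap[frame_slice],
            valid=self.valid[frame_slice],
            sampling_rate=self.sampling_rate,
            foot=self.foot,
            task=self.task,
        )


@dataclass
class StanceSegments:
    """Disjoint sorted half-open (start, end) frame intervals for one foot."""

    intervals: list[tuple[int, int]]
    side: str

    def total_frames(self) -> int:
        return sum(e - s for s, e in self.intervals)


def _mask_runs(mask: np.ndarray) -> list[slice]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [slice(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def resolve_threshold(
    total_force: np.ndarray, force_threshold: float | None
) -> float:
    """Default force threshold: 5% of the trial's median total force."""
    if force_threshold is not None:
        return float(force_threshold)
    med = float(np.median(total_force))
    return DEFAULT_THRESHOLD_FRACTION * med


def compute_cop(
    rec: InsoleRecording,
    geom: ZoneGeometry,
    force_threshold: float | None = None,
) -> COPTrajectory:
    """Compute the per-frame force-weighted centroid COP for one foot.

    Frames with total force below ``force_threshold`` (default: 5% of the
    trial's median total force) are marked invalid; their coordinates are
    NaN.  Raises :class:`EmptyTrajectoryError` if no frame is valid.
    """
    total = rec.total_force()
    thr = resolve_threshold(total, force_threshold)
    valid = (total >= thr) & (total > 0)
    if not valid.any():
        raise EmptyTrajectoryError(
            f"all frames below force threshold for subject "
            f"{rec.subject_id!r}, task {rec.task}, foot {rec.foot}"
        )
    ml = np.full(rec.n_frames, np.nan)
    ap = np.full(rec.n_frames, np.nan)
    ml[valid] = rec.forces[valid] @ geom.ml / total[valid]
    ap[valid] = rec.forces[valid] @ geom.ap / total[valid]
    return COPTrajectory(
        ml=ml,
        ap=ap,
        valid=valid,
        sampling_rate=rec.sampling_rate,
        foot=rec.foot,
        task=rec.task,
    )


def segment_one_foot(
    rec_left: InsoleRecording,
    rec_right: InsoleRecording,
    force_threshold: float | None = None,
    min_segment_s: float = DEFAULT_MIN_SEGMENT_S,
) -> tuple[StanceSegments, StanceSegments]:
    """Split a single-leg-stance trial into left- and right-support segments.

    A frame belongs to the left stance when the left foot carries at least
    the threshold force and the right foot does not (and symmetrically).
    Brief ground touches of the lifted foot therefore split a stance into
    separate intervals.  Thresholds default to 10% of each foot's maximum
    total force (the lifted foot is near zero, so a trial-median default
    would be distorted by the unloaded half).
    """
    n = min(rec_left.n_frames, rec_right.n_frames)
    tot_l = rec_left.total_force()[:n]
    tot_r = rec_right.total_force()[:n]
    if force_threshold is not None:
        thr_l = thr_r = float(force_threshold)
    else:
        thr_l = 0.10 * float(tot_l.max())
        thr_r = 0.10 * float(tot_r.max())
    on_l = tot_l >= thr_l
    on_r = tot_r >= thr_r
    left_mask = on_l & ~on_r
    right_mask = on_r & ~on_l
    fs = rec_left.sampling_rate
    min_frames = max(1, int(round(min_segment_s * fs)))
    left_iv = [
        (s.start, s.stop) for s in _mask_runs(left_mask) if s.stop - s.start >= min_frames
    ]
    right_iv = [
        (s.start, s.stop) for s in _mask_runs(right_mask) if s.stop - s.start >= min_frames
    ]
    if not left_iv and not right_iv:
        raise SegmentationError(
            f"no single-support frames found for subject "
            f"{rec_left.subject_id!r} (task {rec_left.task})"
        )
    return (
        StanceSegments(intervals=left_iv, side="left"),
        StanceSegments(intervals=right_iv, side="right"),
    )


def trajectory_from_segments(
    traj: COPTrajectory, segments: StanceSegments
) -> COPTrajectory:
    """Restrict a trajectory to the frames inside stance segments.

    The segments' frames are concatenated; validity outside the segments is
    forced to False so downstream dynamics treat each segment as its own
    run (the difference chain is broken at segment boundaries).
    """
    keep = np.zeros(traj.n_frames, dtype=bool)
    for s, e in segments.intervals:
        keep[s:e] = True
    valid = traj.valid & keep
    return COPTrajectory(
        ml=np.where(valid, traj.ml, np.nan),
        ap=np.where(valid, traj.ap, np.nan),
        valid=valid,
        sampling_rate=traj.sampling_rate,
        foot=traj.foot,
        task=traj.task,
    )


def trajectory_to_frame(traj: COPTrajectory, subject_id: str = ""):
    """Tidy per-frame export (subject, task, foot, t, ml, ap, valid)."""
    import pandas as pd

    t = np.arange(traj.n_frames) / traj.sampling_rate
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "task": traj.task,
            "foot": traj.foot,
            "t": t,
            "ml": traj.ml,
            "ap": traj.ap,
            "valid": traj.valid,
        }
    )
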