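"""The 60-measure posturography feature bank and cohort feature table.

Each foot's COP trajectory in a task yields 60 stabilometric features in
three families:

* 19 **positional** features — dispersion/position statistics that need no
  local dynamics (means, mean/RMS distances, ranges, 95% confidence
  ellipse, amplitude ratio, interquartile ranges);
* 21 **dynamic** features — statistics of the local displacements (mean and
  peak velocities, excursion length, zero crossings of the COP velocity,
  swept area per second, phase-plane parameters, fractal dimension, hybrid
  mean frequencies, and the sway-density family built on a 3 mm radius);
* 20 **frequency** features — 10 per axis from the Welch power spectral
  density (total power, 50%/95% power frequencies, centroid frequency and
  dispersion, modal frequency, frequency quotient, and band-energy
  fractions below 0.5 Hz, 0.5-2 Hz, above 2 Hz).

Left- and right-foot vectors are combined per feature into an *average*
(L+R)/2 and an *asymmetry* |L-R|/(L+R), giving 120 features per task and
720 across the six balance tasks.  Features that are undefined on a
degenerate input carry NaN, never a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .cop import COPTrajectory, compute_cop, segment_one_foot, trajectory_from_segments
from .exceptions import SolePostureError
from .insole_io import (
    InsoleRecording,
    SubjectMeta,
    TASKS,
    TASK_SETS,
    ZoneGeometry,
    antialias_downsample,
    default_geometry,
)

#: chi-square 95% quantile with 2 degrees of freedom (confidence ellipse).
CHI2_95_2 = 5.991464547107979

#: Sway-density radius (mm): consecutive samples within this circle count.
SWAY_DENSITY_RADIUS_MM = 3.0

#: Moving-average window (s) smoothing the sway-density curve before peaks.
SWAY_DENSITY_SMOOTH_S = 0.5

POSITIONAL_FEATURES = (
    "mean_value_ml",
    "mean_value_ap",
    "mean_distance",
    "mean_distance_ml",
    "mean_distance_ap",
    "rms_radius",
    "rms_ml",
    "rms_ap",
    "range_resultant",
    "range_ml",
    "range_ap",
    "max_distance",
    "ellipse_area",
    "ellipse_major_axis",
    "ellipse_minor_axis",
    "ellipse_orientation",
    "amplitude_ratio_ml_ap",
    "iqr_ml",
    "iqr_ap",
)

DYNAMIC_FEATURES = (
    "mean_velocity",
    "mean_velocity_ml",
    "mean_velocity_ap",
    "total_excursion",
    "peak_velocity_ml",
    "peak_velocity_ap",
    "velocity_sd_ml",
    "velocity_sd_ap",
    "zero_crossing_velocity_ml",
    "zero_crossing_velocity_ap",
    "sway_area_per_second",
    "phase_plane_ml",
    "phase_plane_ap",
    "length_over_area",
    "fractal_dimension",
    "mean_frequency",
    "mean_frequency_ml",
    "mean_frequency_ap",
    "sway_density_mean_peak",
    "sway_density_mean_distance_peaks",
    "sway_density_mean_time_peaks",
)

FREQUENCY_FEATURES = tuple(
    f"{name}_{axis}"
    for axis in ("ml", "ap")
    for name in (
        "total_power",
        "power_frequency_50",
        "power_frequency_95",
        "centroid_frequency",
        "frequency_dispersion",
        "frequency_mode",
        "frequency_quotient",
        "energy_below_05",
        "energy_05_2",
        "energy_above_2",
    )
)

FEATURE_NAMES = POSITIONAL_FEATURES + DYNAMIC_FEATURES + FREQUENCY_FEATURES
assert len(POSITIONAL_FEATURES) == 19
assert len(DYNAMIC_FEATURES) == 21
assert len(FREQUENCY_FEATURES) == 20
assert len(FEATURE_NAMES) == 60

COP_TYPES = ("average", "asymmetric")


# ---------------------------------------------------------------------------
# Per-family feature computations
# ---------------------------------------------------------------------------

def positional_features(traj: COPTrajectory) -> dict[str, float]:
    """The 19 positional measures; all NaN with fewer than 2 valid frames."""
    out = {name: np.nan for name in POSITIONAL_FEATURES}
    pts = traj.valid_points()
    if len(pts) < 2:
        return out
    ml, ap = pts[:, 0], pts[:, 1]
    mean_ml, mean_ap = float(ml.mean()), float(ap.mean())
    dx, dy = ml - mean_ml, ap - mean_ap
    r = np.hypot(dx, dy)
    out["mean_value_ml"] = mean_ml
    out["mean_value_ap"] = mean_ap
    out["mean_distance"] = float(r.mean())
    out["mean_distance_ml"] = float(np.abs(dx).mean())
    out["mean_distance_ap"] = float(np.abs(dy).mean())
    out["rms_radius"] = float(np.sqrt(np.mean(r**2)))
    out["rms_ml"] = float(np.sqrt(np.mean(dx**2)))
    out["rms_ap"] = float(np.sqrt(np.mean(dy**2)))
    out["range_ml"] = float(np.ptp(ml))
    out["range_ap"] = float(np.ptp(ap))
    out["range_resultant"] = _max_pairwise_distance(pts)
    out["max_distance"] = float(r.max())

    cov = np.cov(dx, dy, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam_minor, lam_major = float(max(eigvals[0], 0.0)), float(max(eigvals[1], 0.0))
    out["ellipse_area"] = float(np.pi * CHI2_95_2 * np.sqrt(lam_major * lam_minor))
    out["ellipse_major_axis"] = float(np.sqrt(CHI2_95_2 * lam_major))
    out["ellipse_minor_axis"] = float(np.sqrt(CHI2_95_2 * lam_minor))
    if lam_major > 1e-15 and not np.isclose(lam_major, lam_minor):
        v = eigvecs[:, 1]
        ang = np.degrees(np.arctan2(v[1], v[0]))
        if ang > 90.0:
            ang -= 180.0
        elif ang <= -90.0:
            ang += 180.0
        out["ellipse_orientation"] = float(ang)
    else:
        out["ellipse_orientation"] = 0.0  # isotropic or degenerate: no axis

    if out["range_ap"] > 0:
        out["amplitude_ratio_ml_ap"] = out["range_ml"] / out["range_ap"]
    elif out["range_ml"] == 0.0:
        out["amplitude_ratio_ml_ap"] = 1.0  # a point: isotropic by convention
    out["iqr_ml"] = float(np.percentile(ml, 75) - np.percentile(ml, 25))
    out["iqr_ap"] = float(np.percentile(ap, 75) - np.percentile(ap, 25))
    return out


def _max_pairwise_distance(pts: np.ndarray) -> float:
    """Diameter of the point set; via the convex hull when n is large."""
    if len(pts) > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear points: fall back to brute force
            pass
    if len(pts) < 2:
        return 0.0
    return float(pdist(pts).max())


def _run_velocities(traj: COPTrajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Central-difference velocities per valid run, concatenated.

    Returns (vx, vy, dx, dy) where dx/dy are the centered positions of the
    frames contributing velocities (runs shorter than 2 frames are skipped;
    the difference chain never crosses an invalid gap).
    """
    fs = traj.sampling_rate
    vx_parts, vy_parts, x_parts, y_parts = [], [], [], []
    for run in traj.valid_runs():
        if run.stop - run.start < 2:
            continue
        x = traj.ml[run]
        y = traj.ap[run]
        vx_parts.append(np.gradient(x) * fs)
        vy_parts.append(np.gradient(y) * fs)
        x_parts.append(x)
        y_parts.append(y)
    if not vx_parts:
        empty = np.empty(0)
        return empty, empty, empty, empty
    return (
        np.concatenate(vx_parts),
        np.concatenate(vy_parts),
        np.concatenate(x_parts),
        np.concatenate(y_parts),
    )


def _zero_crossings(v: np.ndarray) -> float:
    s = np.sign(v)
    s = s[s != 0]
    if len(s) < 2:
        return 0.0
    return float(np.count_nonzero(np.diff(s)))


def _sway_density(traj: COPTrajectory) -> tuple[float, float, float]:
    """Sway-density family: (mean peak, mean distance between peaks,
    mean time between peaks).

    The sway-density curve counts, per instant, the consecutive samples of
    the trajectory staying within a 3 mm circle around the current point,
    expressed in seconds.  Peaks are local maxima after 0.5 s moving-average
    smoothing.
    """
    fs = traj.sampling_rate
    r2 = SWAY_DENSITY_RADIUS_MM**2
    peaks_vals: list[float] = []
    peaks_pts: list[np.ndarray] = []
    peaks_dt: list[float] = []
    for run in traj.valid_runs():
        n = run.stop - run.start
        if n < 3:
            continue
        x = traj.ml[run]
        y = traj.ap[run]
        # within-radius matrix; per row, count the unbroken True runs
        # forward and backward from the diagonal
        within = (
            (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
        ) <= r2
        counts = np.zeros(n)
        for i in range(n):
            fwd = within[i, i + 1 :]
            bwd = within[i, :i][::-1]
            counts[i] = (
                (np.argmin(fwd) if not fwd.all() else len(fwd))
                + (np.argmin(bwd) if not bwd.all() else len(bwd))
            )
        sd = counts / fs  # seconds
        w = max(1, int(round(SWAY_DENSITY_SMOOTH_S * fs)))
        if w > 1:
            kernel = np.ones(w) / w
            sd_smooth = np.convolve(sd, kernel, mode="same")
        else:
            sd_smooth = sd
        idx, _ = signal.find_peaks(sd_smooth)
        for k in idx:
            peaks_vals.append(float(sd_smooth[k]))
            peaks_pts.append(np.array([x[k], y[k]]))
        peaks_dt.extend(np.diff(idx) / fs)
    if not peaks_vals:
        return np.nan, np.nan, np.nan
    mean_peak = float(np.mean(peaks_vals))
    if len(peaks_pts) >= 2:
        dists = [
            float(np.hypot(*(peaks_pts[i + 1] - peaks_pts[i])))
            for i in range(len(peaks_pts) - 1)
        ]
        mean_dist = float(np.mean(dists))
    else:
        mean_dist = np.nan
    mean_time = float(np.mean(peaks_dt)) if peaks_dt else np.nan
    return mean_peak, mean_dist, mean_time


def dynamic_features(traj: COPTrajectory) -> dict[str, float]:
    """The 21 dynamic measures; needs >= 3 valid frames and a known rate."""
    out = {name: np.nan for name in DYNAMIC_FEATURES}
    if traj.n_valid < 3:
        return out
    fs = traj.sampling_rate
    vx, vy, x, y = _run_velocities(traj)
    if len(vx) == 0:
        return out
    speed = np.hypot(vx, vy)
    out["mean_velocity"] = float(speed.mean())
    out["mean_velocity_ml"] = float(np.abs(vx).mean())
    out["mean_velocity_ap"] = float(np.abs(vy).mean())
    out["peak_velocity_ml"] = float(np.abs(vx).max())
    out["peak_velocity_ap"] = float(np.abs(vy).max())
    out["velocity_sd_ml"] = float(np.std(vx, ddof=1)) if len(vx) > 1 else np.nan
    out["velocity_sd_ap"] = float(np.std(vy, ddof=1)) if len(vy) > 1 else np.nan
    out["zero_crossing_velocity_ml"] = _zero_crossings(vx)
    out["zero_crossing_velocity_ap"] = _zero_crossings(vy)

    # path length and swept area accumulate per run, normalised by the
    # total valid duration
    totex = 0.0
    area = 0.0
    dur = 0.0
    for run in traj.valid_runs():
        n = run.stop - run.start
        if n < 2:
            continue
        rx = traj.ml[run]
        ry = traj.ap[run]
        totex += float(np.hypot(np.diff(rx), np.diff(ry)).sum())
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        area += 0.5 * float(
            np.abs(cx[:-1] * cy[1:] - cx[1:] * cy[:-1]).sum()
        )
        dur += (n - 1) / fs
    out["total_excursion"] = totex
    if dur > 0:
        out["sway_area_per_second"] = area / dur

    mean_ml_dev = float(np.abs(x - x.mean()).mean())
    mean_ap_dev = float(np.abs(y - y.mean()).mean())
    mean_dist = float(np.hypot(x - x.mean(), y - y.mean()).mean())
    out["phase_plane_ml"] = float(np.sqrt(np.var(x, ddof=1) + np.var(vx, ddof=1)))
    out["phase_plane_ap"] = float(np.sqrt(np.var(y, ddof=1) + np.var(vy, ddof=1)))

    pos = positional_features(traj)
    if pos["ellipse_area"] and pos["ellipse_area"] > 0:
        out["length_over_area"] = totex / pos["ellipse_area"]
    d = pos["range_resultant"]
    n_pts = traj.n_valid
    if totex > 0 and d > 0 and n_pts > 1:
        denom = np.log(n_pts * d / totex)
        if abs(denom) > 1e-12:
            out["fractal_dimension"] = float(np.log(n_pts) / denom)
    # hybrid mean frequency: the rotation/oscillation frequency of a
    # sinusoid with the trajectory's mean velocity and mean distance
    if mean_dist > 0:
        out["mean_frequency"] = out["mean_velocity"] / (2 * np.pi * mean_dist)
    if mean_ml_dev > 0:
        out["mean_frequency_ml"] = out["mean_velocity_ml"] / (4 * mean_ml_dev)
    if mean_ap_dev > 0:
        out["mean_frequency_ap"] = out["mean_velocity_ap"] / (4 * mean_ap_dev)

    sd_peak, sd_dist, sd_time = _sway_density(traj)
    out["sway_density_mean_peak"] = sd_peak
    out["sway_density_mean_distance_peaks"] = sd_dist
    out["sway_density_mean_time_peaks"] = sd_time
    return out


#: Welch PSD defaults: Hann window, 50% overlap, linear detrend per window.
PSD_MAX_NPERSEG = 128
MIN_PSD_FRAMES = 32


def _welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(PSD_MAX_NPERSEG, len(x) // 2)
    f, p = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
        scaling="density",
    )
    return f, p


def _axis_spectral(x: np.ndarray, fs: float, axis: str) -> dict[str, float]:
    names = [n for n in FREQUENCY_FEATURES if n.endswith(f"_{axis}")]
    out = {n: np.nan for n in names}
    f, p = _welch_psd(x, fs)
    total = float(np.trapezoid(p, f))
    if total <= 1e-18:
        out[f"total_power_{axis}"] = 0.0
        return out
    out[f"total_power_{axis}"] = total
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(f))])
    out[f"power_frequency_50_{axis}"] = float(np.interp(0.5 * total, cum, f))
    out[f"power_frequency_95_{axis}"] = float(np.interp(0.95 * total, cum, f))
    mu0 = total
    mu1 = float(np.trapezoid(f * p, f))
    mu2 = float(np.trapezoid(f**2 * p, f))
    out[f"centroid_frequency_{axis}"] = float(np.sqrt(mu2 / mu0))
    disp = 1.0 - mu1**2 / (mu0 * mu2) if mu2 > 0 else np.nan
    out[f"frequency_dispersion_{axis}"] = float(np.sqrt(max(disp, 0.0)))
    out[f"frequency_mode_{axis}"] = float(f[np.argmax(p)])

    def band(lo: float, hi: float) -> float:
        # cumulative spectrum interpolated at the exact band edges, so a
        # peak straddling an edge is split rather than dropped
        return float(np.interp(hi, f, cum) - np.interp(lo, f, cum))

    e_low = band(0.0, 0.5)
    e_mid = band(0.5, 2.0)
    e_high = band(2.0, f[-1])
    out[f"energy_below_05_{axis}"] = e_low / total
    out[f"energy_05_2_{axis}"] = e_mid / total
    out[f"energy_above_2_{axis}"] = e_high / total
    if e_low + e_mid > 0:
        out[f"frequency_quotient_{axis}"] = e_high / (e_low + e_mid)
    return out


def frequency_features(traj: COPTrajectory) -> dict[str, float]:
    """The 20 spectral measures from the Welch PSD of the valid samples.

    Valid samples are concatenated across runs (tasks with intermittent
    loading, such as gait, would otherwise never accumulate a PSD window;
    the join artefacts are broadband and small next to the sway bands).
    Band energies are reported as fractions of total power.  A constant
    signal has zero total power and NaN for every frequency statistic.
    """
    out = {name: np.nan for name in FREQUENCY_FEATURES}
    if traj.n_valid < MIN_PSD_FRAMES:
        return out
    fs = traj.sampling_rate
    pts = traj.valid_points()
    out.update(_axis_spectral(pts[:, 0], fs, "ml"))
    out.update(_axis_spectral(pts[:, 1], fs, "ap"))
    return out


def compute_foot_features(traj: COPTrajectory) -> dict[str, float]:
    """All 60 per-foot features, in canonical 19/21/20 order."""
    out: dict[str, float] = {}
    out.update(positional_features(traj))
    out.update(dynamic_features(traj))
    out.update(frequency_features(traj))
    return {name: out[name] for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Foot combination
# ---------------------------------------------------------------------------

def combine_average(
    left: dict[str, float], right: dict[str, float]
) -> dict[str, float]:
    """Per-feature (left + right) / 2; NaN if either side is NaN."""
    return {k: (left[k] + right[k]) / 2.0 for k in left}


def combine_asymmetry(
    left: dict[str, float], right: dict[str, float]
) -> dict[str, float]:
    """Per-feature |left - right| / (left + right).

    Both sides zero gives 0 (no asymmetry of an absent quantity); a zero
    denominator with unequal sides gives NaN.  Negative denominators (only
    possible for signed features such as the ML mean) are computed as the
    formula states but trigger a warning, since the ratio then loses its
    [0, 1] interpretation.
    """
    out: dict[str, float] = {}
    n_negative = 0
    for k in left:
        l, r = left[k], right[k]
        if np.isnan(l) or np.isnan(r):
            out[k] = np.nan
            continue
        denom = l + r
        if denom == 0.0:
            out[k] = 0.0 if (l == 0.0 and r == 0.0) else np.nan
            continue
        if denom < 0:
            n_negative += 1
        out[k] = abs(l - r) / denom
    if n_negative:
        warnings.warn(
            f"{n_negative} asymmetry feature(s) had a negative denominator; "
            "their values fall outside [0, 1]",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Cohort feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x (cop_type, task, feature) matrix with class labels.

    ``data`` has a 3-level column MultiIndex (cop_type in
    {average, asymmetric}, task, feature name): 120 columns per task,
    720 for all six tasks.  ``labels`` maps subject id to its class label
    (may be None for unlabeled tables).
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def task_subset(self, task_set: str) -> "FeatureTable":
        """Restrict columns to a named task set (static/active/static_active)."""
        tasks = TASK_SETS[task_set]
        cols = self.data.columns[self.data.columns.get_level_values(1).isin(tasks)]
        return FeatureTable(data=self.data[cols], labels=self.labels)

    def flat(self) -> pd.DataFrame:
        """Columns flattened to 'cop_type|task|feature' strings."""
        out = self.data.copy()
        out.columns = flat_names(self.data.columns)
        return out

    def impute_median(self) -> "FeatureTable":
        """Replace NaN by the column median (all-NaN columns become 0)."""
        med = self.data.median()
        filled = self.data.fillna(med).fillna(0.0)
        n = int(self.data.isna().to_numpy().sum())
        if n:
            warnings.warn(f"imputed {n} missing feature value(s) by column median",
                          stacklevel=2)
        return FeatureTable(data=filled, labels=self.labels)

    def to_csv(self, path) -> str:
        self.data.to_csv(path)
        return str(path)


def flat_names(columns) -> list[str]:
    return ["|".join(c) for c in columns]


def minmax_normalize(
    table: FeatureTable,
    fit_rows: list | None = None,
    clip: bool = False,
) -> FeatureTable:
    """Column-wise min-max scaling to [0, 1].

    Scale parameters come from ``fit_rows`` (default: all subjects, the
    single global scaling).  Rows outside the fit range map outside [0, 1]
    unless ``clip`` is set.  Constant columns map to 0.
    """
    fit = table.data if fit_rows is None else table.data.loc[fit_rows]
    lo = fit.min()
    hi = fit.max()
    span = hi - lo
    scaled = (table.data - lo) / span.replace(0.0, np.nan)
    scaled.loc[:, (span == 0.0).to_numpy()] = 0.0
    if clip:
        scaled = scaled.clip(0.0, 1.0)
    return FeatureTable(data=scaled, labels=table.labels)


def _task_foot_vectors(
    recs: dict[str, InsoleRecording],
    task: str,
    geom: ZoneGeometry,
    force_threshold: float | None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Left/right per-foot feature vectors for one subject-task.

    For the one-foot stance task only the weight-bearing foot's frames are
    used: the left-stance segment yields the "left" vector and the
    right-stance segment the "right" vector, which the average/asymmetry
    combination then compares between stances.
    """
    left_rec, right_rec = recs["left"], recs["right"]
    if task == "OF":
        seg_l, seg_r = segment_one_foot(left_rec, right_rec, force_threshold)
        traj_l = trajectory_from_segments(
            compute_cop(left_rec, geom, force_threshold), seg_l
        )
        traj_r = trajectory_from_segments(
            compute_cop(right_rec, geom, force_threshold), seg_r
        )
    else:
        traj_l = compute_cop(left_rec, geom, force_threshold)
        traj_r = compute_cop(right_rec, geom, force_threshold)
    return compute_foot_features(traj_l), compute_foot_features(traj_r)


def build_feature_table(
    recordings: list[InsoleRecording],
    meta: dict[str, SubjectMeta] | None = None,
    geom: ZoneGeometry | None = None,
    tasks: tuple[str, ...] | None = None,
    target_rate: float = 12.0,
    force_threshold: float | None = None,
    label_fn=None,
) -> FeatureTable:
    """Assemble the cohort feature table from per-foot recordings.

    Recordings above ``target_rate`` are anti-alias down-sampled first.
    Subjects missing a task (or a foot for a task) get NaN for that task's
    120 columns, with a warning; impute before modeling.  ``label_fn`` maps
    a :class:`SubjectMeta` to a class label (default: the group name).
    """
    geom = geom or default_geometry()
    by_subject: dict[str, dict[str, dict[str, InsoleRecording]]] = {}
    task_order = tasks or TASKS
    for rec in recordings:
        if rec.task not in task_order:
            continue
        if rec.sampling_rate > target_rate:
            rec = antialias_downsample(rec, target_rate)
        by_subject.setdefault(rec.subject_id, {}).setdefault(rec.task, {})[
            rec.foot
        ] = rec

    columns = pd.MultiIndex.from_tuples(
        [
            (cop_type, task, feat)
            for task in task_order
            for cop_type in COP_TYPES
            for feat in FEATURE_NAMES
        ],
        names=["cop_type", "task", "feature"],
    )
    rows = {}
    for subject in sorted(by_subject):
        values = {}
        for task in task_order:
            recs = by_subject[subject].get(task, {})
            if "left" not in recs or "right" not in recs:
                warnings.warn(
                    f"subject {subject!r} missing {'both feet' if not recs else 'a foot'} "
                    f"for task {task}; features set to NaN",
                    stacklevel=2,
                )
                for cop_type in COP_TYPES:
                    for feat in FEATURE_NAMES:
                        values[(cop_type, task, feat)] = np.nan
                continue
            try:
                vec_l, vec_r = _task_foot_vectors(recs, task, geom, force_threshold)
            except SolePostureError as exc:
                warnings.warn(
                    f"subject {subject!r}, task {task}: {exc}; features set to NaN",
                    stacklevel=2,
                )
                for cop_type in COP_TYPES:
                    for feat in FEATURE_NAMES:
                        values[(cop_type, task, feat)] = np.nan
                continue
            avg = combine_average(vec_l, vec_r)
            asym = combine_asymmetry(vec_l, vec_r)
            for feat in FEATURE_NAMES:
                values[("average", task, feat)] = avg[feat]
                values[("asymmetric", task, feat)] = asym[feat]
        rows[subject] = values

    data = pd.DataFrame.from_dict(rows, orient="index")[columns]
    data.columns = columns
    data.index.name = "subject_id"
    labels = None
    if meta is not None:
        label_fn = label_fn or (lambda m: m.group)
        labels = pd.Series(
            {s: label_fn(meta[s]) for s in data.index if s in meta},
            name="label",
        ).reindex(data.index)
    return FeatureTable(data=data, labels=labels)
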