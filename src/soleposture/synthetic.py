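"""Synthetic insole-pressure cohorts with known group structure.

Every downstream stage (COP computation, the 60-feature bank, selection,
classification, Shapley interpretation) is testable without human data by
simulating cohorts in which the group differences are *injected in latent
COP space* — a mediolateral mean offset, sway magnitude, low-band spectral
content, velocity zero-crossing rate, and a left/right asymmetry gain —
and then rendering each latent COP trajectory into 8-zone force frames
whose force-weighted centroid reproduces the target COP exactly.

The rendered recordings run at the insole's native 50 Hz; the analysis
chain down-samples them to 12 Hz exactly as it would real acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial import Delaunay

from .exceptions import CohortError, ParameterError, RenderingError
from .insole_io import (
    FEET,
    InsoleRecording,
    SubjectMeta,
    TASKS,
    ZoneGeometry,
    default_geometry,
)

NATIVE_RATE = 50.0

#: Neutral COP rest position on the default insole (mm, ML from medial edge).
BASE_ML = 50.0
BASE_AP = 130.0

#: Baseline total force per loaded foot (N), half body weight of ~140 kg pair.
BASE_FORCE = 700.0

DEFAULT_DURATIONS = {"EO": 30.0, "EC": 30.0, "OF": 60.0, "GAIT": 20.0, "FR": 15.0, "BO": 10.0}

#: Gait cycle: alternating single-support stance windows of this length (s).
GAIT_STANCE_S = 0.6


@dataclass
class TaskEffect:
    """Latent-COP generative parameters for one group on one task.

    ``low_band_gain`` scales the <0.5 Hz ML sway component,
    ``zero_crossing_gain`` the 1.5-3 Hz component of both axes (raising the
    velocity zero-crossing rate), and ``asymmetry_gain`` multiplies the
    right foot's offsets and sway SDs relative to the left.
    """

    ml_offset: float = 0.0  # mm
    ap_offset: float = 0.0  # mm
    sway_sd_ml: float = 3.0  # mm
    sway_sd_ap: float = 4.0  # mm
    low_band_gain: float = 1.0
    zero_crossing_gain: float = 1.0
    asymmetry_gain: float = 1.0
    duration: float = 30.0  # s
    force_profile: str = "constant"  # constant | gait

    def __post_init__(self) -> None:
        for name in ("sway_sd_ml", "sway_sd_ap"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        for name in ("low_band_gain", "zero_crossing_gain", "asymmetry_gain"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.duration) or self.duration < 5.0:
            raise ParameterError("duration must be >= 5 s")
        if not np.isfinite(self.ml_offset) or not np.isfinite(self.ap_offset):
            raise ParameterError("offsets must be finite")

    def scaled(self, gain: float) -> "TaskEffect":
        """Right-foot parameters: offsets and SDs scaled by ``gain``."""
        return replace(
            self,
            ml_offset=self.ml_offset * gain,
            ap_offset=self.ap_offset * gain,
            sway_sd_ml=self.sway_sd_ml * gain,
            sway_sd_ap=self.sway_sd_ap * gain,
        )


def default_task_effect(task: str, **overrides) -> TaskEffect:
    base = dict(
        duration=DEFAULT_DURATIONS[task],
        force_profile="gait" if task == "GAIT" else "constant",
    )
    base.update(overrides)
    return TaskEffect(**base)


@dataclass
class EffectConfig:
    """Per-group, per-task generative parameters: group -> task -> TaskEffect."""

    groups: dict[str, dict[str, TaskEffect]]

    def tasks(self) -> tuple[str, ...]:
        first = next(iter(self.groups.values()))
        return tuple(first)


def null_effects(
    group_names: tuple[str, ...] = ("pd", "age_matched_control"),
    tasks: tuple[str, ...] = TASKS,
) -> EffectConfig:
    """Identical generative parameters for every group (the null cohort)."""
    return EffectConfig(
        groups={
            g: {t: default_task_effect(t) for t in tasks} for g in group_names
        }
    )


def pd_vs_control_preset(
    effect_scale: float = 1.0, tasks: tuple[str, ...] = TASKS
) -> EffectConfig:
    """Parkinsonian postural signature vs age-matched controls.

    Injects, in the pd group: a lateral (ML) mean shift and enlarged sway
    during quiet stance with eyes open, enlarged sway while bending over,
    and a left/right asymmetry gain on both — the directions observed for
    the disease/control contrast.  Magnitudes scale with ``effect_scale``.
    """
    cfg = null_effects(("pd", "age_matched_control"), tasks)
    s = effect_scale
    pd_tasks = cfg.groups["pd"]
    if "EO" in pd_tasks:
        pd_tasks["EO"] = replace(
            pd_tasks["EO"],
            ml_offset=4.0 * s,
            sway_sd_ml=3.0 * (1 + 0.4 * s),
            sway_sd_ap=4.0 * (1 + 0.4 * s),
            asymmetry_gain=1 + 0.15 * s,
        )
    if "BO" in pd_tasks:
        pd_tasks["BO"] = replace(
            pd_tasks["BO"],
            ml_offset=3.0 * s,
            sway_sd_ml=3.0 * (1 + 0.3 * s),
            asymmetry_gain=1 + 0.15 * s,
        )
    return cfg


def faller_vs_nonfaller_preset(
    effect_scale: float = 1.0, tasks: tuple[str, ...] = TASKS
) -> EffectConfig:
    """PD-faller signature: faster eyes-closed sway reversals, more ML
    low-band power during gait, more eyes-closed asymmetry."""
    cfg = null_effects(("pd_faller", "pd_nonfaller"), tasks)
    s = effect_scale
    f_tasks = cfg.groups["pd_faller"]
    if "EC" in f_tasks:
        f_tasks["EC"] = replace(
            f_tasks["EC"],
            zero_crossing_gain=1 + 0.8 * s,
            asymmetry_gain=1 + 0.2 * s,
        )
    if "GAIT" in f_tasks:
        f_tasks["GAIT"] = replace(f_tasks["GAIT"], low_band_gain=1 + 1.5 * s)
    return cfg


def single_ml_offset_preset(
    offset_mm: float = 10.0,
    sway_sd: float = 2.0,
    task: str = "EO",
    tasks: tuple[str, ...] | None = None,
    group_names: tuple[str, ...] = ("pd", "age_matched_control"),
) -> EffectConfig:
    """One dominant injected effect: an ML mean offset on one task.

    With offset 10 mm against 2 mm sway SD the standardized effect size is
    d = 5, which should make the corresponding mean-value-ML feature
    near-perfectly separating — the canonical recovery experiment.
    """
    tasks = tasks or (task,)
    cfg = EffectConfig(
        groups={
            g: {
                t: default_task_effect(t, sway_sd_ml=sway_sd, sway_sd_ap=sway_sd)
                for t in tasks
            }
            for g in group_names
        }
    )
    cfg.groups[group_names[0]][task] = replace(
        cfg.groups[group_names[0]][task], ml_offset=offset_mm
    )
    return cfg


# ---------------------------------------------------------------------------
# Latent COP simulation
# ---------------------------------------------------------------------------

def _bandlimited_components(
    n: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three unit-SD noise components: <0.4 Hz, 0.4-1.5 Hz, 1.5-3 Hz."""
    white = rng.standard_normal((n, 3))
    sos_lo = signal.butter(2, 0.4, btype="low", fs=fs, output="sos")
    sos_mid = signal.butter(2, (0.4, 1.5), btype="band", fs=fs, output="sos")
    sos_hi = signal.butter(2, (1.5, 3.0), btype="band", fs=fs, output="sos")
    comps = []
    for sos, col in zip((sos_lo, sos_mid, sos_hi), range(3)):
        x = signal.sosfiltfilt(sos, white[:, col])
        sd = x.std()
        comps.append(x / sd if sd > 0 else x)
    return comps[0], comps[1], comps[2]


def _sway_axis(
    n: int,
    fs: float,
    rng: np.random.Generator,
    sd: float,
    low_gain: float,
    zc_gain: float,
) -> np.ndarray:
    """Stationary band-limited (<3 Hz) sway with unit mixing then SD scaling."""
    if sd == 0.0:
        return np.zeros(n)
    lo, mid, hi = _bandlimited_components(n, fs, rng)
    mix = low_gain * lo + mid + 0.6 * zc_gain * hi
    s = mix.std()
    if s > 0:
        mix = mix / s
    return sd * mix


def active_template(task: str, t: np.ndarray, duration: float) -> np.ndarray:
    """Deterministic AP excursion template for the active tasks (mm).

    FR: smooth forward reach and return; BO: deeper forward excursion while
    bending; GAIT uses stance-windowed heel-to-toe sweeps instead (see
    :func:`simulate_cop_trajectory`).
    """
    phase = np.clip(t / duration, 0.0, 1.0)
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    if task == "FR":
        return 55.0 * bump
    if task == "BO":
        return 60.0 * bump
    return np.zeros_like(t)


def _gait_stance_mask(t: np.ndarray, side: str) -> tuple[np.ndarray, np.ndarray]:
    """(stance mask, stance phase in [0,1]) for alternating single support."""
    cycle = t / GAIT_STANCE_S
    idx = np.floor(cycle).astype(int)
    phase = cycle - idx
    if side == "left":
        mask = idx % 2 == 0
    else:
        mask = idx % 2 == 1
    return mask, phase


def simulate_cop_trajectory(
    task: str,
    params: TaskEffect,
    rng: np.random.Generator,
    side: str = "left",
    fs: float = NATIVE_RATE,
    noise: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (COP, total force) series for one foot on one task.

    Returns ``(cop, force)`` with ``cop`` of shape (n, 2) in insole mm and
    ``force`` of shape (n,).  Static tasks are a stationary band-limited
    2-D process (mean = offsets, SD = sway SDs) under constant load; active
    tasks add a deterministic template, and gait alternates loaded stance
    windows with zero-force swing.  Passing a precomputed unit-SD ``noise``
    pair lets both feet share one latent realisation.
    """
    if task not in TASKS:
        raise ParameterError(f"unknown task {task!r}")
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    if noise is None:
        noise_ml = _sway_axis(
            n, fs, rng, 1.0, params.low_band_gain, params.zero_crossing_gain
        )
        noise_ap = _sway_axis(n, fs, rng, 1.0, 1.0, params.zero_crossing_gain)
    else:
        noise_ml, noise_ap = noise
    ml = BASE_ML + params.ml_offset + params.sway_sd_ml * noise_ml
    ap = BASE_AP + params.ap_offset + params.sway_sd_ap * noise_ap
    force = np.full(n, BASE_FORCE)

    if task in ("FR", "BO"):
        ap = ap + active_template(task, t, params.duration)
        if task == "BO":
            phase = np.clip(t / params.duration, 0.0, 1.0)
            force = BASE_FORCE * (1.0 - 0.35 * 0.5 * (1 - np.cos(2 * np.pi * phase)))
    elif task == "GAIT":
        mask, phase = _gait_stance_mask(t, side)
        # heel-to-toe AP sweep within each stance, double-bump load curve
        ap = np.where(mask, 45.0 + 150.0 * phase + 0.3 * params.sway_sd_ap * noise_ap, BASE_AP)
        ml = np.where(
            mask,
            BASE_ML + params.ml_offset + params.sway_sd_ml * noise_ml,
            BASE_ML,
        )
        load = np.sin(np.pi * phase) * (1.0 + 0.25 * np.cos(2 * np.pi * phase))
        force = np.where(mask, BASE_FORCE * np.clip(load, 0.0, None), 0.0)
    elif task == "OF":
        half = n // 2
        loaded = np.zeros(n, dtype=bool)
        if side == "left":
            loaded[:half] = True
        else:
            loaded[half:] = True
        force = np.where(loaded, BASE_FORCE, 0.0)
    if not (np.all(np.isfinite(ml)) and np.all(np.isfinite(ap))):
        raise ParameterError("non-finite values in simulated trajectory")
    return np.column_stack([ml, ap]), force


# ---------------------------------------------------------------------------
# Rendering latent COP into 8-zone forces
# ---------------------------------------------------------------------------

def _project_to_hull(points: np.ndarray, hull_pts: np.ndarray) -> np.ndarray:
    """Project points onto the nearest point of the convex hull boundary."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(hull_pts)
    verts = hull_pts[hull.vertices]
    best = None
    best_d = None
    m = len(verts)
    for k in range(m):
        a = verts[k]
        b = verts[(k + 1) % m]
        ab = b - a
        tt = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
        proj = a + tt[:, None] * ab
        d = np.linalg.norm(points - proj, axis=1)
        if best is None:
            best, best_d = proj, d
        else:
            upd = d < best_d
            best[upd] = proj[upd]
            best_d[upd] = d[upd]
    return best


def _active_set_frame(A: np.ndarray, b: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Minimum-norm f >= 0 with A f = b, by active-set elimination."""
    n = A.shape[1]
    free = list(range(n))
    for _ in range(n):
        Af = A[:, free]
        G = Af @ Af.T
        try:
            lam = np.linalg.solve(G, b)
        except np.linalg.LinAlgError:
            lam, *_ = np.linalg.lstsq(G, b, rcond=None)
        f_free = Af.T @ lam
        if f_free.min() >= -tol:
            f = np.zeros(n)
            f[free] = np.clip(f_free, 0.0, None)
            if np.linalg.norm(A @ f - b) <= 1e-6 * max(1.0, np.linalg.norm(b)):
                return f
            # clipping perturbed the equalities: refine once on support
            support = [free[i] for i in range(len(free)) if f_free[i] > tol]
            if support:
                As = A[:, support]
                fs_, *_ = np.linalg.lstsq(As, b, rcond=None)
                if fs_.min() >= -tol:
                    f = np.zeros(n)
                    f[support] = np.clip(fs_, 0.0, None)
                    if np.linalg.norm(A @ f - b) <= 1e-6 * max(1.0, np.linalg.norm(b)):
                        return f
            raise RenderingError("equality constraints not met after clipping")
        drop = int(np.argmin(f_free))
        free.pop(drop)
        if len(free) < 1:
            break
    raise RenderingError("no feasible non-negative force distribution")


def render_zone_forces(
    cop: np.ndarray,
    total_force: np.ndarray,
    geom: ZoneGeometry | None = None,
) -> np.ndarray:
    """Non-negative 8-zone forces realising target COP and total force.

    Per frame, solves the minimum-norm least-squares problem
    ``min ||f||^2  s.t.  sum f_i = F,  sum f_i D_i = F * COP,  f >= 0``.
    The unconstrained minimum-norm solution is computed in closed form for
    all frames at once; frames where it has negative components fall back
    to a small active-set solve.  COP targets outside the zone convex hull
    are projected onto the hull boundary (with a warning).  Zero-force
    frames render as all-zero forces.
    """
    geom = geom or default_geometry()
    cop = np.asarray(cop, dtype=float)
    total_force = np.asarray(total_force, dtype=float)
    n = len(cop)
    A = np.vstack([geom.ml, geom.ap, np.ones(8)])
    pts = geom.points

    loaded = total_force > 0
    cop_used = cop.copy()
    if loaded.any():
        tri = Delaunay(pts)
        outside = loaded & (tri.find_simplex(cop) < 0)
        if outside.any():
            cop_used[outside] = _project_to_hull(cop[outside], pts)
            warnings.warn(
                f"{int(outside.sum())} COP frame(s) outside the zone hull "
                "were projected onto the hull boundary",
                stacklevel=2,
            )

    b = np.column_stack(
        [total_force * cop_used[:, 0], total_force * cop_used[:, 1], total_force]
    )
    pinv = A.T @ np.linalg.inv(A @ A.T)  # (8, 3)
    forces = b @ pinv.T
    forces[~loaded] = 0.0
    bad = loaded & (forces.min(axis=1) < -1e-12)
    for i in np.flatnonzero(bad):
        try:
            forces[i] = _active_set_frame(A, b[i])
        except RenderingError as exc:
            raise RenderingError(f"frame {i}: {exc}") from exc
    return np.clip(forces, 0.0, None)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

GROUP_KEY_META = {
    "pd_faller": ("pd", True),
    "pd_nonfaller": ("pd", False),
}


@dataclass
class SyntheticCohort:
    """Rendered recordings, subject metadata and the generative truth."""

    recordings: list[InsoleRecording]
    meta: dict[str, SubjectMeta]
    truth: dict = field(default_factory=dict)

    def labels(self) -> dict[str, str]:
        """Subject id -> generative group key (classification label)."""
        return dict(self.truth["group_key"])


def _subject_effects(
    effects: dict[str, TaskEffect], rng: np.random.Generator
) -> dict[str, TaskEffect]:
    """Per-subject latent parameters: mild lognormal/additive jitter."""
    out = {}
    for task, eff in effects.items():
        out[task] = replace(
            eff,
            ml_offset=eff.ml_offset + rng.normal(0.0, 0.4),
            ap_offset=eff.ap_offset + rng.normal(0.0, 0.4),
            sway_sd_ml=eff.sway_sd_ml * float(np.exp(rng.normal(0.0, 0.1))),
            sway_sd_ap=eff.sway_sd_ap * float(np.exp(rng.normal(0.0, 0.1))),
        )
    return out


def simulate_cohort(
    n_per_group: dict[str, int],
    effects: EffectConfig,
    seed: int,
    geom: ZoneGeometry | None = None,
    fs: float = NATIVE_RATE,
) -> SyntheticCohort:
    """Simulate and render a full cohort, deterministic given ``seed``.

    Each subject draws jittered per-task latent parameters; the right foot
    scales the left foot's parameters by the task's ``asymmetry_gain`` and
    *shares its latent noise realisation*, so a gain of exactly 1 yields
    mirror-identical feet and all-zero asymmetry features (up to rendering
    round-off).
    """
    geom = geom or default_geometry()
    for g, n in n_per_group.items():
        if g not in effects.groups:
            raise CohortError(f"no effect parameters for group {g!r}")
        if n < 2:
            raise CohortError(f"need >= 2 subjects per group, got {n} for {g!r}")
    ss = np.random.SeedSequence(seed)
    recordings: list[InsoleRecording] = []
    meta: dict[str, SubjectMeta] = {}
    group_key: dict[str, str] = {}
    latent: dict[str, dict] = {}
    sid = 0
    for gkey in sorted(n_per_group):
        base_group, faller = GROUP_KEY_META.get(gkey, (gkey, None))
        for _ in range(n_per_group[gkey]):
            subject = f"S{sid:03d}"
            sid += 1
            rng = np.random.default_rng(ss.spawn(1)[0])
            subj_eff = _subject_effects(effects.groups[gkey], rng)
            meta[subject] = SubjectMeta(
                subject_id=subject, group=base_group, faller=faller
            )
            group_key[subject] = gkey
            latent[subject] = {t: vars(e).copy() for t, e in subj_eff.items()}
            for task, eff in subj_eff.items():
                n_frames = int(round(eff.duration * fs))
                shared = (
                    _sway_axis(n_frames, fs, rng, 1.0, eff.low_band_gain,
                               eff.zero_crossing_gain),
                    _sway_axis(n_frames, fs, rng, 1.0, 1.0,
                               eff.zero_crossing_gain),
                )
                for foot in FEET:
                    params = eff if foot == "left" else eff.scaled(eff.asymmetry_gain)
                    cop, force = simulate_cop_trajectory(
                        task, params, rng, side=foot, fs=fs, noise=shared
                    )
                    forces = render_zone_forces(cop, force, geom)
                    recordings.append(
                        InsoleRecording(
                            subject_id=subject,
                            task=task,
                            foot=foot,
                            timestamps=np.arange(n_frames) / fs,
                            forces=forces,
                            sampling_rate=fs,
                        )
                    )
    truth = {"seed": seed, "group_key": group_key, "latent": latent}
    return SyntheticCohort(recordings=recordings, meta=meta, truth=truth)
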