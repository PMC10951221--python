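import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from soleposture import COPTrajectory, InsoleRecording, default_geometry

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


def make_trajectory(ml, ap, fs=12.0, task="EO", foot="left", valid=None):
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if valid is None:
        valid = np.isfinite(ml) & np.isfinite(ap)
    return COPTrajectory(
        ml=np.where(valid, ml, np.nan),
        ap=np.where(valid, ap, np.nan),
        valid=np.asarray(valid, dtype=bool),
        sampling_rate=fs,
        foot=foot,
        task=task,
    )


def make_recording(forces, fs=50.0, task="EO", foot="left", subject="s1"):
    forces = np.asarray(forces, dtype=float)
    n = len(forces)
    return InsoleRecording(
        subject_id=subject,
        task=task,
        foot=foot,
        timestamps=np.arange(n) / fs,
        forces=forces,
        sampling_rate=fs,
    )


@pytest.fixture
def sine_trajectory():
    """ML = sin(2*pi*1*t), AP = 0.5*sin(2*pi*0.5*t), 30 s at 12 Hz."""
    t = np.arange(int(30 * 12)) / 12.0
    return make_trajectory(np.sin(2 * np.pi * t), 0.5 * np.sin(np.pi * t))
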