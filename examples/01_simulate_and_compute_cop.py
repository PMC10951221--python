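"""Simulate a small insole cohort and compute center-of-pressure traces.

Builds a two-group synthetic cohort (Parkinson's-like vs age-matched
control), renders each latent COP trajectory into 8-zone forces at 50 Hz,
down-samples one recording to the 12 Hz analysis rate, and recomputes the
COP from the rendered forces.
"""

import warnings

import numpy as np

from soleposture import antialias_downsample, compute_cop, default_geometry, simulate_cohort
from soleposture.synthetic import pd_vs_control_preset

warnings.filterwarnings("ignore")  # a few COP frames get hull-projected

cohort = simulate_cohort(
    {"pd": 3, "age_matched_control": 3}, pd_vs_control_preset(), seed=11
)
print(f"{len(cohort.recordings)} recordings "
      f"({len(cohort.meta)} subjects x 6 tasks x 2 feet)")

rec = next(r for r in cohort.recordings if r.task == "EO" and r.foot == "left")
print(f"subject {rec.subject_id}: task {rec.task}, {rec.n_frames} frames at "
      f"{rec.sampling_rate:.0f} Hz, total force ~{rec.total_force().mean():.0f}")

rec12 = antialias_downsample(rec, 12.0)
traj = compute_cop(rec12, default_geometry())
pts = traj.valid_points()
print(f"COP at 12 Hz: {traj.n_valid} valid frames, "
      f"mean ML {pts[:, 0].mean():.1f} mm, mean AP {pts[:, 1].mean():.1f} mm, "
      f"sway SD (ML, AP) = ({pts[:, 0].std():.2f}, {pts[:, 1].std():.2f}) mm")
# The mean ML position is the weight-bearing axis under the foot; the sway
# SDs are the quiet-stance postural noise the feature bank summarises.
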