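"""Small report plots: stabilogram, averaged ROC, per-group z-score polar."""

from __future__ import annotations

import numpy as np

from .cop import COPTrajectory
from .selection import CVReport


def plot_stabilogram(traj: COPTrajectory, ax=None):
    """COP path in the (ML, AP) plane; invalid frames are simply absent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = traj.valid_points()
    ax.plot(pts[:, 0], pts[:, 1], lw=0.6)
    ax.set_xlabel("ML (mm)")
    ax.set_ylabel("AP (mm)")
    ax.set_title(f"{traj.task} / {traj.foot}")
    ax.set_aspect("equal")
    return ax


def plot_mean_roc(reports: dict[str, CVReport], ax=None):
    """Fold-averaged ROC curves with AUC +/- SEM per architecture."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for arch, rep in reports.items():
        ax.plot(
            rep.fpr_grid,
            rep.mean_tpr,
            label=f"{arch}: AUC {rep.auc_mean:.2f}±{rep.auc_sem:.2f}",
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    return ax


def plot_group_zscores(zscores, ax=None):
    """Polar plot of per-group mean z-scores across features.

    The radial origin is z = -1 so that opposite-signed group scores are
    both visible; the black circle marks z = 0.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    features = list(zscores.columns)
    angles = np.linspace(0, 2 * np.pi, len(features), endpoint=False)
    closed = np.concatenate([angles, angles[:1]])
    for group, row in zscores.iterrows():
        vals = np.concatenate([row.to_numpy(), row.to_numpy()[:1]])
        ax.plot(closed, vals, label=str(group))
    ax.plot(closed, np.zeros_like(closed), "k-", lw=1.0)
    ax.set_xticks(angles)
    ax.set_xticklabels(features, fontsize=6)
    ax.legend(loc="upper right", fontsize=7)
    return ax
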