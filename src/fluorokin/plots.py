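"""Report figures: mTRE over the motion cycle and the six kinematic
components over time."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import ErrorSeries
from .kinematics import JointPose

__all__ = ["plot_mtre_series", "plot_kinematics"]

_COMPONENT_LABELS = [
    ("Flexion(+)/Extension(-)", "deg"),
    ("Adduction(+)/Abduction(-)", "deg"),
    ("Internal(+)/External(-)", "deg"),
    ("Medial(+)/Lateral(-)", "mm"),
    ("Anterior(+)/Posterior(-)", "mm"),
    ("Proximal(+)/Distal(-)", "mm"),
]


def plot_mtre_series(series: ErrorSeries, times=None, path=None, ax=None):
    """Per-frame mTRE with the registration-success threshold line."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 3))
    t = np.asarray(times) if times is not None else np.arange(len(series.mtre))
    ax.plot(t, series.mtre, lw=1.2, label="mTRE")
    ax.axhline(series.threshold, color="r", ls="--", lw=1,
               label=f"success threshold ({series.threshold} mm)")
    ax.set_xlabel("time (s)" if times is not None else "frame")
    ax.set_ylabel("mTRE (mm)")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def plot_kinematics(series_by_label: dict[str, list[JointPose]], times, path=None):
    """Six kinematic components over time, one panel each; multiple labelled
    series (e.g. reconstructed-model vs reference-model registrations)."""
    fig, axes = plt.subplots(2, 3, figsize=(10, 5.5), sharex=True)
    for label, series in series_by_label.items():
        data = np.stack([jp.to_vector() for jp in series])
        for k, ax in enumerate(axes.ravel()):
            ax.plot(times, data[:, k], lw=1.1, label=label)
    for k, ax in enumerate(axes.ravel()):
        name, unit = _COMPONENT_LABELS[k]
        ax.set_title(name, fontsize=9)
        ax.set_ylabel(unit, fontsize=8)
    for ax in axes[1]:
        ax.set_xlabel("time (s)", fontsize=8)
    axes[0, 0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
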