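"""Report figures: flow curves, ROI overlays, cohort SV distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import FlowCurve, ROIMask, SITES

__all__ = ["plot_flow_curve", "plot_roi_overlay", "plot_cohort_distributions"]


def plot_flow_curve(curve: FlowCurve, path: str | Path, truth: np.ndarray | None = None):
    """Flow rate vs. cardiac phase, optionally against an analytic truth."""
    t = np.arange(curve.n_phases) / curve.n_phases * 100.0
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(t, curve.q, "o-", lw=1.2, ms=3, label="measured")
    if truth is not None:
        tt = np.arange(len(truth)) / len(truth) * 100.0
        ax.plot(tt, truth, "--", lw=1.0, label="analytic")
        ax.legend(frameon=False, fontsize=8)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("cardiac cycle (%)")
    ax.set_ylabel("flow rate (µL/s)")
    ax.set_title(f"CSF flow, site {curve.site}")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_roi_overlay(magnitude_frame: np.ndarray, roi: ROIMask, path: str | Path):
    """ROI contour over a magnitude frame."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(magnitude_frame, cmap="gray", interpolation="nearest")
    ax.contour(roi.mask.astype(float), levels=[0.5], colors="r", linewidths=1.0)
    ax.set_title(f"ROI ({roi.site}), {roi.n_voxels} voxels, {roi.area_mm2:.2f} mm$^2$")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_cohort_distributions(table: pd.DataFrame, path: str | Path):
    """Strip plot of per-patient stroke volumes per site, split by outcome."""
    rng = np.random.default_rng(0)  # jitter only
    fig, axes = plt.subplots(1, len(SITES), figsize=(2.2 * len(SITES), 3.2), sharey=False)
    for ax, site in zip(axes, SITES):
        col = f"sv_{site}"
        for i, (group, color) in enumerate(
            (("relieved", "tab:blue"), ("not_relieved", "tab:orange"))
        ):
            vals = table.loc[table["group"] == group, col]
            x = i + rng.uniform(-0.12, 0.12, len(vals))
            ax.plot(x, vals, "o", ms=3.5, alpha=0.7, color=color)
        ax.set_xticks([0, 1], ["relief", "no relief"], fontsize=7)
        ax.set_title(site, fontsize=9)
        if ax is axes[0]:
            ax.set_ylabel("SV (µL per CC)")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
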