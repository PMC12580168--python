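"""Passport profile figures.

Two complementary displays per subject:

* corrected-limits view — the [Hb] series (black) with the original
  individual limits (red) and the PV-corrected limits (purple); visits
  whose atypical finding is explained by PV are shaded green;
* PV-overlay view — the [Hb] series and original limits on the left
  axis, the estimated-PV z-score (blue) on a right axis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .domain import Flag

COLORS = {
    "hb": "black",
    "original": "tab:red",
    "corrected": "purple",
    "pv_z": "tab:blue",
    "explained": "tab:green",
}


def _visits(profile) -> np.ndarray:
    return profile.samples["visit_index"].to_numpy()


def plot_corrected_limits(profile, ax=None):
    """[Hb] series with original and PV-corrected individual limits."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = _visits(profile)
    ax.plot(x, profile.hb, "o-", color=COLORS["hb"], label="[Hb]")
    ax.plot(
        x,
        [l.lower for l in profile.limits_hb],
        "-",
        color=COLORS["original"],
        label="original limits",
    )
    ax.plot(
        x, [l.upper for l in profile.limits_hb], "-", color=COLORS["original"]
    )
    ax.plot(
        x,
        [c.lower for c in profile.corrected_limits_hb],
        "--",
        color=COLORS["corrected"],
        label="corrected limits",
    )
    ax.plot(
        x,
        [c.upper for c in profile.corrected_limits_hb],
        "--",
        color=COLORS["corrected"],
    )
    for xi, flag in zip(x, profile.flags_hb):
        if flag is Flag.ATPF_EXPLAINED_BY_PV:
            ax.axvspan(
                xi - 0.3, xi + 0.3, color=COLORS["explained"], alpha=0.25
            )
    ax.set_xlabel("visit")
    ax.set_ylabel("[Hb] (g·dL$^{-1}$)")
    ax.set_title(f"{profile.subject_id} — corrected limits")
    ax.legend(loc="best", fontsize=8)
    return ax.figure


def plot_pv_overlay(profile, ax=None):
    """[Hb] with limits (left axis) and PV z-score overlay (right axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = _visits(profile)
    ax.plot(x, profile.hb, "o-", color=COLORS["hb"], label="[Hb]")
    ax.plot(
        x,
        [l.lower for l in profile.limits_hb],
        "-",
        color=COLORS["original"],
        label="limits",
    )
    ax.plot(
        x, [l.upper for l in profile.limits_hb], "-", color=COLORS["original"]
    )
    ax.set_xlabel("visit")
    ax.set_ylabel("[Hb] (g·dL$^{-1}$)")
    ax2 = ax.twinx()
    ax2.plot(
        x, profile.pv_z, "s--", color=COLORS["pv_z"], label="PV z-score"
    )
    ax2.set_ylabel("estimated PV (z-score)", color=COLORS["pv_z"])
    ax2.axhline(0.0, color=COLORS["pv_z"], alpha=0.2, linewidth=0.8)
    ax.set_title(f"{profile.subject_id} — PV overlay")
    return ax.figure


def plot_sensitivity_grid(grid, ax=None):
    """Heat map of the perturbation sensitivity grid (levels × markers)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    data = np.abs(grid.to_numpy(dtype=float))
    vmax = np.nanmax(data) or 1.0
    im = ax.imshow(data, cmap="Reds", vmin=0, vmax=vmax, aspect="auto")
    ax.set_title("|mean ΔPV| per marker perturbation")
    ax.set_xticks(range(len(grid.columns)), grid.columns)
    ax.set_yticks(range(len(grid.index)), [f"{v:+g}%" for v in grid.index])
    ax.set_xlabel("marker")
    ax.set_ylabel("perturbation")
    ax.figure.colorbar(im, ax=ax, label="ΔPV estimate (mL)")
    return ax.figure


def close(fig) -> None:
    plt.close(fig)
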