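"""Figure helpers: attractor images, class density-profile bands, sign-flip diagnostics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .attractor import AttractorImage, profile_band_summary

__all__ = ["plot_attractor", "plot_profile_bands", "plot_theta_core_groups"]

_CLASS_COLORS = {"control": "tab:blue", "paf": "tab:red"}


def plot_attractor(image: AttractorImage, path=None, title: str = "SPAR attractor"):
    """Render the normalized attractor density on the (v, w) plane."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ext = image.extent
    ax.imshow(
        image.grid.T,
        origin="lower",
        extent=(-ext, ext, -ext, ext),
        cmap="viridis",
        interpolation="nearest",
    )
    ax.set_xlabel("v")
    ax.set_ylabel("w")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def _band(ax, grid, profiles, color, label):
    s = profile_band_summary(profiles)
    ax.plot(grid, s["mean"], color=color, label=label)
    ax.plot(grid, s["mean_plus_sd"], color=color, linestyle=":")
    ax.fill_between(grid, s["p5"], s["p95"], color=color, alpha=0.2)


def plot_profile_bands(grid, profiles_by_class: dict, xlabel: str, path=None, title=""):
    """Per-class mean / mean+SD / 5th-95th percentile bands of density profiles."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for cls, profiles in profiles_by_class.items():
        if profiles:
            _band(ax, grid, profiles, _CLASS_COLORS.get(cls, "gray"), cls)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    ax.set_title(title)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_theta_core_groups(grid, groups: dict, path=None):
    """Theta-core density bands per group (e.g. flipped / unflipped / corrected)."""
    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (name, profiles) in zip(axes, groups.items()):
        if profiles:
            _band(ax, grid, profiles, "tab:purple", name)
        ax.set_xlabel("theta (rad)")
        ax.set_title(name)
    axes[0].set_ylabel("density")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
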