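"""Power-curve plots (matplotlib, styling free)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt

from .empirical import EmpiricalPowerCurve
from .power import PowerSurface

__all__ = ["plot_power_surface", "plot_empirical_vs_predicted"]


def plot_power_surface(surface: PowerSurface, threshold: float = 0.80, ax=None):
    """One power curve per trial count: power vs number of subjects."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ns = surface.design.n_subjects_grid
    for j, t in enumerate(surface.design.trials_grid):
        ax.plot(ns, surface.power[:, j], label=f"{t} trial{'s' if t > 1 else ''}")
    ax.axhline(threshold, color="grey", ls="--", lw=1)
    ax.set_xlabel("number of subjects")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{surface.design.design}-subject design, "
                 f"effect {abs(surface.design.effect):.2f}")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_empirical_vs_predicted(
    curve: EmpiricalPowerCurve,
    predicted: dict[int, float] | None = None,
    ax=None,
):
    """Dotted observed-power curve, optionally with a solid predicted curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(
        curve.sample_sizes,
        curve.observed_power,
        "o:",
        label=f"observed ({curve.window_length} strides)",
    )
    if predicted:
        sizes = sorted(predicted)
        ax.plot(sizes, [predicted[s] for s in sizes], "-", label="predicted")
    ax.axhline(0.80, color="grey", ls="--", lw=1)
    ax.set_xlabel("number of subjects")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return ax
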