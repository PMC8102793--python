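"""Figure output: stripcharts with decile bars and shift-function panels."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .robust import ShiftResult  # noqa: E402


def stripchart(x, y, labels=("Females", "Males"), outcome: str = "outcome",
               path=None):
    """Jittered stripchart of the two group distributions (no shift panel)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 3))
    rng = np.random.default_rng(0)
    for i, (sample, lab, color) in enumerate(
            zip((x, y), labels, ("tab:orange", "tab:purple"))):
        ax.plot(sample, i + 0.08 * rng.standard_normal(sample.size), ".",
                alpha=0.6, color=color, label=lab)
    ax.set_yticks([0, 1], labels)
    ax.set_xlabel(outcome)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def shift_panels(x, y, shift: ShiftResult, labels=("Females", "Males"),
                 outcome: str = "outcome", path=None):
    """Two-panel group comparison: stripchart with Harrell-Davis deciles (top)
    and the decile shift function with simultaneous bootstrap CIs (bottom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(6, 6))

    rng = np.random.default_rng(0)  # jitter for display only
    for i, (sample, lab, color) in enumerate(
            zip((x, y), labels, ("tab:orange", "tab:purple"))):
        jitter = 0.08 * rng.standard_normal(sample.size)
        ax0.plot(sample, i + jitter, ".", alpha=0.5, color=color, label=lab)
        q = shift.q_x if i == 0 else shift.q_y
        for j, v in enumerate(q):
            lw = 2.5 if j == 4 else 1.0  # heavier bar at the median
            ax0.plot([v, v], [i - 0.25, i + 0.25], color="k", lw=lw)
    ax0.set_yticks([0, 1], labels)
    ax0.set_xlabel(outcome)
    ax0.set_title(f"{outcome}: group distributions with deciles")

    colors = np.where(shift.difference >= 0, "tab:orange", "tab:purple")
    ax1.axhline(0.0, color="gray", lw=0.8)
    ax1.vlines(shift.q_x, shift.ci_low, shift.ci_high, color="k", lw=1)
    ax1.scatter(shift.q_x, shift.difference, c=colors, zorder=3)
    ax1.set_xlabel(f"{labels[0]} deciles ({outcome})")
    ax1.set_ylabel(f"{labels[0]} - {labels[1]}")
    ax1.set_title("Shift function (simultaneous 95% bootstrap CIs)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
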