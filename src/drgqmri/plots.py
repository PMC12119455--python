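"""Optional figures: group dot plots and ROC curves."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .stats import RocResult

__all__ = ["plot_group_dots", "plot_roc"]


def plot_group_dots(values_by_group: dict, ylabel: str, ax=None):
    """Per-group dot plot with median bars; returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)  # fixed jitter for reproducible figures
    for i, (group, vals) in enumerate(values_by_group.items()):
        vals = np.asarray(vals, dtype=float)
        x = i + rng.uniform(-0.12, 0.12, vals.size)
        ax.plot(x, vals, "o", ms=5, alpha=0.7)
        ax.hlines(np.median(vals), i - 0.25, i + 0.25, color="k", lw=2)
    ax.set_xticks(range(len(values_by_group)))
    ax.set_xticklabels(list(values_by_group))
    ax.set_ylabel(ylabel)
    return ax


def plot_roc(result: RocResult, label: Optional[str] = None, ax=None):
    """ROC curve with the chance diagonal and the AUC in the legend."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fpr = 1.0 - result.specificity
    order = np.argsort(fpr, kind="stable")
    lab = f"AUC = {result.auc:.2f}"
    if label:
        lab = f"{label} ({lab})"
    ax.plot(fpr[order], result.sensitivity[order], drawstyle="steps-post",
            label=lab)
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", frameon=False)
    return ax
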