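"""Basic figures: Kaplan-Meier survival curves and 3' coverage profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .survival import SurvivalSample


def plot_survival_curves(samples: list[SurvivalSample], path=None, ax=None):
    """Step-function survival curves, one per cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for s in samples:
        t = np.sort(s.death_times)
        surv = 1.0 - np.arange(1, t.size + 1) / s.n
        ax.step(np.concatenate(([0], t)), np.concatenate(([1.0], surv)),
                where="post", label=s.label or None)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("fraction alive")
    ax.set_ylim(0, 1.02)
    if any(s.label for s in samples):
        ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_coverage_profile(profile: pd.DataFrame, path=None, ax=None):
    """Normalized mean coverage vs distance from the 3' end, one line per sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for sample in profile.columns:
        ax.plot(profile.index, profile[sample], label=sample, lw=1)
    ax.axvline(750, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("distance from 3' end (bp)")
    ax.set_ylabel("normalized coverage")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
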