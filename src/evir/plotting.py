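"""Minimal figures: group-mean spectra with confidence bands and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .biomarker_stats import RocResult
from .preprocess import GroupMeanSpectrum

__all__ = ["plot_group_means", "plot_roc"]

_GROUP_COLORS = {"control": "tab:green", "case": "tab:red"}


def plot_group_means(means: list[GroupMeanSpectrum], ax=None, reverse_axis: bool = True):
    """Mean ± CI band per group; wavenumber axis displayed descending by
    spectroscopy convention (storage stays ascending)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for gm in means:
        color = _GROUP_COLORS.get(gm.group, "tab:blue")
        ax.plot(gm.wavenumbers, gm.mean, color=color, label=f"{gm.group} (n={gm.n})")
        ax.fill_between(gm.wavenumbers, gm.ci_low, gm.ci_high, color=color, alpha=0.25)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("absorbance (a.u.)")
    if reverse_axis:
        ax.invert_xaxis()
    ax.legend()
    return ax


def plot_roc(curves: dict[str, RocResult], ax=None):
    """Overlayed ROC step curves with AUCs in the legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, roc in curves.items():
        fpr = 1.0 - roc.specificity
        ax.step(fpr, roc.sensitivity, where="post", label=f"{name} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k-", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    return ax
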