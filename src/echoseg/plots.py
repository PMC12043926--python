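"""Evaluation plots: Bland-Altman, scatter with identity line, loss curves."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import bland_altman, pearson_and_r2

__all__ = ["bland_altman_plot", "agreement_scatter", "loss_curve_plot"]


def bland_altman_plot(reference, prediction, label: str = "", ax=None):
    """Paired differences vs means, with bias and +/-2 SD limits of agreement."""
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    bias, loa = bland_altman(ref, pred)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + pred) / 2, pred - ref, s=12, alpha=0.7)
    ax.axhline(bias, color="k", lw=1, label=f"bias {bias:.2f}")
    for sign in (-1, 1):
        ax.axhline(bias + sign * loa, color="tab:blue", lw=1, ls="--")
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel("prediction - reference")
    ax.legend(frameon=False)
    return ax


def agreement_scatter(reference, prediction, label: str = "", ax=None):
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, pred, s=12, alpha=0.7)
    lims = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
    ax.plot(lims, lims, "k--", lw=1)
    try:
        _, r2 = pearson_and_r2(ref, pred)
        ax.set_title(f"{label}  r$^2$ = {r2:.2f}")
    except Exception:
        ax.set_title(label)
    ax.set_xlabel(f"reference {label}")
    ax.set_ylabel(f"predicted {label}")
    return ax


def loss_curve_plot(curve, stop_epoch=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.epoch_index, curve.validation_loss, marker="o", ms=3)
    if stop_epoch is not None:
        ax.axvline(stop_epoch, color="tab:red", ls="--", lw=1, label=f"elbow @ {stop_epoch}")
        ax.legend(frameon=False)
    ax.set_xlabel("epoch")
    ax.set_ylabel("validation soft Dice loss")
    return ax
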