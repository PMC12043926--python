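"""Agreement and accuracy statistics for evaluating the pipeline.

Pearson r / r-squared, Bland-Altman bias and limits of agreement, Cohen's
kappa for normal-vs-abnormal calls, the Dice overlap score, and a seeded
percentile bootstrap.

Conventions
-----------
* Limits of agreement use exactly ``2 * SD`` of the paired differences
  (sample SD, n-1) by default; pass ``z=1.96`` for the textbook normal
  quantile.
* ``dice_score`` of two empty masks is defined as 1: on frames where a
  chamber is genuinely absent from both sources the masks agree perfectly.
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.stats

from .errors import DegenerateError, ShapeError, UndefinedKappaError

__all__ = [
    "pearson_and_r2",
    "bland_altman",
    "cohens_kappa",
    "accuracy_score",
    "dice_score",
    "bootstrap_ci",
]


def pearson_and_r2(x, y) -> tuple[float, float]:
    """Product-moment correlation and the r^2 of the linear fit of y on x.

    Raises
    ------
    DegenerateError
        If fewer than 3 pairs, non-finite values, or either variable has
        zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeError("x and y must be paired")
    if x.size < 3:
        raise DegenerateError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateError("zero variance")
    r = float(scipy.stats.pearsonr(x, y).statistic)
    # for simple linear regression the coefficient of determination is r^2
    return r, r * r


def bland_altman(reference, prediction, z: float = 2.0) -> tuple[float, float]:
    """Bland-Altman bias and limits-of-agreement half-width.

    Differences are ``prediction - reference``; bias is their mean and the
    half-width is ``z * SD`` (default z = 2, sample SD with n-1).
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if ref.shape != pred.shape:
        raise ShapeError("paired arrays required")
    if ref.size < 2:
        raise DegenerateError("need at least 2 pairs")
    d = pred - ref
    bias = float(d.mean())
    loa = float(z * d.std(ddof=1))
    return bias, loa


def accuracy_score(labels_a, labels_b) -> float:
    """Fraction of positions where the two label sequences agree."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ShapeError("label sequences must be paired")
    if a.size == 0:
        raise DegenerateError("empty label sequences")
    return float((a == b).mean())


def cohens_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: chance-corrected agreement of two categorical raters.

    kappa = (p_o - p_e) / (1 - p_e), with p_e the sum of products of the two
    raters' marginal frequencies.

    Raises
    ------
    UndefinedKappaError
        If both raters are constant, so chance agreement p_e = 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ShapeError("label sequences must be paired")
    if a.size == 0:
        raise DegenerateError("empty label sequences")
    cats = np.union1d(np.unique(a), np.unique(b))
    n = a.size
    pa = np.array([(a == c).sum() for c in cats]) / n
    pb = np.array([(b == c).sum() for c in cats]) / n
    pe = float(np.dot(pa, pb))
    if pe >= 1.0 - 1e-12:
        raise UndefinedKappaError("both raters constant; kappa undefined")
    po = float((a == b).mean())
    return (po - pe) / (1.0 - pe)


def dice_score(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks.

    Both masks empty -> 1 (documented convention; perfect agreement on an
    absent structure).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def bootstrap_ci(
    data: Sequence | tuple,
    statistic: Callable,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Seeded percentile bootstrap confidence interval.

    Parameters
    ----------
    data
        A single array, or a tuple of equal-length paired arrays that are
        resampled jointly (e.g. ``(reference, prediction)``).
    statistic
        Callable applied to the resampled array(s); must return a scalar.
    """
    paired = isinstance(data, tuple)
    arrays = [np.asarray(d) for d in (data if paired else (data,))]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ShapeError("paired arrays must share length")
    if n < 2:
        raise DegenerateError("need at least 2 observations")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = [a[idx] for a in arrays]
        stats[i] = statistic(*resampled) if paired else statistic(resampled[0])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
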