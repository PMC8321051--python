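"""Otsu threshold selection, binarization and median-background subtraction.

Binarization is the workhorse of the whole pipeline: tissue (bright) becomes
foreground, blood pool (dark) becomes background.  The threshold ``t`` is
chosen to minimise the intra-class variance

    J(t) = w_f(t) * var_f(t) + w_b(t) * var_b(t)

where a pixel ``p`` belongs to the background iff ``p < t`` and to the
foreground iff ``p >= t``, class weights are pixel-count fractions and the
class variances are population variances.  Candidate thresholds are the
distinct pixel values actually present in the image — no histogram binning —
so the minimiser is exact and ties are broken toward the smallest candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OtsuSplit",
    "otsu_threshold",
    "apply_threshold",
    "median_background",
    "subtract_background",
]


@dataclass(frozen=True)
class OtsuSplit:
    """Result of Otsu threshold selection on one intensity image.

    Attributes
    ----------
    threshold : float
        Selected threshold ``t``; background iff pixel < t.
    n_background, n_foreground : int
        Pixel counts of the two classes (sum to the image size).
    weight_background, weight_foreground : float
        Class weights, ``n_class / (w*h)``; sum to 1.
    mean_background, mean_foreground : float
        Class means (0.0 for an empty class).
    var_background, var_foreground : float
        Population variances of the classes (0.0 for an empty class).
    objective : float
        Intra-class variance at ``threshold``.
    degenerate : bool
        True when the image holds a single distinct value.
    """

    threshold: float
    n_background: int
    n_foreground: int
    weight_background: float
    weight_foreground: float
    mean_background: float
    mean_foreground: float
    var_background: float
    var_foreground: float
    objective: float
    degenerate: bool = False


def otsu_threshold(image: np.ndarray) -> OtsuSplit:
    """Select the exact intra-class-variance-minimising threshold.

    Parameters
    ----------
    image : ndarray
        Intensity array with values in [0, 1]; any shape, flattened internally.

    Returns
    -------
    OtsuSplit
        Full description of the optimal split.

    Raises
    ------
    ValueError
        If the array is empty.
    """
    values = np.asarray(image, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("otsu_threshold: empty image")

    v = np.sort(values)
    n = v.size
    uniq, first = np.unique(v, return_index=True)
    if uniq.size == 1:
        t = float(uniq[0])
        return OtsuSplit(
            threshold=t,
            n_background=0,
            n_foreground=n,
            weight_background=0.0,
            weight_foreground=1.0,
            mean_background=0.0,
            mean_foreground=t,
            var_background=0.0,
            var_foreground=0.0,
            objective=0.0,
            degenerate=True,
        )

    # prefix sums over the sorted values; candidate t = uniq[i] puts the
    # first[i] smallest values (all strictly below t) in the background
    csum = np.concatenate(([0.0], np.cumsum(v)))
    csum2 = np.concatenate(([0.0], np.cumsum(v * v)))

    nb = first.astype(np.int64)  # background counts per candidate
    nf = n - nb

    sum_b = csum[nb]
    sum_f = csum[n] - sum_b
    sum2_b = csum2[nb]
    sum2_f = csum2[n] - sum2_b

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_b = np.where(nb > 0, sum_b / np.maximum(nb, 1), 0.0)
        mean_f = np.where(nf > 0, sum_f / np.maximum(nf, 1), 0.0)
        var_b = np.where(nb > 0, sum2_b / np.maximum(nb, 1) - mean_b**2, 0.0)
        var_f = np.where(nf > 0, sum2_f / np.maximum(nf, 1) - mean_f**2, 0.0)
    var_b = np.maximum(var_b, 0.0)  # guard tiny negative round-off
    var_f = np.maximum(var_f, 0.0)

    objective = (nb * var_b + nf * var_f) / n
    best = int(np.argmin(objective))  # first minimum = smallest candidate

    return OtsuSplit(
        threshold=float(uniq[best]),
        n_background=int(nb[best]),
        n_foreground=int(nf[best]),
        weight_background=nb[best] / n,
        weight_foreground=nf[best] / n,
        mean_background=float(mean_b[best]),
        mean_foreground=float(mean_f[best]),
        var_background=float(var_b[best]),
        var_foreground=float(var_f[best]),
        objective=float(objective[best]),
        degenerate=False,
    )


def apply_threshold(image: np.ndarray, t: float) -> np.ndarray:
    """Binarize ``image``: 1 where ``image >= t``, else 0 (uint8 mask)."""
    return (np.asarray(image, dtype=float) >= t).astype(np.uint8)


def median_background(frames: np.ndarray) -> np.ndarray:
    """Per-pixel median over the frame axis.

    ``frames`` has shape (N, h, w) with N >= 3.  For even N the midpoint of
    the two central order statistics is used.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 3:
        raise ValueError("median_background: need a (N>=3, h, w) stack")
    return np.median(frames, axis=0)


def subtract_background(frames: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Elementwise ``max(F_n - S, 0)``; residuals are clipped at zero so the
    result stays an intensity stack in [0, 1]."""
    frames = np.asarray(frames, dtype=float)
    background = np.asarray(background, dtype=float)
    if frames.shape[1:] != background.shape:
        raise ValueError("subtract_background: shape mismatch")
    return np.clip(frames - background[None, :, :], 0.0, None)
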