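"""Extreme-frame selection and combined-image construction.

The two frames whose background-subtracted foreground centroids are farthest
apart are taken as the fully-open and fully-closed valve frames; combining
them closes the atrial boundary even when the thin interatrial septum drifts
out of the imaging plane in individual frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExtremePair",
    "CombinedImages",
    "foreground_centroid",
    "select_extreme_pair",
    "combine",
]


@dataclass(frozen=True)
class ExtremePair:
    """Pair of frame indices with maximal centroid separation.

    ``frame_x`` and ``frame_y`` are 1-based with frame_x < frame_y;
    ``distance`` is the Euclidean pixel distance between the two
    foreground centroids.
    """

    frame_x: int
    frame_y: int
    distance: float


@dataclass(frozen=True)
class CombinedImages:
    """Combined images of the two extreme frames.

    binary : Bx OR By (raw-frame masks)
    binary_subtracted : BSx OR BSy (background-subtracted masks)
    gray : (Fx + Fy) / 2
    gray_subtracted : (FSx + FSy) / 2

    The grayscale combinations use the mean rather than the raw sum so that
    intensities — and therefore the recursive threshold grid — stay on the
    [0, 1] scale; a monotone rescaling does not move Otsu's split.
    """

    binary: np.ndarray
    binary_subtracted: np.ndarray
    gray: np.ndarray
    gray_subtracted: np.ndarray


def foreground_centroid(mask: np.ndarray) -> tuple[float, float] | None:
    """Centroid (column, row) of the 1-pixels of a binary mask; None if empty."""
    rows, cols = np.nonzero(np.asarray(mask))
    if rows.size == 0:
        return None
    return float(cols.mean()), float(rows.mean())


def select_extreme_pair(masks: list[np.ndarray] | np.ndarray) -> ExtremePair:
    """Find the frame pair with maximally distant foreground centroids.

    Frames whose mask is empty are skipped.  Ties are broken by the
    lexicographically smallest (x, y) index pair.

    Raises
    ------
    ValueError
        If fewer than two masks have any foreground.
    """
    centroids: list[tuple[int, float, float]] = []
    for i, mask in enumerate(masks):
        c = foreground_centroid(mask)
        if c is not None:
            centroids.append((i, c[0], c[1]))
    if len(centroids) < 2:
        raise ValueError("select_extreme_pair: fewer than 2 non-empty masks")

    idx = np.array([c[0] for c in centroids])
    pts = np.array([[c[1], c[2]] for c in centroids])
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    upper = np.triu(np.ones_like(d2, dtype=bool), k=1)
    d2 = np.where(upper, d2, -np.inf)
    best = d2.max()
    # argwhere scans row-major: first hit is the lexicographically smallest pair
    i, j = np.argwhere(d2 == best)[0]
    return ExtremePair(
        frame_x=int(idx[i]) + 1,
        frame_y=int(idx[j]) + 1,
        distance=float(np.sqrt(best)),
    )


def combine(
    frames: np.ndarray,
    frames_subtracted: np.ndarray,
    masks: list[np.ndarray] | np.ndarray,
    masks_subtracted: list[np.ndarray] | np.ndarray,
    pair: ExtremePair,
) -> CombinedImages:
    """Build the four combined images for the extreme pair (x, y)."""
    x = pair.frame_x - 1
    y = pair.frame_y - 1
    return CombinedImages(
        binary=(np.logical_or(masks[x], masks[y])).astype(np.uint8),
        binary_subtracted=(
            np.logical_or(masks_subtracted[x], masks_subtracted[y])
        ).astype(np.uint8),
        gray=(np.asarray(frames[x], dtype=float) + np.asarray(frames[y], dtype=float))
        / 2.0,
        gray_subtracted=(
            np.asarray(frames_subtracted[x], dtype=float)
            + np.asarray(frames_subtracted[y], dtype=float)
        )
        / 2.0,
    )
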