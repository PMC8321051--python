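"""Left-atrium boundary localisation by recursive threshold lowering.

In the apical 4-chamber view the left atrium sits in the bottom-right corner
of the frame.  A closed boundary around it exists in the combined binary
image only if the interatrial septum — often ≤ 1 mm thin and faint — survives
binarization.  When the initial Otsu thresholds are too high to keep the
septum, the two thresholds l1 (raw combined image) and l2 (background-
subtracted combined image) are lowered on a grid with step ``c`` until an
enclosed region appears that is large enough (spans at least a fraction ``p``
of the search box in both dimensions) and lies fully inside the box.

Enclosed regions are 4-connected background components that do not touch the
image border; their contours are traced with Moore-neighbor tracing
terminated by Jacob's stopping criterion (stop when the start pixel is
re-entered from its original backtrack direction).

Coordinate convention: 0-based, x = column increasing rightward, y = row
increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .binarize import otsu_threshold

__all__ = [
    "BoxSpec",
    "CandidateRegion",
    "AtriumBoundary",
    "BoundaryNotFoundError",
    "find_enclosed_regions",
    "qualifies",
    "recursive_search",
    "region_centroid",
]

# 4-connectivity for background components: diagonal background pixels do not
# leak through an 8-connected foreground boundary
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# Moore neighborhood in clockwise screen order (y down), starting west
_MOORE = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


class BoundaryNotFoundError(ValueError):
    """Raised when no qualifying closed boundary exists at any threshold pair."""


@dataclass(frozen=True)
class BoxSpec:
    """Bottom-right search box.

    ``(cx, cy)`` is the top-left corner (column, row); ``bx`` × ``by`` is the
    box size.  ``frac`` is the fraction of each image dimension the box
    covers (default 0.6: slightly more than the bottom-right quadrant, since
    involuntary cardiac motion can carry the atrium past the midlines).
    """

    cx: int
    cy: int
    bx: int
    by: int
    frac: float = 0.6

    @classmethod
    def bottom_right(cls, width: int, height: int, frac: float = 0.6) -> "BoxSpec":
        cx = round((1.0 - frac) * width)
        cy = round((1.0 - frac) * height)
        return cls(cx=cx, cy=cy, bx=min(round(frac * width), width - cx),
                   by=min(round(frac * height), height - cy), frac=frac)


@dataclass
class CandidateRegion:
    """An enclosed background region (candidate atrial cavity).

    ``pixels`` is a (k, 2) int array of (column, row) coordinates of the
    4-connected hole; ``contour`` is the ordered closed Moore-traced path
    around it as a list of (column, row) tuples.
    """

    pixels: np.ndarray
    contour: list[tuple[int, int]]
    xmin: int
    xmax: int
    ymin: int
    ymax: int

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class AtriumBoundary:
    """Accepted left-atrium region with the thresholds that produced it."""

    region: CandidateRegion
    centroid: tuple[float, float]
    l1_final: float
    l2_final: float
    decrements: tuple[int, int] = field(default=(0, 0))


def _moore_trace(obj: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Trace the boundary of the True-region of ``obj`` starting at ``start``.

    ``start`` must be the first object pixel in raster order so that its west
    neighbor is guaranteed off-object.  Returns the ordered closed contour; a
    single isolated pixel yields a one-element contour.

    Termination follows Jacob's stopping criterion — stop on re-entering the
    start pixel from its original backtrack direction — generalised to any
    repeated (pixel, backtrack) state, which also terminates the 1-pixel-wide
    shapes on which the strict criterion is known to cycle.
    """
    h, w = obj.shape
    sx, sy = start

    def is_obj(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and bool(obj[y, x])

    px, py = sx, sy
    b_idx = 0  # entered from the west
    seen = {(px, py, b_idx)}
    contour = [(sx, sy)]
    max_steps = 8 * int(obj.sum()) + 8

    for _ in range(max_steps):
        found = False
        for step in range(1, 9):
            k = (b_idx + step) % 8
            dx, dy = _MOORE[k]
            nx, ny = px + dx, py + dy
            if is_obj(nx, ny):
                # backtrack for the next pixel = neighbor examined just before
                pk = (b_idx + step - 1) % 8
                bx_, by_ = px + _MOORE[pk][0], py + _MOORE[pk][1]
                b_idx = _MOORE_INDEX[(bx_ - nx, by_ - ny)]
                px, py = nx, ny
                found = True
                break
        if not found:  # isolated single pixel
            return contour
        state = (px, py, b_idx)
        if state in seen:
            break
        seen.add(state)
        contour.append((px, py))
    while len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def find_enclosed_regions(mask: np.ndarray) -> list[CandidateRegion]:
    """Enclosed holes of a binary foreground mask.

    Returns one :class:`CandidateRegion` per 4-connected background component
    that does not touch the image border, i.e. per hole fully surrounded by
    foreground.  An all-foreground mask (or one whose background all reaches
    the border) yields an empty list.
    """
    mask = np.asarray(mask)
    background = mask == 0
    labels, n = ndimage.label(background, structure=_STRUCT4)
    if n == 0:
        return []

    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    touches_border = np.zeros(n + 1, dtype=bool)
    touches_border[np.unique(border)] = True

    regions: list[CandidateRegion] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        if touches_border[lab]:
            continue
        sl = slices[lab - 1]
        sub = labels[sl] == lab
        rows, cols = np.nonzero(sub)
        y0, x0 = sl[0].start, sl[1].start
        cols_g = cols + x0
        rows_g = rows + y0
        # trace in the bbox view (raster-first pixel starts the trace),
        # then shift back to image coordinates
        local = _moore_trace(sub, (int(cols[0]), int(rows[0])))
        contour = [(x + x0, y + y0) for x, y in local]
        regions.append(
            CandidateRegion(
                pixels=np.column_stack([cols_g, rows_g]),
                contour=contour,
                xmin=int(cols_g.min()),
                xmax=int(cols_g.max()),
                ymin=int(rows_g.min()),
                ymax=int(rows_g.max()),
            )
        )
    return regions


def qualifies(region: CandidateRegion, box: BoxSpec, p: float) -> bool:
    """Is ``region`` large enough and fully inside the search box?

    Large enough: its bounding box spans at least ``p * bx`` columns and
    ``p * by`` rows (inclusive, ``>=``).  Inside: the bounding box lies
    entirely within the box.
    """
    return (
        region.xmax - region.xmin >= p * box.bx
        and region.ymax - region.ymin >= p * box.by
        and region.xmin >= box.cx
        and region.xmax <= box.cx + box.bx - 1
        and region.ymin >= box.cy
        and region.ymax <= box.cy + box.by - 1
    )


def _threshold_grid(init: float, step: float) -> np.ndarray:
    """Descending grid init, init-c, ... floored at 0 (0 included once)."""
    if init <= 0.0:
        return np.array([0.0])
    n_steps = int(np.ceil(init / step))
    vals = init - step * np.arange(n_steps + 1)
    vals = np.maximum(vals, 0.0)
    if vals[-1] > 0.0:
        vals = np.append(vals, 0.0)
    return vals


def recursive_search(
    gray: np.ndarray,
    gray_subtracted: np.ndarray,
    box: BoxSpec,
    p: float = 0.1,
    c: float = 0.005,
    l1_init: float | None = None,
    l2_init: float | None = None,
) -> AtriumBoundary:
    """Lower (l1, l2) on a grid until a qualifying closed boundary appears.

    The scan order nests l2 inside l1: for each l1 in {l1_init, l1_init-c,
    ...} the full l2 grid {l2_init, l2_init-c, ...} is tried before l1 drops
    again.  The initial pair is tested before any decrement.  At each pair the
    raw combined image is binarized with l1, the background-subtracted one
    with l2, the two masks are OR-ed, and the enclosed regions of the result
    are tested with :func:`qualifies`.  If several regions qualify at the
    accepted pair the largest-area one is returned.

    Raises
    ------
    BoundaryNotFoundError
        If both grids are exhausted (thresholds reached 0) without success.
    """
    if c <= 0:
        raise ValueError("recursive_search: step c must be positive")
    if l1_init is None:
        l1_init = otsu_threshold(gray).threshold
    if l2_init is None:
        l2_init = otsu_threshold(gray_subtracted).threshold

    gray = np.asarray(gray, dtype=float)
    gray_subtracted = np.asarray(gray_subtracted, dtype=float)

    l1_grid = _threshold_grid(l1_init, c)
    l2_grid = _threshold_grid(l2_init, c)

    prev_combined: np.ndarray | None = None
    for k1, l1 in enumerate(l1_grid):
        mask_c = gray >= l1
        for k2, l2 in enumerate(l2_grid):
            combined = mask_c | (gray_subtracted >= l2)
            # identical mask to the previous pair cannot newly qualify
            if prev_combined is not None and np.array_equal(combined, prev_combined):
                continue
            prev_combined = combined
            qualifying = [
                r for r in find_enclosed_regions(combined.astype(np.uint8))
                if qualifies(r, box, p)
            ]
            if qualifying:
                region = max(qualifying, key=lambda r: r.area)
                return AtriumBoundary(
                    region=region,
                    centroid=region_centroid(region),
                    l1_final=float(l1),
                    l2_final=float(l2),
                    decrements=(k1, k2),
                )
    raise BoundaryNotFoundError("no atrium boundary found")


def region_centroid(region: CandidateRegion) -> tuple[float, float]:
    """Centroid (column, row) of the filled region's pixels."""
    if region.pixels.shape[0] == 0:
        raise ValueError("region_centroid: empty region")
    return (
        float(region.pixels[:, 0].mean()),
        float(region.pixels[:, 1].mean()),
    )
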