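"""Prong construction and leaflet hit detection.

A cone of ``npr`` rays ("prongs") is cast upward from the atrial centroid.
In the apical 4-chamber view the mitral valve always lies above the left
atrium's centroid, so the first tissue pixel each prong crosses marks a
leaflet.  When the valve is closed the leaflets lie roughly horizontally and
the hit points cluster tightly; when it is open the prongs hit the leaflets
at scattered points — or nothing at all — and the per-frame dispersion sigma
of the hit points is large.

Prong length is a fraction ``length_frac`` (default 0.25) of the height of
the atrial bounding box: long enough that systolic motion of the valve plane
stays within reach, short enough to keep the point count small.  A miss maps
the hit to the prong tip, deliberately inflating sigma, which matches the
"touching nothing at all means open" reading of the scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProngSet", "HitSet", "SigmaSeries", "build_prongs", "detect_hits",
           "sigma_of_hits", "sigma_series"]


@dataclass(frozen=True)
class ProngSet:
    """Cone of sampled rays from the atrial centroid.

    ``samples[k]`` is an (m_k, 2) int array of (column, row) pixel samples of
    prong k, ordered outward at 1-pixel radial spacing (consecutive
    duplicates after rounding collapsed, samples outside the image dropped).
    ``angles_deg[k]`` is measured from vertical-up, negative to the left.
    """

    origin: tuple[float, float]
    angles_deg: tuple[float, ...]
    samples: tuple[np.ndarray, ...]
    length_px: float

    @property
    def n_prongs(self) -> int:
        return len(self.angles_deg)


@dataclass(frozen=True)
class HitSet:
    """Per-frame prong hits: ``hits`` is (N, npr, 2) of (column, row), and
    ``miss`` is (N, npr) boolean (True where the prong touched nothing and
    the hit is its tip)."""

    hits: np.ndarray
    miss: np.ndarray


@dataclass(frozen=True)
class SigmaSeries:
    """Per-frame 2-D dispersion of the prong hit points.

    ``values[n] = sqrt(popvar(x) + popvar(y))`` over frame n's hits
    (population variance, divisor npr).
    """

    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def build_prongs(
    centroid: tuple[float, float],
    bbox_height: float,
    image_shape: tuple[int, int],
    n_prongs: int = 5,
    cone_deg: float = 40.0,
    length_frac: float = 0.25,
) -> ProngSet:
    """Build the prong cone above ``centroid``.

    Parameters
    ----------
    centroid : (column, row)
        Atrial centroid; rays point upward (decreasing row).
    bbox_height : float
        ``ymax - ymin`` of the atrial bounding box; prong length is
        ``length_frac * bbox_height`` pixels.
    image_shape : (height, width)
        Samples falling outside the image are dropped.
    n_prongs : int
        Odd so the middle prong is vertical.
    cone_deg : float
        Full cone angle; prong angles are equidistant over
        [-cone_deg/2, +cone_deg/2] from vertical.
    """
    if n_prongs < 1 or n_prongs % 2 == 0:
        raise ValueError("build_prongs: n_prongs must be odd and >= 1")
    if not (0.0 < cone_deg < 180.0):
        raise ValueError("build_prongs: cone_deg must lie in (0, 180)")
    if not (0.0 < length_frac <= 1.0):
        raise ValueError("build_prongs: length_frac must lie in (0, 1]")
    h, w = image_shape
    cx, cy = centroid
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("build_prongs: centroid outside image")

    if n_prongs == 1:
        angles = np.array([0.0])
    else:
        angles = -cone_deg / 2.0 + np.arange(n_prongs) * cone_deg / (n_prongs - 1)

    length_px = length_frac * bbox_height
    npp = int(np.floor(length_px))
    radii = np.arange(1, npp + 1)

    samples = []
    for theta in np.deg2rad(angles):
        xs = np.rint(cx + radii * np.sin(theta)).astype(int)
        ys = np.rint(cy - radii * np.cos(theta)).astype(int)
        pts = np.column_stack([xs, ys])
        inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        pts = pts[inside]
        if len(pts) > 1:  # collapse consecutive duplicates from rounding
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
            pts = pts[keep]
        samples.append(pts)

    return ProngSet(
        origin=(float(cx), float(cy)),
        angles_deg=tuple(float(a) for a in angles),
        samples=tuple(samples),
        length_px=float(length_px),
    )


def detect_hits(prongs: ProngSet, frame_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First tissue sample along each prong.

    Returns ``(hits, miss)``: hits is (npr, 2) of (column, row) — the first
    sample (smallest radial index) whose mask value is 1, or the prong tip if
    none — and miss is the (npr,) boolean miss flag.
    """
    mask = np.asarray(frame_mask)
    hits = np.empty((prongs.n_prongs, 2), dtype=int)
    miss = np.zeros(prongs.n_prongs, dtype=bool)
    for k, pts in enumerate(prongs.samples):
        if len(pts) == 0:
            miss[k] = True
            ox, oy = prongs.origin
            hits[k] = (int(round(ox)), int(round(oy)))
            continue
        on = mask[pts[:, 1], pts[:, 0]] != 0
        idx = np.argmax(on)
        if on[idx]:
            hits[k] = pts[idx]
        else:
            miss[k] = True
            hits[k] = pts[-1]
    return hits, miss


def sigma_of_hits(hits: np.ndarray) -> float:
    """Total 2-D dispersion sqrt(popvar(x) + popvar(y)) of one frame's hits."""
    pts = np.asarray(hits, dtype=float)
    return float(np.sqrt(pts[:, 0].var() + pts[:, 1].var()))


def sigma_series(
    frame_masks: list[np.ndarray] | np.ndarray, prongs: ProngSet
) -> tuple[SigmaSeries, HitSet]:
    """Per-frame hit detection and dispersion over a binary stack."""
    all_hits = []
    all_miss = []
    sigmas = []
    for mask in frame_masks:
        hits, miss = detect_hits(prongs, mask)
        all_hits.append(hits)
        all_miss.append(miss)
        sigmas.append(sigma_of_hits(hits))
    return (
        SigmaSeries(values=np.asarray(sigmas, dtype=float)),
        HitSet(hits=np.asarray(all_hits), miss=np.asarray(all_miss)),
    )
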