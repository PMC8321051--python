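"""Synthetic apical-4-chamber echocardiogram phantoms with known kinematics.

The phantom is a schematic four-chamber scene, not an anatomical rendering:
the analysis pipeline only assumes the scene's topology — dark blood-filled
cavities enclosed by bright tissue walls, a thin interatrial septum, and two
thin mitral leaflets hinged near the left-atrial roof that open and close.
Layout (fractions of a 256-pixel reference frame, scaled to any size):

* an outer bright wall ring encloses the heart;
* a horizontal atrioventricular wall separates ventricles (top) from atria
  (bottom); a thick interventricular septum splits the top chambers and a
  thin (1–2 px) interatrial septum splits the bottom ones;
* the left atrium is the bottom-right cavity, fully inside the bottom-right
  60% search box;
* per frame the leaflets take one of two poses driven by the ground-truth
  schedule: closed — a thin horizontal bar across the valve orifice a short
  way below the roof (prong hits cluster) — or open — two vertical flaps
  along the orifice edges, out of the prong cone (prongs miss, sigma high);
* optionally a segment of the interatrial septum is drawn at a faint gray
  level instead of full wall intensity, so the atrial boundary only closes
  once the recursive threshold search drops below that level;
* multiplicative log-normal speckle (the standard first-order surrogate for
  ultrasound texture) and integer-pixel global jitter emulate acquisition
  noise; everything is deterministic given the seed.

Disease modes map to the three movement rules.  ``stenotic`` holds the valve
shut except for two brief 2-frame attempted openings (stenosis obstructs,
but does not abolish, opening); it is detected as too-closed, rule 2.
``prolapsed`` mirrors it — open except for two brief 2-frame attempted
closures (prolapse is a failure to close fully); rule 3.  The brief
opposite-state excursions matter: the open/closed threshold is the largest
gap in the sorted sigma series, a purely relative criterion, so a series
from a valve pinned in one pose for every frame has no gap to find and the
labelling of its small noise fluctuations would be arbitrary.  ``fluttering``
flips the state every 1–2 frames (rapid transitions, rule 1) and ``healthy``
cycles periodically with long runs of each state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "MODES"]

MODES = ("healthy", "stenotic", "prolapsed", "fluttering")

_REF = 256.0  # reference frame size the layout fractions are drawn on


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic video.

    speckle_sigma is the log-scale standard deviation of the multiplicative
    noise; jitter_px the maximum global integer translation per frame.
    septum_gap_level, if set, draws a faint segment of the interatrial septum
    at that gray level (in (0, 1)) to exercise the recursive threshold
    search.
    """

    mode: str = "healthy"
    n_frames: int = 64
    width: int = 256
    height: int = 256
    wall_intensity: float = 0.8
    cavity_intensity: float = 0.05
    septum_gap_level: float | None = None
    cycle_frames: int = 16
    speckle_sigma: float = 0.15
    jitter_px: int = 2
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Generating schedule and the verdict it implies."""

    is_open: np.ndarray
    verdict: str
    expected_rule: int | None
    rapid_transition_windows: int

    @property
    def open_fraction(self) -> float:
        return float(np.mean(self.is_open))


def _span(lo: float, hi: float, size: int) -> tuple[int, int]:
    """Half-open pixel span for reference coords [lo, hi] scaled to size."""
    s = size / _REF
    a = round(lo * s)
    b = max(a + 1, round((hi + 1) * s))
    return a, b


def _rapid_windows(is_open: np.ndarray) -> int:
    change = is_open[1:] != is_open[:-1]
    return int(np.sum(change[1:] & change[:-1]))


def _schedule(spec: PhantomSpec, rng: np.random.Generator) -> GroundTruth:
    n = spec.n_frames
    if spec.mode == "healthy":
        phase = np.arange(n) % spec.cycle_frames
        is_open = phase < spec.cycle_frames // 2
        verdict, rule = "healthy", None
    elif spec.mode == "stenotic":
        is_open = np.zeros(n, dtype=bool)
        # two brief 2-frame attempted openings (incomplete-opening phenotype)
        for start in (n // 3, (2 * n) // 3):
            is_open[start : start + 2] = True
        verdict, rule = "diseased", 2
    elif spec.mode == "prolapsed":
        is_open = np.ones(n, dtype=bool)
        # two brief 2-frame attempts at closure (incomplete-closure phenotype)
        for start in (n // 3, (2 * n) // 3):
            is_open[start : start + 2] = False
        verdict, rule = "diseased", 3
    elif spec.mode == "fluttering":
        states: list[bool] = []
        cur = bool(rng.integers(0, 2))
        while len(states) < n:
            states.extend([cur] * int(rng.integers(1, 3)))
            cur = not cur
        is_open = np.array(states[:n])
        if _rapid_windows(is_open) <= 0.05 * n:  # vanishingly rare draw
            is_open = (np.arange(n) % 2).astype(bool)
        verdict, rule = "diseased", 1
    else:
        raise ValueError(f"generate_phantom: unknown mode {spec.mode!r}")
    return GroundTruth(
        is_open=is_open,
        verdict=verdict,
        expected_rule=rule,
        rapid_transition_windows=_rapid_windows(is_open),
    )


def _base_scene(spec: PhantomSpec) -> np.ndarray:
    """Static walls and septa (no valve)."""
    w, h = spec.width, spec.height
    img = np.full((h, w), spec.cavity_intensity, dtype=float)
    wall = spec.wall_intensity

    ox0, ox1 = _span(10, 15, w)
    oy0, oy1 = _span(10, 15, h)
    ix0, _ = _span(240, 245, w)
    iy0, _ = _span(240, 245, h)
    ix1, iy1 = _span(245, 245, w)[1], _span(245, 245, h)[1]
    # outer ring
    img[oy0:iy1, ox0:ox1] = wall
    img[oy0:iy1, ix0:ix1] = wall
    img[oy0:oy1, ox0:ix1] = wall
    img[iy0:iy1, ox0:ix1] = wall

    # atrioventricular wall (full width)
    ay0, ay1 = _span(138, 145, h)
    img[ay0:ay1, ox0:ix1] = wall

    # interventricular septum (thick, ventricles only)
    vx0, vx1 = _span(122, 130, w)
    img[oy0:ay1, vx0:vx1] = wall

    # interatrial septum (thin, atria only)
    sx0, sx1 = _span(148, 149, w)
    img[ay0:iy1, sx0:sx1] = wall
    if spec.septum_gap_level is not None:
        gy0, gy1 = _span(185, 200, h)
        img[gy0:gy1, sx0:sx1] = spec.septum_gap_level
    return img


def _draw_valve(img: np.ndarray, spec: PhantomSpec, is_open: bool) -> None:
    """Overlay the mitral apparatus for one frame, in place.

    Hinge stubs sit on the atrial roof at the orifice edges in every frame.
    Closed: a thin horizontal bar spans the orifice ~15% of the cavity height
    below the roof.  Open: the leaflets swing up along the orifice edges as
    vertical flaps, clear of the prong cone.
    """
    w, h = img.shape[1], img.shape[0]
    wall = spec.wall_intensity

    lx0, lx1 = _span(160, 161, w)   # left hinge / flap columns
    rx0, rx1 = _span(228, 229, w)   # right hinge / flap columns
    sy0, sy1 = _span(146, 152, h)   # hinge stub rows
    img[sy0:sy1, lx0:lx1] = wall
    img[sy0:sy1, rx0:rx1] = wall

    if is_open:
        fy0, fy1 = _span(146, 185, h)
        img[fy0:fy1, lx0:lx1] = wall
        img[fy0:fy1, rx0:rx1] = wall
    else:
        by0, by1 = _span(177, 178, h)
        bx0, bx1 = _span(166, 224, w)
        img[by0:by1, bx0:bx1] = wall


def _jitter(img: np.ndarray, dx: int, dy: int, fill: float) -> np.ndarray:
    """Global integer translation with constant fill at the exposed edge."""
    if dx == 0 and dy == 0:
        return img.copy()
    h, w = img.shape
    out = np.full_like(img, fill)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    ys0, ys1 = max(0, dy), min(h, h + dy)
    out[ys0:ys1, xs0:xs1] = img[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the phantom video.

    Returns
    -------
    frames : (N, h, w) float array in [0, 1]
    truth : GroundTruth
        The per-frame open/closed schedule, the verdict it encodes and the
        movement rule a correct analysis should report.
    """
    if spec.mode not in MODES:
        raise ValueError(f"generate_phantom: unknown mode {spec.mode!r}")
    if spec.n_frames < 3:
        raise ValueError("generate_phantom: need at least 3 frames")
    rng = np.random.default_rng(spec.seed)
    truth = _schedule(spec, rng)
    base = _base_scene(spec)

    frames = np.empty((spec.n_frames, spec.height, spec.width), dtype=float)
    for n in range(spec.n_frames):
        img = base.copy()
        _draw_valve(img, spec, bool(truth.is_open[n]))
        if spec.jitter_px > 0:
            dx = int(rng.integers(-spec.jitter_px, spec.jitter_px + 1))
            dy = int(rng.integers(-spec.jitter_px, spec.jitter_px + 1))
            img = _jitter(img, dx, dy, spec.cavity_intensity)
        if spec.speckle_sigma > 0:
            noise = rng.standard_normal(img.shape)
            img = img * np.exp(
                spec.speckle_sigma * noise - 0.5 * spec.speckle_sigma**2
            )
        frames[n] = np.clip(img, 0.0, 1.0)
    return frames, truth
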