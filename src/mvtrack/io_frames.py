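"""Reading echo videos into a canonical grayscale stack; report I/O.

The canonical container is :class:`FrameStack`: N frames of h×w doubles on
the unit intensity scale.  The unit scale matters downstream — the recursive
boundary search lowers thresholds in steps of c = 0.005, which is only
meaningful on [0, 1].

Supported inputs: a directory of numbered PNG/TIFF/JPEG/BMP frames (ordered
lexicographically by zero-padded name), a multi-page TIFF stack, or any
video container imageio can open with the plugins installed on the host.
Color inputs are reduced to luminance as the channel mean (ultrasound video
is effectively gray, so the choice of weights is immaterial); integer inputs
are rescaled by their dtype maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["FrameStack", "Report", "load_frames", "save_frames",
           "write_report", "read_report"]

_FRAME_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass(frozen=True)
class FrameStack:
    """N grayscale frames with intensities in [0, 1].

    ``frames`` has shape (N, height, width).
    """

    frames: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise ValueError("FrameStack: frames must be (N, h, w)")
        if f.shape[0] < 3:
            raise ValueError("too few frames: need at least 3")
        if f.min() < 0.0 or f.max() > 1.0:
            raise ValueError("FrameStack: intensities must lie in [0, 1]")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


def _to_gray_unit(img: np.ndarray) -> np.ndarray:
    """One frame to float64 luminance in [0, 1]."""
    arr = np.asarray(img)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    if arr.ndim == 3:  # (h, w, channels); drop alpha, average the rest
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    return arr


def load_frames(path: str | Path) -> FrameStack:
    """Load a video file or frame directory into a FrameStack.

    Raises
    ------
    IOError
        If the path does not exist or no backend can read it.
    ValueError
        If fewer than 3 frames are found.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"load_frames: no such path: {path}")

    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise IOError(f"load_frames: no image files in {path}")
        for f in files:
            frames.append(_to_gray_unit(iio.imread(f)))
    else:
        try:
            if path.suffix.lower() in {".tif", ".tiff"}:
                stack = iio.imread(path)
                if stack.ndim == 2:
                    stack = stack[None]
                frames = [_to_gray_unit(fr) for fr in stack]
            else:
                frames = [_to_gray_unit(fr) for fr in iio.imiter(path)]
        except ValueError:
            raise
        except Exception as exc:  # no backend / corrupt container
            raise IOError(f"load_frames: cannot read {path}: {exc}") from exc

    if len(frames) < 3:
        raise ValueError("too few frames: need at least 3")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("load_frames: frames differ in size")
    return FrameStack(frames=np.stack(frames))


def save_frames(stack: FrameStack | np.ndarray, directory: str | Path) -> list[Path]:
    """Write the stack as zero-padded 8-bit PNG frames; returns the paths."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for n, frame in enumerate(frames):
        p = directory / f"frame_{n:05d}.png"
        iio.imwrite(p, np.rint(np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


@dataclass
class Report:
    """Machine-readable result of one pipeline run."""

    n_frames: int
    width: int
    height: int
    sigma: list[float]
    states: list[str]
    sigma_threshold: float
    sigma_degenerate: bool
    verdict: str
    rules_triggered: list[int]
    transition_count: int
    open_fraction: float
    closed_fraction: float
    l1_init: float
    l2_init: float
    l1_final: float
    l2_final: float
    decrements: list[int]
    atrium_centroid: list[float]
    atrium_bbox: list[int]
    extreme_pair: list[int]
    extreme_distance: float
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sigma) != self.n_frames or len(self.states) != self.n_frames:
            raise ValueError("Report: sigma/state lists must have length N")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "Report":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})


def write_report(report: Report, path: str | Path) -> None:
    """Serialize the report as JSON (round-trips via :func:`read_report`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def read_report(path: str | Path) -> Report:
    with open(path) as fh:
        return Report.from_dict(json.load(fh))
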