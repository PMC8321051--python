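"""Open/closed labelling of the sigma series and rule-based disease calls.

The sigma dispersion of the prong hits is bimodal over a cardiac cycle: low
while the valve is closed, high while it is open.  The threshold separating
the two is found without supervision: sort the per-frame sigma values
ascending and take the value just before the largest adjacent gap.  Frames
with sigma at or below the threshold are labelled closed, the rest open.

Three rules then separate healthy from diseased motion:

1. rapid transitions — the state changes twice within 3 consecutive frames
   more often than 5% of the frame count (arrhythmias: fibrillation,
   flutter, tachycardia);
2. too closed — more than 85% of frames closed (obstructed opening,
   e.g. mitral stenosis);
3. too open — more than 85% of frames open (failure to close,
   e.g. mitral prolapse).

Both cut-offs are strict inequalities; equality is healthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prongs import SigmaSeries

__all__ = [
    "GapThreshold",
    "StateSeries",
    "Verdict",
    "gap_threshold",
    "label_states",
    "count_rapid_transitions",
    "classify_disease",
]

OPEN = "open"
CLOSED = "closed"


@dataclass(frozen=True)
class GapThreshold:
    """Largest-gap sigma threshold; ``degenerate`` when all sigmas are equal
    (no gap — every frame is then labelled closed)."""

    value: float
    degenerate: bool = False


@dataclass(frozen=True)
class StateSeries:
    """Per-frame open/closed labels.  ``is_open[n]`` is False (closed) iff
    ``sigma[n] <= threshold``."""

    is_open: np.ndarray
    threshold: float
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.is_open)

    @property
    def labels(self) -> list[str]:
        return [OPEN if o else CLOSED for o in self.is_open]

    @property
    def open_fraction(self) -> float:
        return float(np.mean(self.is_open))

    @property
    def closed_fraction(self) -> float:
        return 1.0 - self.open_fraction


@dataclass(frozen=True)
class Verdict:
    """Healthy/diseased call with the rules that fired.

    Rule indices: 1 = rapid transitions, 2 = too closed, 3 = too open.
    """

    label: str
    rules_triggered: tuple[int, ...]
    transition_count: int
    open_fraction: float
    closed_fraction: float
    transition_frac: float = 0.05
    open_close_frac: float = 0.85

    @property
    def diseased(self) -> bool:
        return self.label == "diseased"


def gap_threshold(series: SigmaSeries | np.ndarray) -> GapThreshold:
    """Sigma value just before the largest shift in the sorted series.

    Ties between equal gaps go to the smallest index (lowest threshold).
    If every sigma is equal there is no gap: the common value is returned
    with the degenerate flag set, which labels every frame closed.
    """
    sigma = np.asarray(getattr(series, "values", series), dtype=float)
    if sigma.size < 2:
        raise ValueError("gap_threshold: need at least 2 sigma values")
    s = np.sort(sigma)
    gaps = np.diff(s)
    k = int(np.argmax(gaps))  # first maximum = smallest k
    if gaps[k] == 0.0:
        return GapThreshold(value=float(s[0]), degenerate=True)
    return GapThreshold(value=float(s[k]), degenerate=False)


def label_states(
    series: SigmaSeries | np.ndarray, threshold: GapThreshold | float
) -> StateSeries:
    """Label each frame: closed iff sigma <= threshold (boundary inclusive)."""
    sigma = np.asarray(getattr(series, "values", series), dtype=float)
    if isinstance(threshold, GapThreshold):
        value, degenerate = threshold.value, threshold.degenerate
    else:
        value, degenerate = float(threshold), False
    return StateSeries(
        is_open=sigma > value, threshold=value, degenerate=degenerate
    )


def count_rapid_transitions(states: StateSeries | np.ndarray) -> int:
    """Number of 3-frame windows in which the state changes twice.

    Windows overlap: every index triple (i, i+1, i+2) is examined.
    """
    is_open = np.asarray(getattr(states, "is_open", states), dtype=bool)
    if is_open.size < 3:
        raise ValueError("count_rapid_transitions: need at least 3 frames")
    change = is_open[1:] != is_open[:-1]
    return int(np.sum(change[1:] & change[:-1]))


def classify_disease(
    states: StateSeries,
    transition_frac: float = 0.05,
    open_close_frac: float = 0.85,
) -> Verdict:
    """Apply the three movement rules to a labelled series.

    Rule 1 fires iff transition_count > transition_frac * N (exact
    real-valued comparison), rules 2/3 iff the closed/open fraction exceeds
    ``open_close_frac`` strictly.  The heart is diseased iff any rule fires.
    """
    n = len(states)
    if n < 3:
        raise ValueError("classify_disease: need at least 3 frames")
    transitions = count_rapid_transitions(states)
    rules: list[int] = []
    if transitions > transition_frac * n:
        rules.append(1)
    if states.closed_fraction > open_close_frac:
        rules.append(2)
    if states.open_fraction > open_close_frac:
        rules.append(3)
    return Verdict(
        label="diseased" if rules else "healthy",
        rules_triggered=tuple(rules),
        transition_count=transitions,
        open_fraction=states.open_fraction,
        closed_fraction=states.closed_fraction,
        transition_frac=transition_frac,
        open_close_frac=open_close_frac,
    )
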