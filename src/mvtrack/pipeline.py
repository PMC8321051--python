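"""End-to-end orchestration: video in, healthy/diseased report out.

Stage order: load → per-frame Otsu binarization → median background →
subtraction → binarize the subtracted stack → extreme-frame pair →
combined images → recursive atrium boundary search → centroid → prong cone
→ per-frame hits and sigma → largest-gap threshold → open/closed labels →
three movement rules.

The hit-detection masks rebinarize every *raw* frame at the final accepted
threshold l1: the thin leaflets need the lowered threshold to survive, and a
leaflet that barely moves would vanish from the background-subtracted stack.
There is no randomness anywhere on this path — identical input and config
give an identical report.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import binarize, boundary, frame_select, prongs, valve_state
from .config import Config
from .io_frames import FrameStack, Report, load_frames

__all__ = ["run_pipeline"]

log = logging.getLogger("mvtrack")


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(
    source: str | Path | FrameStack | np.ndarray,
    config: Config | None = None,
) -> Report:
    """Run the full analysis on a video path, FrameStack or (N, h, w) array.

    Raises
    ------
    ValueError / IOError
        Propagated from the failing stage with the stage name attached,
        e.g. "too few frames" from loading or "no atrium boundary found"
        from the recursive search.
    """
    config = config or Config()

    _stage("load")
    if isinstance(source, FrameStack):
        stack = source
    elif isinstance(source, (str, Path)):
        stack = load_frames(source)
    else:
        stack = FrameStack(frames=np.asarray(source, dtype=float))
    frames = stack.frames
    n, h, w = frames.shape

    _stage("binarize frames")
    masks = [
        binarize.apply_threshold(f, binarize.otsu_threshold(f).threshold)
        for f in frames
    ]

    _stage("median background subtraction")
    background = binarize.median_background(frames)
    frames_sub = binarize.subtract_background(frames, background)
    masks_sub = [
        binarize.apply_threshold(f, binarize.otsu_threshold(f).threshold)
        for f in frames_sub
    ]

    _stage("extreme-frame selection")
    try:
        pair = frame_select.select_extreme_pair(masks_sub)
    except ValueError as exc:
        raise ValueError(f"extreme-frame selection: {exc}") from exc
    log.info("extreme pair: frames %d and %d (distance %.2f px)",
             pair.frame_x, pair.frame_y, pair.distance)
    combined = frame_select.combine(frames, frames_sub, masks, masks_sub, pair)

    _stage("recursive atrium boundary search")
    box = boundary.BoxSpec.bottom_right(w, h, config.box_frac)
    l1_init = binarize.otsu_threshold(combined.gray).threshold
    l2_init = binarize.otsu_threshold(combined.gray_subtracted).threshold
    try:
        atrium = boundary.recursive_search(
            combined.gray,
            combined.gray_subtracted,
            box,
            p=config.contour_frac,
            c=config.step,
            l1_init=l1_init,
            l2_init=l2_init,
        )
    except boundary.BoundaryNotFoundError as exc:
        raise boundary.BoundaryNotFoundError(
            f"atrium boundary search: {exc}"
        ) from exc
    region = atrium.region
    log.info(
        "atrium accepted at l1=%.4f l2=%.4f after (%d, %d) decrements; "
        "centroid (%.1f, %.1f)",
        atrium.l1_final, atrium.l2_final, *atrium.decrements, *atrium.centroid,
    )

    _stage("prong construction")
    prong_set = prongs.build_prongs(
        atrium.centroid,
        bbox_height=region.ymax - region.ymin,
        image_shape=(h, w),
        n_prongs=config.prong_count,
        cone_deg=config.cone_deg,
        length_frac=config.prong_len_frac,
    )

    _stage("hit detection and sigma series")
    hit_masks = [binarize.apply_threshold(f, atrium.l1_final) for f in frames]
    sigma, _hits = prongs.sigma_series(hit_masks, prong_set)
    log.debug("sigma series: %s", np.array2string(sigma.values, precision=3))

    _stage("valve state labelling")
    threshold = valve_state.gap_threshold(sigma)
    states = valve_state.label_states(sigma, threshold)
    log.info("sigma threshold %.4f%s", threshold.value,
             " (degenerate: no gap)" if threshold.degenerate else "")

    _stage("disease classification")
    verdict = valve_state.classify_disease(
        states,
        transition_frac=config.transition_frac,
        open_close_frac=config.open_close_frac,
    )
    log.info("verdict: %s (rules %s)", verdict.label,
             list(verdict.rules_triggered))

    return Report(
        n_frames=n,
        width=w,
        height=h,
        sigma=[float(s) for s in sigma.values],
        states=states.labels,
        sigma_threshold=threshold.value,
        sigma_degenerate=threshold.degenerate,
        verdict=verdict.label,
        rules_triggered=list(verdict.rules_triggered),
        transition_count=verdict.transition_count,
        open_fraction=verdict.open_fraction,
        closed_fraction=verdict.closed_fraction,
        l1_init=float(l1_init),
        l2_init=float(l2_init),
        l1_final=atrium.l1_final,
        l2_final=atrium.l2_final,
        decrements=list(atrium.decrements),
        atrium_centroid=[float(c) for c in atrium.centroid],
        atrium_bbox=[region.xmin, region.xmax, region.ymin, region.ymax],
        extreme_pair=[pair.frame_x, pair.frame_y],
        extreme_distance=pair.distance,
        config=config.to_dict(),
    )
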