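"""Contrast-bolus window detection from a per-frame vessel-opacity curve.

The opacity score of a frame is the number of vessel pixels surviving
segmentation cleanup — robust to global exposure drift, unlike raw mean
intensity.  The window is the longest contiguous run of frames whose score
reaches a configurable fraction of the curve maximum; the automatic result
can be overridden per endpoint from the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cine_io import CineSequence
from .errors import DetectionError, ValidationError
from .segmentation import FrangiParams, binarize_and_clean, frangi_vesselness

logger = logging.getLogger(__name__)

DEFAULT_DETECT_FRACTION = 0.3


@dataclass(frozen=True)
class ContrastWindow:
    """Inclusive [start, end] frame interval during which vessels are opacified."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValidationError(
                f"invalid contrast window ({self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, idx: int) -> bool:
        return self.start <= idx <= self.end

    def indices(self) -> range:
        return range(self.start, self.end + 1)

    def validate_for(self, frame_count: int) -> None:
        if self.end >= frame_count:
            raise ValidationError(
                f"window ({self.start}, {self.end}) exceeds frame count {frame_count}"
            )


@dataclass
class OpacityCurve:
    """Per-frame cleaned vessel-pixel counts."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise ValidationError("opacity curve must be 1-D")
        if (self.values < 0).any():
            raise ValidationError("opacity values must be >= 0")

    @property
    def frame_count(self) -> int:
        return int(self.values.shape[0])


def compute_opacity_curve(
    sequence: CineSequence,
    params: FrangiParams | None = None,
    threshold_strategy: str | float = "otsu",
    min_component_px: int = 50,
    closing_radius_px: int = 1,
) -> OpacityCurve:
    """Segment every frame and count surviving vessel pixels.

    With the "otsu" strategy the threshold is computed *once*, by pooling
    the nonzero vesselness values of all frames, and applied as a fixed
    threshold everywhere: per-frame thresholds would adapt to whatever weak
    ridges a dye-free frame contains and make counts incomparable across
    frames.
    """
    params = params or FrangiParams()
    vesselness = [frangi_vesselness(sequence.frames[i], params) for i in range(len(sequence))]
    if isinstance(threshold_strategy, str):
        if threshold_strategy != "otsu":
            raise ValidationError(f"unknown threshold strategy {threshold_strategy!r}")
        pooled = np.concatenate([v[v > 0].ravel() for v in vesselness])
        if pooled.size == 0 or np.ptp(pooled) == 0:
            return OpacityCurve(values=np.zeros(len(sequence), dtype=np.int64))
        from skimage.filters import threshold_otsu

        threshold_strategy = float(np.clip(threshold_otsu(pooled), 0.0, 1.0))
    counts = np.empty(len(sequence), dtype=np.int64)
    for i, v in enumerate(vesselness):
        mask = binarize_and_clean(v, threshold_strategy, min_component_px, closing_radius_px)
        counts[i] = int(mask.sum())
    return OpacityCurve(values=counts)


def detect_contrast_window(
    curve: OpacityCurve, fraction: float = DEFAULT_DETECT_FRACTION
) -> ContrastWindow:
    """Longest contiguous run of frames with opacity >= fraction * max.

    Equal-length runs tie-break to the earliest start.  Raises
    DetectionError when the curve is all zero (caller should fall back to a
    manual window).
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must lie in (0, 1)")
    vals = curve.values
    peak = int(vals.max()) if vals.size else 0
    if peak <= 0:
        raise DetectionError("no contrast detected (all-zero opacity curve)")
    above = vals >= fraction * peak

    best_start = best_len = -1
    run_start = None
    for i, flag in enumerate(above):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if run_start is not None and len(above) - run_start > best_len:
        best_start, best_len = run_start, len(above) - run_start
    return ContrastWindow(start=best_start, end=best_start + best_len - 1)


def apply_manual_window(
    auto: ContrastWindow | None,
    user_start: int | None,
    user_end: int | None,
    frame_count: int,
) -> ContrastWindow:
    """Override automatic endpoints with user-supplied frame indices."""
    for v, name in ((user_start, "start"), (user_end, "end")):
        if v is not None and not (0 <= v < frame_count):
            raise ValidationError(f"manual {name} {v} outside [0, {frame_count})")
    if auto is None and (user_start is None or user_end is None):
        raise ValidationError(
            "no automatic window available; both --contrast-start and "
            "--contrast-end are required"
        )
    start = user_start if user_start is not None else auto.start
    end = user_end if user_end is not None else auto.end
    if start > end:
        raise ValidationError(f"manual window ({start}, {end}) has start > end")
    window = ContrastWindow(start=start, end=end)
    window.validate_for(frame_count)
    return window


def dye_free_indices(
    window: ContrastWindow, frame_count: int, include_postbolus: bool = False
) -> list[int]:
    """Frames to track: everything before the window; optionally after it too.

    Post-bolus frames are excluded by default because residual dye may
    still faintly opacify vessels there.
    """
    window.validate_for(frame_count)
    idx = list(range(window.start))
    if include_postbolus:
        idx += list(range(window.end + 1, frame_count))
    return idx
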