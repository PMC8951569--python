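"""Frame-to-template association by zero-lag normalized cross-correlation.

Similarity is the Pearson correlation of pixel intensities over a region:

    r = sum((a - mean(a)) (b - mean(b))) /
        sqrt(sum((a - mean(a))^2) * sum((b - mean(b))^2))

computed at zero spatial lag (no translation search): frames are
*associated* wholesale, which doubles as the cardiac-phase assignment —
the winning template is taken to share the query's phase.  In background
mode the region is the template's background mask, so the score compares
dye-independent anatomy only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cine_io import CineSequence
from .errors import BankError, DegenerateInputError, ValidationError
from .segmentation import VesselContour
from .templates import TemplateBank

logger = logging.getLogger(__name__)

REGION_FULL = "full"
REGION_BACKGROUND = "background"


@dataclass
class MatchResult:
    query_frame_index: int
    best_template_index: int  # frame_index of the winning template
    score: float
    all_scores: np.ndarray  # one score per bank template, bank order
    transferred_contour: VesselContour


def normalized_cross_correlation(
    a: np.ndarray, b: np.ndarray, region: np.ndarray | None = None
) -> float:
    """Pearson correlation of two rasters over an optional region mask.

    Symmetric in its arguments and invariant to affine intensity rescaling
    of either input.  Raises DegenerateInputError when either input has
    zero variance over the region.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != a.shape:
            raise ValidationError("region mask shape mismatch")
        if region.sum() < 2:
            raise ValidationError("region must contain at least 2 pixels")
        a = a[region]
        b = b[region]
    else:
        a = a.ravel()
        b = b.ravel()
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateInputError("zero variance over the matching region")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise DegenerateInputError("zero variance over the matching region")
    r = float(da @ db) / np.sqrt(va * vb)
    return float(np.clip(r, -1.0, 1.0))


def match_frame(
    query: np.ndarray,
    bank: TemplateBank,
    region_mode: str = REGION_BACKGROUND,
    query_frame_index: int = -1,
) -> MatchResult:
    """Score a dye-free frame against every template; transfer the winner's contour.

    Ties break to the lowest template frame index; degenerate comparisons
    score 0 and never beat any positive score.
    """
    if region_mode not in (REGION_FULL, REGION_BACKGROUND):
        raise ValidationError(f"unknown region mode {region_mode!r}")
    if len(bank) == 0:
        raise BankError("empty template bank")
    query = np.asarray(query, dtype=np.float64)
    if query.shape != bank.templates[0].image.shape:
        raise ValidationError("query dimensions do not match bank frames")

    scores = np.empty(len(bank), dtype=np.float64)
    for k, template in enumerate(bank.templates):
        region = template.background_mask if region_mode == REGION_BACKGROUND else None
        try:
            scores[k] = normalized_cross_correlation(query, template.image, region)
        except DegenerateInputError:
            logger.warning(
                "degenerate comparison against template %d; scoring 0",
                template.frame_index,
            )
            scores[k] = 0.0
    best = int(np.argmax(scores))  # argmax returns the first (lowest-index) maximum
    winner = bank.templates[best]
    return MatchResult(
        query_frame_index=query_frame_index,
        best_template_index=winner.frame_index,
        score=float(scores[best]),
        all_scores=scores,
        transferred_contour=winner.contour.retagged(query_frame_index),
    )


def track_sequence(
    sequence: CineSequence,
    bank: TemplateBank,
    dye_free_indices: list[int],
    region_mode: str = REGION_BACKGROUND,
) -> list[MatchResult]:
    """Match every dye-free frame against the bank, preserving order."""
    n = len(sequence)
    for idx in dye_free_indices:
        if not (0 <= idx < n):
            raise ValidationError(f"dye-free index {idx} outside [0, {n})")
        if idx in bank.window:
            raise ValidationError(
                f"dye-free index {idx} lies inside the contrast window "
                f"({bank.window.start}, {bank.window.end})"
            )
    return [
        match_frame(sequence.frames[idx], bank, region_mode, query_frame_index=idx)
        for idx in dye_free_indices
    ]
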