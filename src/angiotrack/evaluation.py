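"""Quantitative scoring of tracking output against synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contrast import ContrastWindow
from .errors import ValidationError
from .matching import MatchResult
from .segmentation import fill_contours
from .synthetic import SyntheticGroundTruth
from .templates import TemplateBank

DEFAULT_PHASE_TOLERANCE = 1


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a| + |b|); defined as 1 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shape mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def circular_phase_distance(p: int, q: int, period: int) -> int:
    d = abs(int(p) - int(q)) % period
    return min(d, period - d)


@dataclass
class TrackingReport:
    per_frame_dice: list[float] = field(default_factory=list)
    mean_dice: float | None = None
    phase_hit_rate: float | None = None
    bolus_start_error: int | None = None
    bolus_end_error: int | None = None

    def to_dict(self) -> dict:
        return {
            "per_frame_dice": self.per_frame_dice,
            "mean_dice": self.mean_dice,
            "phase_hit_rate": self.phase_hit_rate,
            "bolus_start_error": self.bolus_start_error,
            "bolus_end_error": self.bolus_end_error,
        }


def evaluate_tracking(
    results: list[MatchResult],
    truth: SyntheticGroundTruth,
    bank: TemplateBank,
    detected: ContrastWindow | None = None,
    phase_tolerance: int = DEFAULT_PHASE_TOLERANCE,
) -> TrackingReport:
    """Per-frame Dice of transferred contours vs truth, phase hits, window error.

    A frame counts as a phase hit when the winning template's true phase is
    within `phase_tolerance` of the query frame's true phase, modulo the
    cardiac period (discretizing a continuous cycle makes exact-frame
    equality too strict).
    """
    n_frames, rows, cols = truth.true_masks.shape
    report = TrackingReport()
    if detected is not None:
        report.bolus_start_error = detected.start - truth.true_bolus_window.start
        report.bolus_end_error = detected.end - truth.true_bolus_window.end
    if not results:
        return report

    hits = 0
    for res in results:
        q = res.query_frame_index
        if not (0 <= q < n_frames):
            raise ValidationError(f"query index {q} outside ground truth (n={n_frames})")
        if not (0 <= res.best_template_index < n_frames):
            raise ValidationError(
                f"template index {res.best_template_index} outside ground truth"
            )
        predicted = fill_contours(res.transferred_contour, (rows, cols))
        report.per_frame_dice.append(dice(predicted, truth.true_masks[q]))
        d = circular_phase_distance(
            int(truth.true_phase[res.best_template_index]),
            int(truth.true_phase[q]),
            truth.period_frames,
        )
        hits += d <= phase_tolerance
    report.mean_dice = float(np.mean(report.per_frame_dice))
    report.phase_hit_rate = hits / len(results)
    return report
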