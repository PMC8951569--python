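"""End-to-end orchestration: detect window -> build bank -> track -> report."""

from __future__ import annotations

from dataclasses import dataclass

from .cine_io import CineSequence
from .config import RunConfig
from .contrast import (
    ContrastWindow,
    apply_manual_window,
    compute_opacity_curve,
    detect_contrast_window,
    dye_free_indices,
)
from .errors import DetectionError
from .matching import MatchResult, track_sequence
from .templates import TemplateBank, build_template_bank


@dataclass
class TrackingRun:
    window: ContrastWindow
    auto_window: ContrastWindow | None
    bank: TemplateBank
    dye_free: list[int]
    results: list[MatchResult]

    def report_dict(self) -> dict:
        return {
            "window": [self.window.start, self.window.end],
            "auto_window": (
                [self.auto_window.start, self.auto_window.end]
                if self.auto_window is not None
                else None
            ),
            "bank_frames": self.bank.frame_indices,
            "dye_free_frames": self.dye_free,
            "matches": [
                {
                    "query_index": r.query_frame_index,
                    "best_template_index": r.best_template_index,
                    "score": r.score,
                    "scores": [float(s) for s in r.all_scores],
                }
                for r in self.results
            ],
        }


def run_tracking(
    sequence: CineSequence,
    config: RunConfig | None = None,
    manual_start: int | None = None,
    manual_end: int | None = None,
) -> TrackingRun:
    """Run the full pipeline on a loaded sequence.

    Automatic bolus detection is skipped when both manual endpoints are
    given; a detection failure is fatal only when no manual window exists.
    """
    config = config or RunConfig()
    params = config.segmentation.frangi_params()
    seg_kwargs = dict(
        threshold_strategy=config.segmentation.threshold,
        min_component_px=config.segmentation.min_component_px,
        closing_radius_px=config.segmentation.closing_radius_px,
    )

    auto: ContrastWindow | None = None
    if manual_start is None or manual_end is None:
        curve = compute_opacity_curve(sequence, params, **seg_kwargs)
        try:
            auto = detect_contrast_window(curve, config.detection.fraction)
        except DetectionError:
            if manual_start is None or manual_end is None:
                raise
    if manual_start is None and manual_end is None and auto is not None:
        window = auto
        window.validate_for(len(sequence))
    else:
        window = apply_manual_window(auto, manual_start, manual_end, len(sequence))

    bank = build_template_bank(
        sequence,
        window,
        seg_params=params,
        dilation_radius_px=config.matching.dilation_radius_px,
        **seg_kwargs,
    )
    dye_free = dye_free_indices(
        window, len(sequence), include_postbolus=config.detection.include_postbolus
    )
    results = track_sequence(sequence, bank, dye_free, region_mode=config.matching.region)
    return TrackingRun(
        window=window, auto_window=auto, bank=bank, dye_free=dye_free, results=results
    )
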