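"""Template bank: segmented contrast-window frames with background masks.

Each template carries the frame image, its cleaned vessel mask, traced
contours, and a *background mask* — the complement of the dilated vessel
mask.  Matching on the background only compares dye-independent anatomy
(ribs, diaphragm, catheter); the dilation margin keeps the dye halo out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.morphology import dilation, disk

from .cine_io import CineSequence, contours_to_json
from .contrast import ContrastWindow
from .errors import BankError, ValidationError
from .segmentation import (
    FrangiParams,
    VesselContour,
    binarize_and_clean,
    extract_contours,
    frangi_vesselness,
)

logger = logging.getLogger(__name__)

DEFAULT_DILATION_RADIUS = 5
MIN_BACKGROUND_FRACTION = 0.2


@dataclass
class TemplateFrame:
    frame_index: int
    image: np.ndarray
    mask: np.ndarray
    contour: VesselContour
    background_mask: np.ndarray

    @property
    def true_background_fraction(self) -> float:
        return float(self.background_mask.mean())


@dataclass
class TemplateBank:
    templates: list[TemplateFrame]
    window: ContrastWindow

    def __post_init__(self) -> None:
        if not self.templates:
            raise BankError("template bank is empty")
        indices = [t.frame_index for t in self.templates]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValidationError("template indices must be strictly increasing")
        if any(i not in self.window for i in indices):
            raise ValidationError("template index outside contrast window")

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def frame_indices(self) -> list[int]:
        return [t.frame_index for t in self.templates]


def build_template_bank(
    sequence: CineSequence,
    window: ContrastWindow,
    seg_params: FrangiParams | None = None,
    dilation_radius_px: int = DEFAULT_DILATION_RADIUS,
    threshold_strategy: str | float = "otsu",
    min_component_px: int = 50,
    closing_radius_px: int = 1,
) -> TemplateBank:
    """Segment every contrast-window frame into a TemplateFrame.

    Frames whose cleaned vessel mask comes out empty (faint opacification
    at the window edges) are dropped with a warning rather than failing the
    whole bank.
    """
    window.validate_for(len(sequence))
    if dilation_radius_px < 0:
        raise ValidationError("dilation_radius_px must be >= 0")
    seg_params = seg_params or FrangiParams()

    selem = disk(dilation_radius_px) if dilation_radius_px > 0 else None
    templates: list[TemplateFrame] = []
    for idx in window.indices():
        image = sequence.frames[idx]
        vesselness = frangi_vesselness(image, seg_params)
        mask = binarize_and_clean(
            vesselness, threshold_strategy, min_component_px, closing_radius_px
        )
        if not mask.any():
            logger.warning("dropping frame %d from bank: empty vessel mask", idx)
            continue
        dilated = dilation(mask, selem) if selem is not None else mask
        background = ~dilated
        frac = float(background.mean())
        if frac < MIN_BACKGROUND_FRACTION:
            logger.warning(
                "template %d: background fraction %.2f < %.2f; matching "
                "quality may degrade",
                idx,
                frac,
                MIN_BACKGROUND_FRACTION,
            )
        templates.append(
            TemplateFrame(
                frame_index=idx,
                image=image,
                mask=mask,
                contour=extract_contours(mask, frame_index=idx),
                background_mask=background,
            )
        )
    if not templates:
        raise BankError(
            f"every frame in window ({window.start}, {window.end}) yielded an "
            "empty vessel mask"
        )
    return TemplateBank(templates=templates, window=window)


def save_bank(bank: TemplateBank, path: str | Path) -> None:
    """Serialize the bank (masks as PNG, contours as JSON, plus a manifest)."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "window": [bank.window.start, bank.window.end],
        "templates": bank.frame_indices,
    }
    for t in bank.templates:
        iio.imwrite(out / f"mask_{t.frame_index:04d}.png", t.mask.astype(np.uint8) * 255)
        contours_to_json([t.contour.polylines], out / f"contour_{t.frame_index:04d}.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
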