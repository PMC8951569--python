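"""Cine sequence I/O: DICOM reading, overlay rendering, contour JSON.

Intensities are min-max normalized to [0, 1] *globally over the whole
sequence*, never per frame, so that the contrast-bolus wash-in/wash-out
signal survives normalization.  All pixel coordinates are 0-based
(row, col); contour vertices are float (row, col) pairs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from . import dicom as _dcm
from .errors import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FALLBACK_FPS = 15.0


@dataclass
class CineSequence:
    """Ordered stack of 2-D grayscale frames in [0, 1] with metadata.

    Attributes
    ----------
    frames : (n, rows, cols) float64 array, values in [0, 1].
    frame_rate : frames/second, or None when absent from metadata.
    pixel_spacing : (row mm, col mm), or None.
    source_id : provenance string (file path, simulator tag, ...).
    """

    frames: np.ndarray
    frame_rate: float | None = None
    pixel_spacing: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise InputError("frames must be a (n, rows, cols) stack")
        if self.frames.shape[0] < 2:
            raise InputError("a cine sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise InputError("frames contain non-finite values")
        if self.frames.min() < 0.0 or self.frames.max() > 1.0:
            raise InputError("frame intensities must lie in [0, 1]")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class OverlayStyle:
    """Colors and line width for contour overlays (RGB, 0-255)."""

    predicted_color: tuple[int, int, int] = (255, 255, 0)  # yellow
    reference_color: tuple[int, int, int] = (0, 255, 0)  # green
    line_thickness: int = 1

    def __post_init__(self) -> None:
        for color in (self.predicted_color, self.reference_color):
            if len(color) != 3 or any(not (0 <= c <= 255) for c in color):
                raise ValidationError("RGB components must be in [0, 255]")
        if self.line_thickness < 1:
            raise ValidationError("line_thickness must be >= 1")


def _normalize_stack(stack: np.ndarray, source: str) -> np.ndarray:
    stack = np.asarray(stack, dtype=np.float64)
    lo, hi = float(stack.min()), float(stack.max())
    if hi <= lo:
        raise InputError(f"{source}: degenerate constant sequence (min-max undefined)")
    return (stack - lo) / (hi - lo)


def read_cine(path: str | os.PathLike) -> CineSequence:
    """Read a multi-frame DICOM file or a directory of single-frame DICOMs.

    Returns a CineSequence normalized to [0, 1] by the global min/max of the
    stored values.  MONOCHROME1 frames are inverted first so radio-opaque
    structures (vessels filled with dye) are always dark.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"{p}: no such file or directory")
    if p.is_dir():
        files = sorted(x for x in p.iterdir() if x.is_file())
        if not files:
            raise FormatError(f"{p}: empty directory")
        parts = []
        for f in files:
            try:
                parts.append((f, _dcm.read_dicom_file(f)))
            except FormatError:
                logger.warning("skipping unreadable file %s", f)
        if not parts:
            raise FormatError(f"{p}: no readable DICOM files")
        # ascending InstanceNumber, ties broken lexicographically by name
        parts.sort(key=lambda fp: (
            fp[1].instance_number if fp[1].instance_number is not None else 1 << 30,
            fp[0].name,
        ))
        shapes = {fp[1].pixels.shape[1:] for fp in parts}
        if len(shapes) != 1:
            raise InputError(f"{p}: series frames have differing dimensions {shapes}")
        stacks = [_maybe_invert(fp[1]) for fp in parts]
        stack = np.concatenate(stacks, axis=0)
        meta = parts[0][1]
    else:
        try:
            meta = _dcm.read_dicom_file(p)
        except FormatError:
            raise
        except Exception as exc:  # corrupt stream
            raise FormatError(f"{p}: unreadable DICOM ({exc})") from exc
        stack = _maybe_invert(meta)

    if stack.shape[0] < 2:
        raise InputError(f"{p}: fewer than 2 frames")
    return CineSequence(
        frames=_normalize_stack(stack, str(p)),
        frame_rate=meta.frame_rate,
        pixel_spacing=meta.pixel_spacing,
        source_id=str(p),
    )


def _maybe_invert(fs: _dcm.DicomFrameSet) -> np.ndarray:
    pixels = fs.pixels.astype(np.float64)
    if fs.photometric == "MONOCHROME1":
        pixels = pixels.max() - pixels
    return pixels


# ---------------------------------------------------------------------------
# overlay rendering


def rasterize_polyline(
    polyline: np.ndarray, shape: tuple[int, int], thickness: int = 1
) -> np.ndarray:
    """Binary raster of a polyline's stroke (rounded to the pixel grid)."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(polyline, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValidationError("polyline must be an (n>=2, 2) array of (row, col)")
    ipts = np.clip(
        np.round(pts).astype(int),
        [0, 0],
        [shape[0] - 1, shape[1] - 1],
    )
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    if thickness > 1:
        mask = dilation(mask, disk(thickness - 1))
    return mask


def render_overlay_frame(
    frame: np.ndarray,
    contour_sets: list[tuple[list[np.ndarray], tuple[int, int, int]]],
    thickness: int = 1,
) -> np.ndarray:
    """Gray frame replicated to RGB uint8 with each contour set stroked in its color."""
    gray = np.clip(np.round(np.asarray(frame) * 255), 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for polylines, color in contour_sets:
        for poly in polylines:
            stroke = rasterize_polyline(poly, frame.shape, thickness)
            rgb[stroke] = color
    return rgb


def _check_contours_bounds(
    contours_per_frame: list[list[np.ndarray]], shape: tuple[int, int]
) -> None:
    lo = -0.5  # pixel extents run from -0.5 to n-0.5
    for i, polylines in enumerate(contours_per_frame):
        for poly in polylines:
            pts = np.asarray(poly, dtype=np.float64)
            if pts.size == 0:
                continue
            if (
                pts[:, 0].min() < lo
                or pts[:, 1].min() < lo
                or pts[:, 0].max() > shape[0] - 0.5
                or pts[:, 1].max() > shape[1] - 0.5
            ):
                raise ValidationError(f"contour vertex out of bounds on frame {i}")


def write_overlay(
    sequence: CineSequence,
    contours_per_frame: list[list[np.ndarray]],
    style: OverlayStyle,
    path: str | os.PathLike,
    reference_contours_per_frame: list[list[np.ndarray]] | None = None,
) -> None:
    """Write PNG overlay frames (one file per frame under `path`).

    `contours_per_frame` (predicted, drawn in ``style.predicted_color``) must
    supply one possibly-empty contour list per frame; the optional reference
    set is drawn in ``style.reference_color``.
    """
    n = len(sequence)
    if len(contours_per_frame) != n:
        raise ValidationError(
            f"expected {n} contour sets, got {len(contours_per_frame)}"
        )
    shape = sequence.frame_shape
    _check_contours_bounds(contours_per_frame, shape)
    if reference_contours_per_frame is not None:
        if len(reference_contours_per_frame) != n:
            raise ValidationError("reference contour sets must match frame count")
        _check_contours_bounds(reference_contours_per_frame, shape)

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    digits = max(4, len(str(n - 1)))
    for i in range(n):
        sets = [(contours_per_frame[i], style.predicted_color)]
        if reference_contours_per_frame is not None:
            sets.append((reference_contours_per_frame[i], style.reference_color))
        rgb = render_overlay_frame(sequence.frames[i], sets, style.line_thickness)
        iio.imwrite(out / f"frame_{i:0{digits}d}.png", rgb)


def write_overlay_video(
    sequence: CineSequence,
    contours_per_frame: list[list[np.ndarray]],
    style: OverlayStyle,
    path: str | os.PathLike,
) -> None:
    """Write an overlay video; falls back to 15 fps if frame_rate is absent."""
    fps = sequence.frame_rate
    if fps is None:
        logger.warning("no frame_rate in metadata; defaulting to %.0f fps", DEFAULT_FALLBACK_FPS)
        fps = DEFAULT_FALLBACK_FPS
    _check_contours_bounds(contours_per_frame, sequence.frame_shape)
    frames = [
        render_overlay_frame(
            sequence.frames[i],
            [(contours_per_frame[i], style.predicted_color)],
            style.line_thickness,
        )
        for i in range(len(sequence))
    ]
    iio.imwrite(path, np.stack(frames), fps=fps)


# ---------------------------------------------------------------------------
# contour JSON interchange


def contours_to_json(contours_per_frame: list[list[np.ndarray]], path: str | os.PathLike) -> None:
    """Save per-frame polylines as JSON: [[[row, col], ...], ...] per frame."""
    payload = [
        [np.asarray(poly, dtype=float).tolist() for poly in polylines]
        for polylines in contours_per_frame
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def contours_from_json(path: str | os.PathLike) -> list[list[np.ndarray]]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        [np.asarray(poly, dtype=np.float64) for poly in polylines]
        for polylines in payload
    ]
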