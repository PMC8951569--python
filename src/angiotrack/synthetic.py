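"""Ground-truthed synthetic cine-angiogram generator.

Renders a branching vessel tree (cubic splines, tapering widths, optional
focal stenoses) over a static background, animated by a smooth periodic
global deformation (translation plus sinusoidal bending) of configurable
amplitude, with a contrast bolus that ramps in and out over a configured
frame window, and seeded additive Gaussian noise.  Per-frame true vessel
masks, the true bolus window, and true cardiac-phase labels are returned
alongside the image stack, so the full pipeline can be validated without
patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .cine_io import CineSequence
from .contrast import ContrastWindow
from .dicom import write_dicom
from .errors import GenerationError, ValidationError

BOLUS_RAMP_FRAMES = 3  # linear ramp length at each end of the bolus


@dataclass(frozen=True)
class Stenosis:
    """Focal narrowing at arc-length fraction `position`, lumen reduced by `severity`."""

    position: float
    severity: float
    extent: float = 0.12  # arc-length fraction affected (full width of the bump)

    def __post_init__(self) -> None:
        if not (0.0 < self.position < 1.0):
            raise ValidationError("stenosis position must lie in (0, 1)")
        if not (0.0 < self.severity < 1.0):
            raise ValidationError("stenosis severity must lie in (0, 1) — no occlusion")
        if self.extent <= 0:
            raise ValidationError("stenosis extent must be positive")


@dataclass(frozen=True)
class BranchSpec:
    """One vessel branch: a smooth curve through control points.

    `width` is the lumen diameter in pixels — a scalar, or a (start, end)
    pair linearly interpolated along arc length.
    """

    control_points: tuple[tuple[float, float], ...]
    width: float | tuple[float, float] = 6.0
    stenosis: Stenosis | None = None

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise ValidationError("a branch needs at least 2 control points")
        w = self.width if isinstance(self.width, tuple) else (self.width, self.width)
        if min(w) <= 0:
            raise ValidationError("branch widths must be > 0")

    def width_pair(self) -> tuple[float, float]:
        if isinstance(self.width, tuple):
            return self.width
        return (float(self.width), float(self.width))


@dataclass(frozen=True)
class PhantomConfig:
    frame_size: tuple[int, int] = (160, 160)
    n_frames: int = 60
    period_frames: int = 20
    bolus_window: ContrastWindow | None = field(default_factory=lambda: ContrastWindow(20, 45))
    vessel_tree: tuple[BranchSpec, ...] = ()
    motion_amplitude_px: float = 5.0
    vessel_contrast: float = 0.55
    noise_sigma: float = 0.02
    background: str = "edges"  # {"gradient", "edges"}
    seed: int = 0
    name: str = "phantom"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.period_frames < 4:
            raise ValidationError("period_frames must be >= 4")
        if self.bolus_window is not None and self.bolus_window.end >= self.n_frames:
            raise ValidationError("bolus window must lie within [0, n_frames)")
        if not (0.0 < self.vessel_contrast <= 1.0):
            raise ValidationError("vessel_contrast must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.motion_amplitude_px < 0:
            raise ValidationError("motion_amplitude_px must be >= 0")
        if self.background not in ("gradient", "edges"):
            raise ValidationError("background must be 'gradient' or 'edges'")
        if not self.vessel_tree:
            raise ValidationError("vessel_tree must contain at least one branch")


@dataclass
class SyntheticGroundTruth:
    true_masks: np.ndarray  # (n, rows, cols) bool — geometry present every frame
    true_bolus_window: ContrastWindow | None
    true_phase: np.ndarray  # (n,) int
    period_frames: int


def bolus_profile(t: int, window: ContrastWindow | None) -> float:
    """0 outside the window; linear 3-frame ramps to a plateau of 1 inside.

    `window=None` means no injection at all (profile identically 0).
    """
    if window is None or t not in window:
        return 0.0
    up = (t - window.start + 1) / BOLUS_RAMP_FRAMES
    down = (window.end - t + 1) / BOLUS_RAMP_FRAMES
    return float(min(1.0, up, down))


def _sample_branch(branch: BranchSpec, spacing: float = 0.4):
    """Densely sample the branch spline: positions (m, 2) and half-widths (m,)."""
    pts = np.asarray(branch.control_points, dtype=np.float64)
    if len(pts) == 2:  # straight segment
        t = np.linspace(0, 1, max(2, int(np.hypot(*(pts[1] - pts[0])) / spacing)))
        pos = pts[0] + t[:, None] * (pts[1] - pts[0])
    else:
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        spline = CubicSpline(chord, pts, axis=0)
        dense_t = np.linspace(0, chord[-1], max(2, int(chord[-1] / spacing) + 1))
        pos = spline(dense_t)
    # arc-length fraction along the sampled curve
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    frac = arc / arc[-1] if arc[-1] > 0 else arc
    w0, w1 = branch.width_pair()
    widths = w0 + (w1 - w0) * frac
    if branch.stenosis is not None:
        st = branch.stenosis
        d = np.abs(frac - st.position)
        half = st.extent / 2.0
        # smooth cosine bump: full severity at the center, 0 beyond the extent
        bump = np.where(d < half, 0.5 * (1 + np.cos(np.pi * d / half)), 0.0)
        widths = widths * (1.0 - st.severity * bump)
    return pos, widths / 2.0


def _displacement(phase: int, period: int, amplitude: float, rows: int):
    """Periodic global motion: translation plus a row-dependent bend.

    Returns (dy scalar, dx_base scalar, bend scalar); the column shift of a
    point at row y is dx_base + bend * sin(pi * y / rows).
    """
    theta = 2.0 * np.pi * phase / period
    dy = amplitude * np.sin(theta)
    dx = 0.5 * amplitude * np.cos(theta)
    bend = 0.4 * amplitude * np.sin(theta)
    return dy, dx, bend


def _rasterize_tube(
    shape: tuple[int, int], pos: np.ndarray, half_widths: np.ndarray
) -> np.ndarray:
    """Union of disks along the sampled centerline (chunked broadcasting)."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    # consecutive samples are spatially close, so a local bounding box per
    # chunk keeps the distance computation small
    chunk = 64
    for lo in range(0, len(pos), chunk):
        p = pos[lo : lo + chunk]
        h = half_widths[lo : lo + chunk]
        hw = float(h.max())
        r0 = max(int(np.floor(p[:, 0].min() - hw)), 0)
        r1 = min(int(np.ceil(p[:, 0].max() + hw)), rows - 1)
        c0 = max(int(np.floor(p[:, 1].min() - hw)), 0)
        c1 = min(int(np.ceil(p[:, 1].max() + hw)), cols - 1)
        if r1 < r0 or c1 < c0:
            continue
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        d2 = (yy[..., None] - p[:, 0]) ** 2 + (xx[..., None] - p[:, 1]) ** 2
        mask[r0 : r1 + 1, c0 : c1 + 1] |= (d2 <= h**2).any(axis=-1)
    return mask


def _static_background(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = config.frame_size
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    img = 0.55 + 0.25 * (yy / rows)  # vertical exposure gradient
    if config.background == "edges":
        # cardiac silhouette: big soft-edged dark ellipse
        cy, cx = rows * 0.62, cols * 0.30
        ell = ((yy - cy) / (rows * 0.45)) ** 2 + ((xx - cx) / (cols * 0.38)) ** 2 <= 1.0
        img -= 0.18 * ndimage.gaussian_filter(ell.astype(np.float64), 4.0)
        # rib-like diagonal bands
        bands = 0.5 * (1 + np.sin((yy * 0.9 + xx * 0.45) * 2 * np.pi / 48.0))
        img -= 0.04 * bands
        # static soft-tissue texture (seeded, frozen across frames)
        texture = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 7.0)
        texture /= max(np.abs(texture).max(), 1e-12)
        img += 0.08 * texture
    return np.clip(img, 0.05, 0.95)


def generate_synthetic_cine(
    config: PhantomConfig,
) -> tuple[CineSequence, SyntheticGroundTruth]:
    """Render the phantom sequence and its exact ground truth.

    Deterministic given the config (including its seed).  Raises
    GenerationError when the moving vessel tree leaves the frame.
    """
    rows, cols = config.frame_size
    rng = np.random.default_rng(config.seed)
    background = _static_background(config, rng)
    period = config.period_frames
    amp = config.motion_amplitude_px

    branch_samples = [_sample_branch(b) for b in config.vessel_tree]

    # one mask and one warped background per distinct phase
    phase_masks: dict[int, np.ndarray] = {}
    phase_bg: dict[int, np.ndarray] = {}
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    for phase in range(min(period, config.n_frames)):
        dy, dx, bend = _displacement(phase, period, amp, rows)
        mask = np.zeros((rows, cols), dtype=bool)
        for pos, hw in branch_samples:
            moved = pos.copy()
            moved[:, 0] += dy
            moved[:, 1] += dx + bend * np.sin(np.pi * pos[:, 0] / rows)
            if (
                moved[:, 0].min() < 0
                or moved[:, 0].max() > rows - 1
                or moved[:, 1].min() < 0
                or moved[:, 1].max() > cols - 1
            ):
                raise GenerationError(
                    "vessel geometry leaves the frame under motion; reduce "
                    "motion_amplitude_px or move control points inward"
                )
            mask |= _rasterize_tube((rows, cols), moved, hw)
        phase_masks[phase] = mask
        # backward warp of the static background by the same field
        src_y = yy - dy
        src_x = xx - (dx + bend * np.sin(np.pi * yy / rows))
        phase_bg[phase] = ndimage.map_coordinates(
            background, [src_y, src_x], order=1, mode="reflect"
        )

    frames = np.empty((config.n_frames, rows, cols), dtype=np.float64)
    masks = np.empty((config.n_frames, rows, cols), dtype=bool)
    for t in range(config.n_frames):
        phase = t % period
        mask = phase_masks[phase]
        img = phase_bg[phase].copy()
        opacity = config.vessel_contrast * bolus_profile(t, config.bolus_window)
        if opacity > 0:
            soft = ndimage.gaussian_filter(
                mask.astype(np.float64), 0.7, truncate=2.0
            )
            img -= opacity * np.clip(soft, 0.0, 1.0)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        frames[t] = np.clip(img, 0.0, 1.0)
        masks[t] = mask

    if amp == 0:
        # degenerate cycle: the heart never moves, every frame shares one
        # motion state, so all phase labels collapse to 0
        phases = np.zeros(config.n_frames, dtype=np.int64)
    else:
        phases = np.arange(config.n_frames, dtype=np.int64) % period

    sequence = CineSequence(
        frames=frames,
        frame_rate=15.0,
        pixel_spacing=(0.2, 0.2),
        source_id=f"synthetic:{config.name}:seed={config.seed}",
    )
    truth = SyntheticGroundTruth(
        true_masks=masks,
        true_bolus_window=config.bolus_window,
        true_phase=phases,
        period_frames=period,
    )
    return sequence, truth


# ---------------------------------------------------------------------------
# canonical robustness configurations


def default_test_suite_configs() -> list[PhantomConfig]:
    """Named phantoms covering the robustness axes: curvature, width
    variation, stenosis, branching.  60 frames, period 20, bolus 20-45,
    fixed seeds — each includes one fully dye-free cardiac cycle."""
    base = dict(
        frame_size=(160, 160),
        n_frames=60,
        period_frames=20,
        bolus_window=ContrastWindow(20, 45),
        motion_amplitude_px=5.0,
        vessel_contrast=0.55,
        noise_sigma=0.02,
        background="edges",
    )
    return [
        PhantomConfig(
            name="high_curvature",
            seed=101,
            vessel_tree=(
                BranchSpec(
                    control_points=((30, 45), (55, 100), (85, 50), (115, 105), (128, 70)),
                    width=6.0,
                ),
            ),
            **base,
        ),
        PhantomConfig(
            name="width_taper",
            seed=102,
            vessel_tree=(
                BranchSpec(
                    control_points=((30, 55), (70, 90), (105, 70), (128, 90)),
                    width=(8.0, 2.0),
                ),
            ),
            **base,
        ),
        PhantomConfig(
            name="stenosed",
            seed=103,
            vessel_tree=(
                BranchSpec(
                    control_points=((30, 60), (75, 95), (125, 75)),
                    width=6.0,
                    stenosis=Stenosis(position=0.5, severity=0.5),
                ),
            ),
            **base,
        ),
        PhantomConfig(
            name="multi_branch",
            seed=104,
            vessel_tree=(
                BranchSpec(control_points=((28, 80), (75, 90), (125, 60)), width=6.0),
                BranchSpec(control_points=((52, 86), (85, 115), (118, 122)), width=4.0),
                BranchSpec(control_points=((95, 80), (115, 100), (126, 118)), width=3.5),
            ),
            **base,
        ),
    ]


def get_preset(name: str) -> PhantomConfig:
    for cfg in default_test_suite_configs():
        if cfg.name == name:
            return cfg
    names = [c.name for c in default_test_suite_configs()]
    raise ValidationError(f"unknown preset {name!r}; choose from {names}")


def reseeded(config: PhantomConfig, seed: int) -> PhantomConfig:
    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# export


def save_simulation(
    out_dir: str | Path,
    sequence: CineSequence,
    truth: SyntheticGroundTruth,
    fmt: str = "dicom",
) -> None:
    """Write the rendered sequence plus a ground-truth bundle.

    The bundle is ``truth.json`` (window, phases, period) plus per-frame
    mask PNGs under ``masks/``; the sequence goes to ``cine.dcm`` (12-bit
    DICOM) or a ``frames/`` PNG directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "dicom":
        stored = np.round(sequence.frames * 4095).astype(np.uint16)
        write_dicom(
            out / "cine.dcm",
            stored,
            frame_rate=sequence.frame_rate,
            pixel_spacing=sequence.pixel_spacing,
        )
    elif fmt == "png":
        fdir = out / "frames"
        fdir.mkdir(exist_ok=True)
        for i, frame in enumerate(sequence.frames):
            iio.imwrite(
                fdir / f"frame_{i:04d}.png",
                np.round(frame * 255).astype(np.uint8),
            )
    else:
        raise ValidationError(f"unknown export format {fmt!r}")

    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for i, mask in enumerate(truth.true_masks):
        iio.imwrite(mask_dir / f"mask_{i:04d}.png", mask.astype(np.uint8) * 255)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "bolus_window": (
                    None
                    if truth.true_bolus_window is None
                    else [truth.true_bolus_window.start, truth.true_bolus_window.end]
                ),
                "true_phase": truth.true_phase.tolist(),
                "period_frames": truth.period_frames,
                "n_frames": int(truth.true_masks.shape[0]),
            },
            fh,
            indent=2,
        )


def load_truth_bundle(path: str | Path) -> SyntheticGroundTruth:
    p = Path(path)
    with open(p / "truth.json") as fh:
        meta = json.load(fh)
    masks = []
    for i in range(meta["n_frames"]):
        masks.append(iio.imread(p / "masks" / f"mask_{i:04d}.png") > 127)
    return SyntheticGroundTruth(
        true_masks=np.stack(masks),
        true_bolus_window=(
            ContrastWindow(*meta["bolus_window"]) if meta["bolus_window"] else None
        ),
        true_phase=np.asarray(meta["true_phase"], dtype=np.int64),
        period_frames=int(meta["period_frames"]),
    )
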