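"""Multi-scale vesselness filtering, mask cleanup, and exact contour tracing.

The vesselness response follows the classic 2-D Hessian-eigenvalue
formulation: per scale sigma, with |lambda1| <= |lambda2|,

    V_sigma = 0                          if the polarity sign test fails
            = exp(-Rb^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2)))   otherwise

with blobness Rb = lambda1/lambda2 and structureness
S = sqrt(lambda1^2 + lambda2^2); the final response is the per-pixel
maximum over scales.  Dark tubes on a bright background (contrast-filled
vessels in standard display) correspond to lambda2 > 0.

Contours are traced along pixel *edges* ("crack" boundaries) at
half-integer coordinates, which makes the mask -> contours -> fill
round-trip exactly the identity on the pixel grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, remove_small_objects

from .errors import ScaleError, ValidationError

DARK_ON_BRIGHT = "dark-on-bright"
BRIGHT_ON_DARK = "bright-on-dark"


@dataclass
class FrangiParams:
    """Scales and sensitivities for the vesselness filter.

    `c` is expressed on the Hessian-norm scale of a [0, 1]-normalized image
    (the conventional value of ~15 assumes 8-bit intensities and must be
    rescaled accordingly).
    """

    sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    beta: float = 0.5
    c: float = 0.08
    polarity: str = DARK_ON_BRIGHT

    def __post_init__(self) -> None:
        self.sigmas = tuple(float(s) for s in self.sigmas)
        if not self.sigmas:
            raise ValidationError("sigmas must be non-empty")
        if any(s <= 0 for s in self.sigmas):
            raise ValidationError("all sigmas must be > 0")
        if any(b >= a for a, b in zip(self.sigmas[1:], self.sigmas[:-1])):
            raise ValidationError("sigmas must be strictly increasing")
        if self.beta <= 0 or self.c <= 0:
            raise ValidationError("beta and c must be strictly positive")
        if self.polarity not in (DARK_ON_BRIGHT, BRIGHT_ON_DARK):
            raise ValidationError(f"unknown polarity {self.polarity!r}")


@dataclass
class VesselContour:
    """Closed crack-boundary polylines of a vessel mask.

    Each polyline is an (n, 2) float array of (row, col) vertices at
    half-integer coordinates with first vertex == last vertex.
    """

    polylines: list[np.ndarray] = field(default_factory=list)
    source_frame_index: int = 0

    def retagged(self, frame_index: int) -> "VesselContour":
        return VesselContour(
            polylines=[p.copy() for p in self.polylines],
            source_frame_index=frame_index,
        )


def _hessian(frame: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # scale-normalized second derivatives, reflect padding
    opts = dict(sigma=sigma, mode="reflect")
    hrr = ndimage.gaussian_filter(frame, order=(2, 0), **opts)
    hcc = ndimage.gaussian_filter(frame, order=(0, 2), **opts)
    hrc = ndimage.gaussian_filter(frame, order=(1, 1), **opts)
    s2 = sigma * sigma
    return hrr * s2, hrc * s2, hcc * s2


def frangi_vesselness(frame: np.ndarray, params: FrangiParams | None = None) -> np.ndarray:
    """Per-pixel vesselness in [0, 1], maximum over the configured scales.

    A margin of ceil(3 * sigma_max) pixels is forcibly zeroed to suppress
    boundary artifacts of the Gaussian derivatives.
    """
    params = params or FrangiParams()
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValidationError("frame must be 2-D")
    if not np.all(np.isfinite(frame)):
        raise ValidationError("frame contains non-finite values")
    sigma_max = max(params.sigmas)
    margin = math.ceil(3 * sigma_max)
    if min(frame.shape) <= 2 * margin:
        raise ScaleError(
            f"frame {frame.shape} too small for sigma_max={sigma_max} "
            f"(needs > {2 * margin} px per side)"
        )

    out = np.zeros_like(frame)
    two_beta2 = 2.0 * params.beta**2
    two_c2 = 2.0 * params.c**2
    for sigma in params.sigmas:
        hrr, hrc, hcc = _hessian(frame, sigma)
        # eigenvalues of [[hrr, hrc], [hrc, hcc]]
        half_trace = 0.5 * (hrr + hcc)
        root = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
        ev_lo = half_trace - root
        ev_hi = half_trace + root
        # order by |.|: lambda1 smaller magnitude
        swap = np.abs(ev_lo) > np.abs(ev_hi)
        lam1 = np.where(swap, ev_hi, ev_lo)
        lam2 = np.where(swap, ev_lo, ev_hi)

        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(lam2 != 0, (lam1 / np.where(lam2 != 0, lam2, 1.0)) ** 2, 0.0)
        s2 = lam1**2 + lam2**2
        v = np.exp(-rb2 / two_beta2) * (1.0 - np.exp(-s2 / two_c2))
        if params.polarity == DARK_ON_BRIGHT:
            v[lam2 <= 0] = 0.0
        else:
            v[lam2 >= 0] = 0.0
        np.maximum(out, v, out=out)

    if margin > 0:
        out[:margin, :] = 0.0
        out[-margin:, :] = 0.0
        out[:, :margin] = 0.0
        out[:, -margin:] = 0.0
    return np.clip(out, 0.0, 1.0)


def binarize_and_clean(
    vesselness: np.ndarray,
    threshold_strategy: str | float = "otsu",
    min_component_px: int = 50,
    closing_radius_px: int = 1,
) -> np.ndarray:
    """Threshold a vesselness map, close small gaps, drop small components.

    `threshold_strategy` is either the string "otsu" (Otsu over the nonzero
    vesselness values) or a fixed float threshold in [0, 1].  Components use
    8-connectivity.
    """
    v = np.asarray(vesselness, dtype=np.float64)
    if v.ndim != 2:
        raise ValidationError("vesselness must be 2-D")
    if v.min() < 0 or v.max() > 1:
        raise ValidationError("vesselness values must lie in [0, 1]")
    if min_component_px < 0 or closing_radius_px < 0:
        raise ValidationError("min_component_px and closing_radius_px must be >= 0")

    if isinstance(threshold_strategy, str):
        if threshold_strategy != "otsu":
            raise ValidationError(f"unknown threshold strategy {threshold_strategy!r}")
        nonzero = v[v > 0]
        if nonzero.size == 0 or np.ptp(nonzero) == 0:
            return np.zeros_like(v, dtype=bool)
        t = float(threshold_otsu(nonzero))
    else:
        t = float(threshold_strategy)
        if not (0.0 <= t <= 1.0):
            raise ValidationError(f"fixed threshold {t} outside [0, 1]")

    mask = v >= t
    if closing_radius_px > 0:
        # Chebyshev ball: a Euclidean radius-1 disk is a 4-neighbour cross,
        # which cannot bridge 1-px diagonal/axial gaps
        footprint = np.ones((2 * closing_radius_px + 1,) * 2, dtype=bool)
        mask = closing(mask, footprint)
    if min_component_px > 0:
        mask = remove_small_objects(mask, max_size=min_component_px - 1, connectivity=2)
    return mask


# ---------------------------------------------------------------------------
# crack-boundary contour tracing and exact filling

# headings: 0=E(+c), 1=S(+r), 2=W(-c), 3=N(-r)
_STEP = {0: (0, 1), 1: (1, 0), 2: (0, -1), 3: (-1, 0)}


def extract_contours(mask: np.ndarray, frame_index: int = 0) -> VesselContour:
    """Trace closed boundary polylines along pixel edges.

    Every boundary (outer borders and holes alike) becomes one closed
    polyline of half-integer (row, col) vertices.  Diagonally touching
    pixels (8-connectivity) are traced as a single loop.  The polylines
    reproduce the mask exactly under :func:`fill_contours`.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if not mask.any():
        return VesselContour(polylines=[], source_frame_index=frame_index)

    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    # directed crack edges with interior on the left, keyed by start corner.
    # corners are (2r+1)-style doubled integers to stay hashable/exact:
    # corner (i, j) denotes the point (i/2 - 1, j/2 - 1) in mask coordinates.
    edges: dict[tuple[int, int], list[tuple[tuple[int, int], int]]] = {}

    def add_edge(start: tuple[int, int], end: tuple[int, int], heading: int) -> None:
        edges.setdefault(start, []).append((end, heading))

    rows, cols = np.nonzero(padded)
    up = ~padded[rows - 1, cols]
    down = ~padded[rows + 1, cols]
    left = ~padded[rows, cols - 1]
    right = ~padded[rows, cols + 1]
    for r, c, u, d, lf, rt in zip(rows, cols, up, down, left, right):
        # doubled corner coords for pixel (r, c): corners at (2r±1, 2c±1)
        tl = (2 * r - 1, 2 * c - 1)
        tr = (2 * r - 1, 2 * c + 1)
        bl = (2 * r + 1, 2 * c - 1)
        br = (2 * r + 1, 2 * c + 1)
        if u:
            add_edge(tr, tl, 2)  # walk W along the top edge
        if d:
            add_edge(bl, br, 0)  # walk E along the bottom edge
        if lf:
            add_edge(tl, bl, 1)  # walk S along the left edge
        if rt:
            add_edge(br, tr, 3)  # walk N along the right edge

    polylines: list[np.ndarray] = []
    # deterministic loop extraction: start from lexicographically smallest corner
    while edges:
        start = min(edges)
        vertices = [start]
        point = start
        # take any outgoing edge from the start
        nxt, heading = edges[point].pop()
        if not edges[point]:
            del edges[point]
        while nxt != start:
            vertices.append(nxt)
            point = nxt
            options = edges[point]
            if len(options) == 1:
                nxt, heading = options.pop()
            else:
                # corner where two diagonal pixels meet: prefer the right
                # turn so 8-connected components trace as one loop
                want = (heading + 1) % 4
                pick = 0
                for k, (_, h) in enumerate(options):
                    if h == want:
                        pick = k
                        break
                nxt, heading = options.pop(pick)
            if not options:
                del edges[point]
        vertices.append(start)
        arr = np.asarray(vertices, dtype=np.float64) / 2.0 - 1.0
        polylines.append(_simplify_collinear(arr))

    return VesselContour(polylines=polylines, source_frame_index=frame_index)


def _simplify_collinear(poly: np.ndarray) -> np.ndarray:
    """Merge consecutive collinear axis-aligned segments (keeps closure)."""
    if len(poly) <= 3:
        return poly
    keep = [poly[0]]
    for i in range(1, len(poly) - 1):
        a, b, c = keep[-1], poly[i], poly[i + 1]
        if (a[0] == b[0] == c[0]) or (a[1] == b[1] == c[1]):
            continue
        keep.append(b)
    keep.append(poly[-1])
    return np.asarray(keep)


def fill_contours(
    contour: VesselContour, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize closed crack-boundary polylines back to a binary mask.

    Uses even-odd parity of vertical-edge crossings at pixel centers, which
    is exact for the half-integer rectilinear polylines produced by
    :func:`extract_contours`.
    """
    toggles = np.zeros(shape, dtype=np.int64)
    for poly in contour.polylines:
        pts = np.asarray(poly, dtype=np.float64)
        if len(pts) < 2:
            continue
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            if c0 != c1:
                continue  # horizontal segments never cross a leftward ray
            lo, hi = (r0, r1) if r0 < r1 else (r1, r0)
            col = int(math.ceil(c0))
            if col < 0 or col >= shape[1]:
                continue
            r_first = int(math.floor(lo)) + 1
            r_last = int(math.ceil(hi)) - 1
            r_first = max(r_first, 0)
            r_last = min(r_last, shape[0] - 1)
            if r_first <= r_last:
                toggles[r_first : r_last + 1, col] += 1
    return (np.cumsum(toggles, axis=1) % 2).astype(bool)


def count_components(mask: np.ndarray) -> int:
    """Number of 8-connected components (diagnostic helper)."""
    return int(label(np.asarray(mask, dtype=bool), connectivity=2).max())
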