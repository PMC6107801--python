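"""Programmatic afterimage stimuli: inducer / remaining-contour pairs.

Every stimulus used by the model's demonstrations and tests is generated
here as a pure function of its geometric specification — no randomness, no
external assets, bit-reproducible across runs.  An inducer is a chromatic
shape on a white canvas; the paired remaining contour is a black achromatic
outline on white.  What matters for the model is topology, not artwork:
which chromatic edge (inner, outer, both, or none) the remaining contour
overlaps.  Geometry below is therefore chosen to preserve those overlap
relations for each of the classic stimulus families:

``ring_outer`` / ``ring_inner``
    A single colored annulus with the contour straddling its outer or inner
    circular edge — the minimal negative / positive effect pair.
``stars_vanlier`` and the ``stars_rect_*`` variants
    A stylized two-star stimulus: a cyan four-point star, a complementary
    red four-point star rotated 45 degrees painted over it, and a white
    central square.  The baseline contour outlines the cyan star; the rect
    variants add a small square contour that either straddles the white
    square's chromatic border (overlap) or sits strictly inside the uniform
    white center (apart).
``spiral_full`` / ``spiral_outer`` / ``spiral_inner``
    A reddish Archimedean spiral strip with an open contour along both
    side edges, the outer side only, or the inner side only.
``star_single_color``
    A single-color eight-point star (union of the two four-point stars,
    all cyan — no transparency cues) with the four-point contour.
``averaging_negative_a`` / ``averaging_negative_b`` / ``averaging_positive``
    Two-color stimuli for the color-averaging effects: a half-red/half-blue
    disk under one enclosing circle (a) or with an added dividing contour
    (b), and a two-color annulus with the inner circle remaining (positive
    filling-in of the enclosed white interior).

Named region masks ("interior", "annulus", "vertices", ...) accompany each
pair so that perceived-color metrics can be evaluated on the areas the
corresponding predictions are about.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ShapeSpec",
    "StimulusPair",
    "make_ring",
    "make_contour",
    "fixture",
    "fixture_names",
    "rle_encode",
    "rle_decode",
]

WHITE = (1.0, 1.0, 1.0)
BLACK = (0.0, 0.0, 0.0)

# Default palette: cyan and red are exact opponent complements
# ((0,1,1) and (1,0,0) have opposite chromatic opponent components).
CYAN = (0.0, 1.0, 1.0)
RED = (1.0, 0.0, 0.0)
RING_RED = (1.0, 0.2, 0.2)
AVG_RED = (1.0, 0.1, 0.1)
AVG_BLUE = (0.1, 0.1, 1.0)

_MARGIN = 8.0


@dataclass(frozen=True)
class ShapeSpec:
    """Geometry of a generated shape on a white canvas."""

    kind: str = "ring"
    canvas: tuple[int, int] = (128, 128)
    center: tuple[float, float] | None = None
    radii: tuple[float, float] = (30.0, 40.0)  # (inner, outer) for rings
    thickness: float = 2.0  # contour band thickness, px
    n_points: int = 4
    rotation_deg: float = 0.0
    turns: float = 2.25
    strip_width: float = 8.0
    pitch: float = 15.0
    start_radius: float = 14.0
    color: tuple[float, float, float] = RING_RED

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise ValueError("contour thickness must be >= 1 px")
        h, w = self.canvas
        if h < 32 or w < 32:
            raise ValueError("canvas must be at least 32 x 32")

    @property
    def center_yx(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.canvas
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(dy, dx) offsets of every pixel from the shape center."""
        h, w = self.canvas
        cy, cx = self.center_yx
        yy, xx = np.mgrid[0:h, 0:w]
        return yy - cy, xx - cx


@dataclass
class StimulusPair:
    """An inducer image, its remaining-contour image and named regions."""

    name: str
    inducer: np.ndarray
    contour: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    colors: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def _blank(canvas: tuple[int, int]) -> np.ndarray:
    h, w = canvas
    return np.ones((h, w, 3), dtype=float)


def _paint(img: np.ndarray, mask: np.ndarray, color) -> None:
    img[mask] = np.asarray(color, dtype=float)


def _check_margin(spec: ShapeSpec, extent: float) -> None:
    h, w = spec.canvas
    cy, cx = spec.center_yx
    room = min(cy, cx, h - 1 - cy, w - 1 - cx)
    if extent > room - _MARGIN:
        raise ValueError(
            f"shape extent {extent:.1f}px leaves less than {_MARGIN:.0f}px margin "
            f"on a {h}x{w} canvas"
        )


# ---------------------------------------------------------------------------
# rings


def _ring_mask(spec: ShapeSpec) -> np.ndarray:
    r_in, r_out = spec.radii
    dy, dx = spec.grid()
    d = np.hypot(dy, dx)
    return (d >= r_in) & (d < r_out)


def make_ring(spec: ShapeSpec) -> np.ndarray:
    """Colored annulus on white; membership is half-open [r_inner, r_outer)."""
    r_in, r_out = spec.radii
    if not (0 < r_in < r_out):
        raise ValueError(f"need 0 < inner < outer radius, got {spec.radii}")
    _check_margin(spec, r_out)
    img = _blank(spec.canvas)
    _paint(img, _ring_mask(spec), spec.color)
    return img


def _circle_band(spec: ShapeSpec, radius: float) -> np.ndarray:
    dy, dx = spec.grid()
    d = np.hypot(dy, dx)
    t = spec.thickness
    return (d >= radius - t / 2) & (d < radius + t / 2)


def make_contour(spec: ShapeSpec, side="outer") -> np.ndarray:
    """Black outline tracing one edge of a ring inducer.

    ``side`` is ``"inner"``, ``"outer"``, ``"full"`` (both edges) or
    ``("offset", d)`` — the outer contour displaced ``d`` pixels toward the
    shape interior without touching either chromatic edge.
    """
    if spec.kind != "ring":
        raise ValueError("make_contour currently supports ring specs")
    r_in, r_out = spec.radii
    t = spec.thickness
    if isinstance(side, tuple) and len(side) == 2 and side[0] == "offset":
        d = float(side[1])
        r = r_out - d
        # The displaced band must stay clear of the +-1 px support of both
        # chromatic edges (that support is where the edge response lives).
        if r + t / 2 >= r_out - 1.0 or r - t / 2 <= r_in + 1.0:
            raise ValueError(
                f"offset contour at radius {r:.1f} collides with a chromatic edge"
            )
        bands = [_circle_band(spec, r)]
    elif side == "outer":
        bands = [_circle_band(spec, r_out)]
    elif side == "inner":
        bands = [_circle_band(spec, r_in)]
    elif side == "full":
        bands = [_circle_band(spec, r_in), _circle_band(spec, r_out)]
    else:
        raise ValueError(f"unknown contour side {side!r}")
    img = _blank(spec.canvas)
    for band in bands:
        _paint(img, band, BLACK)
    return img


# ---------------------------------------------------------------------------
# stars
#
# Four-point stars are L^p balls with p < 1 (astroid-like): membership is an
# analytic function of pixel position, so edges and contour bands are under
# exact geometric control — no polygon-rasterization ambiguity about which
# side of an edge a contour pixel falls on (the model's predictions are
# sensitive to exactly that).

_STAR_P = 0.7
_STAR_RADIUS = 40.0
_SQUARE_HALF = 12.0


def _astroid_mu(spec: ShapeSpec, rotation_deg: float = 0.0) -> np.ndarray:
    """L^p 'radius' of every pixel in a frame rotated by rotation_deg.

    The sublevel set mu <= R is a concave four-point star with points on the
    rotated axes at distance R.
    """
    dy, dx = spec.grid()
    a = np.deg2rad(rotation_deg)
    u = np.cos(a) * dx + np.sin(a) * dy
    v = -np.sin(a) * dx + np.cos(a) * dy
    p = _STAR_P
    return (np.abs(u) ** p + np.abs(v) ** p) ** (1.0 / p)


def _star_radius(spec: ShapeSpec) -> float:
    return _STAR_RADIUS * spec.canvas[0] / 128.0


def _star_mask(spec: ShapeSpec, rotation_deg: float = 0.0) -> np.ndarray:
    return _astroid_mu(spec, rotation_deg) <= _star_radius(spec)


def _outline_band(mask: np.ndarray, thickness: float = 2.0) -> np.ndarray:
    """Contour band tracing a shape's boundary on its interior side.

    A filled shape contains its boundary pixels, so the drawn outline of the
    shape occupies those same (chromatic-side) rows; implemented with the
    Euclidean signed distance so the band has uniform width everywhere.
    """
    mask = np.asarray(mask, dtype=bool)
    signed = ndimage.distance_transform_edt(~mask) - ndimage.distance_transform_edt(mask)
    return (signed > -(thickness + 0.5)) & (signed <= 0.5)


def _chebyshev(spec: ShapeSpec) -> np.ndarray:
    dy, dx = spec.grid()
    return np.maximum(np.abs(dy), np.abs(dx))


# ---------------------------------------------------------------------------
# spirals


def _spiral_offset(spec: ShapeSpec) -> np.ndarray:
    """Signed radial offset of every pixel from the nearest spiral arm."""
    dy, dx = spec.grid()
    r = np.hypot(dy, dx)
    phi = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    b = spec.pitch / (2 * np.pi)
    theta_max = spec.turns * 2 * np.pi
    best = np.full(r.shape, np.inf)
    k_max = int(np.ceil(spec.turns)) + 1
    for k in range(k_max + 1):
        theta = phi + 2 * np.pi * k
        valid = theta <= theta_max
        arm_r = spec.start_radius + b * theta
        offset = np.where(valid, r - arm_r, np.inf)
        closer = np.abs(offset) < np.abs(best)
        best = np.where(closer, offset, best)
    return best


# ---------------------------------------------------------------------------
# fixtures


def _scaled(spec: ShapeSpec, size: int) -> ShapeSpec:
    if size == 128:
        return spec
    f = size / 128.0
    return replace(
        spec,
        canvas=(size, size),
        radii=(spec.radii[0] * f, spec.radii[1] * f),
        thickness=max(spec.thickness * f, 1.0),
        pitch=spec.pitch * f,
        strip_width=max(spec.strip_width * f, 2.0),
        start_radius=spec.start_radius * f,
    )


def _ring_pair(name: str, side, size: int) -> StimulusPair:
    # Cyan inducer as in the schematic ring stimulus (its afterimage
    # complement is red); high-chroma, so the percept is well above the
    # solver-noise floor.
    spec = _scaled(ShapeSpec(kind="ring", radii=(30.0, 40.0), color=CYAN), size)
    inducer = make_ring(spec)
    contour = make_contour(spec, side)
    dy, dx = spec.grid()
    d = np.hypot(dy, dx)
    regions = {
        "interior": d <= spec.radii[0] - 4.0,
        "annulus": _ring_mask(spec),
        "surround": d >= spec.radii[1] + 4.0,
    }
    return StimulusPair(name, inducer, contour, regions, {"primary": spec.color})


def _square_half(spec: ShapeSpec) -> float:
    return _SQUARE_HALF * spec.canvas[0] / 128.0


def _square_band(spec: ShapeSpec, half: float) -> np.ndarray:
    cheb = _chebyshev(spec)
    return np.abs(cheb - half) <= 1.0


def _stars_pair(name: str, size: int) -> StimulusPair:
    """Two interleaved four-point stars with a white central square.

    The red star (points on the diagonals) is painted first and the cyan
    star (points on the axes; the one whose outline remains) over it, so
    the red points are visible between the cyan ones and the area around
    the central white square carries the cyan star's color.  The white
    square stands in for the central transparency region of the classic
    two-star stimulus and anchors the added-rectangle variants: the
    "overlap" square contour straddles the square's chromatic border, the
    "apart" one sits strictly inside the uniform white center.
    """
    spec = ShapeSpec(kind="star", canvas=(size, size))
    star_a = _star_mask(spec, 0.0)
    star_b = _star_mask(spec, 45.0)
    half = _square_half(spec)
    cheb = _chebyshev(spec)
    inducer = _blank(spec.canvas)
    _paint(inducer, star_b, RED)
    _paint(inducer, star_a, CYAN)
    _paint(inducer, cheb <= half, WHITE)
    contour_mask = _outline_band(star_a)
    if name == "stars_rect_overlap":
        contour_mask = contour_mask | _square_band(spec, half)
    elif name == "stars_rect_apart":
        contour_mask = contour_mask | _square_band(spec, half / 2.0)
    contour = _blank(spec.canvas)
    _paint(contour, contour_mask, BLACK)
    regions = {
        # Inside the smaller (apart) square with clearance from its band.
        "interior": cheb <= half / 2.0 - 2.0,
        "central_square": cheb <= half - 2.0,
    }
    return StimulusPair(
        name, inducer, contour, regions, {"primary": CYAN, "secondary": RED}
    )


def _single_star_pair(name: str, size: int) -> StimulusPair:
    """One cyan star plus the other star's outline: no transparency cues.

    The two-star stimulus with one color removed: only the diagonal star
    keeps its (cyan) color, while the remaining contour still traces the
    axis-aligned star.  Most of that contour runs through white and is
    inert; it meets the chromatic edges only where the two stars cross,
    at the vertices of the central polygon.
    """
    spec = ShapeSpec(kind="star", canvas=(size, size))
    star_kept = _star_mask(spec, 45.0)
    star_removed = _star_mask(spec, 0.0)
    img = _blank(spec.canvas)
    _paint(img, star_kept, CYAN)
    contour = _blank(spec.canvas)
    _paint(contour, _outline_band(star_removed), BLACK)
    dy, dx = spec.grid()
    d = np.hypot(dy, dx)
    R = _star_radius(spec)
    inter = star_kept & star_removed
    depth = ndimage.distance_transform_edt(inter)
    regions = {
        "central_polygon": depth >= 4.0 * spec.canvas[0] / 128.0,
        "vertices": star_kept & (d >= 0.7 * R),
    }
    return StimulusPair(name, img, contour, regions, {"primary": CYAN})


def _spiral_pair(name: str, size: int) -> StimulusPair:
    spec = _scaled(ShapeSpec(kind="spiral", color=RING_RED), size)
    extent = spec.start_radius + spec.pitch * spec.turns + spec.strip_width / 2.0
    _check_margin(spec, extent)
    s = _spiral_offset(spec)
    strip = np.abs(s) < spec.strip_width / 2.0
    img = _blank(spec.canvas)
    _paint(img, strip, spec.color)
    half = spec.strip_width / 2.0
    t = spec.thickness
    # Contour bands extend outward (in +radius) from the named edge, the
    # same half-open convention as strip membership [-w/2, +w/2): the inner
    # contour coincides with the innermost strip rows, the outer contour
    # with the first background rows outside the strip.
    outer_band = (s >= half) & (s < half + t)
    inner_band = (s >= -half) & (s < -half + t)
    if name == "spiral_full":
        band = outer_band | inner_band
    elif name == "spiral_outer":
        band = outer_band
    elif name == "spiral_inner":
        band = inner_band
    else:  # pragma: no cover
        raise ValueError(name)
    contour = _blank(spec.canvas)
    _paint(contour, band, BLACK)
    dy, dx = spec.grid()
    d = np.hypot(dy, dx)
    regions = {
        "strip": strip,
        # Achromatic surround of the strip, clear of the edge-response
        # support, out to just beyond the outermost turn.
        "gap": (np.abs(s) >= half + 2.0) & (d < extent + 2.0),
        # Achromatic gap on the outside of the strip only.
        "outer_gap": (s >= half + 2.0) & (d < extent + 2.0),
        # Central disk enclosed by the innermost turn.
        "core": d <= spec.start_radius - half - 1.0,
    }
    return StimulusPair(name, img, contour, regions, {"primary": spec.color})


def _averaging_pair(name: str, size: int) -> StimulusPair:
    f = size / 128.0
    spec = ShapeSpec(kind="ring", canvas=(size, size))
    dy, dx = spec.grid()
    d = np.hypot(dy, dx)
    left = dx < 0
    img = _blank(spec.canvas)
    contour = _blank(spec.canvas)
    if name in ("averaging_negative_a", "averaging_negative_b"):
        r = 30.0 * f
        disk = d < r
        _paint(img, disk & left, AVG_RED)
        _paint(img, disk & ~left, AVG_BLUE)
        cspec = replace(spec, radii=(r / 2, r))
        band = _circle_band(cspec, r)
        if name == "averaging_negative_b":
            band = band | ((np.abs(dx) <= 1.0) & (d < r + 1.0))
        _paint(contour, band, BLACK)
        regions = {"disk": d <= r - 4.0}
    else:  # averaging_positive
        r_in, r_out = 24.0 * f, 32.0 * f
        ring = (d >= r_in) & (d < r_out)
        _paint(img, ring & left, AVG_RED)
        _paint(img, ring & ~left, AVG_BLUE)
        cspec = replace(spec, radii=(r_in, r_out))
        _paint(contour, _circle_band(cspec, r_in), BLACK)
        regions = {"interior": d <= r_in - 4.0}
    return StimulusPair(
        name, img, contour, regions, {"primary": AVG_RED, "secondary": AVG_BLUE}
    )


_FIXTURES = {
    "ring_outer": lambda size: _ring_pair("ring_outer", "outer", size),
    "ring_inner": lambda size: _ring_pair("ring_inner", "inner", size),
    "stars_vanlier": lambda size: _stars_pair("stars_vanlier", size),
    "stars_rect_overlap": lambda size: _stars_pair("stars_rect_overlap", size),
    "stars_rect_apart": lambda size: _stars_pair("stars_rect_apart", size),
    "spiral_full": lambda size: _spiral_pair("spiral_full", size),
    "spiral_outer": lambda size: _spiral_pair("spiral_outer", size),
    "spiral_inner": lambda size: _spiral_pair("spiral_inner", size),
    "star_single_color": lambda size: _single_star_pair("star_single_color", size),
    "averaging_negative_a": lambda size: _averaging_pair("averaging_negative_a", size),
    "averaging_negative_b": lambda size: _averaging_pair("averaging_negative_b", size),
    "averaging_positive": lambda size: _averaging_pair("averaging_positive", size),
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture(name: str, size: int = 128) -> StimulusPair:
    """Deterministic stimulus pair for one of the bundled fixtures.

    ``size`` scales the default 128 x 128 canvas (geometry scales with it),
    so tests can run on smaller grids.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {', '.join(fixture_names())}"
        ) from None
    return builder(size)


# ---------------------------------------------------------------------------
# region mask serialization


def rle_encode(mask: np.ndarray) -> list[int]:
    """Run-length encode a boolean mask (flattened, starting with zeros)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != flat.size:
        raise ValueError("run lengths do not match mask size")
    return flat.reshape(shape)
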