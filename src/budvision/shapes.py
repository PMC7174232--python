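"""Parametric bud silhouettes and their closed-form geometry.

Synthetic buds are modelled as star polygons in elliptical coordinates: the
local radius is ``r(phi) = R * (1 + a*cos(k*phi) + smooth perturbation)``,
stretched by an axis ratio (elongation) and rotated.  The frill term
``a*cos(k*phi)`` emulates petal scalloping and directly controls the
irregularity descriptors; fetal (pre-bloom) buds get small ``R`` and small
``a``, open blooms larger values.

Canonical families (circle, ellipse, square) additionally admit exact
continuous-geometry values for all 14 morphological descriptors, used as
analytic ground truth for the rasterized pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.special import ellipe

from .morphology import MorphologyVector

FAMILIES = ("circle", "ellipse", "square", "bud")


@dataclass(frozen=True)
class ShapeSpec:
    """Full description of one synthetic bud silhouette.

    Parameters
    ----------
    family : str
        ``circle``, ``ellipse``, ``square`` or ``bud``.
    scale_px : float
        Characteristic radius in pixels (circle radius; ellipse semi-minor
        axis; square half-side; bud base radius). Must exceed 2.
    elongation : float
        Axis ratio >= 1 applied along the rotated major direction.
    frill_amplitude : float
        Petal modulation amplitude ``a`` in ``r = R*(1 + a*cos(k*phi))``;
        must stay below 1 so the radius remains positive.
    frill_count : int
        Petal count ``k``.
    rotation_rad : float
        Orientation of the major axis.
    center : tuple of float
        ``(x, y)`` position in plate coordinates.
    fourier_extra : tuple
        Optional smooth perturbation, ``(order, cos_amp, sin_amp)`` triples
        added to the radial modulation (bud family only).
    """

    family: str
    scale_px: float
    elongation: float = 1.0
    frill_amplitude: float = 0.0
    frill_count: int = 0
    rotation_rad: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    fourier_extra: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}")
        if self.scale_px <= 2:
            raise ValueError("scale_px must exceed 2 pixels")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        total_amp = self.frill_amplitude + sum(
            abs(c) + abs(s) for _, c, s in self.fourier_extra
        )
        if not 0 <= self.frill_amplitude < 1 or total_amp >= 1:
            raise ValueError("radial modulation must stay below 1")
        if self.frill_count < 0:
            raise ValueError("frill_count must be >= 0")

    @property
    def max_radius(self) -> float:
        """Upper bound on the distance from center to any silhouette point."""
        amp = self.frill_amplitude + sum(
            abs(c) + abs(s) for _, c, s in self.fourier_extra
        )
        if self.family == "square":
            return self.scale_px * self.elongation * np.sqrt(2.0)
        return self.scale_px * self.elongation * (1.0 + amp)

    def _radial_modulation(self, phi: np.ndarray) -> np.ndarray:
        r = 1.0 + self.frill_amplitude * np.cos(self.frill_count * phi)
        for order, camp, samp in self.fourier_extra:
            r += camp * np.cos(order * phi) + samp * np.sin(order * phi)
        return r


def rasterize(spec: ShapeSpec, shape_hw: tuple[int, int] | None = None) -> np.ndarray:
    """Render a silhouette as a boolean mask by pixel-center inclusion.

    If ``shape_hw`` is None the grid is the tight bounding box around the
    shape's maximal radius and the mask is returned with the implied origin
    at ``floor(center - max_radius) - 1``; callers needing plate placement
    should pass the full plate shape.
    """
    if shape_hw is None:
        r = int(np.ceil(spec.max_radius)) + 2
        cx, cy = spec.center
        xs = np.arange(int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1)
        ys = np.arange(int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1)
    else:
        h, w = shape_hw
        xs = np.arange(w)
        ys = np.arange(h)
    X, Y = np.meshgrid(xs, ys)
    return _inside(spec, X.astype(float), Y.astype(float))


def rasterize_cropped(spec: ShapeSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize into a tight crop; returns ``(mask, (x0, y0) offset)``."""
    r = int(np.ceil(spec.max_radius)) + 2
    cx, cy = spec.center
    x0 = int(np.floor(cx)) - r
    y0 = int(np.floor(cy)) - r
    xs = np.arange(x0, x0 + 2 * r + 1)
    ys = np.arange(y0, y0 + 2 * r + 1)
    X, Y = np.meshgrid(xs, ys)
    mask = _inside(spec, X.astype(float), Y.astype(float))
    ys_any = np.nonzero(mask.any(axis=1))[0]
    xs_any = np.nonzero(mask.any(axis=0))[0]
    if len(ys_any) == 0:
        raise ValueError("shape rasterized to an empty mask")
    crop = mask[ys_any[0] : ys_any[-1] + 1, xs_any[0] : xs_any[-1] + 1]
    return crop, (x0 + int(xs_any[0]), y0 + int(ys_any[0]))


def _inside(spec: ShapeSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    ct, st = np.cos(spec.rotation_rad), np.sin(spec.rotation_rad)
    dx = X - spec.center[0]
    dy = Y - spec.center[1]
    u = ct * dx + st * dy  # along major axis
    v = -st * dx + ct * dy
    a = spec.scale_px * spec.elongation
    b = spec.scale_px
    if spec.family == "circle":
        return u**2 + v**2 <= spec.scale_px**2
    if spec.family == "ellipse":
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if spec.family == "square":
        # half-open coverage so an axis-aligned side-s square spans exactly
        # s pixels (closed intervals would add one row and column)
        return (u >= -a) & (u < a) & (v >= -b) & (v < b)
    # bud: star-polygon radial model in elongation-normalized coordinates
    un = u / spec.elongation
    rho = np.hypot(un, v)
    phi = np.arctan2(v, un)
    return rho <= spec.scale_px * spec._radial_modulation(phi)


# ---------------------------------------------------------------------------
# analytic (continuous-geometry) morphology


def boundary_points(spec: ShapeSpec, n: int = 4096) -> np.ndarray:
    """Dense ``(n, 2)`` sampling of the silhouette boundary (plate coords)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    a = spec.scale_px * spec.elongation
    b = spec.scale_px
    if spec.family == "circle":
        u, v = spec.scale_px * np.cos(t), spec.scale_px * np.sin(t)
    elif spec.family == "ellipse":
        u, v = a * np.cos(t), b * np.sin(t)
    elif spec.family == "square":
        u, v = _square_boundary(a, b, n)
    else:
        r = spec.scale_px * spec._radial_modulation(t)
        u, v = spec.elongation * r * np.cos(t), r * np.sin(t)
    ct, st = np.cos(spec.rotation_rad), np.sin(spec.rotation_rad)
    x = spec.center[0] + ct * u - st * v
    y = spec.center[1] + st * u + ct * v
    return np.column_stack([x, y])


def _square_boundary(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    per_side = n // 4
    s = np.linspace(-1.0, 1.0, per_side, endpoint=False)
    u = np.concatenate([a * s, np.full(per_side, a), -a * s, np.full(per_side, -a)])
    v = np.concatenate([np.full(per_side, -b), b * s, np.full(per_side, b), -b * s])
    return u, v


def _arclength_radial_variance(spec: ShapeSpec, n: int = 1 << 15) -> tuple[float, float]:
    """Arc-length-weighted variance of boundary distances to the center."""
    pts = boundary_points(spec, n)
    c = np.asarray(spec.center, dtype=float)
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    w = np.hypot(seg[:, 0], seg[:, 1])
    d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    mean = np.average(d, weights=w)
    var = np.average((d - mean) ** 2, weights=w)
    dn = d / mean
    return float(var), float(np.average((dn - np.average(dn, weights=w)) ** 2, weights=w))


def analytic_morphology(spec: ShapeSpec) -> MorphologyVector:
    """Exact continuous-geometry values of all 14 descriptors.

    Supported for the canonical families (circle, ellipse, square); bud
    silhouettes have no closed form and raise ``ValueError``.  The ellipse
    perimeter uses the complete elliptic integral of the second kind.
    """
    a = spec.scale_px * spec.elongation
    b = spec.scale_px
    if spec.family == "circle":
        r = spec.scale_px
        P, A = 2 * np.pi * r, np.pi * r**2
        long_ax = short_ax = 2 * r
        rin = rex = r
        irr = nirr = 0.0
    elif spec.family == "ellipse":
        P = float(4 * a * ellipe(1 - (b / a) ** 2))
        A = np.pi * a * b
        long_ax, short_ax = 2 * a, 2 * b
        rin, rex = b, a
        irr, nirr = _arclength_radial_variance(spec)
    elif spec.family == "square":
        w, h = 2 * a, 2 * b  # rectangle sides (square when elongation == 1)
        P, A = 2 * (w + h), w * h
        diag = float(np.hypot(w, h))
        long_ax = diag
        short_ax = _rect_perp_chord(w, h)
        rin, rex = min(w, h) / 2, diag / 2
        irr, nirr = _arclength_radial_variance(spec)
    else:
        raise ValueError("bud silhouettes have no closed-form morphology")
    eq_d = float(np.sqrt(4 * A / np.pi))
    return MorphologyVector(
        perimeter=float(P),
        area=float(A),
        long_axis=float(long_ax),
        short_axis=float(short_ax),
        incircle_r=float(rin),
        excircle_r=float(rex),
        eq_diameter=eq_d,
        circularity=float(4 * np.pi * A / P**2),
        shape_param=float(P**2 / A),
        aspect_ratio=float(long_ax / short_ax),
        compactness=float(eq_d / long_ax),
        roundness=float(rin / rex),
        irregularity=irr,
        norm_irregularity=nirr,
    )


def _rect_perp_chord(w: float, h: float) -> float:
    """Length of the chord through the rectangle center perpendicular to its
    diagonal (the continuous short axis of a rectangle)."""
    diag = np.hypot(w, h)
    u = np.array([w, h]) / diag
    v = np.array([-u[1], u[0]])
    rect = shapely.Polygon(
        [(-w / 2, -h / 2), (w / 2, -h / 2), (w / 2, h / 2), (-w / 2, h / 2)]
    )
    line = shapely.LineString([tuple(-2 * diag * v), tuple(2 * diag * v)])
    return float(rect.intersection(line).length)
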