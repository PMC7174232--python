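"""Contour morphometrics: the 14 shape descriptors used to grade dried
flower buds.

Ten of the descriptors are classical (perimeter, area, long/short axis,
incircle and excircle radii, area-equivalent diameter, circularity
``4*pi*A/P^2``, shape parameter ``P^2/A``, aspect ratio, compactness,
roundness); the remaining two are the *irregularity* — the population
variance of the distances from every contour point to the shape's center of
mass — and its scale-free variant computed after dividing the distances by
their mean.  Circle-like buds score low irregularity, frilly open blooms
score high.

All operations take the filled :class:`~budvision.plates.InstanceMask`
and/or the traced :class:`~budvision.plates.Contour` of one instance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .plates import Contour, InstanceMask

#: canonical feature order and CSV column names
FEATURE_NAMES = (
    "perimeter",
    "area",
    "long_axis",
    "short_axis",
    "incircle_r",
    "excircle_r",
    "eq_diameter",
    "circularity",
    "shape_param",
    "aspect_ratio",
    "compactness",
    "roundness",
    "irregularity",
    "norm_irregularity",
)


@dataclass(frozen=True)
class MorphologyVector:
    """The 14 morphological descriptors of one bud, in canonical order."""

    perimeter: float
    area: float
    long_axis: float
    short_axis: float
    incircle_r: float
    excircle_r: float
    eq_diameter: float
    circularity: float
    shape_param: float
    aspect_ratio: float
    compactness: float
    roundness: float
    irregularity: float
    norm_irregularity: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def centroid(mask: InstanceMask) -> tuple[float, float]:
    """Center of mass of the filled region: mean of foreground pixel
    coordinates, returned as ``(x, y)`` in plate coordinates."""
    ys, xs = np.nonzero(mask.mask)
    if len(xs) == 0:
        raise ValueError("empty mask has no centroid")
    x0, y0 = mask.offset
    return (float(xs.mean()) + x0, float(ys.mean()) + y0)


def perimeter(c: Contour) -> float:
    """Summed Euclidean step lengths along the closed chain (1 or sqrt(2)
    per step for an 8-connected contour), including the closing edge."""
    pts = c.points.astype(float)
    diffs = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def principal_extents(
    c: Contour, mask: InstanceMask, center: tuple[float, float] | None = None
) -> tuple[float, float, np.ndarray]:
    """Long and short axis of an instance.

    Long axis: largest pairwise distance between contour points (computed on
    the convex hull, which contains the diametral pair).  Short axis: extent
    of the line through the center of mass perpendicular to the long-axis
    direction, measured between its two extreme intersections with the
    filled mask.

    Returns ``(long_axis, short_axis, unit long-axis direction)``.
    """
    pts = c.points.astype(float)
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:
        hp = pts
    d2 = cdist(hp, hp)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    long_axis = float(d2[i, j])
    if long_axis == 0.0:
        warnings.warn("degenerate contour: all points coincide")
        return 0.0, 0.0, np.array([1.0, 0.0])
    u = (hp[j] - hp[i]) / long_axis  # long-axis direction
    v = np.array([-u[1], u[0]])  # perpendicular
    if center is None:
        center = centroid(mask)
    cx, cy = center
    x0, y0 = mask.offset
    h, w = mask.mask.shape
    # sample the perpendicular line at sub-pixel steps, test mask membership
    tmax = np.hypot(h, w)
    ts = np.arange(-tmax, tmax + 0.25, 0.25)
    px = cx + ts * v[0] - x0
    py = cy + ts * v[1] - y0
    ix = np.rint(px).astype(int)
    iy = np.rint(py).astype(int)
    ok = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    hit = np.zeros_like(ts, dtype=bool)
    hit[ok] = mask.mask[iy[ok], ix[ok]]
    if not hit.any():
        warnings.warn("short axis line misses the mask; returning 0")
        return long_axis, 0.0, u
    t_hit = ts[hit]
    short_axis = float(t_hit.max() - t_hit.min())
    return long_axis, short_axis, u


def max_inscribed_circle(mask: InstanceMask) -> float:
    """Radius of the largest inscribed circle: maximum over foreground
    pixels of the exact Euclidean distance to the nearest background pixel."""
    padded = np.pad(mask.mask, 1)
    dist = ndimage.distance_transform_edt(padded)
    return float(dist.max())


def min_enclosing_circle(c: Contour | np.ndarray) -> float:
    """Radius of the minimal enclosing circle of the contour points."""
    pts = c.points if isinstance(c, Contour) else np.asarray(c, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    return float(shapely.minimum_bounding_radius(shapely.MultiPoint(pts)))


def radial_variance(
    c: Contour | np.ndarray, center: tuple[float, float]
) -> tuple[float, float]:
    """Irregularity and normalized irregularity of a contour.

    ``d_i`` are the distances from each contour point to the center of
    mass; irregularity is their population variance (px^2), the normalized
    variant is the population variance of ``d_i / mean(d_i)``
    (dimensionless, scale-free).
    """
    pts = c.points if isinstance(c, Contour) else np.asarray(c, dtype=float)
    if len(pts) < 4:
        raise ValueError("need at least 4 contour points")
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    mean = d.mean()
    if mean == 0:
        raise ValueError("mean contour distance is zero")
    return float(d.var()), float((d / mean).var())


def compute_morphology(mask: InstanceMask, c: Contour) -> MorphologyVector:
    """Assemble the full 14-descriptor vector for one instance.

    The area is the foreground pixel count; the area-equivalent diameter is
    the diameter of the disk of equal area, ``sqrt(4*A/pi)``; the ratio
    descriptors follow the classical definitions listed in the module
    docstring.  Raises ``ValueError`` if any descriptor is NaN.
    """
    area = float(mask.area)
    perim = perimeter(c)
    cen = centroid(mask)
    long_axis, short_axis, _ = principal_extents(c, mask, cen)
    rin = max_inscribed_circle(mask)
    rex = min_enclosing_circle(c)
    irr, nirr = radial_variance(c, cen)
    eq_d = float(np.sqrt(4.0 * area / np.pi))
    if short_axis <= 0:
        raise ValueError("degenerate instance: zero short axis")
    vec = MorphologyVector(
        perimeter=perim,
        area=area,
        long_axis=long_axis,
        short_axis=short_axis,
        incircle_r=rin,
        excircle_r=rex,
        eq_diameter=eq_d,
        circularity=4.0 * np.pi * area / perim**2,
        shape_param=perim**2 / area,
        aspect_ratio=long_axis / short_axis,
        compactness=eq_d / long_axis,
        roundness=rin / rex,
        irregularity=irr,
        norm_irregularity=nirr,
    )
    arr = vec.to_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite morphological descriptor")
    return vec
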