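"""Plate-image processing: denoising, thresholding, segmentation, contours,
fiducial detection and perspective rectification.

A *plate* is one acquired frame holding many dried flower buds: either a
16-bit grayscale transmittance image (dark silhouettes on a bright field,
``gel16`` mode) or an 8-bit RGB photograph of buds on white paper inside a
square sample area delimited by four printed corner fiducials (``phone8``
mode).  This module turns a plate into an ordered list of per-bud binary
masks, pixel-chain contours and color crops.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row; bounding boxes
are half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.transform import ProjectiveTransform, warp


class PlateError(ValueError):
    """Raised for invalid plate inputs or failed processing stages."""


@dataclass
class PlateImage:
    """One acquired or synthetic frame.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` uint16 for ``gel16`` mode, ``(H, W, 3)`` uint8 for
        ``phone8`` mode.
    mode : str
        ``"gel16"`` or ``"phone8"``.
    dpi : float, optional
        Pixel pitch metadata; informational only.
    """

    pixels: np.ndarray
    mode: str
    dpi: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("gel16", "phone8"):
            raise PlateError(f"unknown plate mode {self.mode!r}")
        p = np.asarray(self.pixels)
        if self.mode == "gel16" and p.ndim != 2:
            raise PlateError("gel16 plates must be single-channel")
        if self.mode == "phone8" and (p.ndim != 3 or p.shape[2] != 3):
            raise PlateError("phone8 plates must be HxWx3 RGB")
        if p.shape[0] < 32 or p.shape[1] < 32:
            raise PlateError("plate smaller than 32x32 pixels")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class InstanceMask:
    """One segmented bud: a filled binary mask cropped to its bounding box.

    ``offset`` locates the crop's top-left corner ``(x0, y0)`` in plate
    coordinates; ``index`` is the ordinal position within the plate's
    row-major instance ordering.
    """

    mask: np.ndarray
    offset: tuple[int, int]
    index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise PlateError("instance mask must be a nonempty 2-D binary grid")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1), half-open, in plate coordinates."""
        x0, y0 = self.offset
        h, w = self.mask.shape
        return (x0, y0, x0 + w, y0 + h)

    def to_plate(self, shape_hw: tuple[int, int]) -> np.ndarray:
        """Paste the cropped mask into a full-plate boolean grid."""
        full = np.zeros(shape_hw, dtype=bool)
        x0, y0 = self.offset
        h, w = self.mask.shape
        full[y0 : y0 + h, x0 : x0 + w] = self.mask
        return full


@dataclass
class Contour:
    """Closed 8-connected pixel chain of an instance's outer boundary.

    ``points`` is an ``(n, 2)`` integer array of ``(x, y)`` plate
    coordinates; the last point connects back to the first (the first point
    is not repeated).  Orientation is counter-clockwise in the standard
    image frame (y axis pointing down).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 4:
            raise PlateError("contour needs >= 4 (x, y) points")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# preprocessing


def median_denoise(img: PlateImage) -> PlateImage:
    """3x3 median filter with edge replication (gel-mode denoising step)."""
    out = ndimage.median_filter(img.pixels, size=3, mode="nearest")
    return PlateImage(out, img.mode, img.dpi)


def otsu_threshold(img: PlateImage | np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu threshold over a 256-bin histogram; dark side is foreground.

    The histogram spans the image's own min-max range (so 16-bit input is
    effectively rescaled to 256 levels first), and the returned threshold
    maximizes between-class variance.  The binary mask marks pixels at or
    below the threshold: in both acquisition modes the buds are darker than
    the background (backlit silhouettes / white paper).

    Returns ``(threshold, mask)``.  A phone-mode RGB plate is converted to
    luma grayscale first.
    """
    if isinstance(img, PlateImage):
        px = img.pixels
        if img.mode == "phone8":
            px = rgb2gray(px) * 255.0
    else:
        px = np.asarray(img)
        if px.ndim == 3:
            px = rgb2gray(px) * 255.0
    px = px.astype(np.float64)
    if np.ptp(px) == 0:
        raise PlateError("degenerate histogram: constant image")
    thr = float(threshold_otsu(px, nbins=256))
    return thr, px <= thr


_STRUCT8 = np.ones((3, 3), dtype=bool)


def segment_components(mask: np.ndarray, min_area: int = 64) -> list[InstanceMask]:
    """Split a binary mask into 8-connected components of area >= min_area.

    Components are returned in the plate's row-major reading order: they are
    grouped into rows by vertical bounding-box overlap (transitively), rows
    sorted top to bottom, and components within a row sorted by left edge.
    An empty result is not an error.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    slices = ndimage.find_objects(labels)
    comps = []
    for lab, (area, sl) in enumerate(zip(areas, slices), start=1):
        if area < min_area or sl is None:
            continue
        sub = labels[sl] == lab
        x0, y0 = sl[1].start, sl[0].start
        comps.append((y0, sl[0].stop, x0, sub))
    if not comps:
        return []
    comps.sort(key=lambda c: (c[0], c[2]))
    # group into rows by chained vertical overlap
    rows: list[list] = [[comps[0]]]
    row_y1 = comps[0][1]
    for c in comps[1:]:
        if c[0] < row_y1:
            rows[-1].append(c)
            row_y1 = max(row_y1, c[1])
        else:
            rows.append([c])
            row_y1 = c[1]
    ordered = []
    for row in rows:
        ordered.extend(sorted(row, key=lambda c: c[2]))
    return [
        InstanceMask(sub, (x0, y0), index=i)
        for i, (y0, _y1, x0, sub) in enumerate(ordered)
    ]


# ---------------------------------------------------------------------------
# contour tracing

# clockwise screen-order neighbour offsets (dr, dc), starting East
_DR = (0, 1, 1, 1, 0, -1, -1, -1)
_DC = (1, 1, 0, -1, -1, -1, 0, 1)


def extract_contour(inst: InstanceMask) -> Contour:
    """Outer boundary of an instance by Moore border following.

    Returns the closed 8-connected chain of boundary pixels in plate
    coordinates, oriented counter-clockwise (holes are ignored; only the
    outer border is traced).  Masks of 1-3 pixels have no meaningful closed
    chain and raise ``PlateError``.
    """
    if inst.area <= 3:
        raise PlateError("contour degenerate: instance has fewer than 4 pixels")
    m = np.pad(inst.mask, 1)
    rows, cols = np.nonzero(m)
    sr, sc = int(rows[0]), int(cols[0])  # uppermost-leftmost foreground pixel

    # walk (pixel, backtrack-direction) states; the transition is
    # deterministic, so the walk enters a cycle — that cycle is the closed
    # outer boundary (any transient prefix is trimmed)
    chain: list[tuple[int, int]] = []
    seen: dict[tuple, int] = {}
    cur = (sr, sc)
    back = 4  # direction of the background pixel we entered from (West)
    while (cur, back) not in seen:
        seen[(cur, back)] = len(chain)
        chain.append(cur)
        found = None
        for i in range(1, 9):
            d = (back + i) % 8
            r, c = cur[0] + _DR[d], cur[1] + _DC[d]
            if m[r, c]:
                found = d
                prev = (back + i - 1) % 8
                break
        if found is None:  # isolated pixel (area>3 prevents this, but be safe)
            break
        nxt = (cur[0] + _DR[found], cur[1] + _DC[found])
        # backtrack for the next scan: direction from nxt towards the last
        # background pixel checked before entering it
        bgr, bgc = cur[0] + _DR[prev], cur[1] + _DC[prev]
        back = _dir_index(nxt, (bgr, bgc))
        cur = nxt
    if found is not None:
        chain = chain[seen[(cur, back)] :]

    x0, y0 = inst.offset
    pts = np.array([(c - 1 + x0, r - 1 + y0) for r, c in chain], dtype=int)
    if len(pts) < 4:
        raise PlateError("contour degenerate: fewer than 4 boundary points")
    # enforce counter-clockwise orientation (negative shoelace in y-down frame)
    x, y = pts[:, 0].astype(float), pts[:, 1].astype(float)
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    if area2 > 0:
        pts = pts[::-1]
    return Contour(pts)


def _dir_index(frm: tuple[int, int], to: tuple[int, int]) -> int:
    dr, dc = to[0] - frm[0], to[1] - frm[1]
    for i in range(8):
        if _DR[i] == dr and _DC[i] == dc:
            return i
    raise PlateError("non-adjacent pixels in contour trace")  # pragma: no cover


def fill_contour(contour: Contour) -> InstanceMask:
    """Fill a closed pixel chain back into a solid instance mask.

    Inverse of :func:`extract_contour` for simply connected masks: boundary
    pixels plus every pixel not reachable from outside through 4-connected
    background.
    """
    pts = contour.points
    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    w = pts[:, 0].max() - x0 + 1
    h = pts[:, 1].max() - y0 + 1
    grid = np.zeros((h + 2, w + 2), dtype=bool)
    grid[pts[:, 1] - y0 + 1, pts[:, 0] - x0 + 1] = True
    outside = np.zeros_like(grid)
    four = ndimage.generate_binary_structure(2, 1)
    lab, _ = ndimage.label(~grid, structure=four)
    outside = lab == lab[0, 0]
    filled = ~outside
    return InstanceMask(filled[1:-1, 1:-1], (int(x0), int(y0)))


# ---------------------------------------------------------------------------
# phone-mode rectification


def detect_finder_patterns(img: PlateImage) -> np.ndarray:
    """Locate the four corner fiducials of the square sample area.

    The fiducials are QR-like concentric filled squares (dark ring around a
    dark core); their centers sit exactly on the corners of the sample
    square.  Candidates are dark connected components containing a hole
    (Euler number <= 0) whose center coincides with a separate dark core
    component; the corner estimate is the sub-pixel mean of ring and core
    centroids.

    Returns a ``(4, 2)`` float array of ``(x, y)`` corners ordered TL, TR,
    BR, BL.  Raises ``PlateError`` reporting the count when fewer or more
    than four fiducials are found.
    """
    if img.mode != "phone8":
        raise PlateError("finder patterns exist only on phone8 plates")
    _, dark = otsu_threshold(img)
    labels, n = ndimage.label(dark, structure=_STRUCT8)
    if n == 0:
        raise PlateError("0 finder patterns detected (expected 4)")
    from skimage.measure import regionprops

    props = regionprops(labels)
    centroids = {p.label: np.array([p.centroid[1], p.centroid[0]]) for p in props}
    H, W = dark.shape
    corners = []
    for p in props:
        # outer ring: one large hole (euler 0, filled area much larger than
        # the ring itself), square-ish, away from the frame edge (the dark
        # surround beyond the paper touches the frame; fiducials don't)
        if p.euler_number != 0 or p.area < 64:
            continue
        if p.bbox[0] == 0 or p.bbox[1] == 0 or p.bbox[2] == H or p.bbox[3] == W:
            continue
        bh = p.bbox[2] - p.bbox[0]
        bw = p.bbox[3] - p.bbox[1]
        if not (0.5 <= bh / bw <= 2.0) or p.area_filled < 1.5 * p.area:
            continue
        ring_c = centroids[p.label]
        tol = max(2.5, 0.15 * np.sqrt(p.area))
        core = None
        for q in props:
            if q.label == p.label:
                continue
            if not (0.2 * p.area <= q.area <= p.area):
                continue
            qc = centroids[q.label]
            inside = (
                p.bbox[0] < q.centroid[0] < p.bbox[2]
                and p.bbox[1] < q.centroid[1] < p.bbox[3]
            )
            if inside and np.linalg.norm(qc - ring_c) < tol:
                core = qc
                break
        if core is not None:
            corners.append(0.5 * (ring_c + core))
    if len(corners) != 4:
        raise PlateError(
            f"{len(corners)} finder patterns detected (expected 4)"
        )
    return _order_corners(np.array(corners))


def _order_corners(pts: np.ndarray) -> np.ndarray:
    """Order four points TL, TR, BR, BL by coordinate sums/differences."""
    s = pts.sum(axis=1)
    d = pts[:, 0] - pts[:, 1]
    tl = pts[np.argmin(s)]
    br = pts[np.argmax(s)]
    tr = pts[np.argmax(d)]
    bl = pts[np.argmin(d)]
    return np.array([tl, tr, br, bl], dtype=float)


def correct_perspective(
    img: PlateImage, corners: np.ndarray, out_px: int
) -> PlateImage:
    """Rectify the square sample area delimited by four corners.

    Solves the homography mapping the corners (TL, TR, BR, BL) onto the
    corners of an ``out_px x out_px`` square and resamples the plate with
    bilinear interpolation.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise PlateError("need exactly four (x, y) corners")
    # degenerate if any three corners are (nearly) collinear
    for i in range(4):
        a, b, c = np.delete(corners, i, axis=0)
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) < 1e-6:
            raise PlateError("degenerate corners: three points are collinear")
    dst = np.array(
        [[0, 0], [out_px - 1, 0], [out_px - 1, out_px - 1], [0, out_px - 1]],
        dtype=float,
    )
    tf = ProjectiveTransform.from_estimate(dst, corners)  # output -> input
    if not tf:
        raise PlateError("homography estimation failed")
    px = img.pixels
    was_int = np.issubdtype(px.dtype, np.integer)
    out = warp(
        px.astype(float),
        tf,
        output_shape=(out_px, out_px) + px.shape[2:],
        order=1,
        mode="edge",
        preserve_range=True,
    )
    if was_int:
        out = np.clip(np.rint(out), 0, np.iinfo(px.dtype).max).astype(px.dtype)
    return PlateImage(out, img.mode, img.dpi)


def crop_instances(
    img: PlateImage, instances: list[InstanceMask], margin_px: int = 0
) -> list[np.ndarray]:
    """Bounding-box + margin crops of each instance from a (color) plate.

    Background pixels are retained (no masking); crops are clipped at the
    image edges, order follows the instance list.
    """
    H, W = img.pixels.shape[:2]
    crops = []
    for inst in instances:
        x0, y0, x1, y1 = inst.bbox
        x0 = max(0, x0 - margin_px)
        y0 = max(0, y0 - margin_px)
        x1 = min(W, x1 + margin_px)
        y1 = min(H, y1 + margin_px)
        crops.append(img.pixels[y0:y1, x0:x1].copy())
    return crops


def segment_plate(
    img: PlateImage, min_area: int = 64, denoise: bool = True
) -> list[InstanceMask]:
    """Full segmentation of one plate: denoise, threshold, split.

    Gel plates are median-filtered first; phone plates (already rectified)
    go straight to grayscale thresholding.
    """
    work = img
    if img.mode == "gel16" and denoise:
        work = median_denoise(img)
    _, mask = otsu_threshold(work)
    return segment_components(mask, min_area=min_area)
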