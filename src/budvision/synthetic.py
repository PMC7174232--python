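"""Synthetic plate-image generator with analytic ground truth.

Emulates the two acquisition setups used to photograph dried chrysanthemum
tea buds:

``gel16``
    a backlit transmittance imager — dark filled silhouettes on a bright
    16-bit grayscale field, many buds per frame in an organized grid.
``phone8``
    a hand-held color photograph — textured colored buds on white paper
    inside a 10x10-style square sample area delimited by four QR-like
    corner fiducials, degraded by an illumination gradient, a soft cast
    shadow and a projective (perspective) warp.

Every rendered instance carries its ground-truth mask, class label,
flowering-stage label, generating :class:`~budvision.shapes.ShapeSpec`, and
— for canonical circle/ellipse/square shapes — the closed-form morphology.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform, warp

from .morphology import MorphologyVector
from .plates import PlateImage
from .shapes import ShapeSpec, analytic_morphology, rasterize_cropped


class PlacementError(ValueError):
    """A sampled shape does not fit its grid cell."""


@dataclass(frozen=True)
class ClassProfile:
    """Sampling distribution of one tea product class.

    Ranges are uniform ``(low, high)`` over the corresponding
    :class:`~budvision.shapes.ShapeSpec` parameter.  ``color_mean`` and
    ``texture_strength`` only matter in phone mode; gel mode discards all
    color and texture by construction.
    """

    name: str
    stage: str  # "fetal" or "bloom"
    scale_px: tuple[float, float]
    elongation: tuple[float, float] = (1.0, 1.3)
    frill_amplitude: tuple[float, float] = (0.03, 0.1)
    frill_count: tuple[int, int] = (6, 10)
    family: str = "bud"
    color_mean: tuple[float, float, float] = (180.0, 160.0, 100.0)
    color_jitter: float = 10.0
    texture_strength: float = 0.07
    perturb: float = 0.02

    def __post_init__(self) -> None:
        if self.stage not in ("fetal", "bloom"):
            raise ValueError("stage must be 'fetal' or 'bloom'")
        for rng_field in ("scale_px", "elongation", "frill_amplitude"):
            lo, hi = getattr(self, rng_field)
            if hi < lo:
                raise ValueError(f"degenerate sampling range for {rng_field}")

    def sample_shape(
        self, rng: np.random.Generator, center: tuple[float, float] = (0.0, 0.0)
    ) -> ShapeSpec:
        scale = rng.uniform(*self.scale_px)
        elong = rng.uniform(*self.elongation)
        amp = rng.uniform(*self.frill_amplitude)
        k = int(rng.integers(self.frill_count[0], self.frill_count[1] + 1))
        rot = rng.uniform(0.0, 2 * np.pi)
        extra = ()
        if self.family == "bud" and self.perturb > 0:
            extra = tuple(
                (order, rng.uniform(-self.perturb, self.perturb),
                 rng.uniform(-self.perturb, self.perturb))
                for order in (2, 3)
            )
        return ShapeSpec(
            family=self.family,
            scale_px=scale,
            elongation=elong,
            frill_amplitude=amp if self.family == "bud" else 0.0,
            frill_count=k if self.family == "bud" else 0,
            rotation_rad=rot,
            center=center,
            fourier_extra=extra,
        )


@dataclass
class PlateSpec:
    """Geometry, photometry and degradation settings of one rendered plate."""

    mode: str
    grid_rows: int = 3
    grid_cols: int = 3
    image_size: tuple[int, int] = (512, 512)  # (H, W)
    background_level: float | None = None  # gel: 58000, phone paper: 245
    foreground_level: float = 6000.0  # gel silhouette level
    noise_sigma: float = 0.0
    salt_pepper: float = 0.0
    illumination_amplitude: float = 0.0  # phone only
    shadow_strength: float = 0.0  # phone only
    homography: np.ndarray | None = None  # phone only; maps rectified -> photo
    finder_size_px: int = 41  # phone fiducial outer size (odd => exact center)
    sample_px: int | None = None  # side of the square sample area
    seed: int = 0
    class_sequence: list[int] | None = None  # per-cell class index (None = skip)

    def __post_init__(self) -> None:
        if self.mode not in ("gel16", "phone8"):
            raise ValueError(f"unknown plate mode {self.mode!r}")
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must hold at least one instance")
        if self.background_level is None:
            self.background_level = 58000.0 if self.mode == "gel16" else 245.0
        if self.homography is not None:
            H = np.asarray(self.homography, dtype=float)
            if H.shape != (3, 3) or abs(np.linalg.det(H)) < 1e-12:
                raise ValueError("homography must be an invertible 3x3 matrix")
            self.homography = H


@dataclass
class GroundTruthInstance:
    """One rendered bud with full ground truth.

    ``mask``/``offset`` are in plate coordinates for gel plates and in
    rectified sample-area coordinates (origin at the TL fiducial center)
    for phone plates, so morphology targets are warp-independent.
    ``analytic`` holds the closed-form morphology for canonical shape
    families and is None for bud silhouettes.
    """

    class_name: str
    stage: str
    shape: ShapeSpec
    mask: np.ndarray
    offset: tuple[int, int]
    index: int
    analytic: MorphologyVector | None = None

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return (float(xs.mean()) + self.offset[0], float(ys.mean()) + self.offset[1])

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _grid_centers(
    region_origin: tuple[float, float],
    region_size: tuple[float, float],
    rows: int,
    cols: int,
) -> tuple[list[tuple[float, float]], float, float]:
    ox, oy = region_origin
    rw, rh = region_size
    cw, ch = rw / cols, rh / rows
    centers = [
        (ox + (c + 0.5) * cw, oy + (r + 0.5) * ch)
        for r in range(rows)
        for c in range(cols)
    ]
    return centers, cw, ch


def _place_instances(
    classes: list[ClassProfile],
    plate: PlateSpec,
    rng: np.random.Generator,
    region_origin: tuple[float, float],
    region_size: tuple[float, float],
    gt_origin: tuple[float, float] = (0.0, 0.0),
) -> list[GroundTruthInstance]:
    """Sample and rasterize one shape per occupied grid cell (row-major)."""
    if not classes:
        raise ValueError("class list is empty")
    cells = plate.grid_rows * plate.grid_cols
    seq = plate.class_sequence
    if seq is None:
        seq = [i % len(classes) for i in range(cells)]
    if len(seq) > cells:
        raise PlacementError(f"{len(seq)} instances requested for {cells} cells")
    centers, cw, ch = _grid_centers(
        region_origin, region_size, plate.grid_rows, plate.grid_cols
    )
    limit = min(cw, ch) / 2.0 - 2.0
    out: list[GroundTruthInstance] = []
    idx = 0
    for cell, ci in enumerate(seq):
        if ci is None:
            continue
        profile = classes[ci]
        spec = profile.sample_shape(rng)
        if spec.max_radius > limit:
            raise PlacementError(
                f"class {profile.name!r}: shape radius {spec.max_radius:.1f}px "
                f"exceeds grid-cell budget {limit:.1f}px "
                f"({plate.grid_rows}x{plate.grid_cols} grid on {plate.image_size})"
            )
        # jitter small enough that buds sharing a grid row always overlap
        # vertically (keeps the plate's row-major reading order well defined)
        slack = max(0.0, min(0.4 * (limit - spec.max_radius), 0.45 * spec.scale_px))
        jx, jy = rng.uniform(-slack, slack, size=2)
        cx, cy = centers[cell]
        spec = dataclasses.replace(spec, center=(cx + jx, cy + jy))
        mask, (x0, y0) = rasterize_cropped(spec)
        ana = analytic_morphology(spec) if spec.family != "bud" else None
        out.append(
            GroundTruthInstance(
                class_name=profile.name,
                stage=profile.stage,
                shape=spec,
                mask=mask,
                offset=(x0 - int(gt_origin[0]), y0 - int(gt_origin[1])),
                index=idx,
                analytic=ana,
            )
        )
        idx += 1
    return out


# ---------------------------------------------------------------------------
# gel mode


def render_gel_plate(
    classes: list[ClassProfile], plate: PlateSpec
) -> tuple[PlateImage, list[GroundTruthInstance]]:
    """Render a 16-bit transmittance plate: dark buds on a bright field.

    Instances occupy a non-overlapping grid in row-major order; the ground
    truth list is ordered identically.  Identical seeds give bit-identical
    images.
    """
    if plate.mode != "gel16":
        raise ValueError("render_gel_plate requires a gel16 PlateSpec")
    rng = np.random.default_rng(plate.seed)
    H, W = plate.image_size
    gts = _place_instances(classes, plate, rng, (0.0, 0.0), (float(W), float(H)))
    canvas = np.full((H, W), float(plate.background_level))
    for gt in gts:
        x0, y0 = gt.offset
        h, w = gt.mask.shape
        region = canvas[y0 : y0 + h, x0 : x0 + w]
        region[gt.mask] = plate.foreground_level
    if plate.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, plate.noise_sigma, canvas.shape)
    if plate.salt_pepper > 0:
        n_sp = int(plate.salt_pepper * canvas.size)
        ys = rng.integers(0, H, n_sp)
        xs = rng.integers(0, W, n_sp)
        canvas[ys, xs] = np.where(rng.random(n_sp) < 0.5, 0.0, 65535.0)
    img = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    return PlateImage(img, "gel16"), gts


# ---------------------------------------------------------------------------
# phone mode


def _draw_fiducial(canvas: np.ndarray, cx: int, cy: int, size: int) -> None:
    """QR-like concentric-square fiducial centered exactly on (cx, cy)."""
    h1 = size // 2
    h2 = max(2, int(round(size * 5 / 14)))
    h3 = max(1, int(round(size * 3 / 14)))
    canvas[cy - h1 : cy + h1 + 1, cx - h1 : cx + h1 + 1] = (15.0, 15.0, 15.0)
    canvas[cy - h2 : cy + h2 + 1, cx - h2 : cx + h2 + 1] = (250.0, 250.0, 250.0)
    canvas[cy - h3 : cy + h3 + 1, cx - h3 : cx + h3 + 1] = (15.0, 15.0, 15.0)


def sample_area_geometry(plate: PlateSpec) -> tuple[int, int, int]:
    """Sample-square origin ``(ox, oy)`` and side ``S`` for a phone plate."""
    H, W = plate.image_size
    f = plate.finder_size_px
    S = plate.sample_px or (min(H, W) - 2 * (f + 6))
    ox = (W - S) // 2
    oy = (H - S) // 2
    return ox, oy, S


def render_phone_plate(
    classes: list[ClassProfile], plate: PlateSpec
) -> tuple[PlateImage, list[GroundTruthInstance]]:
    """Render an 8-bit RGB phone photograph of the sample sheet.

    White paper, four corner fiducials at the corners of the square sample
    area, colored textured buds inside, then illumination gradient, cast
    shadow and projective warp.  Ground truth is recorded in rectified
    coordinates with origin at the TL fiducial center.
    """
    if plate.mode != "phone8":
        raise ValueError("render_phone_plate requires a phone8 PlateSpec")
    rng = np.random.default_rng(plate.seed)
    H, W = plate.image_size
    ox, oy, S = sample_area_geometry(plate)
    f = plate.finder_size_px
    canvas = np.full((H, W, 3), float(plate.background_level))

    inner = (ox + f + 2.0, oy + f + 2.0)
    inner_size = (float(S - 2 * (f + 2)), float(S - 2 * (f + 2)))
    gts = _place_instances(classes, plate, rng, inner, inner_size, gt_origin=(ox, oy))
    for gt in gts:
        x0, y0 = gt.offset[0] + ox, gt.offset[1] + oy
        h, w = gt.mask.shape
        profile = next(c for c in classes if c.name == gt.class_name)
        color = np.clip(
            np.asarray(profile.color_mean)
            + rng.normal(0.0, profile.color_jitter, 3),
            0,
            235,
        )
        tex = gaussian_filter(rng.standard_normal((h, w)), 3.0)
        span = np.abs(tex).max() or 1.0
        factor = 1.0 + profile.texture_strength * tex / span
        region = canvas[y0 : y0 + h, x0 : x0 + w]
        region[gt.mask] = color[None, :] * factor[gt.mask, None]

    for cx, cy in ((ox, oy), (ox + S, oy), (ox + S, oy + S), (ox, oy + S)):
        _draw_fiducial(canvas, cx, cy, f)

    if plate.illumination_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        X, Y = np.meshgrid(np.arange(W), np.arange(H))
        ramp = (X / W - 0.5) * np.cos(theta) + (Y / H - 0.5) * np.sin(theta)
        canvas *= (1.0 + plate.illumination_amplitude * ramp)[:, :, None]
    if plate.shadow_strength > 0:
        px = rng.uniform(ox, ox + S)
        py = rng.uniform(oy, oy + S)
        X, Y = np.meshgrid(np.arange(W), np.arange(H))
        G = np.exp(-((X - px) ** 2 + (Y - py) ** 2) / (2 * (S / 3.0) ** 2))
        canvas *= (1.0 - plate.shadow_strength * G)[:, :, None]
    if plate.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, plate.noise_sigma, canvas.shape)

    if plate.homography is not None:
        Hm = plate.homography
        corners = np.array(
            [[ox, oy], [ox + S, oy], [ox + S, oy + S], [ox, oy + S]], dtype=float
        )
        mapped = _apply_homography(Hm, corners)
        pad = f / 2 + 2
        if (
            mapped[:, 0].min() < pad
            or mapped[:, 1].min() < pad
            or mapped[:, 0].max() > W - pad
            or mapped[:, 1].max() > H - pad
        ):
            raise ValueError("homography maps the sample area outside the frame")
        tf = ProjectiveTransform(matrix=np.linalg.inv(Hm))
        canvas = warp(
            canvas, tf, output_shape=(H, W, 3), order=1, cval=60.0,
            preserve_range=True,
        )
    img = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return PlateImage(img, "phone8"), gts


def _apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    homo = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    return homo[:, :2] / homo[:, 2:3]


def random_homography(
    rng: np.random.Generator,
    image_size: tuple[int, int],
    strength: float = 0.03,
) -> np.ndarray:
    """Mild random projective warp (rectified -> photo coordinates)."""
    H, W = image_size
    src = np.array([[0, 0], [W, 0], [W, H], [0, H]], dtype=float)
    amp = strength * min(H, W)
    dst = src + rng.uniform(-amp, amp, size=(4, 2))
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf:  # pragma: no cover - 4-point estimate
        raise ValueError("degenerate corner perturbation")
    return tf.params


# ---------------------------------------------------------------------------
# benchmark datasets


@dataclass
class BenchmarkDataset:
    """Aligned gel- and phone-mode renderings of one labeled instance set.

    ``type_labels``/``stage_labels`` follow the shuffled instance order;
    ``locator[i] = (plate_index, within_plate_index)`` maps instance ``i``
    into each mode's plate list (the class sequence is identical across
    modes; the sampled shapes are mode-specific)."""

    profiles: list[ClassProfile]
    type_labels: np.ndarray
    stage_labels: np.ndarray
    locator: list[tuple[int, int]]
    gel: list[tuple[PlateImage, list[GroundTruthInstance]]] | None = None
    phone: list[tuple[PlateImage, list[GroundTruthInstance]]] | None = None
    phone_sample_px: int | None = None  # true sample-square side, pixels

    @property
    def n_instances(self) -> int:
        return len(self.type_labels)


def make_benchmark_dataset(
    classes: list[ClassProfile],
    n_per_class: int,
    seed: int,
    modes: tuple[str, ...] = ("gel16", "phone8"),
    grid: tuple[int, int] = (3, 3),
    image_size: tuple[int, int] = (512, 512),
    phone_image_size: tuple[int, int] = (672, 672),
    gel_noise_sigma: float = 600.0,
    gel_salt_pepper: float = 5e-4,
    phone_illumination: float = 0.08,
    phone_shadow: float = 0.10,
    phone_noise_sigma: float = 2.0,
    warp_phone: bool = True,
) -> BenchmarkDataset:
    """Render enough plates to yield exactly ``n_per_class`` instances per
    class in each requested mode, with type and stage labels."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(classes)), n_per_class)
    rng.shuffle(order)
    rows, cols = grid
    per_plate = rows * cols
    chunks = [order[i : i + per_plate] for i in range(0, len(order), per_plate)]
    locator = [
        (pi, j) for pi, chunk in enumerate(chunks) for j in range(len(chunk))
    ]
    plate_seeds = rng.integers(0, 2**31 - 1, size=(len(modes), len(chunks)))

    ds = BenchmarkDataset(
        profiles=list(classes),
        type_labels=np.array([classes[i].name for i in order]),
        stage_labels=np.array([classes[i].stage for i in order]),
        locator=locator,
    )
    for mi, mode in enumerate(modes):
        plates = []
        for pi, chunk in enumerate(chunks):
            if mode == "gel16":
                spec = PlateSpec(
                    mode="gel16",
                    grid_rows=rows,
                    grid_cols=cols,
                    image_size=image_size,
                    noise_sigma=gel_noise_sigma,
                    salt_pepper=gel_salt_pepper,
                    seed=int(plate_seeds[mi, pi]),
                    class_sequence=list(chunk),
                )
                plates.append(render_gel_plate(classes, spec))
            else:
                sub = np.random.default_rng(int(plate_seeds[mi, pi]))
                Hm = (
                    random_homography(sub, phone_image_size, strength=0.03)
                    if warp_phone
                    else None
                )
                spec = PlateSpec(
                    mode="phone8",
                    grid_rows=rows,
                    grid_cols=cols,
                    image_size=phone_image_size,
                    illumination_amplitude=phone_illumination,
                    shadow_strength=phone_shadow,
                    noise_sigma=phone_noise_sigma,
                    homography=Hm,
                    seed=int(plate_seeds[mi, pi]),
                    class_sequence=list(chunk),
                )
                plates.append(render_phone_plate(classes, spec))
                ds.phone_sample_px = sample_area_geometry(spec)[2]
        if mode == "gel16":
            ds.gel = plates
        else:
            ds.phone = plates
    return ds


# ---------------------------------------------------------------------------
# study-condition class profiles

#: Seven commercial tea products: three harvested in full bloom, four as
#: tight pre-bloom ("fetal") buds.  Sizes follow the qualitative ordering
#: reported for the real products at desk scale (the bloom teas, HG above
#: all, are the largest; KM and HJ the smallest), colors approximate the
#: dried petals.
DEFAULT_CLASS_PROFILES: list[ClassProfile] = [
    ClassProfile("HB", "bloom", (20, 27), (1.25, 1.6), (0.12, 0.22), (8, 12),
                 color_mean=(195, 190, 150)),
    ClassProfile("HG", "bloom", (28, 36), (1.2, 1.5), (0.15, 0.25), (8, 13),
                 color_mean=(210, 175, 75)),
    ClassProfile("KX", "bloom", (15, 20), (1.2, 1.55), (0.12, 0.20), (7, 11),
                 color_mean=(175, 115, 45)),
    ClassProfile("HT", "fetal", (14, 19), (1.1, 1.35), (0.04, 0.10), (6, 10),
                 color_mean=(185, 190, 140)),
    ClassProfile("KM", "fetal", (10, 14), (1.0, 1.25), (0.02, 0.08), (6, 9),
                 color_mean=(200, 150, 60)),
    ClassProfile("HJ", "fetal", (9, 13), (1.15, 1.5), (0.05, 0.12), (6, 10),
                 color_mean=(215, 185, 100)),
    ClassProfile("DT", "fetal", (13, 17), (1.1, 1.4), (0.03, 0.09), (6, 9),
                 color_mean=(170, 170, 110)),
]


def stage_contrast_profiles() -> list[ClassProfile]:
    """Two classes separated cleanly by size: a tight fetal-like bud and a
    large open bloom-like bud (disjoint scale ranges)."""
    return [
        ClassProfile("fetal-like", "fetal", (10, 14), (1.0, 1.3), (0.02, 0.08),
                     (6, 9), color_mean=(200, 160, 80)),
        ClassProfile("bloom-like", "bloom", (24, 32), (1.2, 1.6), (0.12, 0.25),
                     (8, 12), color_mean=(200, 190, 140)),
    ]


#: Well-separated hues at near-equal luma (so thresholding treats every
#: class alike) for the color-only contrast experiment.
_COLOR_WHEEL = (
    (210, 90, 80), (220, 130, 30), (160, 150, 40), (80, 170, 80),
    (50, 160, 160), (90, 120, 210), (170, 90, 190),
)


def color_only_profiles(n_classes: int = 7) -> list[ClassProfile]:
    """Classes sharing one shape distribution and differing only in color.

    Shape features cannot separate these by construction; color can.  Stage
    labels alternate bloom/fetal so both tasks remain defined."""
    if not 2 <= n_classes <= len(_COLOR_WHEEL):
        raise ValueError(f"n_classes must be in [2, {len(_COLOR_WHEEL)}]")
    shared = dict(
        scale_px=(14, 19), elongation=(1.1, 1.4),
        frill_amplitude=(0.05, 0.12), frill_count=(6, 10),
    )
    return [
        ClassProfile(
            f"C{i+1}", "bloom" if i < 3 else "fetal",
            color_mean=_COLOR_WHEEL[i], **shared,
        )
        for i in range(n_classes)
    ]


# ---------------------------------------------------------------------------
# plate persistence (text-free binary image formats written on demand only)


def save_plate(
    path: str | Path,
    plate: PlateImage,
    gts: list[GroundTruthInstance] | None = None,
) -> None:
    """Write a plate (16-bit TIFF / 8-bit PNG) plus a JSON ground-truth
    sidecar holding labels and shape specs (masks are regenerable)."""
    path = Path(path)
    if plate.mode == "gel16":
        import tifffile

        tifffile.imwrite(path.with_suffix(".tiff"), plate.pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path.with_suffix(".png"), plate.pixels)
    if gts is not None:
        side = [
            {
                "class_name": g.class_name,
                "stage": g.stage,
                "index": g.index,
                "offset": list(g.offset),
                "shape": {
                    "family": g.shape.family,
                    "scale_px": g.shape.scale_px,
                    "elongation": g.shape.elongation,
                    "frill_amplitude": g.shape.frill_amplitude,
                    "frill_count": g.shape.frill_count,
                    "rotation_rad": g.shape.rotation_rad,
                    "center": list(g.shape.center),
                    "fourier_extra": [list(t) for t in g.shape.fourier_extra],
                },
            }
            for g in gts
        ]
        path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_plate(path: str | Path, mode: str) -> PlateImage:
    """Read a plate image written by :func:`save_plate`."""
    path = Path(path)
    if mode == "gel16":
        import tifffile

        return PlateImage(tifffile.imread(path), "gel16")
    import imageio.v3 as iio

    return PlateImage(iio.imread(path)[..., :3], "phone8")
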