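"""Shared fixtures: canonical rasterized shapes and random blob masks."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from budvision.plates import Contour, InstanceMask, extract_contour
from budvision.shapes import ShapeSpec, rasterize_cropped


def instance_from_spec(spec: ShapeSpec) -> tuple[InstanceMask, Contour]:
    mask, offset = rasterize_cropped(spec)
    inst = InstanceMask(mask, offset)
    return inst, extract_contour(inst)


@pytest.fixture(scope="session")
def disk80():
    return instance_from_spec(ShapeSpec("circle", 80.0, center=(100.0, 100.0)))


@pytest.fixture(scope="session")
def square100():
    # half-side 50 => side 100
    return instance_from_spec(ShapeSpec("square", 50.0, center=(80.0, 80.0)))


@pytest.fixture(scope="session")
def ellipse_2to1():
    # semi-minor 40, elongation 2 => semi-major 80
    return instance_from_spec(
        ShapeSpec("ellipse", 40.0, elongation=2.0, center=(120.0, 120.0))
    )


def random_blob(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A fat, simply connected random mask: threshold smoothed noise, keep
    the largest component, fill its holes."""
    while True:
        field = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 8)
        mask = field > np.quantile(field, 0.7)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        areas = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + np.argmax(areas))
        mask = ndimage.binary_fill_holes(mask)
        if mask.sum() >= 20:
            return mask


@pytest.fixture(scope="session")
def blob_instances():
    rng = np.random.default_rng(42)
    out = []
    for _ in range(30):
        m = random_blob(rng)
        ys, xs = np.nonzero(m)
        crop = m[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
        out.append(InstanceMask(crop, (int(xs.min()), int(ys.min()))))
    return out
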