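"""The 14 contour descriptors against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from budvision.morphology import (
    FEATURE_NAMES,
    centroid,
    compute_morphology,
    max_inscribed_circle,
    min_enclosing_circle,
    perimeter,
    principal_extents,
    radial_variance,
)
from budvision.plates import Contour, InstanceMask, extract_contour
from budvision.shapes import ShapeSpec

from .conftest import instance_from_spec


# --- independent oracles ---------------------------------------------------


def brute_incircle(mask: InstanceMask) -> float:
    """Max over foreground pixels of min distance to any background pixel
    (background padded one ring around the crop)."""
    m = np.pad(mask.mask, 1)
    fg = np.argwhere(m)
    bg = np.argwhere(~m)
    return cdist(fg, bg).min(axis=1).max()


def brute_excircle(pts: np.ndarray) -> float:
    """Smallest covering circle by enumerating all pair and triple
    candidates (O(n^3)); exact for any point set."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    best = np.inf
    # pairs: diameter circles
    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2
            r = np.linalg.norm(pts[i] - pts[j]) / 2
            if r < best and np.linalg.norm(pts - c, axis=1).max() <= r + 1e-9:
                best = r
    # triples: circumcircles
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c3 = pts[i], pts[j], pts[k]
                d = 2 * (a[0] * (b[1] - c3[1]) + b[0] * (c3[1] - a[1]) + c3[0] * (a[1] - b[1]))
                if abs(d) < 1e-12:
                    continue
                ux = ((a @ a) * (b[1] - c3[1]) + (b @ b) * (c3[1] - a[1]) + (c3 @ c3) * (a[1] - b[1])) / d
                uy = ((a @ a) * (c3[0] - b[0]) + (b @ b) * (a[0] - c3[0]) + (c3 @ c3) * (b[0] - a[0])) / d
                cc = np.array([ux, uy])
                r = np.linalg.norm(a - cc)
                if r < best and np.linalg.norm(pts - cc, axis=1).max() <= r + 1e-9:
                    best = r
    return best


# --- tests -----------------------------------------------------------------


class TestCentroid:
    def test_centered_disk(self, disk80):
        inst, _ = disk80
        cx, cy = centroid(inst)
        assert cx == pytest.approx(100.0, abs=0.5)
        assert cy == pytest.approx(100.0, abs=0.5)

    def test_single_pixel(self):
        m = np.zeros((3, 3), bool)
        m[1, 2] = True
        assert centroid(InstanceMask(m, (10, 20))) == (12.0, 21.0)

    def test_l_shape_matches_enumeration(self):
        m = np.zeros((6, 6), bool)
        m[:, 0] = True
        m[5, :] = True
        inst = InstanceMask(m, (3, 4))
        ys, xs = np.nonzero(m)
        assert centroid(inst) == (xs.mean() + 3, ys.mean() + 4)


class TestPerimeter:
    def test_square_chain_is_36(self):
        inst = InstanceMask(np.ones((10, 10), bool), (0, 0))
        assert perimeter(extract_contour(inst)) == pytest.approx(36.0)

    def test_disk_r100_within_6pct_of_circumference(self):
        inst, c = instance_from_spec(ShapeSpec("circle", 100.0, center=(120.0, 120.0)))
        assert perimeter(c) == pytest.approx(2 * np.pi * 100, rel=0.06)

    def test_reversal_invariant(self, blob_instances):
        c = extract_contour(blob_instances[0])
        rev = Contour(c.points[::-1])
        assert perimeter(c) == pytest.approx(perimeter(rev))


class TestPrincipalExtents:
    def test_ellipse_2to1_axes(self, ellipse_2to1):
        inst, c = ellipse_2to1
        long_ax, short_ax, _ = principal_extents(c, inst)
        assert long_ax == pytest.approx(160.0, abs=2.0)
        assert short_ax == pytest.approx(80.0, abs=2.0)
        assert long_ax / short_ax == pytest.approx(2.0, abs=0.05)

    def test_long_axis_equals_allpairs_bruteforce(self, blob_instances):
        for inst in blob_instances[:15]:
            c = extract_contour(inst)
            long_ax, _, _ = principal_extents(c, inst)
            oracle = cdist(c.points, c.points).max()
            assert long_ax == pytest.approx(oracle, abs=1e-9)

    def test_90_degree_rotation_leaves_extents(self, ellipse_2to1):
        inst, c = ellipse_2to1
        la, sa, _ = principal_extents(c, inst)
        rot = InstanceMask(np.rot90(inst.mask), (0, 0))
        cr = extract_contour(rot)
        la2, sa2, _ = principal_extents(cr, rot)
        assert la2 == pytest.approx(la, abs=1.0)
        assert sa2 == pytest.approx(sa, abs=1.0)


class TestInscribedCircle:
    def test_square_side_100(self, square100):
        inst, _ = square100
        assert max_inscribed_circle(inst) == pytest.approx(50.0, abs=1.0)

    def test_disk_r60(self):
        inst, _ = instance_from_spec(ShapeSpec("circle", 60.0, center=(70.0, 70.0)))
        assert max_inscribed_circle(inst) == pytest.approx(60.0, abs=1.0)

    def test_random_blobs_match_bruteforce(self, blob_instances):
        for inst in blob_instances[:8]:
            assert max_inscribed_circle(inst) == pytest.approx(
                brute_incircle(inst), abs=1e-9
            )


class TestEnclosingCircle:
    def test_equilateral_triangle_circumradius(self):
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        assert min_enclosing_circle(tri) == pytest.approx(1 / np.sqrt(3))

    def test_square_raster(self, square100):
        _, c = square100
        assert min_enclosing_circle(c) == pytest.approx(
            100 * np.sqrt(2) / 2, abs=0.8
        )

    def test_random_point_sets_match_pair_triple_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            pts = rng.uniform(0, 100, size=(rng.integers(3, 25), 2))
            assert min_enclosing_circle(pts) == pytest.approx(
                brute_excircle(pts), abs=1e-6
            )


class TestRadialVariance:
    def test_disk_is_nearly_round(self, disk80):
        inst, c = disk80
        irr, nirr = radial_variance(c, centroid(inst))
        assert irr <= 0.3
        assert nirr <= 1e-4

    def test_scaling_contour_by_2(self, blob_instances):
        c = extract_contour(blob_instances[1]).points.astype(float)
        cen = c.mean(axis=0)
        irr1, n1 = radial_variance(c, tuple(cen))
        irr2, n2 = radial_variance(c * 2, tuple(cen * 2))
        assert irr2 == pytest.approx(4 * irr1, rel=1e-9)
        assert n2 == pytest.approx(n1, abs=1e-6)

    def test_star_matches_dense_curve_oracle(self):
        spec = ShapeSpec("bud", 50.0, frill_amplitude=0.2, frill_count=8,
                         center=(80.0, 80.0))
        inst, c = instance_from_spec(spec)
        irr, nirr = radial_variance(c, centroid(inst))
        # oracle: 1e5-point arc-length-weighted sampling of r(t)=50(1+0.2cos8t)
        t = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        r = 50 * (1 + 0.2 * np.cos(8 * t))
        x, y = r * np.cos(t), r * np.sin(t)
        seg = np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0])))
        mean = np.average(r, weights=seg)
        o_irr = np.average((r - mean) ** 2, weights=seg)
        rn = r / mean
        o_nirr = np.average((rn - np.average(rn, weights=seg)) ** 2, weights=seg)
        assert irr == pytest.approx(o_irr, rel=0.05)
        assert nirr == pytest.approx(o_nirr, rel=0.05)

    def test_zero_mean_distance_raises(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            radial_variance(pts, (0.0, 0.0))


class TestComputeMorphology:
    def test_disk_extremal_ratios(self, disk80):
        inst, c = disk80
        v = compute_morphology(inst, c)
        assert v.circularity == pytest.approx(1.0, abs=0.12)
        assert v.roundness == pytest.approx(1.0, abs=0.03)
        assert v.compactness == pytest.approx(1.0, abs=0.03)
        assert v.aspect_ratio == pytest.approx(1.0, abs=0.03)

    def test_vector_has_14_fields_in_canonical_order(self, disk80):
        inst, c = disk80
        v = compute_morphology(inst, c)
        assert len(FEATURE_NAMES) == 14
        assert list(v.to_dict()) == list(FEATURE_NAMES)
        assert len(v.to_array()) == 14

    def test_square_shape_parameter(self, square100):
        inst, c = square100
        v = compute_morphology(inst, c)
        assert v.shape_param == pytest.approx(16.0, abs=0.8)
        assert v.eq_diameter == pytest.approx(np.sqrt(4 * v.area / np.pi))
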