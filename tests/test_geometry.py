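"""Geometry primitives: contour tracing, hulls, distances, curvature,
ellipse perimeter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ellipe

from ovimorph import geometry as g


# ---------------------------------------------------------------------------
# contour tracing


def test_square_mask_traces_its_border_pixels():
    mask = np.zeros((10, 10), bool)
    mask[3:7, 3:7] = True
    c = g.extract_contour(mask)
    assert len(c) == 12  # 4x4 block has 12 border pixels under Moore tracing
    # closed 8-adjacent chain
    diffs = np.abs(np.diff(np.vstack([c, c[:1]]), axis=0))
    assert diffs.max() == 1
    # deterministic start: topmost-then-leftmost boundary pixel
    assert tuple(c[0]) == (3, 3)


def test_disk_contour_arc_length_approximates_circumference():
    r = 20
    yy, xx = np.mgrid[0:50, 0:50]
    disk = (xx - 25) ** 2 + (yy - 25) ** 2 <= r * r
    c = g.extract_contour(disk)
    assert g.contour_perimeter(c) == pytest.approx(2 * np.pi * r, rel=0.05)


def test_empty_mask_raises():
    with pytest.raises(ValueError, match="no foreground"):
        g.extract_contour(np.zeros((5, 5), bool))


def test_largest_component_wins_and_holes_are_ignored():
    mask = np.zeros((40, 60), bool)
    mask[5:35, 5:40] = True
    mask[15:25, 15:30] = False  # interior hole
    mask[10:13, 50:53] = True  # small separate blob
    c = g.extract_contour(mask)
    xs = c[:, 0]
    assert xs.max() < 45  # blob not traced
    # outer boundary only: no contour pixel inside the hole region
    inside_hole = (c[:, 0] >= 16) & (c[:, 0] < 29) & (c[:, 1] >= 16) & (c[:, 1] < 24)
    assert not inside_hole.any()


def test_rendered_polygon_area_matches_raster_count():
    # shoelace area of the traced boundary vs foreground pixel count
    from ovimorph import synthetic

    mask, _ = synthetic.render_side(synthetic.SheepSpec())
    c = g.extract_contour(mask)
    assert g.contour_area(c) == pytest.approx(mask.sum(), rel=0.03)


def test_contour_export_roundtrip(tmp_path):
    mask = np.zeros((8, 8), bool)
    mask[2:6, 2:6] = True
    c = g.extract_contour(mask)
    g.contour_to_csv(c, tmp_path / "c.csv")
    g.contour_to_geojson(c, tmp_path / "c.json")
    import csv as _csv, json as _json

    rows = list(_csv.reader(open(tmp_path / "c.csv")))
    assert rows[0] == ["index", "x", "y"] and len(rows) == len(c) + 1
    ring = _json.loads((tmp_path / "c.json").read_text())["coordinates"][0]
    assert ring[0] == ring[-1] and len(ring) == len(c) + 1


def test_mask_png_roundtrip(tmp_path):
    mask = np.zeros((15, 20), bool)
    mask[4:11, 6:17] = True
    g.save_mask(mask, tmp_path / "m.png")
    back = g.load_mask(tmp_path / "m.png")
    assert np.array_equal(mask, back)


# ---------------------------------------------------------------------------
# convex hull


def _brute_force_hull_vertices(pts: np.ndarray) -> set:
    """O(n^4) oracle: a point is a hull vertex iff it is not inside (or on
    the interior of) the triangle of any other three points."""
    n = len(pts)

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    verts = set()
    for i in range(n):
        p = pts[i]
        inside = False
        others = np.delete(pts, i, axis=0)
        for a in range(len(others)):
            for b in range(a + 1, len(others)):
                for c in range(b + 1, len(others)):
                    A, B, C = others[a], others[b], others[c]
                    d1 = cross2(B - A, p - A)
                    d2 = cross2(C - B, p - B)
                    d3 = cross2(A - C, p - C)
                    if (d1 > 1e-12 and d2 > 1e-12 and d3 > 1e-12) or (
                        d1 < -1e-12 and d2 < -1e-12 and d3 < -1e-12
                    ):
                        inside = True
                        break
                if inside:
                    break
            if inside:
                break
        if not inside:
            verts.add(tuple(np.round(p, 9)))
    return verts


def test_hull_square_plus_center_and_collinear_degeneracy():
    square = np.array([[0, 0], [4, 0], [4, 4], [0, 4], [2, 2]], float)
    hull = g.convex_hull(square)
    assert {tuple(p) for p in hull} == {(0, 0), (4, 0), (4, 4), (0, 4)}
    line = np.array([[0, 0], [1, 1], [2, 2]], float)
    degen = g.convex_hull(line)
    assert {tuple(p) for p in degen} == {(0, 0), (2, 2)}


def test_hull_matches_brute_force_oracle(rng):
    pts = rng.normal(size=(25, 2))
    assert {tuple(np.round(p, 9)) for p in g.convex_hull(pts)} == (
        _brute_force_hull_vertices(pts)
    )


def test_hull_idempotent_and_contains_all_points(rng):
    for _ in range(5):
        pts = rng.uniform(-10, 10, size=(80, 2))
        hull = g.convex_hull(pts)
        again = g.convex_hull(hull)
        assert {tuple(p) for p in again} == {tuple(p) for p in hull}
        # every point inside or on the hull: cross products one-signed
        h = np.vstack([hull, hull[:1]])
        e = h[1:] - h[:-1]
        for p in pts:
            w = p - h[:-1]
            crosses = e[:, 0] * w[:, 1] - e[:, 1] * w[:, 0]
            assert (crosses >= -1e-9).all() or (crosses <= 1e-9).all()


# ---------------------------------------------------------------------------
# point-line distance


def test_point_line_distance_basic_cases():
    line = g.Line(0, 1, 0)  # y = 0
    assert g.point_line_distance((0, 1), line) == pytest.approx(1.0)
    assert g.point_line_distance((5, 0), line) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        g.Line(0, 0, 3)


def test_point_line_distance_matches_projection_oracle(rng):
    for _ in range(50):
        a, b = rng.normal(size=(2, 2)) * 10
        if np.allclose(a, b):
            continue
        p = rng.normal(size=2) * 10
        line = g.line_through(a, b)
        # oracle: distance to the foot of the perpendicular
        t = np.dot(p - a, b - a) / np.dot(b - a, b - a)
        foot = a + t * (b - a)
        assert g.point_line_distance(p, line) == pytest.approx(
            float(np.hypot(*(p - foot))), abs=1e-9
        )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.floats(-5, 5),
    st.floats(-5, 5),
    st.floats(-3, 3).filter(lambda a: abs(a) > 1e-3),
    st.floats(-3, 3),
    st.floats(-3, 3),
    st.floats(-4, 4).filter(lambda k: abs(k) > 1e-3),
)
def test_point_line_distance_scale_invariant(x, y, a, b, c, k):
    d1 = g.point_line_distance((x, y), g.Line(a, b, c))
    d2 = g.point_line_distance((x, y), g.Line(k * a, k * b, k * c))
    assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# u-chord curvature


def test_curvature_exact_on_sampled_circle():
    r = 50.0
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    circle = np.column_stack([r * np.cos(t), r * np.sin(t)])
    for i in (0, 57, 200, 399):
        for u in (3, 10, 40):
            assert g.u_chord_curvature(circle, i, u) == pytest.approx(1 / r, rel=1e-9)


def test_curvature_zero_on_straight_edge():
    pts = np.column_stack([np.arange(30.0), np.zeros(30)])
    assert g.u_chord_curvature(pts, 15, 5) == 0.0


def test_curvature_is_inverse_circumradius_of_triangle(rng):
    for _ in range(20):
        tri = rng.normal(size=(3, 2)) * 10
        a = np.hypot(*(tri[1] - tri[0]))
        b = np.hypot(*(tri[2] - tri[1]))
        c = np.hypot(*(tri[2] - tri[0]))
        u, v = tri[1] - tri[0], tri[2] - tri[0]
        area = abs(u[0] * v[1] - u[1] * v[0]) / 2
        if area < 1e-6:
            continue
        R = a * b * c / (4 * area)  # closed-form circumradius
        assert g.u_chord_curvature(tri, 1, 1) == pytest.approx(1 / R, rel=1e-9)


def test_curvature_contour_too_short_raises():
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    with pytest.raises(ValueError, match="too short"):
        g.u_chord_curvature(pts, 0, 2)


def test_curvature_profile_agrees_with_pointwise():
    t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    pts = np.column_stack([10 * np.cos(t), 6 * np.sin(t)])
    prof = g.curvature_profile(pts, 4)
    for i in (0, 13, 50, 99):
        assert prof[i] == pytest.approx(g.u_chord_curvature(pts, i, 4))


# ---------------------------------------------------------------------------
# restricted extremum


def _square_contour():
    mask = np.zeros((12, 12), bool)
    mask[1:11, 1:11] = True
    return g.extract_contour(mask)


def test_restricted_extremum_square_cases():
    c = _square_contour()
    full = g.RangeBox(0, 1, 0, 1)
    top = g.restricted_extremum(c, full, "y", "min")
    assert tuple(top) == (1, 1)  # tie on the top edge -> smallest index
    right_half = g.RangeBox(0.5, 1.0, 0.0, 1.0)
    right = g.restricted_extremum(c, right_half, "x", "max")
    assert right[0] == 10


def test_restricted_extremum_empty_range_raises():
    c = _square_contour()  # ring: nothing strictly inside
    with pytest.raises(ValueError, match="empty range"):
        g.restricted_extremum(c, g.RangeBox(0.3, 0.7, 0.3, 0.7), "y", "min")
    with pytest.raises(ValueError):
        g.restricted_extremum(c, g.RangeBox(0, 1, 0, 1), "z", "min")


# ---------------------------------------------------------------------------
# ellipse perimeter


def test_ellipse_perimeter_closed_forms_and_oracle():
    r = 3.7
    assert g.ellipse_perimeter(r, r) == pytest.approx(2 * np.pi * r, abs=1e-8)
    assert g.ellipse_perimeter(2, 0) == pytest.approx(8.0, abs=1e-8)
    assert g.ellipse_perimeter(2, 1) == pytest.approx(9.6884, abs=1e-4)
    # complete-elliptic-integral oracle: P = 4 a E(e^2)
    for a, b in [(2, 1), (5, 3), (10, 0.5), (7, 7)]:
        oracle = 4 * a * ellipe(1 - (b / a) ** 2)
        assert g.ellipse_perimeter(a, b) == pytest.approx(oracle, abs=1e-6)
    with pytest.raises(ValueError):
        g.ellipse_perimeter(-1, 2)


def test_ellipse_perimeter_symmetry_monotonicity_bounds(rng):
    for _ in range(20):
        a, b = rng.uniform(0.5, 20, size=2)
        p = g.ellipse_perimeter(a, b)
        assert p == pytest.approx(g.ellipse_perimeter(b, a), abs=1e-8)
        assert p >= 2 * np.pi * min(a, b) - 1e-8  # inscribed circle
        assert p <= 2 * np.pi * max(a, b) + 1e-8  # circumscribed circle
        assert g.ellipse_perimeter(a * 1.1, b) >= p - 1e-10
        assert g.ellipse_perimeter(a, b * 1.1) >= p - 1e-10
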