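"""Geometry primitives on binary silhouette masks and their contours.

Image coordinate convention throughout the package: origin at the top-left
pixel, ``x`` increases rightward (columns), ``y`` increases downward (rows).
"Smallest y" therefore means *topmost*.  Side-view animals are assumed to
face right; :func:`ovimorph.landmarks.ensure_facing_right` normalises pose.

A contour is an ordered, closed chain of boundary pixels (8-adjacent
neighbours, clockwise in image coordinates) produced by Moore-neighbour
tracing of the largest foreground component.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial.legendre import leggauss
from PIL import Image
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Line",
    "RangeBox",
    "load_mask",
    "save_mask",
    "binarize",
    "extract_contour",
    "contour_to_csv",
    "contour_to_geojson",
    "contour_area",
    "contour_perimeter",
    "convex_hull",
    "point_line_distance",
    "line_through",
    "u_chord_curvature",
    "curvature_profile",
    "restricted_extremum",
    "box_indices",
    "ellipse_perimeter",
]


@dataclass(frozen=True)
class Line:
    """Implicit line ``a*x + b*y + c = 0``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a == 0 and self.b == 0:
            raise ValueError("degenerate line: (a, b) must not be (0, 0)")


@dataclass(frozen=True)
class RangeBox:
    """Axis-aligned search window given as fractions of a bounding box.

    ``x_lo`` .. ``y_hi`` are in [0, 1] relative to the silhouette's bounding
    box (x: left→right, y: top→bottom).
    """

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def __post_init__(self) -> None:
        if not (self.x_lo < self.x_hi and self.y_lo < self.y_hi):
            raise ValueError("RangeBox requires lo < hi on both axes")


# ---------------------------------------------------------------------------
# masks


def binarize(image: np.ndarray, threshold: int = 127) -> np.ndarray:
    """Threshold a grayscale raster to a boolean foreground mask.

    Already-boolean arrays pass through unchanged.
    """
    arr = np.asarray(image)
    if arr.dtype == bool:
        return arr
    return arr > threshold


def load_mask(path: str | Path, threshold: int = 127) -> np.ndarray:
    """Read a PNG mask (0 = background, 255 = foreground) as a boolean array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return binarize(arr, threshold)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground = 255)."""
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(path)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        raise ValueError("no foreground")
    if n == 1:
        return labels == 1
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


# Moore neighbourhood in clockwise order starting East, for (dx, dy).
_MOORE = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)], dtype=int
)
_DIR_INDEX = {(int(dx), int(dy)): i for i, (dx, dy) in enumerate(_MOORE)}


def extract_contour(mask: np.ndarray, threshold: int = 127) -> np.ndarray:
    """Trace the closed outer boundary of the largest foreground component.

    Moore-neighbour tracing with 8-connectivity; interior holes are ignored.
    The chain starts at the topmost-then-leftmost boundary pixel and runs
    clockwise in image coordinates.

    Returns an ``(n, 2)`` integer array of ``(x, y)`` pixel coordinates with
    consecutive points 8-adjacent and the first/last points adjacent.
    """
    mask = binarize(np.asarray(mask), threshold)
    if not mask.any():
        raise ValueError("no foreground")
    comp = _largest_component(mask)
    ys, xs = np.nonzero(comp)
    # deterministic start: topmost row, then leftmost column
    top = ys.min()
    start = (int(xs[ys == top].min()), int(top))

    h, w = comp.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and comp[y, x]

    points: list[tuple[int, int]] = [start]
    # entered the start pixel "from above" (backtrack direction North);
    # scanning starts one step clockwise from the backtrack.
    prev_dir = _DIR_INDEX[(0, -1)]  # direction start -> backtrack pixel
    cur = start
    first_move: tuple[int, int] | None = None
    while True:
        found = False
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            dx, dy = _MOORE[d]
            nxt = (cur[0] + int(dx), cur[1] + int(dy))
            if fg(*nxt):
                found = True
                break
        if not found:  # isolated single pixel
            break
        if cur == start and first_move is None:
            first_move = nxt
        elif cur == start and nxt == first_move:
            break  # closed the loop, re-entering the same way
        points.append(nxt)
        # backtrack direction as seen from the new pixel
        prev_dir = _DIR_INDEX[(cur[0] - nxt[0], cur[1] - nxt[1])]
        cur = nxt
        if cur == start:
            # will decide on next iteration whether the loop truly closed
            continue
    # drop the duplicated closing start point if present
    if len(points) > 1 and points[-1] == start:
        points.pop()
    return np.array(points, dtype=int)


def contour_area(contour: np.ndarray) -> float:
    """Unsigned shoelace area of the closed pixel chain."""
    p = np.asarray(contour, float)
    x, y = p[:, 0], p[:, 1]
    return abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0


def contour_perimeter(contour: np.ndarray) -> float:
    """Arc length of the closed chain (sum of consecutive segment lengths)."""
    p = np.asarray(contour, float)
    d = np.roll(p, -1, axis=0) - p
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def contour_to_csv(contour: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["index", "x", "y"])
        for i, (x, y) in enumerate(contour):
            wr.writerow([i, int(x), int(y)])


def contour_to_geojson(contour: np.ndarray, path: str | Path) -> None:
    ring = [[int(x), int(y)] for x, y in contour]
    ring.append(ring[0])
    obj = {"type": "Polygon", "coordinates": [ring]}
    Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# convex hull


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Minimal convex polygon of a point set.

    Vertices are returned counterclockwise in mathematical orientation
    (i.e. as scipy orders them in the x-right / y-up frame), with collinear
    interior vertices removed.  A fully collinear input degenerates to its
    two extreme points.
    """
    pts = np.asarray(points, float)
    if len(pts) < 2:
        raise ValueError("hull needs at least 2 points")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # all points collinear: return the two extremes along the spread axis
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        axis = int(np.argmax(hi - lo))
        order = np.argsort(pts[:, axis], kind="stable")
        return pts[[order[0], order[-1]]]
    return pts[hull.vertices]


def points_on_hull(points: np.ndarray, tol: float = 0.4) -> np.ndarray:
    """Boolean mask of the points lying on (within ``tol``) the hull boundary.

    Used to restrict landmark searches to the "convex wrap" of a contour:
    the candidate set is the intersection of contour pixels with the hull
    polygon's edges.
    """
    pts = np.asarray(points, float)
    hull = convex_hull(pts)
    if len(hull) == 2:
        segs = [(hull[0], hull[1])]
    else:
        segs = [(hull[i], hull[(i + 1) % len(hull)]) for i in range(len(hull))]
    on = np.zeros(len(pts), bool)
    for a, b in segs:
        ab = b - a
        L2 = float(ab @ ab)
        if L2 == 0:
            continue
        t = np.clip((pts - a) @ ab / L2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        on |= np.hypot(*(pts - proj).T) <= tol
    return on


# ---------------------------------------------------------------------------
# distances and curvature


def line_through(p: np.ndarray, q: np.ndarray) -> Line:
    """Implicit line through two distinct points."""
    (x1, y1), (x2, y2) = np.asarray(p, float), np.asarray(q, float)
    if x1 == x2 and y1 == y2:
        raise ValueError("cannot define a line through coincident points")
    return Line(a=y2 - y1, b=x1 - x2, c=x2 * y1 - x1 * y2)


def point_line_distance(point: np.ndarray, line: Line) -> float:
    """Perpendicular distance ``|a*x + b*y + c| / sqrt(a^2 + b^2)``."""
    x, y = np.asarray(point, float)
    return abs(line.a * x + line.b * y + line.c) / float(np.hypot(line.a, line.b))


def _points_line_distances(points: np.ndarray, line: Line) -> np.ndarray:
    p = np.asarray(points, float)
    return np.abs(line.a * p[:, 0] + line.b * p[:, 1] + line.c) / float(
        np.hypot(line.a, line.b)
    )


def u_chord_curvature(contour: np.ndarray, index: int, u: int) -> float:
    """Discrete curvature at contour point ``index`` using chord offset ``u``.

    The estimate is the Menger curvature of the triangle formed by the point
    and its neighbours ``u`` positions away on each side (wraparound
    indexing): ``4 * area / (|e1| |e2| |e3|)``.  It is the inverse of the
    circumradius, hence exact (``1/r``) for points lying on a circle, and 0
    for a collinear triple.
    """
    pts = np.asarray(contour, float)
    n = len(pts)
    if u < 1:
        raise ValueError("u must be >= 1")
    if n <= 2 * u:
        raise ValueError("contour too short for the requested u")
    a = pts[(index - u) % n]
    b = pts[index % n]
    c = pts[(index + u) % n]
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    if area2 == 0:
        return 0.0
    e1 = float(np.hypot(*(b - a)))
    e2 = float(np.hypot(*(c - b)))
    e3 = float(np.hypot(*(c - a)))
    return 2.0 * area2 / (e1 * e2 * e3)


def curvature_profile(contour: np.ndarray, u: int) -> np.ndarray:
    """Vectorised Menger u-chord curvature at every contour point."""
    pts = np.asarray(contour, float)
    n = len(pts)
    if n <= 2 * u:
        raise ValueError("contour too short for the requested u")
    a = np.roll(pts, u, axis=0)
    b = pts
    c = np.roll(pts, -u, axis=0)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    )
    e1 = np.hypot(*(b - a).T)
    e2 = np.hypot(*(c - b).T)
    e3 = np.hypot(*(c - a).T)
    denom = e1 * e2 * e3
    out = np.zeros(n)
    ok = denom > 0
    out[ok] = 2.0 * area2[ok] / denom[ok]
    return out


def default_u(contour: np.ndarray, fraction: float = 0.01) -> int:
    """Default chord offset: a fixed fraction of the contour point count."""
    return max(3, int(round(fraction * len(contour))))


# ---------------------------------------------------------------------------
# restricted extremum search


def box_indices(contour: np.ndarray, box: RangeBox) -> np.ndarray:
    """Indices of contour points inside ``box`` scaled to the contour bbox."""
    pts = np.asarray(contour, float)
    x_lo, y_lo = pts.min(axis=0)
    x_hi, y_hi = pts.max(axis=0)
    bx_lo = x_lo + box.x_lo * (x_hi - x_lo)
    bx_hi = x_lo + box.x_hi * (x_hi - x_lo)
    by_lo = y_lo + box.y_lo * (y_hi - y_lo)
    by_hi = y_lo + box.y_hi * (y_hi - y_lo)
    sel = (
        (pts[:, 0] >= bx_lo)
        & (pts[:, 0] <= bx_hi)
        & (pts[:, 1] >= by_lo)
        & (pts[:, 1] <= by_hi)
    )
    return np.nonzero(sel)[0]


def restricted_extremum(
    contour: np.ndarray, box: RangeBox, axis: str, mode: str
) -> np.ndarray:
    """Extremal contour point within a bounding-box-relative search window.

    ``axis`` is ``"x"`` or ``"y"``, ``mode`` is ``"min"`` or ``"max"``.
    Ties are broken by the smallest contour index (determinism).
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    idx = box_indices(contour, box)
    if len(idx) == 0:
        raise ValueError("empty range")
    vals = np.asarray(contour)[idx, 0 if axis == "x" else 1]
    pick = np.argmin(vals) if mode == "min" else np.argmax(vals)
    # np.argmin/argmax return the first occurrence → smallest contour index
    return np.asarray(contour)[idx[pick]]


# ---------------------------------------------------------------------------
# ellipse perimeter

_GL_NODES, _GL_WEIGHTS = leggauss(64)


def ellipse_perimeter(alpha: float, beta: float) -> float:
    """Perimeter of an ellipse with semi-axes ``alpha`` and ``beta``.

    Evaluates ``4 * ∫_0^{π/2} sqrt(α² cos²t + β² sin²t) dt`` with 64-node
    Gauss–Legendre quadrature; a split-interval Richardson check guards the
    1e-8 absolute tolerance.  Degenerate axes are allowed (``β = 0`` gives
    the doubled segment ``4α``).
    """
    if alpha < 0 or beta < 0:
        raise ValueError("ellipse semi-axes must be nonnegative")

    def quad(lo: float, hi: float) -> float:
        half = (hi - lo) / 2.0
        t = lo + half * (_GL_NODES + 1.0)
        f = np.sqrt((alpha * np.cos(t)) ** 2 + (beta * np.sin(t)) ** 2)
        return half * float(f @ _GL_WEIGHTS)

    hi = np.pi / 2.0
    whole = quad(0.0, hi)
    split = quad(0.0, hi / 2.0) + quad(hi / 2.0, hi)
    if abs(whole - split) > 1e-8:
        # fall back to the finer partition (near-degenerate axis ratios)
        parts = np.linspace(0.0, hi, 9)
        split = sum(quad(a, b) for a, b in zip(parts[:-1], parts[1:]))
    return 4.0 * split
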