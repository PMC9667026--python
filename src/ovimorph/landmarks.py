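"""Anatomical landmark detection on silhouette contours.

Side view (animal facing right): head vertex, front hoof, facial vertex
(nose tip), hip top, withers, chest front (brisket), sciatic tuberosity,
chest bottom (sternum), shank width and the ground line.  Dorsal view
(head to the right): the lateral curvature maxima at the shoulders and the
rump, whose ``|Δy|`` give shoulder and rump width.

Search windows are expressed as :class:`~ovimorph.geometry.RangeBox`
fractions of the silhouette bounding box, so the same configuration applies
across image resolutions and animal sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    RangeBox,
    box_indices,
    curvature_profile,
    default_u,
    line_through,
    _points_line_distances,
    points_on_hull,
    restricted_extremum,
)

__all__ = [
    "RangeConfig",
    "LandmarkSet",
    "ensure_facing_right",
    "detect_head_vertex",
    "detect_front_hoof",
    "detect_facial_vertex",
    "detect_hip_top",
    "detect_withers",
    "detect_chest_front",
    "detect_sciatic_tuberosity",
    "detect_chest_bottom",
    "detect_dorsal_widths",
    "detect_shank",
    "ground_line",
    "detect_side",
    "detect_dorsal",
]


@dataclass(frozen=True)
class RangeConfig:
    """Per-landmark search windows (fractions of the silhouette bbox)."""

    head: RangeBox = field(default_factory=lambda: RangeBox(0.55, 1.0, 0.0, 0.5))
    hoof: RangeBox = field(default_factory=lambda: RangeBox(0.5, 1.0, 0.5, 1.0))
    hip: RangeBox = field(default_factory=lambda: RangeBox(0.0, 0.45, 0.0, 0.5))
    chest_bottom: RangeBox = field(default_factory=lambda: RangeBox(0.45, 0.66, 0.35, 0.80))
    sciatic: RangeBox = field(default_factory=lambda: RangeBox(0.0, 0.10, 0.25, 0.75))
    shoulder: RangeBox = field(default_factory=lambda: RangeBox(0.50, 0.66, 0.0, 1.0))
    rump: RangeBox = field(default_factory=lambda: RangeBox(0.08, 0.30, 0.0, 1.0))
    shank: RangeBox = field(default_factory=lambda: RangeBox(0.60, 1.0, 0.70, 1.0))


_SIDE_NAMES = (
    "head_vertex",
    "front_hoof",
    "facial_vertex",
    "hip_top",
    "withers",
    "chest_front",
    "sciatic_tuberosity",
    "chest_bottom",
)
_DORSAL_NAMES = ("shoulder_left", "shoulder_right", "rump_left", "rump_right")


@dataclass
class LandmarkSet:
    """Named landmark pixels for one view of one animal."""

    view: str  # "side" | "dorsal"
    points: dict[str, tuple[int, int]] = field(default_factory=dict)
    ground_y: int | None = None
    shank_diameter_px: float | None = None

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.points[name]

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "view": self.view,
            "points": {k: [int(v[0]), int(v[1])] for k, v in self.points.items()},
            "ground_y": self.ground_y,
            "shank_diameter_px": self.shank_diameter_px,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LandmarkSet":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        obj = json.loads(text)
        return cls(
            view=obj["view"],
            points={k: (int(v[0]), int(v[1])) for k, v in obj["points"].items()},
            ground_y=obj.get("ground_y"),
            shank_diameter_px=obj.get("shank_diameter_px"),
        )


# ---------------------------------------------------------------------------
# pose


def ensure_facing_right(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip a side-view mask left-right if the animal faces left.

    The head is the topmost region of a standing sheep's silhouette; if the
    topmost foreground pixel sits left of the silhouette's centroid the
    animal is taken to face left.  Returns ``(mask, flipped)``.
    """
    m = np.asarray(mask, bool)
    ys, xs = np.nonzero(m)
    if len(xs) == 0:
        raise ValueError("no foreground")
    top_x = xs[ys == ys.min()].mean()
    if top_x < xs.mean():
        return m[:, ::-1], True
    return m, False


# ---------------------------------------------------------------------------
# helpers


def _index_of(contour: np.ndarray, point) -> int:
    pts = np.asarray(contour)
    hit = np.nonzero((pts[:, 0] == point[0]) & (pts[:, 1] == point[1]))[0]
    if len(hit) == 0:
        raise ValueError("anchor point is not on the contour")
    return int(hit[0])


def _arc_between(contour: np.ndarray, i: int, j: int) -> np.ndarray:
    """Indices of the *shorter* closed-chain arc from ``i`` to ``j`` inclusive."""
    n = len(contour)
    fwd = (j - i) % n
    bwd = (i - j) % n
    if fwd <= bwd:
        return (i + np.arange(fwd + 1)) % n
    return (j + np.arange(bwd + 1)) % n


def _hull_candidates(contour: np.ndarray, box: RangeBox) -> np.ndarray:
    """Contour indices inside ``box`` that lie on the convex hull boundary."""
    idx = box_indices(contour, box)
    if len(idx) == 0:
        raise ValueError("empty range")
    on = points_on_hull(np.asarray(contour, float))
    keep = idx[on[idx]]
    return keep if len(keep) else idx


# ---------------------------------------------------------------------------
# side-view detectors


def detect_head_vertex(contour: np.ndarray, cfg: RangeConfig | None = None):
    """Topmost contour point in the right-half head window."""
    cfg = cfg or RangeConfig()
    return restricted_extremum(contour, cfg.head, axis="y", mode="min")


def detect_front_hoof(contour: np.ndarray, cfg: RangeConfig | None = None):
    """Rightmost convex-wrap contour point in the lower-half hoof window.

    Ties in x (a vertical leading edge grazing the hull) resolve to the
    lowest point — the hoof is the ground-contact corner.
    """
    cfg = cfg or RangeConfig()
    idx = _hull_candidates(contour, cfg.hoof)
    pts = np.asarray(contour)[idx]
    at_max = pts[pts[:, 0] == pts[:, 0].max()]
    return at_max[int(np.argmax(at_max[:, 1]))]


def detect_facial_vertex(contour: np.ndarray):
    """Globally rightmost contour point (nose tip); ties → smallest index."""
    pts = np.asarray(contour)
    return pts[int(np.argmax(pts[:, 0]))]


def detect_hip_top(contour: np.ndarray, cfg: RangeConfig | None = None):
    """Topmost contour point in the left-half hip window."""
    cfg = cfg or RangeConfig()
    return restricted_extremum(contour, cfg.hip, axis="y", mode="min")


def detect_withers(contour: np.ndarray, head_vertex, hip_top):
    """Dorsal point farthest from the hip-top ↔ head-vertex chord.

    The chord ("straight line b") joins the two dorsal anchors; the withers
    is the point of the dorsal arc between them with the largest
    perpendicular distance to it.
    """
    if tuple(head_vertex) == tuple(hip_top):
        raise ValueError("withers anchors coincide")
    i = _index_of(contour, hip_top)
    j = _index_of(contour, head_vertex)
    arc = _arc_between(contour, i, j)
    line = line_through(hip_top, head_vertex)
    d = _points_line_distances(np.asarray(contour, float)[arc], line)
    order = np.argsort(arc, kind="stable")  # tie-break on contour index
    k = order[int(np.argmax(d[order]))]
    return np.asarray(contour)[arc[k]]


def detect_chest_front(contour: np.ndarray, facial_vertex, front_hoof, trim: float = 0.1):
    """Brisket point: closest interior approach of the front contour to the
    nose ↔ front-hoof chord.

    Both anchors lie on the chord (distance 0), so a ``trim`` fraction of the
    arc next to each anchor is excluded before taking the minimum.
    """
    if tuple(facial_vertex) == tuple(front_hoof):
        raise ValueError("chest-front anchors coincide")
    i = _index_of(contour, facial_vertex)
    j = _index_of(contour, front_hoof)
    arc = _arc_between(contour, i, j)
    k = max(1, int(round(trim * len(arc))))
    inner = arc[k:-k] if len(arc) > 2 * k else arc
    line = line_through(facial_vertex, front_hoof)
    d = _points_line_distances(np.asarray(contour, float)[inner], line)
    order = np.argsort(inner, kind="stable")
    m = order[int(np.argmin(d[order]))]
    return np.asarray(contour)[inner[m]]


def _refine_peak(sel: np.ndarray, kappa: np.ndarray, frac: float = 0.96) -> int:
    """Centre of the near-maximal curvature plateau within ``sel``.

    The discrete Menger estimate of a convex corner is twin-humped: it dips
    slightly at the apex itself and peaks a few points up each flank.  The
    apex is recovered as the midpoint of the contiguous run of points whose
    curvature stays within ``frac`` of the maximum.  If that run reaches the
    edge of the selected contour segment (no interior peak, e.g. an arc of
    constant curvature), the first maximal index is returned, preserving the
    smallest-index tie rule.
    """
    sel = np.asarray(sel)
    k = kappa[sel]
    star = int(np.argmax(k))
    thr = frac * k[star]
    lo = star
    while lo > 0 and k[lo - 1] >= thr and sel[lo - 1] == sel[lo] - 1:
        lo -= 1
    hi = star
    while hi < len(sel) - 1 and k[hi + 1] >= thr and sel[hi + 1] == sel[hi] + 1:
        hi += 1
    touches_edge = (lo == 0) or (hi == len(sel) - 1)
    if touches_edge:
        return int(sel[star])
    return int(sel[(lo + hi) // 2])


def _curvature_max_in_box(contour: np.ndarray, box: RangeBox, u: int | None):
    idx = box_indices(contour, box)
    if len(idx) == 0:
        raise ValueError("empty range")
    u = u if u is not None else default_u(contour)
    kappa = curvature_profile(contour, u)
    return np.asarray(contour)[_refine_peak(idx, kappa)]


def detect_sciatic_tuberosity(
    contour: np.ndarray, cfg: RangeConfig | None = None, u: int | None = None
):
    """Maximum u-chord-curvature point in the rear (sciatic) window."""
    cfg = cfg or RangeConfig()
    return _curvature_max_in_box(contour, cfg.sciatic, u)


def detect_chest_bottom(
    contour: np.ndarray, cfg: RangeConfig | None = None, u: int | None = None
):
    """Maximum u-chord-curvature point in the sternum window."""
    cfg = cfg or RangeConfig()
    return _curvature_max_in_box(contour, cfg.chest_bottom, u)


def ground_line(contour: np.ndarray) -> int:
    """Ground row: the maximal y over the contour (hoof-ground contact)."""
    return int(np.asarray(contour)[:, 1].max())


def detect_shank(
    contour: np.ndarray,
    chest_bottom,
    front_hoof,
    cfg: RangeConfig | None = None,
) -> float:
    """Front-leg width (px) at one third of the sternum→hoof drop.

    The measuring row sits ``1/3`` of the way down from the chest bottom to
    the hoof; the leg is the pair of contour crossings at that row closest
    in x to the front hoof, and the width is the inclusive pixel span.
    """
    pts = np.asarray(contour)
    y_level = int(round(chest_bottom[1] + (front_hoof[1] - chest_bottom[1]) / 3.0))
    xs = np.sort(pts[pts[:, 1] == y_level, 0])
    if len(xs) < 2:
        raise ValueError("no crossings at the shank row")
    # right edge of the leg carrying the hoof: crossing nearest the hoof x
    right = xs[int(np.argmin(np.abs(xs - front_hoof[0])))]
    left_candidates = xs[xs < right - 1]
    if len(left_candidates) == 0:
        raise ValueError("no crossings at the shank row")
    left = left_candidates.max()
    return float(right - left + 1)


def detect_side(
    contour: np.ndarray, cfg: RangeConfig | None = None, u: int | None = None
) -> LandmarkSet:
    """Run the full side-view landmark chain on one contour."""
    cfg = cfg or RangeConfig()
    head = detect_head_vertex(contour, cfg)
    hoof = detect_front_hoof(contour, cfg)
    face = detect_facial_vertex(contour)
    hip = detect_hip_top(contour, cfg)
    withers = detect_withers(contour, head, hip)
    chest_front = detect_chest_front(contour, face, hoof)
    sciatic = detect_sciatic_tuberosity(contour, cfg, u)
    chest_bottom = detect_chest_bottom(contour, cfg, u)
    shank = detect_shank(contour, chest_bottom, hoof, cfg)
    return LandmarkSet(
        view="side",
        points={
            "head_vertex": tuple(int(v) for v in head),
            "front_hoof": tuple(int(v) for v in hoof),
            "facial_vertex": tuple(int(v) for v in face),
            "hip_top": tuple(int(v) for v in hip),
            "withers": tuple(int(v) for v in withers),
            "chest_front": tuple(int(v) for v in chest_front),
            "sciatic_tuberosity": tuple(int(v) for v in sciatic),
            "chest_bottom": tuple(int(v) for v in chest_bottom),
        },
        ground_y=ground_line(contour),
        shank_diameter_px=shank,
    )


# ---------------------------------------------------------------------------
# dorsal view


def detect_dorsal_widths(
    contour: np.ndarray, cfg: RangeConfig | None = None, u: int | None = None
):
    """Lateral curvature maxima at the shoulders and the rump.

    The body axis is the horizontal through the silhouette centroid; within
    each window the maximal-curvature point is taken on each side of the
    axis.  Returns ``(shoulder_left, shoulder_right, rump_left, rump_right)``
    where "left" is the smaller-y side of the image.
    """
    cfg = cfg or RangeConfig()
    pts = np.asarray(contour)
    axis_y = pts[:, 1].mean()
    u = u if u is not None else default_u(contour)
    kappa = curvature_profile(contour, u)

    def side_max(box: RangeBox, upper: bool):
        idx = box_indices(contour, box)
        if len(idx) == 0:
            raise ValueError("empty range")
        sel = idx[(pts[idx, 1] < axis_y) if upper else (pts[idx, 1] > axis_y)]
        if len(sel) == 0:
            raise ValueError("empty range on one side of the body axis")
        return pts[_refine_peak(sel, kappa)]

    return (
        side_max(cfg.shoulder, True),
        side_max(cfg.shoulder, False),
        side_max(cfg.rump, True),
        side_max(cfg.rump, False),
    )


def detect_dorsal(
    contour: np.ndarray, cfg: RangeConfig | None = None, u: int | None = None
) -> LandmarkSet:
    sl, sr, rl, rr = detect_dorsal_widths(contour, cfg, u)
    return LandmarkSet(
        view="dorsal",
        points={
            "shoulder_left": tuple(int(v) for v in sl),
            "shoulder_right": tuple(int(v) for v in sr),
            "rump_left": tuple(int(v) for v in rl),
            "rump_right": tuple(int(v) for v in rr),
        },
    )


def render_overlay(mask: np.ndarray, landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a quick-look PNG with landmark crosses burned into the mask."""
    from PIL import Image

    img = np.stack([np.where(np.asarray(mask, bool), 200, 0).astype(np.uint8)] * 3, -1)
    h, w = img.shape[:2]
    for x, y in landmarks.points.values():
        for d in range(-4, 5):
            if 0 <= y + d < h and 0 <= x < w:
                img[y + d, x] = (255, 40, 40)
            if 0 <= y < h and 0 <= x + d < w:
                img[y, x + d] = (255, 40, 40)
    Image.fromarray(img).save(path)
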