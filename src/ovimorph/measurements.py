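"""Calibrated body-size traits from landmarks, plus manual-vs-machine error.

The eight traits (all cm):

HW   height at wither        ground to withers, vertical
HH   hip height              ground to hip top, vertical
CD   chest depth             withers to sternum lower edge, vertical
BSL  body slanting length    brisket (chest front) to sciatic tuberosity
SW   shoulder width          lateral span at the scapulae (dorsal view)
RW   rump width              lateral span at the hip joints (dorsal view)
CC   chest circumference     perimeter of the ellipse with axes SW and CD
SC   shank circumference     π times the front-leg shank diameter

Body weight (BW, kg) is an input column from the weighing hardware or a
regression prediction; it is never measured here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ScaleModel, pixels_to_cm
from .geometry import ellipse_perimeter
from .landmarks import LandmarkSet

__all__ = [
    "BodyMeasurements",
    "ErrorReport",
    "measure_side",
    "measure_dorsal",
    "chest_circumference",
    "shank_circumference",
    "correction_coefficient",
    "percentage_error",
    "mean_error",
    "error_report",
]

TRAITS = ("HW", "BSL", "CD", "HH", "SW", "RW", "CC", "SC")


@dataclass
class BodyMeasurements:
    """The eight body-size traits (cm) and optional body weight (kg)."""

    HW: float | None = None
    BSL: float | None = None
    CD: float | None = None
    HH: float | None = None
    SW: float | None = None
    RW: float | None = None
    CC: float | None = None
    SC: float | None = None
    BW: float | None = None

    def validate(self) -> None:
        for name in TRAITS + ("BW",):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.CD is not None and self.HW is not None and self.CD >= self.HW:
            raise ValueError("chest depth must be smaller than wither height")
        if self.SC is not None and self.CC is not None and self.SC >= self.CC:
            raise ValueError("shank girth must be smaller than chest girth")

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in TRAITS + ("BW",)}

    def update(self, other: "BodyMeasurements") -> "BodyMeasurements":
        for k in TRAITS + ("BW",):
            v = getattr(other, k)
            if v is not None:
                setattr(self, k, v)
        return self


def _require(landmarks: LandmarkSet, *names: str) -> None:
    missing = [n for n in names if n not in landmarks.points]
    if missing:
        raise ValueError(f"missing landmark(s): {', '.join(missing)}")


def measure_side(
    landmarks: LandmarkSet, model: ScaleModel, distance: float
) -> BodyMeasurements:
    """Side-view traits: HW, HH, CD, BSL and the shank-derived SC.

    Vertical traits are pixel differences to the ground row; BSL is the
    Euclidean brisket→sciatic distance.  All pixel lengths are converted
    with the side-view scale model at the given object distance.
    """
    _require(landmarks, "withers", "hip_top", "chest_bottom", "chest_front",
             "sciatic_tuberosity")
    if landmarks.ground_y is None:
        raise ValueError("missing landmark(s): ground_y")
    g = landmarks.ground_y
    wx, wy = landmarks["withers"]
    _, hy = landmarks["hip_top"]
    _, cby = landmarks["chest_bottom"]
    cf = np.asarray(landmarks["chest_front"], float)
    st = np.asarray(landmarks["sciatic_tuberosity"], float)

    def cm(px: float) -> float:
        return pixels_to_cm(px, distance, model)

    out = BodyMeasurements(
        HW=cm(g - wy),
        HH=cm(g - hy),
        CD=cm(abs(cby - wy)),
        BSL=cm(float(np.hypot(*(cf - st)))),
    )
    if landmarks.shank_diameter_px is not None:
        out.SC = shank_circumference(cm(landmarks.shank_diameter_px))
    return out


def measure_dorsal(
    landmarks: LandmarkSet, model: ScaleModel, distance: float
) -> BodyMeasurements:
    """Dorsal-view traits: SW and RW as |Δy| of the lateral landmark pairs."""
    _require(landmarks, "shoulder_left", "shoulder_right", "rump_left", "rump_right")

    def width(a: str, b: str) -> float:
        return pixels_to_cm(
            abs(landmarks[a][1] - landmarks[b][1]), distance, model
        )

    return BodyMeasurements(
        SW=width("shoulder_left", "shoulder_right"),
        RW=width("rump_left", "rump_right"),
    )


def chest_circumference(sw: float, cd: float) -> float:
    """Girth of the elliptical thorax cross-section.

    The chest width (≈ shoulder width, dorsal view) and the chest depth
    (side view) are the full axes of the ellipse; the circumference is the
    ellipse perimeter with semi-axes ``sw/2`` and ``cd/2``.
    """
    if sw <= 0 or cd <= 0:
        raise ValueError("chest width and depth must be positive")
    return ellipse_perimeter(sw / 2.0, cd / 2.0)


def shank_circumference(diameter_cm: float) -> float:
    """Shank girth from the circular cross-section: ``C = π d``."""
    if diameter_cm < 0:
        raise ValueError("diameter must be nonnegative")
    return float(np.pi * diameter_cm)


def correction_coefficient(manual, machine) -> float:
    """Multiplicative correction factor from a manual/machine validation set.

    The mean of the per-animal manual/machine ratios; subsequent machine
    values for the trait are multiplied by it.
    """
    a = np.asarray(list(manual), float)
    m = np.asarray(list(machine), float)
    if a.shape != m.shape or a.size == 0:
        raise ValueError("manual and machine lists must have equal nonzero length")
    if np.any(m <= 0):
        raise ValueError("machine values must be positive")
    return float(np.mean(a / m))


def percentage_error(da: float, dm: float) -> float:
    """Relative error of a machine value against its manual reference (%).

    ``Perr = |Da - Dm| / Da * 100`` with Da the manual and Dm the machine
    measurement.
    """
    if da == 0:
        raise ValueError("manual reference must be nonzero")
    return abs(da - dm) / abs(da) * 100.0


def mean_error(perr_values) -> float:
    """Arithmetic mean of per-animal percentage errors (the trait's A, %)."""
    v = np.asarray(list(perr_values), float)
    if v.size == 0:
        raise ValueError("no errors to average")
    return float(v.mean())


@dataclass
class ErrorReport:
    """Per-trait percentage errors and their means over a validation set."""

    perr: dict[str, list[float]] = field(default_factory=dict)

    @property
    def mean(self) -> dict[str, float]:
        return {k: mean_error(v) for k, v in self.perr.items() if v}

    def as_dict(self) -> dict:
        return {"perr": self.perr, "A": self.mean}


def error_report(manual_rows, machine_rows) -> ErrorReport:
    """Pairwise manual-vs-machine errors for every shared trait column.

    Both arguments are sequences of mappings (or BodyMeasurements) aligned
    by animal.
    """
    rep = ErrorReport()
    for man, mac in zip(manual_rows, machine_rows, strict=True):
        man_d = man.as_dict() if isinstance(man, BodyMeasurements) else dict(man)
        mac_d = mac.as_dict() if isinstance(mac, BodyMeasurements) else dict(mac)
        for trait in TRAITS:
            a, m = man_d.get(trait), mac_d.get(trait)
            if a is not None and m is not None and not (np.isnan(a) or np.isnan(m)):
                rep.perr.setdefault(trait, []).append(percentage_error(a, m))
    return rep
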