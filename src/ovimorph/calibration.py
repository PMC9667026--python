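"""Pixel-to-centimetre scale modelling.

A calibration plate of known physical size is photographed at a series of
distances (plate heights); each photograph yields a px-per-cm ratio.  The
ratio varies with object distance, so a per-view quadratic

    ratio(d) = c2 * d**2 + c1 * d + c0      [px per cm]

is fitted by ordinary least squares and used to convert measured pixel
lengths into centimetres.  The dorsal (back) camera and the lateral (side)
camera have independent optics and are never mixed; each carries its own
model and fitted distance domain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationSample",
    "ScaleModel",
    "PLATE_CM",
    "REFERENCE_MODELS",
    "mean_ratio",
    "fit_scale_model",
    "pixels_to_cm",
    "read_samples_csv",
    "write_samples_csv",
]

#: Edge length of one calibration-plate block (cm).
PLATE_CM = 7.0


@dataclass(frozen=True)
class CalibrationSample:
    """One plate observation: camera-to-plate distance and px/cm ratio."""

    distance: float  # cm
    ratio: float  # px per cm

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")


@dataclass(frozen=True)
class ScaleModel:
    """Quadratic px-per-cm scale model for one camera view."""

    view: str  # "back" | "side"
    c2: float
    c1: float
    c0: float
    r_squared: float = 1.0
    domain: tuple[float, float] = (0.0, 105.0)

    def ratio(self, distance: float) -> float:
        lo, hi = self.domain
        if not (lo <= distance <= hi):
            warnings.warn(
                f"distance {distance} cm outside the fitted {self.view} "
                f"domain [{lo}, {hi}] cm; extrapolating",
                stacklevel=2,
            )
        return self.c2 * distance**2 + self.c1 * distance + self.c0

    @classmethod
    def constant(cls, px_per_cm: float, view: str = "side") -> "ScaleModel":
        """Distance-independent model (fixed camera geometry)."""
        return cls(view=view, c2=0.0, c1=0.0, c0=px_per_cm, domain=(0.0, np.inf))

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "view": self.view,
            "c2": self.c2,
            "c1": self.c1,
            "c0": self.c0,
            "r_squared": self.r_squared,
            "domain": list(self.domain),
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ScaleModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        obj = json.loads(text)
        return cls(
            view=obj["view"],
            c2=obj["c2"],
            c1=obj["c1"],
            c0=obj["c0"],
            r_squared=obj.get("r_squared", 1.0),
            domain=tuple(obj.get("domain", (0.0, 105.0))),
        )


#: Published reference scale models for the two camera views: the dorsal
#: plate travels 0–105 cm, the lateral plate 0–50 cm.
REFERENCE_MODELS = {
    "back": ScaleModel(view="back", c2=0.0002, c1=0.0015, c0=1.9325, domain=(0.0, 105.0)),
    "side": ScaleModel(view="side", c2=0.0015, c1=0.1008, c0=21.314, domain=(0.0, 50.0)),
}


def mean_ratio(pixel_gaps, plate_cm: float = PLATE_CM) -> float:
    """Mean px-per-cm ratio from the pixel gaps between calibration blocks.

    ``(sum of gaps / n) / plate_cm`` for n recognised block gaps.
    """
    gaps = np.asarray(list(pixel_gaps), float)
    if gaps.size == 0:
        raise ValueError("at least one pixel gap is required")
    if plate_cm <= 0:
        raise ValueError("plate size must be positive")
    return float(gaps.mean() / plate_cm)


def fit_scale_model(samples, view: str) -> ScaleModel:
    """Least-squares quadratic fit of ratio against distance.

    Exact (machine precision, R² = 1) when the samples are noise-free values
    of a quadratic.  Requires at least three distinct distances.
    """
    samples = list(samples)
    d = np.array([s.distance for s in samples], float)
    r = np.array([s.ratio for s in samples], float)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct distances for a quadratic fit")
    V = np.vander(d, 3)  # columns d^2, d, 1
    coef, *_ = np.linalg.lstsq(V, r, rcond=None)
    pred = V @ coef
    ss_res = float(((r - pred) ** 2).sum())
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScaleModel(
        view=view,
        c2=float(coef[0]),
        c1=float(coef[1]),
        c0=float(coef[2]),
        r_squared=r2,
        domain=(float(d.min()), float(d.max())),
    )


def pixels_to_cm(length_px: float, distance: float, model: ScaleModel) -> float:
    """Convert a pixel length to centimetres at the given object distance."""
    ratio = model.ratio(distance)
    if ratio <= 0:
        raise ValueError(f"model ratio {ratio} px/cm is not positive at d={distance}")
    return float(length_px) / ratio


def read_samples_csv(path: str | Path) -> dict[str, list[CalibrationSample]]:
    """Read ``view,distance_cm,ratio_px_per_cm`` rows grouped by view."""
    df = pd.read_csv(path)
    out: dict[str, list[CalibrationSample]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["view"]), []).append(
            CalibrationSample(float(row["distance_cm"]), float(row["ratio_px_per_cm"]))
        )
    return out


def write_samples_csv(samples: dict[str, list[CalibrationSample]], path: str | Path) -> None:
    rows = [
        {"view": view, "distance_cm": s.distance, "ratio_px_per_cm": s.ratio}
        for view, ss in samples.items()
        for s in ss
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
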