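"""Synthetic inputs with known ground truth.

Four generators cover everything the measurement pipeline consumes:

* parametric sheep silhouettes (side and dorsal view) rendered as binary
  masks together with the true pixel location of every landmark;
* trait tables whose sex-stratified moments follow the published breed
  summary, with body weight generated from the published prediction
  equations plus residual noise;
* calibration-plate samples lying on the published per-view quadratic
  scale equations (optionally noisy);
* collection manifests with a configurable missingness pattern.

All generators are pure functions of their configuration and seed.

The silhouette is a stylised polygonal composite — monotone dorsal line
with a distinct hip and withers, raised head, pointed muzzle, brisket,
four legs, and wedge-shaped bony prominences (sciatic tuberosity, sternum,
scapular and hip-joint bulges) — not a photorealistic sheep.  Each feature
the landmark detectors look for exists at one known, sharply defined
location, so pipeline error can be measured exactly in a closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import polygon as _raster_polygon

from .biometry import PUBLISHED_EQUATIONS, REFERENCE_SUMMARY, TRAITS
from .calibration import REFERENCE_MODELS, CalibrationSample

__all__ = [
    "SheepSpec",
    "SimConfig",
    "sample_spec",
    "render_side",
    "render_dorsal",
    "generate_trait_table",
    "generate_calibration_samples",
    "generate_manifest",
]


@dataclass(frozen=True)
class SheepSpec:
    """True dimensions (cm) of one synthetic sheep plus pose parameters."""

    sex: str = "female"
    HW: float = 63.70
    HH: float = 66.33
    BSL: float = 67.50
    CD: float = 29.18
    SW: float = 20.21
    RW: float = 22.12
    shank_diameter: float = 9.01 / np.pi
    head_rise: float = 11.0  # head top above the taller of HW/HH
    nose_drop: float = 7.0  # nose tip below the head top
    head_reach: float = 16.0  # nose tip ahead of the front hoof

    def __post_init__(self) -> None:
        if self.CD >= self.HW:
            raise ValueError("chest depth must be smaller than wither height")
        if abs(self.HH - self.HW) > 0.25 * self.HW:
            raise ValueError("hip height and wither height are anatomically coupled")
        for name in ("HW", "HH", "BSL", "CD", "SW", "RW", "shank_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _summary_lookup(sex: str) -> pd.DataFrame:
    return REFERENCE_SUMMARY[REFERENCE_SUMMARY["sex"] == sex].set_index("trait")


@dataclass
class SimConfig:
    """Study conditions for the simulated population.

    Defaults reproduce the published survey: 332 animals (113 rams,
    219 ewes), sex-specific trait means and SDs, an exchangeable
    inter-trait correlation of 0.6, and body weight from the published
    sex-specific equations with residual SD equal to their reported
    standard errors of the estimate (4.49 kg ewes, 3.75 kg rams).
    """

    n: int = 332
    seed: int = 0
    male_fraction: float = 113 / 332
    rho: float = 0.6
    correlation: np.ndarray | None = None  # full 8x8 PSD matrix, optional
    bw_residual_sd: dict[str, float] = field(
        default_factory=lambda: {"female": 4.49, "male": 3.75}
    )
    bw_equation: dict[str, str] = field(
        default_factory=lambda: {"female": "ewe-3", "male": "ram-6"}
    )
    sd_scale: float = 1.0  # scales every trait SD (0 = deterministic means)
    truncate: bool = True
    px_per_cm: float = 12.0

    def corr_matrix(self) -> np.ndarray:
        if self.correlation is not None:
            C = np.asarray(self.correlation, float)
            if C.shape != (len(TRAITS), len(TRAITS)) or not np.allclose(C, C.T):
                raise ValueError("correlation must be a symmetric 8x8 matrix")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("correlation matrix is not positive semi-definite")
            return C
        C = np.full((len(TRAITS), len(TRAITS)), self.rho)
        np.fill_diagonal(C, 1.0)
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("exchangeable correlation is not PSD for this rho")
        return C


def _draw_traits(
    config: SimConfig, sex: str, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Multivariate-normal trait draws truncated at the published min/max."""
    summ = _summary_lookup(sex)
    mean = summ.loc[list(TRAITS), "mean"].to_numpy(float)
    sd = summ.loc[list(TRAITS), "sd"].to_numpy(float) * config.sd_scale
    lo = summ.loc[list(TRAITS), "min"].to_numpy(float)
    hi = summ.loc[list(TRAITS), "max"].to_numpy(float)
    cov = config.corr_matrix() * np.outer(sd, sd)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(TRAITS)))
    out = np.empty((n, len(TRAITS)))
    filled = 0
    attempts = 0
    while filled < n:
        m = max(n - filled, 16)
        z = rng.standard_normal((m, len(TRAITS)))
        x = mean + z @ chol.T
        if config.truncate:
            ok = np.all((x >= lo) & (x <= hi), axis=1)
            x = x[ok] if attempts <= 200 else np.clip(x, lo, hi)
            attempts += 1
        take = min(len(x), n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return pd.DataFrame(out, columns=list(TRAITS))


def sample_spec(config: SimConfig | None = None, seed: int | None = None) -> SheepSpec:
    """Draw one anatomically consistent :class:`SheepSpec`."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sex = "male" if rng.random() < config.male_fraction else "female"
    row = _draw_traits(config, sex, rng, 1).iloc[0]
    # keep the silhouette well-posed: CD comfortably below HW, HH near HW
    cd = min(float(row["CD"]), 0.58 * float(row["HW"]))
    hh = float(np.clip(row["HH"], row["HW"] - 2.0, row["HW"] + 6.0))
    return SheepSpec(
        sex=sex,
        HW=float(row["HW"]),
        HH=hh,
        BSL=float(row["BSL"]),
        CD=cd,
        SW=float(row["SW"]),
        RW=float(row["RW"]),
        shank_diameter=float(row["SC"]) / np.pi,
        head_rise=float(rng.uniform(10.5, 11.5)),
        nose_drop=float(rng.uniform(6.5, 7.5)),
        head_reach=float(rng.uniform(15.0, 17.0)),
    )


# ---------------------------------------------------------------------------
# rendering


def _rasterize(points_cm: np.ndarray, px_per_cm: float, margin: int = 30):
    """Rasterise a closed (x, h) polygon; h is height above ground (up)."""
    pts = np.asarray(points_cm, float)
    x0 = pts[:, 0].min()
    x_px = (pts[:, 0] - x0) * px_per_cm + margin
    ground_y = int(round(pts[:, 1].max() * px_per_cm)) + margin
    y_px = ground_y - pts[:, 1] * px_per_cm
    shape = (int(np.ceil(y_px.max())) + margin, int(np.ceil(x_px.max())) + margin)
    mask = np.zeros(shape, bool)
    rr, cc = _raster_polygon(y_px, x_px, shape=shape)
    mask[rr, cc] = True

    def to_px(p):
        return (
            int(round((p[0] - x0) * px_per_cm + margin)),
            int(round(ground_y - p[1] * px_per_cm)),
        )

    return mask, ground_y, to_px


def render_side(
    spec: SheepSpec, px_per_cm: float = 12.0
) -> tuple[np.ndarray, dict]:
    """Render the side-view silhouette (facing right) with ground truth.

    Returns ``(mask, meta)``; ``meta["landmarks"]`` maps each landmark name
    to its true pixel coordinates, and ``meta`` also carries ``ground_y``,
    ``shank_diameter_px``, ``px_per_cm`` and the generating spec.
    """
    HW, HH, CD, BSL = spec.HW, spec.HH, spec.CD, spec.BSL
    d = spec.shank_diameter
    h_head = max(HW, HH) + spec.head_rise
    h_nose = h_head - spec.nose_drop
    x_nose = spec.head_reach  # front hoof leading edge is x = 0
    h_mid = HW - CD / 2.0
    # The brisket apex sits just behind the nose→hoof chord, making it the
    # unique interior closest approach used for the chest-front landmark.
    x_a = x_nose * h_mid / h_nose - 0.8
    x_S = x_a - BSL  # sciatic apex (BSL runs horizontally)
    x_P = x_S + 7.0  # hip top
    x_W = x_a - 12.0  # withers
    h_belly = HW - CD
    width = x_nose - x_S  # silhouette bbox width
    x_B = x_S + 0.555 * width  # sternum wedge, centred in its search window
    x_head = x_nose - 5.5  # head apex
    x_rear = x_S + max(9.0, 0.125 * width)  # rear-leg trailing edge

    hip = (x_P, HH)
    withers = (x_W, HW)
    # shallow loin dip at the hip-window edge: keeps the hip a local maximum
    # there while staying nearer the hip↔head chord than the withers
    loin = (x_S + 0.45 * width, min(HH, HW) - 0.4)
    # clockwise in image coordinates, starting at the hip
    poly = [
        hip,
        loin,
        withers,  # dorsal dip; kink at the withers
        (x_head, h_head),  # neck line up to the head apex
        (x_head + 3.0, h_head - 1.8),  # crown falling toward the face
        (x_nose - 1.6, h_nose + 1.6),
        (x_nose, h_nose),  # pointed muzzle (≈45° wedge)
        (x_nose - 1.6, h_nose - 1.6),
        # throat: at least 2 cm behind the nose→hoof chord so the brisket
        # stays the unique closest interior approach
        (min(x_a + 2.0, x_nose * (h_nose - 7.0) / h_nose - 2.0), h_nose - 7.0),
        (x_a - 1.8, h_mid + 3.0),  # neck front
        (x_a, h_mid),  # brisket apex (chest front)
        (x_a - 1.8, h_mid - 3.0),
        (0.0, 0.8 * h_belly),  # armpit → front-leg leading edge (top stays
        (0.0, 0.0),  # above the shank measuring row at 2/3 belly height)
        (-d, 0.0),
        (-d, h_belly + 4.2),  # front-leg trailing edge
        (x_B + 3.2, h_belly + 4.2),  # level belly into the sternum wedge
        (x_B, h_belly),  # sternum wedge (chest bottom)
        (x_B - 3.2, h_belly + 4.2),
        (x_rear + d, h_belly + 4.2),  # level belly → rear leg
        (x_rear + d, 0.0),
        (x_rear, 0.0),
        (x_rear, min(28.0, h_belly + 2.0)),
        (x_S + 1.8, h_mid - 3.0),  # cove up the rump
        (x_S, h_mid),  # sciatic tuberosity wedge
        (x_S + 1.8, h_mid + 3.0),  # rump back up to the hip (steep arrival)
    ]
    mask, ground_y, to_px = _rasterize(np.array(poly), px_per_cm)
    truth = {
        "head_vertex": to_px((x_head, h_head)),
        "front_hoof": to_px((0.0, 0.0)),
        "facial_vertex": to_px((x_nose, h_nose)),
        "hip_top": to_px(hip),
        "withers": to_px(withers),
        "chest_front": to_px((x_a, h_mid)),
        "sciatic_tuberosity": to_px((x_S, h_mid)),
        "chest_bottom": to_px((x_B, h_belly)),
    }
    return mask, {
        "view": "side",
        "landmarks": truth,
        "ground_y": ground_y,
        "shank_diameter_px": d * px_per_cm,
        "px_per_cm": px_per_cm,
        "spec": spec,
    }


def render_dorsal(
    spec: SheepSpec, px_per_cm: float = 12.0
) -> tuple[np.ndarray, dict]:
    """Render the dorsal silhouette (head to the right) with ground truth.

    The torso has a flat base half-width with wedge-shaped lateral bulges
    at the scapulae and the hip joints, so the curvature maxima on each
    side sit exactly at the true SW/RW extremes.
    """
    SW, RW, BSL = spec.SW, spec.RW, spec.BSL
    L = 1.05 * BSL
    neck_len, head_len = 7.0, 13.0
    w0 = min(SW, RW) / 2.0 - 2.2  # base half-width
    x_sh, x_r, arm = 0.72 * L, 0.20 * L, 3.0

    def upper_half(sign: float) -> list[tuple[float, float]]:
        pts = [
            (0.0, sign * w0),
            (x_r - arm, sign * w0),
            (x_r, sign * RW / 2.0),  # hip-joint wedge
            (x_r + arm, sign * w0),
            (x_sh - arm, sign * w0),
            (x_sh, sign * SW / 2.0),  # scapular wedge
            (x_sh + arm, sign * w0),
            (0.9 * L, sign * w0),
            (L, sign * 4.0),  # taper into the neck
            (L + neck_len, sign * 4.0),
        ]
        return pts

    # head capsule: straight sides, semicircular snout
    hc = L + neck_len + head_len - 4.0
    t = np.linspace(np.pi / 2, -np.pi / 2, 45)
    snout = [(hc + 4.0 * np.cos(a), 4.0 * np.sin(a)) for a in t]
    # rounded tail cap (quarter-ellipses meeting at the tail tip)
    t2 = np.linspace(np.pi / 2, 3 * np.pi / 2, 45)
    tail = [(2.2 * np.cos(a), -w0 * np.sin(a)) for a in t2]

    upper = upper_half(+1.0)
    lower = [(hc, -4.0)] + upper_half(-1.0)[::-1]
    poly = np.array(upper + [(hc, 4.0)] + snout + lower + tail)
    mask, _, to_px = _rasterize(poly, px_per_cm)
    truth = {
        "shoulder_left": to_px((x_sh, SW / 2.0)),
        "shoulder_right": to_px((x_sh, -SW / 2.0)),
        "rump_left": to_px((x_r, RW / 2.0)),
        "rump_right": to_px((x_r, -RW / 2.0)),
    }
    return mask, {
        "view": "dorsal",
        "landmarks": truth,
        "px_per_cm": px_per_cm,
        "spec": spec,
    }


# ---------------------------------------------------------------------------
# tables, calibration samples, manifests


def generate_trait_table(config: SimConfig | None = None) -> pd.DataFrame:
    """Simulate a trait table with body weight from the published equations.

    Traits are multivariate-normal per sex (published means/SDs,
    exchangeable correlation, truncated at the published min/max); BW is
    the sex-specific published linear predictor plus Normal(0, SE) noise.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n_male = int(round(config.n * config.male_fraction))
    frames = []
    for sex, n in (("male", n_male), ("female", config.n - n_male)):
        if n == 0:
            continue
        df = _draw_traits(config, sex, rng, n)
        eq = PUBLISHED_EQUATIONS[config.bw_equation[sex]]
        linpred = df.apply(lambda r: eq.predict(r.to_dict()), axis=1)
        df.insert(0, "BW", linpred + rng.normal(0.0, config.bw_residual_sd[sex], n))
        df.insert(0, "sex", sex)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "animal_id", [f"A{i:04d}" for i in range(len(out))])
    return out


def generate_calibration_samples(
    view: str,
    heights=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationSample]:
    """Plate samples on the published per-view quadratic scale equation.

    Default heights step 5 cm across the view's plate travel (0–105 cm
    back, 0–50 cm side), matching the published calibration protocol.
    """
    model = REFERENCE_MODELS[view]
    if heights is None:
        heights = np.arange(model.domain[0], model.domain[1] + 1e-9, 5.0)
    rng = np.random.default_rng(seed)
    out = []
    for h in np.asarray(heights, float):
        r = model.ratio(h) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        out.append(CalibrationSample(distance=float(h), ratio=float(r)))
    return out


def generate_manifest(
    n_total: int,
    n_unrecorded: int,
    n_missing_weight: int,
    n_missing_size: int,
    seed: int = 0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """A collection manifest with the given missingness pattern.

    Disjoint random records are marked unrecorded, stripped of weight, or
    stripped of one body-size trait.
    """
    if n_unrecorded + n_missing_weight + n_missing_size > n_total:
        raise ValueError("missingness counts exceed the total record count")
    cfg = replace(config or SimConfig(), n=n_total, seed=seed)
    df = generate_trait_table(cfg)
    rng = np.random.default_rng(seed + 1)
    idx = rng.permutation(n_total)
    a = n_unrecorded
    b = a + n_missing_weight
    c = b + n_missing_size
    df["recorded"] = True
    df.loc[idx[:a], "recorded"] = False
    df.loc[idx[a:b], "BW"] = np.nan
    for i in idx[b:c]:
        df.loc[i, rng.choice(TRAITS)] = np.nan
    return df
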