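"""Synthetic periorbital images and cohort tables with known ground truth.

Two generators:

* :func:`generate_periorbital_image` renders a schematic face patch -- a
  noisy skin-toned canvas with dark curvilinear wrinkles (Gaussian
  cross-section along quadratic Bezier centerlines, the morphology a ridge
  detector is built for) and dark elliptical pigmented spots -- together
  with the landmark set and pixel-exact ground-truth masks.

* :func:`generate_cohort` draws per-subject tables matching the study
  design the analysis assumes: exact per-decade sample counts, seven skin
  indices generated from a single age factor with configurable feature-age
  correlations, binary disease-history flags from per-disease logistic
  models in age, and lifestyle covariates.

Both are bit-reproducible given their spec/config (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet
from .image_features import region_box, REGIONS, SIDES

__all__ = [
    "FaceImageSpec",
    "WrinkleSpec",
    "SpotSpec",
    "GroundTruth",
    "generate_periorbital_image",
    "CohortConfig",
    "generate_cohort",
    "build_cohort_config",
    "validation_cohort_config",
    "DEFAULT_FEATURE_AGE_CORR",
    "DEFAULT_DISEASE_MODELS",
    "FEATURE_NAMES",
    "DISEASE_CODES",
]

FEATURE_NAMES = ("Wb", "Wu", "Wa", "Pb", "Pu", "Md", "Mw")
DISEASE_CODES = ("D1", "D2", "D3", "D4", "D5", "D6", "D7")

#: Cohort design targets: Pearson correlation of each index with age.
#: Pigmented spots correlate most strongly, wrinkles moderately, and the
#: morphological indices least (droopiness Md much weaker than width Mw).
DEFAULT_FEATURE_AGE_CORR: dict[str, float] = {
    "Wb": 0.588,
    "Wu": 0.603,
    "Wa": 0.584,
    "Pb": 0.723,
    "Pu": 0.758,
    "Md": 0.174,
    "Mw": 0.518,
}

#: Per-disease logistic models in age: (prevalence at age 45, log-odds slope
#: per year). Heart disease (D1) and cancer (D7) are kept age-independent
#: and rare; the chronic metabolic conditions rise with age. These are
#: stated modelling assumptions of the generator, not measured quantities.
DEFAULT_DISEASE_MODELS: dict[str, tuple[float, float]] = {
    "D1": (0.03, 0.00),   # heart disease
    "D2": (0.12, 0.08),   # high blood pressure
    "D3": (0.10, 0.06),   # hyperlipidemia
    "D4": (0.10, 0.05),   # fatty liver
    "D5": (0.08, 0.05),   # kidney disease
    "D6": (0.05, 0.06),   # diabetes
    "D7": (0.03, 0.00),   # cancer
}


# ---------------------------------------------------------------------------
# image generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FaceImageSpec:
    """Parameters of one synthetic periorbital face patch.

    Layout parameters are fractions of the (square) canvas size so the same
    spec scales across resolutions. Identical spec + seed gives bit-identical
    output.
    """

    canvas_size: int = 256
    base_intensity: float = 180.0
    noise_amplitude: float = 3.0

    wrinkle_count: int = 6
    wrinkle_depth: float = 35.0
    wrinkle_width: float = 3.0
    #: restrict wrinkle placement to these "{side}_{region}" slots
    #: (None = cycle deterministically through all six region/side slots)
    wrinkle_regions: tuple[str, ...] | None = None

    spot_count: int = 6
    spot_radius_range: tuple[float, float] = (2.5, 6.0)
    spot_depth: float = 30.0

    # landmark layout (fractions of canvas size)
    eye_center_y: float = 0.42
    eye_offset_x: float = 0.16     # eye centers at 0.5 -+ offset
    eye_half_width: float = 0.08
    canthus_droop: float = 0.012   # lateral canthus sits this much lower
    eyebrow_height: float = 0.11   # eyebrow line above the eye line
    eyebrow_arch: float = 0.03
    eyelid_drop: float = 0.035     # eyelid line below the eye line
    outline_margin: float = 0.06   # facial-outline x-extent from the border
    cheek_drop: float = 0.17

    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_size < 128:
            raise ValueError("canvas must be at least 128 px square")
        if self.wrinkle_count < 0 or self.spot_count < 0:
            raise ValueError("wrinkle/spot counts must be >= 0")
        if self.spot_radius_range[0] > self.spot_radius_range[1]:
            raise ValueError("spot radius range must be (min, max)")


@dataclass(frozen=True)
class WrinkleSpec:
    """Analytic description of one rendered wrinkle (quadratic Bezier)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    p2: tuple[float, float]
    width: float
    depth: float
    slot: str  # "{side}_{region}"

    def sample(self, n: int = 400) -> np.ndarray:
        """Dense points along the Bezier centerline, shape (n, 2)."""
        t = np.linspace(0.0, 1.0, n)[:, None]
        p0, p1, p2 = (np.asarray(p, dtype=float) for p in (self.p0, self.p1, self.p2))
        return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


@dataclass(frozen=True)
class SpotSpec:
    """Analytic description of one rendered pigmented spot (ellipse)."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float
    depth: float
    slot: str


@dataclass
class GroundTruth:
    """Pixel-exact ground truth for one synthetic face patch."""

    wrinkle_mask: np.ndarray          # full-width footprint (bool)
    wrinkle_centerline: np.ndarray    # 1-px centerline raster (bool)
    spot_mask: np.ndarray             # ellipse footprints (bool)
    region_wrinkle_masks: dict[str, np.ndarray] = field(default_factory=dict)
    wrinkles: list[WrinkleSpec] = field(default_factory=list)
    spots: list[SpotSpec] = field(default_factory=list)


def _face_landmarks(spec: FaceImageSpec) -> LandmarkSet:
    n = spec.canvas_size
    eye_y = spec.eye_center_y * n
    points: dict[str, np.ndarray] = {}
    lines: dict[str, np.ndarray] = {}

    for side, sign in (("left", -1.0), ("right", 1.0)):
        cx = (0.5 + sign * spec.eye_offset_x) * n
        half = spec.eye_half_width * n
        medial_x = cx - sign * half
        lateral_x = cx + sign * half
        points[f"{side}_medial_canthus"] = np.array([medial_x, eye_y])
        points[f"{side}_lateral_canthus"] = np.array([lateral_x, eye_y + spec.canthus_droop * n])
        points[f"{side}_cheek"] = np.array([cx, eye_y + spec.cheek_drop * n])

        brow_y = eye_y - spec.eyebrow_height * n
        xs = medial_x + (lateral_x - medial_x) * np.linspace(0, 1, 5)
        arch = spec.eyebrow_arch * n * np.sin(np.pi * np.linspace(0, 1, 5))
        lines[f"{side}_eyebrow"] = np.column_stack([xs, brow_y - arch])

        lid_y = eye_y + spec.eyelid_drop * n
        sag = 0.01 * n * np.sin(np.pi * np.linspace(0, 1, 5))
        lines[f"{side}_eyelid"] = np.column_stack([xs, lid_y + sag])

        outline_x = (0.5 + sign * (0.5 - spec.outline_margin)) * n
        ys = np.linspace(0.30 * n, 0.68 * n, 5)
        bow = sign * 0.015 * n * np.sin(np.pi * (ys - ys[0]) / (ys[-1] - ys[0]))
        lines[f"{side}_outline"] = np.column_stack([outline_x + bow, ys])

    lm = LandmarkSet(points=points, lines=lines, image_size=(n, n))
    for side in SIDES:
        lat = lm.point(f"{side}_lateral_canthus")
        lm.points[f"{side}_temple"] = np.array(
            [lm.interp_line_x(f"{side}_outline", float(lat[1])), float(lat[1])]
        )
    lm.validate()
    return lm


def _stamp_gaussian_line(canvas: np.ndarray, pts: np.ndarray, depth: float, sigma: float) -> None:
    """Darkening from a Gaussian-profile line along `pts` (max-combined in place)."""
    h, w = canvas.shape
    r = max(2, int(np.ceil(3 * sigma)))
    for x, y in pts:
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
        y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        gy, gx = np.mgrid[y0:y1, x0:x1]
        d2 = (gx - x) ** 2 + (gy - y) ** 2
        patch = depth * np.exp(-d2 / (2 * sigma**2))
        np.maximum(canvas[y0:y1, x0:x1], patch, out=canvas[y0:y1, x0:x1])


def _all_slots() -> list[str]:
    return [f"{side}_{region}" for region in REGIONS for side in SIDES]


def _placement_box(lm: LandmarkSet, slot: str, pad: float, n: int) -> tuple[float, float, float, float]:
    side, region = slot.split("_", 1)
    x0, y0, x1, y1 = region_box(lm, region, side, margin=0, image_shape=(n, n))
    x0, y0, x1, y1 = x0 + pad, y0 + pad, x1 - pad, y1 - pad
    if x1 - x0 < 4 or y1 - y0 < 4:
        raise ValueError(
            f"canvas too small to place structures in {slot}: placement box "
            f"after a {pad:.0f}-px safety pad is below 4x4 px"
        )
    return x0, y0, x1, y1


def generate_periorbital_image(
    spec: FaceImageSpec,
) -> tuple[np.ndarray, LandmarkSet, GroundTruth]:
    """Render one synthetic periorbital face patch.

    Returns ``(image, landmarks, ground_truth)`` where image is a uint8
    grayscale-valued 3-channel raster (H, W, 3). Wrinkles are quadratic
    Bezier valleys of Gaussian cross-section; spots are smooth dark
    ellipses. The ground-truth wrinkle mask is the half-depth footprint
    (pixels within half a width of the centerline); the centerline mask is
    the 1-px rasterized Bezier curve.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas_size
    lm = _face_landmarks(spec)

    slots = list(spec.wrinkle_regions) if spec.wrinkle_regions else _all_slots()
    for slot in slots:
        side, region = slot.split("_", 1)
        if side not in SIDES or region not in REGIONS:
            raise ValueError(f"unknown wrinkle slot {slot!r}")

    wrinkle_dark = np.zeros((n, n))
    centerline = np.zeros((n, n), dtype=bool)
    region_masks: dict[str, np.ndarray] = {}
    wrinkles: list[WrinkleSpec] = []
    sigma_w = spec.wrinkle_width / 2.0

    for i in range(spec.wrinkle_count):
        slot = slots[i % len(slots)]
        bx0, by0, bx1, by1 = _placement_box(lm, slot, pad=spec.wrinkle_width + 2, n=n)
        wide = (bx1 - bx0) >= (by1 - by0)
        # endpoints near opposite sides of the box's long axis, jittered
        if wide:
            ya, yb = rng.uniform(by0, by1, 2)
            p0 = (bx0 + rng.uniform(0, 0.15) * (bx1 - bx0), ya)
            p2 = (bx1 - rng.uniform(0, 0.15) * (bx1 - bx0), yb)
        else:
            xa, xb = rng.uniform(bx0, bx1, 2)
            p0 = (xa, by0 + rng.uniform(0, 0.15) * (by1 - by0))
            p2 = (xb, by1 - rng.uniform(0, 0.15) * (by1 - by0))
        mid = (np.asarray(p0) + np.asarray(p2)) / 2
        chord = np.asarray(p2) - np.asarray(p0)
        norm = np.linalg.norm(chord)
        perp = np.array([-chord[1], chord[0]]) / max(norm, 1e-9)
        bow = rng.uniform(-0.18, 0.18) * norm
        p1 = np.clip(mid + bow * perp, [bx0, by0], [bx1, by1])

        wr = WrinkleSpec(
            p0=tuple(map(float, p0)),
            p1=tuple(map(float, p1)),
            p2=tuple(map(float, p2)),
            width=spec.wrinkle_width,
            depth=spec.wrinkle_depth,
            slot=slot,
        )
        wrinkles.append(wr)

        this_dark = np.zeros((n, n))
        pts = wr.sample(int(max(100, 4 * norm)))
        _stamp_gaussian_line(this_dark, pts, spec.wrinkle_depth, sigma_w)
        np.maximum(wrinkle_dark, this_dark, out=wrinkle_dark)

        footprint = this_dark >= spec.wrinkle_depth * np.exp(-0.5)
        region_masks.setdefault(slot, np.zeros((n, n), dtype=bool))
        region_masks[slot] |= footprint

        ij = np.round(pts).astype(int)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < n) & (ij[:, 1] >= 0) & (ij[:, 1] < n)
        centerline[ij[ok, 1], ij[ok, 0]] = True

    wrinkle_mask = wrinkle_dark >= spec.wrinkle_depth * np.exp(-0.5) if spec.wrinkle_count else np.zeros((n, n), dtype=bool)

    # spots live in the device-measured regions (beside / under the eyes)
    spot_slots = [s for s in (spec.wrinkle_regions or _all_slots()) if not s.endswith("above_inner_corner")]
    if not spot_slots:
        spot_slots = [f"{side}_{region}" for region in ("beside_eye", "under_eye") for side in SIDES]
    spot_dark = np.zeros((n, n))
    spot_mask = np.zeros((n, n), dtype=bool)
    spots: list[SpotSpec] = []
    for i in range(spec.spot_count):
        slot = spot_slots[i % len(spot_slots)]
        rmax_allowed = spec.spot_radius_range[1]
        bx0, by0, bx1, by1 = _placement_box(lm, slot, pad=rmax_allowed + 1, n=n)
        cx, cy = rng.uniform(bx0, bx1), rng.uniform(by0, by1)
        a = rng.uniform(*spec.spot_radius_range)
        b = a * rng.uniform(0.7, 1.0)
        theta = rng.uniform(0, np.pi)
        sp = SpotSpec(center=(float(cx), float(cy)), semi_major=float(a),
                      semi_minor=float(b), angle=float(theta),
                      depth=spec.spot_depth, slot=slot)
        spots.append(sp)

        r = int(np.ceil(a)) + 1
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, n)
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, n)
        gy, gx = np.mgrid[y0:y1, x0:x1]
        dx, dy = gx - cx, gy - cy
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
        q = u**2 + v**2
        inside = q <= 1.0
        spot_mask[y0:y1, x0:x1] |= inside
        profile = spec.spot_depth * np.sqrt(np.clip(1.0 - q, 0.0, 1.0))
        np.maximum(spot_dark[y0:y1, x0:x1], profile, out=spot_dark[y0:y1, x0:x1])

    img = (
        spec.base_intensity
        - np.maximum(wrinkle_dark, spot_dark)
        + spec.noise_amplitude * rng.standard_normal((n, n))
    )
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = np.repeat(img[:, :, None], 3, axis=2)

    truth = GroundTruth(
        wrinkle_mask=wrinkle_mask,
        wrinkle_centerline=centerline,
        spot_mask=spot_mask,
        region_wrinkle_masks=region_masks,
        wrinkles=wrinkles,
        spots=spots,
    )
    return image, lm, truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic cohort table.

    ``n_per_decade`` subjects are drawn per 10-year interval over
    ``age_range`` with exact counts (the model-building design uses 400 per
    decade over ages 20-69; the independent validation design uses 103).
    Feature i is generated from a single age factor,
    ``x_i = r_i * z(age) + sqrt(1 - r_i**2) * eps_i`` with independent
    standard-normal noise, then affinely mapped onto the 0-100 score scale
    over +-4 latent standard deviations and clipped. Features are therefore
    conditionally independent given age, which is what makes the
    closed-form multiple-correlation oracle for the age models exact.
    """

    n_per_decade: int = 400
    age_range: tuple[int, int] = (20, 70)
    feature_age_corr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_AGE_CORR)
    )
    disease_models: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_MODELS)
    )
    sun_hours_log_mean: float = 1.8   # lognormal weekly sun-exposure hours
    sun_hours_log_sd: float = 0.5
    sunscreen_probs: tuple[float, ...] = (0.15, 0.20, 0.30, 0.20, 0.15)  # ordinal 0..4
    smoker_rate: float = 0.10
    id_prefix: str = "S"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in self.feature_age_corr.items():
            if not abs(r) < 1:
                raise ValueError(f"feature-age correlation for {name} must satisfy |r| < 1, got {r}")
        lo, hi = self.age_range
        if hi <= lo or (hi - lo) % 10 != 0:
            raise ValueError("age range must span a positive whole number of decades")
        if self.n_per_decade <= 0:
            raise ValueError("n_per_decade must be positive")

    @property
    def decades(self) -> list[tuple[int, int]]:
        lo, hi = self.age_range
        return [(d, d + 10) for d in range(lo, hi, 10)]

    @property
    def n_total(self) -> int:
        return self.n_per_decade * len(self.decades)


def build_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Model-building design: 400 per decade, ages 20-69 (n = 2,000)."""
    return CohortConfig(n_per_decade=400, seed=seed, id_prefix="B", **overrides)


def validation_cohort_config(seed: int = 1, **overrides) -> CohortConfig:
    """Independent validation design: 103 per decade, ages 20-69 (n = 515)."""
    return CohortConfig(n_per_decade=103, seed=seed, id_prefix="V", **overrides)


def _latent_to_score(x: np.ndarray) -> np.ndarray:
    # affine map of a ~N(0,1) latent onto [0, 100] over +-4 SD, clipped
    return np.clip(50.0 + 12.5 * x, 0.0, 100.0)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one cohort table.

    Columns: id, age, the seven indices (0-100), D1..D7 and the derived D0
    (any disease), sun_hours, sunscreen_freq, smoker.
    """
    rng = np.random.default_rng(config.seed)
    # round within each decade so reported 2-decimal ages keep counts exact
    ages = np.concatenate(
        [
            np.clip(np.round(rng.uniform(lo, hi, config.n_per_decade), 2), lo, hi - 0.01)
            for lo, hi in config.decades
        ]
    )
    order = rng.permutation(ages.size)
    ages = ages[order]
    n = ages.size

    lo, hi = config.age_range
    z_age = (ages - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))

    data: dict[str, np.ndarray] = {
        "id": np.array([f"{config.id_prefix}{i:05d}" for i in range(n)]),
        "age": ages,
    }
    for name in FEATURE_NAMES:
        r = config.feature_age_corr.get(name, 0.0)
        latent = r * z_age + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
        data[name] = _latent_to_score(latent)

    any_disease = np.zeros(n, dtype=int)
    for code in DISEASE_CODES:
        prev45, slope = config.disease_models[code]
        logit0 = np.log(prev45 / (1.0 - prev45))
        p = 1.0 / (1.0 + np.exp(-(logit0 + slope * (ages - 45.0))))
        flag = (rng.uniform(size=n) < p).astype(int)
        data[code] = flag
        any_disease |= flag

    data["sun_hours"] = np.round(
        rng.lognormal(config.sun_hours_log_mean, config.sun_hours_log_sd, n), 2
    )
    data["sunscreen_freq"] = rng.choice(
        len(config.sunscreen_probs), size=n, p=np.asarray(config.sunscreen_probs)
    )
    data["smoker"] = (rng.uniform(size=n) < config.smoker_rate).astype(int)
    data["D0"] = any_disease

    df = pd.DataFrame(data)
    for name in FEATURE_NAMES:
        df[name] = df[name].round(3)
    return df
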