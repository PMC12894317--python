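"""Periorbital image features: ROI cropping, ridge-based wrinkle detection, scoring.

The wrinkle path follows the classic pipeline for fine-line quantification:
crop the region of interest from facial landmarks, convert to grayscale, run
a multi-scale Hessian-eigenvalue ridge filter tuned to dark line-like
structure, enhance the response with a radial band-pass / magnitude gate in
the Fourier domain, and report the detected-area fraction mapped onto a
0-100 score. Pigmented spots are scored by background-subtraction blob
detection. Score calibration (the affine map from raw area fraction to the
0-100 scale) is estimated from a cohort of patches and persisted as JSON.

Coordinates are pixel-based, origin top-left, x right, y down, 0-based; all
ROI boxes are half-open ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from .landmarks import LandmarkSet, LandmarkError

REGIONS = ("beside_eye", "under_eye", "above_inner_corner")
SIDES = ("left", "right")


# ---------------------------------------------------------------------------
# parameters and calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RidgeParams:
    """Parameters of the multi-scale Hessian ridge filter.

    sigmas : smoothing scales in pixels (>= 1), ascending; the response is
        the per-pixel maximum over scales of the sigma**2-normalized ridge
        measure.
    threshold : binarization level as a fraction of the response maximum,
        in (0, 1); used when turning a response map into "detected area".
    beta : blob-suppression weight of the eigenvalue-ratio term.
    gamma_frac : the structure-strength half-saturation constant is set to
        this fraction of the maximum Hessian Frobenius norm at each scale.
    """

    sigmas: tuple[float, ...] = (1.0, 1.5, 2.0)
    threshold: float = 0.2
    beta: float = 0.5
    gamma_frac: float = 0.5

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sigmas):
            raise ValueError("ridge scales must be >= 1 px")
        if list(self.sigmas) != sorted(self.sigmas):
            raise ValueError("ridge scales must be sorted ascending")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class BandParams:
    """Radial frequency band for Fourier enhancement, in pixel wavelengths.

    Structure with wavelengths in ``[low_wavelength, high_wavelength]`` is
    kept; everything else except the DC (mean) coefficient is zeroed, and
    retained coefficients whose magnitude falls below ``percentile`` of the
    retained-band magnitude distribution are zeroed as well.
    """

    low_wavelength: float = 2.0
    high_wavelength: float = 32.0
    percentile: float = 98.0

    def __post_init__(self) -> None:
        if self.low_wavelength >= self.high_wavelength:
            raise ValueError("band lower wavelength must be < upper wavelength")
        if not 0 <= self.percentile < 100:
            raise ValueError("percentile must be in [0, 100)")


@dataclass
class ScoreCalibration:
    """Affine calibration of a raw area fraction onto the 0-100 score scale.

    ``lower`` maps to 0 and ``upper`` to 100; scores are clipped to [0, 100].
    ``kind`` is "wrinkle", "spot" or "morphology"; ``region`` names the ROI
    (or index) it applies to; ``provenance`` records which cohort produced it.
    """

    kind: str
    region: str
    lower: float
    upper: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"degenerate calibration for {self.kind}/{self.region}: "
                f"lower ({self.lower!r}) must be < upper ({self.upper!r})"
            )

    def apply(self, raw: float | np.ndarray) -> float | np.ndarray:
        score = 100.0 * (np.asarray(raw, dtype=float) - self.lower) / (self.upper - self.lower)
        out = np.clip(score, 0.0, 100.0)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreCalibration":
        return cls(**d)


class CalibrationStore:
    """A persistable collection of :class:`ScoreCalibration` objects."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], ScoreCalibration] = {}

    def add(self, calib: ScoreCalibration) -> None:
        self._store[(calib.kind, calib.region)] = calib

    def get(self, kind: str, region: str) -> ScoreCalibration:
        try:
            return self._store[(kind, region)]
        except KeyError:
            raise KeyError(
                f"no calibration for kind={kind!r} region={region!r}; "
                "run calibrate_scores on a reference cohort first"
            ) from None

    def __len__(self) -> int:
        return len(self._store)

    def __iter__(self):
        return iter(self._store.values())

    def save(self, path: str | Path) -> None:
        payload = [c.to_dict() for _, c in sorted(self._store.items())]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationStore":
        store = cls()
        for d in json.loads(Path(path).read_text()):
            store.add(ScoreCalibration.from_dict(d))
        return store


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def _region_extent(landmarks: LandmarkSet, region: str, side: str) -> tuple[float, float, float, float]:
    """Inclusive coordinate extent (xmin, ymin, xmax, ymax) of a region."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")

    if region == "above_inner_corner":
        brow = landmarks.line(f"{side}_eyebrow")
        lid = landmarks.line(f"{side}_eyelid")
        pts = np.vstack([brow, lid])
        return pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max()

    cheek = landmarks.point(f"{side}_cheek")
    if region == "under_eye":
        lid = landmarks.line(f"{side}_eyelid")
        return lid[:, 0].min(), lid[:, 1].max(), lid[:, 0].max(), cheek[1]

    # beside_eye: between the lateral canthus and the facial outline (temple)
    lat = landmarks.point(f"{side}_lateral_canthus")
    temple = landmarks.point(f"{side}_temple")
    brow = landmarks.line(f"{side}_eyebrow")
    x0, x1 = sorted((float(temple[0]), float(lat[0])))
    y0 = min(float(brow[:, 1].max()), float(lat[1]))
    return x0, y0, x1, float(cheek[1])


def region_box(
    landmarks: LandmarkSet,
    region: str,
    side: str,
    margin: int = 0,
    image_shape: tuple[int, int] | None = None,
) -> tuple[int, int, int, int]:
    """Half-open integer pixel box ``(x0, y0, x1, y1)`` for a periorbital region.

    The box is the axis-aligned bounding box of the region's defining
    landmarks, expanded by ``margin`` pixels and clipped to the image when
    ``image_shape`` (height, width) is given.
    """
    xmin, ymin, xmax, ymax = _region_extent(landmarks, region, side)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate (zero-area) region polygon for {side} {region}")
    x0 = int(np.floor(xmin)) - margin
    y0 = int(np.floor(ymin)) - margin
    x1 = int(np.floor(xmax)) + 1 + margin
    y1 = int(np.floor(ymax)) + 1 + margin
    if image_shape is not None:
        h, w = image_shape
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
    return x0, y0, x1, y1


def crop_periorbital_roi(
    image: np.ndarray,
    landmarks: LandmarkSet,
    region: str,
    side: str = "left",
    margin: int = 2,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop one periorbital region from an image.

    Returns the patch and the half-open box ``(x0, y0, x1, y1)`` it was cut
    from, for traceability. Missing landmarks raise :class:`LandmarkError`
    naming the point; a zero-area region polygon raises ``ValueError``.
    """
    box = region_box(landmarks, region, side, margin=margin, image_shape=image.shape[:2])
    x0, y0, x1, y1 = box
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty crop box {box} for {side} {region}")
    return image[y0:y1, x0:x1, ...], box


# ---------------------------------------------------------------------------
# grayscale and ridge response
# ---------------------------------------------------------------------------

#: ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(patch: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel patch to a float grayscale patch in [0, 255]."""
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.ndim == 2:
        return patch.astype(float)
    if patch.ndim == 3 and patch.shape[2] == 1:
        return patch[:, :, 0].astype(float)
    if patch.ndim == 3 and patch.shape[2] == 3:
        return patch.astype(float) @ _LUMA
    raise ValueError(f"expected 1- or 3-channel raster, got shape {patch.shape}")


def hessian_ridge_response(gray: np.ndarray, params: RidgeParams = RidgeParams()) -> np.ndarray:
    """Multi-scale Hessian-eigenvalue response to dark, line-like structure.

    At each scale sigma the image is Gaussian-smoothed and the Hessian
    computed with sigma**2-normalized derivatives. With eigenvalues ordered
    |l1| <= |l2|, the response combines a blob-suppression term in the ratio
    l1/l2 with a structure-strength term in the Hessian Frobenius norm, and
    is zeroed where l2 <= 0 (bright ridges; a dark line is an intensity
    valley, so its cross-line second derivative is positive). The output is
    the maximum over scales rescaled to [0, 1].
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("ridge filter expects a 2-D grayscale patch")
    smax = max(params.sigmas)
    if min(gray.shape) < 2 * smax:
        raise ValueError(
            f"patch {gray.shape} smaller than kernel support (needs >= {2 * smax:.0f} px per side)"
        )

    # remove the mean so a constant intensity offset cannot leak through the
    # truncated derivative kernels: the response depends on structure only
    gray = gray - gray.mean()

    response = np.zeros_like(gray)
    for sigma in params.sigmas:
        norm = sigma**2
        hxx = norm * ndimage.gaussian_filter(gray, sigma, order=(0, 2))
        hyy = norm * ndimage.gaussian_filter(gray, sigma, order=(2, 0))
        hxy = norm * ndimage.gaussian_filter(gray, sigma, order=(1, 1))

        # eigenvalues of [[hxx, hxy], [hxy, hyy]]
        tr_half = 0.5 * (hxx + hyy)
        disc = np.sqrt(np.maximum(0.25 * (hxx - hyy) ** 2 + hxy**2, 0.0))
        e1, e2 = tr_half - disc, tr_half + disc
        big_is_e2 = np.abs(e2) >= np.abs(e1)
        lam2 = np.where(big_is_e2, e2, e1)  # larger magnitude
        lam1 = np.where(big_is_e2, e1, e2)

        frob2 = hxx**2 + 2 * hxy**2 + hyy**2
        gamma = params.gamma_frac * np.sqrt(frob2.max())
        if gamma == 0:
            continue  # constant patch at this scale: zero response
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio2 = np.where(lam2 != 0, (lam1 / lam2) ** 2, 0.0)
        vesselness = np.exp(-ratio2 / (2 * params.beta**2)) * (
            1.0 - np.exp(-frob2 / (2 * gamma**2))
        )
        vesselness[lam2 <= 0] = 0.0  # keep dark ridges only
        response = np.maximum(response, vesselness)

    peak = response.max()
    return response / peak if peak > 0 else response


# ---------------------------------------------------------------------------
# Fourier enhancement
# ---------------------------------------------------------------------------

def fft_enhance(response: np.ndarray, band: BandParams = BandParams()) -> np.ndarray:
    """Enhance coherent line structure by radial band-pass + magnitude gating.

    The 2-D spectrum is restricted to wavelengths within ``band`` (the DC
    coefficient is kept, so the map's mean survives); retained coefficients
    weaker than the configured magnitude percentile are zeroed. The inverse
    transform is clipped to be nonnegative and min-max rescaled to [0, 1].
    Incoherent speckle spreads its energy over many weak coefficients, so
    the gate suppresses it while coherent ridges survive.
    """
    response = np.asarray(response, dtype=float)
    if response.ndim != 2:
        raise ValueError("expected a 2-D real-valued map")

    spectrum = np.fft.fft2(response)
    fy = np.fft.fftfreq(response.shape[0])[:, None]
    fx = np.fft.fftfreq(response.shape[1])[None, :]
    radius = np.sqrt(fx**2 + fy**2)  # cycles / pixel

    in_band = (radius >= 1.0 / band.high_wavelength) & (radius <= 1.0 / band.low_wavelength)
    dc = radius == 0
    spectrum[~(in_band | dc)] = 0.0

    if band.percentile > 0 and in_band.any():
        mags = np.abs(spectrum[in_band])
        cut = np.percentile(mags, band.percentile)
        weak = in_band & (np.abs(spectrum) < cut)
        spectrum[weak] = 0.0

    out = np.real(np.fft.ifft2(spectrum))
    out = np.clip(out, 0.0, None)
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def raw_wrinkle_fraction(enhanced: np.ndarray, threshold: float = 0.2) -> float:
    """Fraction of pixels whose enhanced response exceeds `threshold` x max."""
    enhanced = np.asarray(enhanced, dtype=float)
    peak = enhanced.max()
    if peak <= 0:
        return 0.0
    return float(np.mean(enhanced > threshold * peak))


def wrinkle_score(
    enhanced: np.ndarray,
    calibration: ScoreCalibration,
    threshold: float = 0.2,
) -> float:
    """0-100 wrinkle score: calibrated area fraction of the detected ridges."""
    if calibration is None:
        raise ValueError("missing wrinkle calibration; run calibrate_scores first")
    return float(calibration.apply(raw_wrinkle_fraction(enhanced, threshold)))


def detect_spots(
    patch: np.ndarray,
    contrast_threshold: float = 10.0,
    background_sigma: float = 12.0,
    radius_range: tuple[float, float] = (1.5, 12.0),
    min_roundness: float = 0.35,
) -> np.ndarray:
    """Binary mask of blob-like dark spots in a skin patch.

    Background skin tone is estimated by large-kernel Gaussian smoothing;
    pixels darker than background by more than ``contrast_threshold`` are
    candidates, and connected components are kept when their equivalent
    radius lies in ``radius_range`` and they are blob-like (minor/major
    axis ratio >= ``min_roundness``), which rejects elongated wrinkles.
    """
    gray = to_grayscale(patch)
    background = ndimage.gaussian_filter(gray, background_sigma)
    candidates = (background - gray) > contrast_threshold

    keep = np.zeros_like(candidates)
    labels = label(candidates, connectivity=2)
    rmin, rmax = radius_range
    for prop in regionprops(labels):
        radius = np.sqrt(prop.area / np.pi)
        if not rmin <= radius <= rmax:
            continue
        if prop.axis_major_length > 0:
            roundness = prop.axis_minor_length / prop.axis_major_length
            if roundness < min_roundness:
                continue
        keep[labels == prop.label] = True
    return keep


def raw_spot_fraction(patch: np.ndarray, **kwargs) -> float:
    """Fraction of patch area covered by detected pigmented-spot blobs."""
    mask = detect_spots(patch, **kwargs)
    return float(mask.mean())


def spot_score(patch: np.ndarray, calibration: ScoreCalibration, **kwargs) -> float:
    """0-100 pigmented-spot score: calibrated blob-area fraction."""
    if calibration is None:
        raise ValueError("missing spot calibration; run calibrate_scores first")
    return float(calibration.apply(raw_spot_fraction(patch, **kwargs)))


def calibrate_scores(
    raw_fractions: np.ndarray,
    kind: str,
    region: str,
    provenance: str = "synthetic-reference-cohort",
) -> ScoreCalibration:
    """Set calibration bounds from a reference cohort of raw area fractions.

    Bounds are the 1st and 99th percentiles of the raw fractions, taken with
    outward-conservative interpolation (``lower``/``higher``) so that small
    reference cohorts (n <= 100) use the full observed range and nothing in
    the reference cohort itself is clipped.
    """
    raw = np.asarray(raw_fractions, dtype=float)
    if raw.size < 30:
        raise ValueError(f"need >= 30 reference patches to calibrate, got {raw.size}")
    lower = float(np.percentile(raw, 1, method="lower"))
    upper = float(np.percentile(raw, 99, method="higher"))
    if upper - lower < 1e-12:
        raise ValueError(
            f"degenerate calibration range for {kind}/{region}: all raw fractions "
            "are (near-)identical; use a more varied reference cohort"
        )
    return ScoreCalibration(kind=kind, region=region, lower=lower, upper=upper, provenance=provenance)


# ---------------------------------------------------------------------------
# per-subject indices (left/right averaged)
# ---------------------------------------------------------------------------

_WRINKLE_REGION_OF = {"Wb": "beside_eye", "Wu": "under_eye", "Wa": "above_inner_corner"}
_SPOT_REGION_OF = {"Pb": "beside_eye", "Pu": "under_eye"}


def wrinkle_index(
    image: np.ndarray,
    landmarks: LandmarkSet,
    index: str,
    calibration: ScoreCalibration,
    params: RidgeParams = RidgeParams(),
    band: BandParams = BandParams(),
) -> float:
    """Per-subject wrinkle index (Wb, Wu or Wa): mean of left and right scores."""
    region = _WRINKLE_REGION_OF[index]
    scores = []
    for side in SIDES:
        patch, _ = crop_periorbital_roi(image, landmarks, region, side)
        enhanced = fft_enhance(hessian_ridge_response(to_grayscale(patch), params), band)
        scores.append(wrinkle_score(enhanced, calibration, params.threshold))
    return float(np.mean(scores))


def spot_index(
    image: np.ndarray,
    landmarks: LandmarkSet,
    index: str,
    calibration: ScoreCalibration,
    **kwargs,
) -> float:
    """Per-subject pigmented-spot index (Pb or Pu): mean of left and right scores."""
    region = _SPOT_REGION_OF[index]
    scores = []
    for side in SIDES:
        patch, _ = crop_periorbital_roi(image, landmarks, region, side)
        scores.append(spot_score(patch, calibration, **kwargs))
    return float(np.mean(scores))
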