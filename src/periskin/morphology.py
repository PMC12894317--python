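"""Landmark-based periorbital morphology: eye droopiness (Md) and temporal width (Mw).

Both indices are pure functions of facial landmark coordinates:

* eye droopiness ``Md = H1 - H2``, the height of the medial canthus minus
  the height of the lateral canthus, with heights measured image-up
  (``height = image_height - y``); a positive Md means the outer corner of
  the eye sits lower, i.e. a droopier eye;
* temporal width ``Mw = (L2 + L3) / L1``, the sum of the distances from
  each outer canthus to the facial outline on its own side, divided by the
  facial width, so the index is invariant to overall face size.

Distances to the facial outline are measured horizontally at the outer
canthus height, against the outline polyline linearly interpolated at that
height; the facial width L1 is the horizontal distance between the two
outline points interpolated at the mean outer-canthus height. Raw values
are mapped onto the common 0-100 scale with percentile-based bounds shared
with the image-score calibration machinery.
"""

from __future__ import annotations

import numpy as np

from .landmarks import LandmarkSet
from .image_features import ScoreCalibration, calibrate_scores

__all__ = ["eye_droopiness", "temporal_width", "normalize_morphology", "morphology_calibration"]


def eye_droopiness(landmarks: LandmarkSet, side: str = "left") -> float:
    """Raw eye droopiness Md = H1 - H2 in pixels for one side."""
    medial = landmarks.point(f"{side}_medial_canthus")
    lateral = landmarks.point(f"{side}_lateral_canthus")
    h = landmarks.image_height
    h1 = h - medial[1]
    h2 = h - lateral[1]
    return float(h1 - h2)


def _outline_distance(landmarks: LandmarkSet, side: str) -> float:
    lat = landmarks.point(f"{side}_lateral_canthus")
    x_out = landmarks.interp_line_x(f"{side}_outline", float(lat[1]))
    return abs(x_out - float(lat[0]))


def temporal_width(landmarks: LandmarkSet) -> float:
    """Raw temporal width Mw = (L2 + L3) / L1 (dimensionless)."""
    l2 = _outline_distance(landmarks, "left")
    l3 = _outline_distance(landmarks, "right")

    lat_l = landmarks.point("left_lateral_canthus")
    lat_r = landmarks.point("right_lateral_canthus")
    y_mid = 0.5 * (float(lat_l[1]) + float(lat_r[1]))
    x_left = landmarks.interp_line_x("left_outline", y_mid)
    x_right = landmarks.interp_line_x("right_outline", y_mid)
    l1 = abs(x_right - x_left)
    if l1 <= 0:
        raise ValueError("facial width L1 is zero; outline landmarks are degenerate")
    return float((l2 + l3) / l1)


def morphology_calibration(raw_values: np.ndarray, index: str) -> ScoreCalibration:
    """Percentile-bound calibration (1st/99th, outward-conservative) for one index."""
    return calibrate_scores(raw_values, kind="morphology", region=index)


def normalize_morphology(
    raw_values: np.ndarray,
    index: str = "Md",
    calibration: ScoreCalibration | None = None,
) -> tuple[np.ndarray, ScoreCalibration]:
    """Map raw morphology values over a cohort onto the 0-100 scale.

    When no calibration is given one is estimated from the values themselves
    (>= 30 required); the calibration used is returned alongside the scores
    so it can be persisted and re-applied to new subjects. The affine map
    preserves ranks, and preserves Pearson correlations exactly whenever no
    value falls outside the calibration bounds.
    """
    raw = np.asarray(raw_values, dtype=float)
    if calibration is None:
        calibration = morphology_calibration(raw, index)
    return calibration.apply(raw), calibration
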