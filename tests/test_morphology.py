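"""Eye droopiness (Md = H1 - H2) and temporal width (Mw = (L2+L3)/L1)."""

import numpy as np
import pytest

import periskin as ps
from periskin.landmarks import LandmarkSet
from periskin.morphology import eye_droopiness, temporal_width, normalize_morphology


def droop_landmarks(medial_y, lateral_y, height=200):
    return LandmarkSet(
        points={
            "left_medial_canthus": [60, medial_y],
            "left_lateral_canthus": [30, lateral_y],
        },
        image_size=(height, height),
    )


def width_landmarks():
    """L1 = 100, L2 = 10, L3 = 12 by construction."""
    return LandmarkSet(
        points={
            "left_lateral_canthus": [30, 50],
            "right_lateral_canthus": [108, 50],
            "left_medial_canthus": [50, 50],
            "right_medial_canthus": [88, 50],
        },
        lines={
            "left_outline": [[20, 30], [20, 70]],
            "right_outline": [[120, 30], [120, 70]],
        },
        image_size=(140, 140),
    )


def test_droopiness_direct_substitution():
    # H1 = 200 - 80 = 120, H2 = 200 - 85 = 115 -> Md = 5
    assert abs(eye_droopiness(droop_landmarks(80, 85)) - 5.0) < 1e-12
    assert abs(eye_droopiness(droop_landmarks(90, 90))) < 1e-12


def test_droopiness_positive_when_outer_corner_lower():
    assert eye_droopiness(droop_landmarks(80, 95)) > 0


def test_droopiness_mirror_invariance(face):
    _, lm, _ = face
    mirrored = lm.mirrored()
    for side, other in (("left", "right"), ("right", "left")):
        assert abs(eye_droopiness(lm, side) - eye_droopiness(mirrored, other)) < 1e-12


def test_droopiness_flips_sign_under_vertical_reflection():
    lm = droop_landmarks(80, 95, height=200)
    flipped = LandmarkSet(
        points={k: [v[0], 199 - v[1]] for k, v in lm.points.items()},
        image_size=lm.image_size,
    )
    assert abs(eye_droopiness(lm) + eye_droopiness(flipped)) < 1e-12


def test_temporal_width_direct_substitution():
    assert abs(temporal_width(width_landmarks()) - 0.22) < 1e-12


def test_temporal_width_scale_and_translation_invariance():
    lm = width_landmarks()
    scaled = LandmarkSet(
        points={k: np.asarray(v) * 2 for k, v in lm.points.items()},
        lines={k: np.asarray(v) * 2 for k, v in lm.lines.items()},
        image_size=(280, 280),
    )
    shifted = lm.translated(7, 11)
    assert abs(temporal_width(scaled) - temporal_width(lm)) < 1e-12
    assert abs(temporal_width(shifted) - temporal_width(lm)) < 1e-12


def test_temporal_width_matches_brute_force_geometry(face):
    """Independent recomputation of L1, L2, L3 from raw coordinates."""
    _, lm, _ = face
    mw = temporal_width(lm)

    def interp_x(line, y):
        pts = sorted(map(tuple, line), key=lambda p: p[1])
        ys = [p[1] for p in pts]
        xs = [p[0] for p in pts]
        return np.interp(y, ys, xs)

    lat_l = lm.point("left_lateral_canthus")
    lat_r = lm.point("right_lateral_canthus")
    l2 = abs(interp_x(lm.line("left_outline"), lat_l[1]) - lat_l[0])
    l3 = abs(interp_x(lm.line("right_outline"), lat_r[1]) - lat_r[0])
    y_mid = (lat_l[1] + lat_r[1]) / 2
    l1 = abs(interp_x(lm.line("right_outline"), y_mid) - interp_x(lm.line("left_outline"), y_mid))
    assert abs(mw - (l2 + l3) / l1) < 1e-12


def test_zero_facial_width_rejected():
    lm = width_landmarks()
    lm.lines["right_outline"] = lm.lines["left_outline"].copy()
    lm.points["right_lateral_canthus"] = lm.points["left_lateral_canthus"].copy()
    with pytest.raises(ValueError, match="L1"):
        temporal_width(lm)


# -- normalization ----------------------------------------------------------

def test_normalization_endpoints_and_order():
    rng = np.random.default_rng(0)
    raw = rng.normal(5, 2, 80)
    scores, cal = normalize_morphology(raw, "Md")
    assert scores[np.argmin(raw)] == 0.0
    assert scores[np.argmax(raw)] == 100.0
    assert np.all(np.diff(scores[np.argsort(raw)]) >= 0)
    assert np.all((scores >= 0) & (scores <= 100))
    # re-applying the persisted calibration is exact
    again, _ = normalize_morphology(raw, "Md", calibration=cal)
    assert np.array_equal(scores, again)


def test_normalization_preserves_pearson_correlation_exactly():
    """Affine invariance of Pearson r: normalized scores correlate with age
    identically to the raw values (no clipping on a small cohort)."""
    rng = np.random.default_rng(1)
    age = rng.uniform(20, 70, 80)
    raw = 0.3 * age + rng.normal(0, 3, 80)
    scores, _ = normalize_morphology(raw, "Mw")
    r_raw = np.corrcoef(raw, age)[0, 1]
    r_scored = np.corrcoef(scores, age)[0, 1]
    assert abs(r_raw - r_scored) < 1e-12


def test_normalization_guards():
    with pytest.raises(ValueError):
        normalize_morphology(np.ones(10), "Md")  # too few
    with pytest.raises(ValueError, match="degenerate"):
        normalize_morphology(np.ones(50), "Md")  # zero range
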