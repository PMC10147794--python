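import numpy as np
import pytest

from scoliofe import metrics, synth
from scoliofe.landmarks import LEVELS, LandmarkSet3D
from scoliofe.metrics import (axial_rotation, cobb_angle, compare_indices,
                              kyphosis, lordosis, measure_indices,
                              wedging_angle)


def tilted_spine(frontal_tilts=None, sagittal_tilts=None, noise_sd=0.0,
                 seed=None):
    """Synthetic landmark set with exact per-level endplate tilts."""
    spec = synth.SynthSpec(thoracic_cobb=0, lumbar_cobb=0, kyphosis=0,
                           lordosis=0)
    frontal = np.zeros(17) if frontal_tilts is None else np.asarray(
        frontal_tilts, dtype=float)
    sagittal = np.zeros(17) if sagittal_tilts is None else np.asarray(
        sagittal_tilts, dtype=float)

    import scoliofe.synth as s
    dims = s.defaults.default_dimension_table()
    ivd = s.defaults.default_ivd_heights()
    frames = {lv: s._vertebra_frame(frontal[i], sagittal[i])
              for i, lv in enumerate(LEVELS)}
    bottom_up = list(reversed(LEVELS))
    centroids, pos = {}, np.zeros(3)
    for i, lv in enumerate(bottom_up):
        h = dims[lv]["height"]
        n = frames[lv][:, 2]
        if i == 0:
            centroids[lv] = pos + n * h / 2
        else:
            prev = bottom_up[i - 1]
            npv = frames[prev][:, 2]
            nm = (npv + n) / np.linalg.norm(npv + n)
            centroids[lv] = (centroids[prev] + npv * dims[prev]["height"] / 2
                             + nm * ivd.get(lv, 5.0) + n * h / 2)
    coords = {}
    rng = np.random.default_rng(seed)
    for lv in LEVELS:
        R, c = frames[lv], centroids[lv]
        d, w, h = dims[lv]["depth"], dims[lv]["width"], dims[lv]["height"]
        v, u, n = R[:, 0], R[:, 1], R[:, 2]
        pts = {
            "sup_left": c + u * w / 2 + n * h / 2,
            "sup_right": c - u * w / 2 + n * h / 2,
            "inf_left": c + u * w / 2 - n * h / 2,
            "inf_right": c - u * w / 2 - n * h / 2,
            "sup_ant": c + v * d / 2 + n * h / 2,
            "sup_post": c - v * d / 2 + n * h / 2,
            "inf_ant": c + v * d / 2 - n * h / 2,
            "inf_post": c - v * d / 2 - n * h / 2,
            "centroid": c,
        }
        for lid, p in pts.items():
            coords[(lv, lid)] = p + (rng.normal(0, noise_sd, 3)
                                     if noise_sd else 0.0)
    return LandmarkSet3D(coords)


class TestCobb:
    def test_straight_spine_zero(self, straight_landmarks):
        r = cobb_angle(straight_landmarks)
        assert r.angle < 1e-6

    def test_constructed_40_degrees(self):
        # end-vertebra endplates tilted +20 and -20 at T5 / T11
        tilts = np.zeros(17)
        tilts[LEVELS.index("T5")] = 20.0
        tilts[LEVELS.index("T11")] = -20.0
        lm = tilted_spine(frontal_tilts=tilts)
        r = cobb_angle(lm, level_range=("T1", "T12"))
        assert r.angle == pytest.approx(40.0, abs=1e-9)
        assert {r.upper_end, r.lower_end} == {"T5", "T11"}

    def test_translation_and_scale_invariance(self):
        b = synth.generate_patient(synth.SynthSpec(thoracic_cobb=35.0))
        lm = b["landmarks"]
        moved = LandmarkSet3D({k: v * 2.5 + np.array([10, -20, 30])
                               for k, v in lm.coords.items()})
        r0 = cobb_angle(lm, level_range=("T1", "T12"))
        r1 = cobb_angle(moved, level_range=("T1", "T12"))
        assert r1.angle == pytest.approx(r0.angle, abs=1e-9)
        assert r1.apex == r0.apex

    def test_end_vertebra_selection_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        tilts = rng.uniform(-15, 15, 17)
        lm = tilted_spine(frontal_tilts=tilts)
        r = cobb_angle(lm, level_range=("T1", "L5"))
        # independent oracle: exhaustive max over tilt-profile pairs
        best, pair = 0.0, None
        for i in range(17):
            for j in range(i + 1, 17):
                a = abs(tilts[i] - tilts[j])
                if a > best:
                    best, pair = a, (LEVELS[i], LEVELS[j])
        assert r.angle == pytest.approx(best, abs=1e-6)
        assert (r.upper_end, r.lower_end) == pair

    def test_too_few_levels(self, straight_landmarks):
        with pytest.raises(ValueError):
            cobb_angle(straight_landmarks, level_range=("T1", "T2"))


class TestSagittal:
    def test_straight_zero(self, straight_landmarks):
        assert kyphosis(straight_landmarks) == pytest.approx(0.0, abs=1e-9)
        assert lordosis(straight_landmarks) == pytest.approx(0.0, abs=1e-9)

    def test_arc_subtending_30(self):
        # linear sagittal tilt ramp T1..T12 spanning 30 degrees
        sag = np.zeros(17)
        sag[:12] = np.linspace(-15.0, 15.0, 12)
        lm = tilted_spine(sagittal_tilts=sag)
        assert kyphosis(lm) == pytest.approx(30.0, abs=1e-9)

    def test_straight_subrange_zero(self):
        sag = np.zeros(17)
        sag[:12] = np.linspace(-15.0, 15.0, 12)
        lm = tilted_spine(sagittal_tilts=sag)
        assert lordosis(lm, ("L1", "L5")) == pytest.approx(0.0, abs=1e-9)


class TestWedging:
    def test_rectangular_body_zero(self, straight_landmarks):
        assert wedging_angle(straight_landmarks, "T8") == pytest.approx(0.0)

    def test_constructed_5_degrees(self, straight_landmarks):
        coords = {k: v.copy() for k, v in straight_landmarks.coords.items()}
        sl = coords[("T8", "sup_left")]
        sr = coords[("T8", "sup_right")]
        width = sl[1] - sr[1]
        dz = width * np.tan(np.radians(5.0))
        coords[("T8", "sup_left")] = sl + [0, 0, dz / 2]
        coords[("T8", "sup_right")] = sr - [0, 0, dz / 2]
        lm = LandmarkSet3D(coords)
        assert wedging_angle(lm, "T8") == pytest.approx(5.0, abs=1e-9)
        assert wedging_angle(lm, "T8", "left") == pytest.approx(5.0, abs=1e-9)

    def test_mirror_flips_sign(self, straight_landmarks):
        coords = {k: v.copy() for k, v in straight_landmarks.coords.items()}
        coords[("T8", "sup_left")] = coords[("T8", "sup_left")] + [0, 0, 1.0]
        lm = LandmarkSet3D(coords)
        mirrored = LandmarkSet3D({
            (lv, lid.replace("left", "L").replace("right", "left")
             .replace("L", "right")): v * np.array([1, -1, 1])
            for (lv, lid), v in lm.coords.items()})
        a = wedging_angle(lm, "T8", "left")
        b = wedging_angle(mirrored, "T8", "left")
        assert b == pytest.approx(-a, abs=1e-9)

    def test_degenerate_corners_rejected(self, straight_landmarks):
        coords = {k: v.copy() for k, v in straight_landmarks.coords.items()}
        coords[("T8", "sup_right")] = coords[("T8", "sup_left")]
        with pytest.raises(ValueError, match="degenerate"):
            wedging_angle(LandmarkSet3D(coords), "T8")


class TestAxialRotation:
    def test_unrotated_zero(self, straight_landmarks):
        assert axial_rotation(straight_landmarks, "T8") == pytest.approx(0.0)

    def test_rotated_10_degrees(self, straight_landmarks):
        theta = np.radians(10.0)
        Rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        c = straight_landmarks[("T8", "centroid")]
        coords = {k: v.copy() for k, v in straight_landmarks.coords.items()}
        for lid in ("sup_left", "sup_right", "inf_left", "inf_right"):
            coords[("T8", lid)] = Rz @ (coords[("T8", lid)] - c) + c
        got = axial_rotation(LandmarkSet3D(coords), "T8")
        assert abs(got) == pytest.approx(10.0, abs=1e-9)

    def test_monte_carlo_noise_recovery(self, straight_landmarks):
        theta = np.radians(10.0)
        Rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        c = straight_landmarks[("T8", "centroid")]
        base = {k: v.copy() for k, v in straight_landmarks.coords.items()}
        for lid in ("sup_left", "sup_right", "inf_left", "inf_right"):
            base[("T8", lid)] = Rz @ (base[("T8", lid)] - c) + c
        rng = np.random.default_rng(123)
        got = []
        for _ in range(200):
            noisy = {k: v + rng.normal(0, 0.5, 3) for k, v in base.items()}
            got.append(abs(axial_rotation(LandmarkSet3D(noisy), "T8")))
        assert np.mean(got) == pytest.approx(10.0, abs=0.5)


class TestCompare:
    def test_identical_all_pass(self):
        d = {"t0": {"thoracic_cobb": 40.0, "kyphosis": 30.0}}
        table = compare_indices(d, d)
        assert (table["error_deg"] == 0).all() and table["pass"].all()

    def test_ten_degree_discrepancy_flagged(self):
        a = {"t0": {"thoracic_cobb": 40.0}}
        b = {"t0": {"thoracic_cobb": 50.0}}
        table = compare_indices(a, b)
        assert not table["pass"].iloc[0]

    def test_mean_sd_formatting(self):
        a = {"t0": {"x": 5.0}, "t1": {"x": 7.0}, "t2": {"x": 9.0}}
        b = {"t0": {"x": 0.0}, "t1": {"x": 0.0}, "t2": {"x": 0.0}}
        table = compare_indices(a, b)
        summary = table.attrs["summary"]
        assert summary.loc[summary["index"] == "x", "formatted"].iloc[0] \
            == "7.0 ± 2.0"

    def test_timepoint_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_indices({"t0": {}}, {"t1": {}})


def test_measure_indices_roundtrip():
    b = synth.generate_patient(synth.SynthSpec(
        thoracic_cobb=40.0, kyphosis=30.0, lordosis=40.0))
    idx = measure_indices(b["landmarks"])
    assert idx.thoracic_cobb == pytest.approx(40.0, abs=1.0)
    assert idx.kyphosis == pytest.approx(30.0, abs=1.0)
    assert idx.lordosis == pytest.approx(40.0, abs=1.0)
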