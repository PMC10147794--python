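"""Automated clinical spine-curvature indices from landmark sets.

Cobb angles (frontal, with exhaustive end-vertebra maximization), kyphosis
and lordosis (sagittal, fixed level ranges), apical axial rotation,
per-level vertebral wedging, and error-vs-reference comparison with the 8
degree acceptance threshold.  All angles are invariant to rigid translation
and uniform scaling of the landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .landmarks import LEVELS, LandmarkSet3D

DEFAULT_THORACIC_RANGE = ("T1", "T12")
DEFAULT_LUMBAR_RANGE = ("T12", "L5")
DEFAULT_KYPHOSIS_RANGE = ("T1", "T12")
DEFAULT_LORDOSIS_RANGE = ("L1", "L5")
ERROR_THRESHOLD_DEG = 8.0


@dataclass
class CobbResult:
    angle: float           # deg
    upper_end: str
    lower_end: str
    apex: str
    convex_side: Optional[str]   # 'left' | 'right' | None when straight


@dataclass
class ClinicalIndices:
    thoracic_cobb: float
    lumbar_cobb: float
    kyphosis: float
    lordosis: float
    axial_rotation: float
    wedging: Dict[str, float] = field(default_factory=dict)
    thoracic: Optional[CobbResult] = None
    lumbar: Optional[CobbResult] = None

    def as_dict(self) -> Dict[str, float]:
        out = {
            "thoracic_cobb": round(self.thoracic_cobb, 1),
            "lumbar_cobb": round(self.lumbar_cobb, 1),
            "kyphosis": round(self.kyphosis, 1),
            "lordosis": round(self.lordosis, 1),
            "axial_rotation": round(self.axial_rotation, 1),
        }
        for level, w in self.wedging.items():
            out[f"wedging_{level}"] = round(w, 1)
        return out


def _levels_in_range(level_range: Tuple[str, str]) -> List[str]:
    i0, i1 = LEVELS.index(level_range[0]), LEVELS.index(level_range[1])
    if i0 > i1:
        i0, i1 = i1, i0
    return list(LEVELS[i0:i1 + 1])


def _plane_projector(plane: str):
    """2D (horizontal, vertical) projection of a 3D point for a view plane."""
    if plane == "frontal":
        return lambda p: np.array([p[1], p[2]])   # (y, z)
    if plane in ("sagittal", "lateral"):
        return lambda p: np.array([p[0], p[2]])   # (x, z)
    raise ValueError(f"unknown plane {plane!r}")


def _endplate_tilt(landmarks: LandmarkSet3D, level: str, edge: str,
                   plane: str) -> float:
    """Signed tilt (deg) of the sup/inf endplate line in the view plane."""
    proj = _plane_projector(plane)
    if plane == "frontal":
        a, b = (f"{edge}_left", f"{edge}_right")
    else:
        a, b = (f"{edge}_post", f"{edge}_ant")
    p, q = proj(landmarks[(level, a)]), proj(landmarks[(level, b)])
    d = q - p
    if np.linalg.norm(d) == 0:
        raise ValueError(f"degenerate endplate at level {level}")
    if d[0] < 0:
        d = -d
    return float(np.degrees(np.arctan2(d[1], d[0])))


def _angle_between(t_upper: float, t_lower: float) -> float:
    a = abs(t_upper - t_lower) % 180.0
    return min(a, 180.0 - a)


def cobb_angle(landmarks: LandmarkSet3D, plane: str = "frontal",
               level_range: Tuple[str, str] = ("T1", "L5")) -> CobbResult:
    """Cobb angle with end vertebrae chosen by exhaustive pair maximization.

    The superior endplate line of the upper candidate and the inferior line
    of the lower candidate define the angle (standard Cobb convention); the
    apex is the level of maximal lateral centroid deviation from the
    end-vertebra chord.
    """
    levels = _levels_in_range(level_range)
    if len(levels) < 3:
        raise ValueError("need at least 3 levels for a Cobb measurement")
    sup = {lv: _endplate_tilt(landmarks, lv, "sup", plane) for lv in levels}
    inf = {lv: _endplate_tilt(landmarks, lv, "inf", plane) for lv in levels}

    best = (0.0, levels[0], levels[-1])
    for i, up in enumerate(levels):
        for lo in levels[i + 1:]:
            ang = _angle_between(sup[up], inf[lo])
            if ang > best[0] + 1e-12:
                best = (ang, up, lo)
    angle, upper, lower = best

    proj = _plane_projector(plane)
    cu = proj(landmarks[(upper, "centroid")])
    cl = proj(landmarks[(lower, "centroid")])
    chord = cl - cu
    chord_n = chord / np.linalg.norm(chord) if np.linalg.norm(chord) else chord
    apex, apex_dev = upper, 0.0
    mid = levels[levels.index(upper):levels.index(lower) + 1]
    for lv in mid:
        c = proj(landmarks[(lv, "centroid")])
        v = c - cu
        dev = v[0] - (v @ chord_n) * chord_n[0] if np.linalg.norm(chord) \
            else v[0]
        if abs(dev) > abs(apex_dev):
            apex, apex_dev = lv, dev
    if abs(apex_dev) < 1e-9:
        apex = mid[len(mid) // 2]
        convex = None
    else:
        # frontal horizontal axis is +y = patient-left
        convex = "left" if apex_dev > 0 else "right"
    return CobbResult(angle=angle, upper_end=upper, lower_end=lower,
                      apex=apex, convex_side=convex)


def kyphosis(landmarks: LandmarkSet3D,
             level_range: Tuple[str, str] = DEFAULT_KYPHOSIS_RANGE) -> float:
    """Sagittal Cobb-style angle between the bounding endplates of the range."""
    levels = _levels_in_range(level_range)
    if len(levels) < 3:
        raise ValueError("need at least 3 levels")
    return _angle_between(
        _endplate_tilt(landmarks, levels[0], "sup", "sagittal"),
        _endplate_tilt(landmarks, levels[-1], "inf", "sagittal"))


def lordosis(landmarks: LandmarkSet3D,
             level_range: Tuple[str, str] = DEFAULT_LORDOSIS_RANGE) -> float:
    levels = _levels_in_range(level_range)
    if len(levels) < 3:
        raise ValueError("need at least 3 levels")
    return _angle_between(
        _endplate_tilt(landmarks, levels[0], "sup", "sagittal"),
        _endplate_tilt(landmarks, levels[-1], "inf", "sagittal"))


def wedging_angle(landmarks: LandmarkSet3D, level: str,
                  convex_side: Optional[str] = None) -> float:
    """Frontal angle between the superior and inferior body corner lines.

    Signed positive when the wedge opens toward the given convex side
    (taller on the convex side); unsigned magnitude when no side is given.
    """
    sup_l = landmarks[(level, "sup_left")]
    sup_r = landmarks[(level, "sup_right")]
    inf_l = landmarks[(level, "inf_left")]
    inf_r = landmarks[(level, "inf_right")]
    if (np.allclose(sup_l, sup_r) or np.allclose(inf_l, inf_r)):
        raise ValueError(f"degenerate (coincident) corners at {level}")
    t_sup = _endplate_tilt(landmarks, level, "sup", "frontal")
    t_inf = _endplate_tilt(landmarks, level, "inf", "frontal")
    magnitude = _angle_between(t_sup, t_inf)
    if convex_side is None:
        return magnitude
    h_left = (sup_l[2] - inf_l[2])
    h_right = (sup_r[2] - inf_r[2])
    opens = "left" if h_left > h_right else "right"
    return magnitude if opens == convex_side else -magnitude


def axial_rotation(landmarks: LandmarkSet3D, level: str) -> float:
    """Transverse-plane angle of the body left-right axis vs patient-left.

    The local axis runs between the midpoints of the left and right frontal
    corner pairs, projected onto the transverse plane.
    """
    left = 0.5 * (landmarks[(level, "sup_left")]
                  + landmarks[(level, "inf_left")])
    right = 0.5 * (landmarks[(level, "sup_right")]
                   + landmarks[(level, "inf_right")])
    axis = left - right
    if np.linalg.norm(axis[:2]) < 1e-12:
        raise ValueError(f"degenerate transverse axis at {level}")
    return float(np.degrees(np.arctan2(axis[0], axis[1])))


def measure_indices(landmarks: LandmarkSet3D,
                    thoracic_range: Tuple[str, str] = DEFAULT_THORACIC_RANGE,
                    lumbar_range: Tuple[str, str] = DEFAULT_LUMBAR_RANGE,
                    kyphosis_range: Tuple[str, str] = DEFAULT_KYPHOSIS_RANGE,
                    lordosis_range: Tuple[str, str] = DEFAULT_LORDOSIS_RANGE,
                    ) -> ClinicalIndices:
    """Full index bundle, with wedging reported at apex-1, apex, apex+1."""
    thoracic = cobb_angle(landmarks, "frontal", thoracic_range)
    lumbar = cobb_angle(landmarks, "frontal", lumbar_range)
    apex = thoracic.apex
    ai = LEVELS.index(apex)
    wedge_levels = [LEVELS[i] for i in (ai - 1, ai, ai + 1)
                    if 0 <= i < len(LEVELS)]
    wedging = {lv: wedging_angle(landmarks, lv, thoracic.convex_side)
               for lv in wedge_levels}
    return ClinicalIndices(
        thoracic_cobb=thoracic.angle,
        lumbar_cobb=lumbar.angle,
        kyphosis=kyphosis(landmarks, kyphosis_range),
        lordosis=lordosis(landmarks, lordosis_range),
        axial_rotation=axial_rotation(landmarks, apex),
        wedging=wedging,
        thoracic=thoracic,
        lumbar=lumbar,
    )


def compare_indices(model: Dict[str, Dict[str, float]],
                    reference: Dict[str, Dict[str, float]],
                    threshold: float = ERROR_THRESHOLD_DEG) -> pd.DataFrame:
    """Absolute per-index, per-timepoint errors against a reference.

    Both inputs map timepoint label -> {index name -> degrees}.  Returns a
    long-format table with pass flags, plus summary mean/sd rows per index.
    """
    if set(model) != set(reference):
        raise ValueError(
            f"timepoint mismatch: {sorted(set(model) ^ set(reference))}")
    rows = []
    for tp in sorted(model):
        common = set(model[tp]) & set(reference[tp])
        for name in sorted(common):
            err = abs(model[tp][name] - reference[tp][name])
            rows.append({"timepoint": tp, "index": name,
                         "error_deg": round(err, 1),
                         "pass": bool(err < threshold)})
    table = pd.DataFrame(rows)
    summary = (table.groupby("index")["error_deg"]
               .agg(["mean", "std"]).fillna(0.0).reset_index())
    summary["formatted"] = summary.apply(
        lambda r: f"{r['mean']:.1f} ± {r['std']:.1f}", axis=1)
    table.attrs["summary"] = summary
    return table
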