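"""Synthetic scoliotic patient generator.

Builds landmark sets with prescribed thoracic/lumbar Cobb, kyphosis and
lordosis by stacking vertebral boxes along a piecewise-arc centerline whose
per-level endplate tilts realize the requested angles exactly in the view
planes.  Projections are exact, so the biplanar round-trip through
triangulation is lossless.  The test substrate replacing clinical
radiographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import defaults
from .growth import PatientProfile
from .landmarks import (LEVELS, BiplanarLandmarks, LandmarkSet3D, project,
                        write_landmarks)
from .materials import FlexibilityParams


@dataclass
class SynthSpec:
    thoracic_cobb: float = 40.0
    lumbar_cobb: float = 20.0
    kyphosis: float = 30.0
    lordosis: float = 40.0
    apex: str = "T8"
    thoracic_span: tuple = ("T5", "T11")
    lumbar_span: tuple = ("T12", "L4")
    dims: Optional[Dict[str, Dict[str, float]]] = None
    ivd_heights: Optional[Dict[str, float]] = None
    noise_sd: float = 0.0          # mm
    seed: Optional[int] = None
    # profile fields
    patient_id: str = "synth"
    age: float = 12.0
    sex: str = "F"
    risser: float = 1.0
    risser_final: Optional[float] = None
    weight: float = 45.0
    cas: Optional[float] = None    # defaults to thoracic_cobb
    calb: Optional[float] = None   # defaults to cas / 2
    timepoints: List[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self) -> None:
        for name in ("thoracic_cobb", "lumbar_cobb", "kyphosis", "lordosis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name} must be in [0, 90] deg, got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("seed is mandatory when noise sd > 0")


def _anchor_tilts(spec: SynthSpec) -> tuple:
    """Per-level (frontal, sagittal) endplate tilts in degrees."""
    n = len(LEVELS)
    idx = {lv: i for i, lv in enumerate(LEVELS)}
    t_up, t_lo = (idx[l] for l in spec.thoracic_span)
    l_up, l_lo = (idx[l] for l in spec.lumbar_span)
    if not (t_up < t_lo <= l_up < l_lo):
        raise ValueError("curve spans must be ordered and non-overlapping")

    frontal = np.zeros(n)
    ht, hl = spec.thoracic_cobb / 2.0, spec.lumbar_cobb / 2.0
    anchors = [(0, 0.0), (t_up, +ht), (t_lo, -ht), (l_up, -hl),
               (l_lo, +hl), (n - 1, 0.0)]
    xs = [a for a, _ in anchors]
    ys = [b for _, b in anchors]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        # degenerate anchor spacing (e.g. lumbar span touching L5)
        xs, ys = zip(*dict(anchors).items())
    frontal = np.interp(np.arange(n), xs, ys)

    k_up, k_lo = idx["T1"], idx["T12"]
    lo_up, lo_lo = idx["L1"], idx["L5"]
    hk, hlo = spec.kyphosis / 2.0, spec.lordosis / 2.0
    sag_anchors = [(k_up, -hk), (k_lo, +hk), (lo_up, +hlo), (lo_lo, -hlo)]
    sagittal = np.interp(np.arange(n), [a for a, _ in sag_anchors],
                         [b for _, b in sag_anchors])
    return frontal, sagittal


def _vertebra_frame(phi_deg: float, psi_deg: float) -> np.ndarray:
    """Orthonormal frame (columns ap, lateral, superior) whose endplate
    lines project to exactly the given frontal (phi) and sagittal (psi)
    tilts."""
    phi, psi = np.radians(phi_deg), np.radians(psi_deg)
    u = np.array([0.0, np.cos(phi), np.sin(phi)])           # lateral
    a = -np.sin(psi) * np.sin(phi) / np.cos(phi)
    v = np.array([np.cos(psi), a, np.sin(psi)])             # antero-posterior
    v /= np.linalg.norm(v)
    nrm = np.cross(v, u)
    nrm /= np.linalg.norm(nrm)
    return np.column_stack([v, u, nrm])


def generate_patient(spec: SynthSpec) -> dict:
    """Build {'landmarks', 'biplanar', 'profile'} for one synthetic patient."""
    dims = spec.dims or defaults.default_dimension_table()
    ivd = spec.ivd_heights or defaults.default_ivd_heights()
    frontal, sagittal = _anchor_tilts(spec)

    frames = {lv: _vertebra_frame(frontal[i], sagittal[i])
              for i, lv in enumerate(LEVELS)}
    bottom_up = list(reversed(LEVELS))
    centroids: Dict[str, np.ndarray] = {}
    pos = np.zeros(3)
    for i, lv in enumerate(bottom_up):
        h = dims[lv]["height"]
        n_axis = frames[lv][:, 2]
        if i == 0:
            centroids[lv] = pos + n_axis * (h / 2.0)
        else:
            prev = bottom_up[i - 1]
            gap = ivd.get(lv, 5.0)
            n_prev = frames[prev][:, 2]
            n_mid = n_prev + n_axis
            n_mid /= np.linalg.norm(n_mid)
            centroids[lv] = (centroids[prev]
                             + n_prev * (dims[prev]["height"] / 2.0)
                             + n_mid * gap
                             + n_axis * (h / 2.0))

    coords = {}
    for lv in LEVELS:
        R = frames[lv]
        c = centroids[lv]
        d, w, h = dims[lv]["depth"], dims[lv]["width"], dims[lv]["height"]
        v, u, nrm = R[:, 0], R[:, 1], R[:, 2]
        coords[(lv, "sup_left")] = c + u * w / 2 + nrm * h / 2
        coords[(lv, "sup_right")] = c - u * w / 2 + nrm * h / 2
        coords[(lv, "inf_left")] = c + u * w / 2 - nrm * h / 2
        coords[(lv, "inf_right")] = c - u * w / 2 - nrm * h / 2
        coords[(lv, "sup_ant")] = c + v * d / 2 + nrm * h / 2
        coords[(lv, "sup_post")] = c - v * d / 2 + nrm * h / 2
        coords[(lv, "inf_ant")] = c + v * d / 2 - nrm * h / 2
        coords[(lv, "inf_post")] = c - v * d / 2 - nrm * h / 2
        coords[(lv, "centroid")] = c.copy()

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for key in sorted(coords):
            coords[key] = coords[key] + rng.normal(0.0, spec.noise_sd, 3)

    landmarks = LandmarkSet3D(coords)
    cas = spec.cas if spec.cas is not None else spec.thoracic_cobb
    calb = spec.calb if spec.calb is not None else cas / 2.0
    flexibility = FlexibilityParams(cas=cas, calb=calb) if cas > 0 else None
    profile = PatientProfile(
        age=spec.age, sex=spec.sex, risser=spec.risser, weight=spec.weight,
        flexibility=flexibility,
        timepoints=list(spec.timepoints), risser_final=spec.risser_final,
        patient_id=spec.patient_id)
    return {"landmarks": landmarks, "biplanar": project(landmarks),
            "profile": profile}


def write_profile(profile: PatientProfile, path) -> None:
    data = {
        "patient_id": profile.patient_id,
        "age": profile.age,
        "sex": profile.sex,
        "risser": profile.risser,
        "risser_final": profile.risser_final,
        "weight": profile.weight,
        "timepoints": list(profile.timepoints),
    }
    if profile.flexibility is not None:
        data["cas"] = profile.flexibility.cas
        data["calb"] = profile.flexibility.calb
        data["c"] = profile.flexibility.c
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_profile(path) -> PatientProfile:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    flex = None
    if "cas" in data:
        flex = FlexibilityParams(cas=data["cas"], calb=data["calb"],
                                 c=data.get("c", 0.3))
    return PatientProfile(
        age=data["age"], sex=data["sex"], risser=data["risser"],
        weight=data["weight"], flexibility=flex,
        timepoints=list(data.get("timepoints", [0.0])),
        risser_final=data.get("risser_final"),
        patient_id=data.get("patient_id", "patient"))


def generate_cohort(specs: List[SynthSpec], outdir) -> List[Path]:
    """Write one bundle directory per spec: landmark CSVs, profile, manifest."""
    if not specs:
        raise ValueError("empty spec list")
    ids = [s.patient_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for spec in specs:
        bundle = generate_patient(spec)
        pdir = outdir / spec.patient_id
        pdir.mkdir(exist_ok=True)
        write_landmarks(bundle["landmarks"], pdir / "landmarks_3d.csv")
        write_landmarks(bundle["biplanar"], pdir / "landmarks_biplanar.csv")
        write_profile(bundle["profile"], pdir / "profile.yaml")
        manifest = {
            "patient_id": spec.patient_id,
            "requested": {
                "thoracic_cobb": spec.thoracic_cobb,
                "lumbar_cobb": spec.lumbar_cobb,
                "kyphosis": spec.kyphosis,
                "lordosis": spec.lordosis,
            },
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        }
        with open(pdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        paths.append(pdir)
    return paths


def cohort_like_reference_table(seed: int = 0) -> List[SynthSpec]:
    """Five specs parameterized like the study cohort rows (age, sex, Risser,
    final standing and lateral-bending Cobb, weight)."""
    rows = [
        ("p1", 11, "F", 0, 38.6, 46.3, 13.7, 37.0),
        ("p2", 11, "F", 1, 42.5, 50.1, 18.5, 37.0),
        ("p3", 16, "M", 2, 48.9, 52.9, 23.2, 60.7),
        ("p4", 13, "M", 3, 39.5, 50.8, 26.2, 45.4),
        ("p5", 14, "F", 4, 48.9, 52.9, 36.8, 49.2),
    ]
    specs = []
    for pid, age, sex, risser, cobb0, cobb_final, calb, weight in rows:
        specs.append(SynthSpec(
            patient_id=pid, age=age, sex=sex, risser=risser, weight=weight,
            thoracic_cobb=min(cobb0, 90.0), cas=cobb_final, calb=calb,
            timepoints=[0.0, 1.0, 2.0, 3.0], seed=seed))
    return specs
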