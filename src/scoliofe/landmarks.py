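"""Vertebral landmark schema, biplanar-to-3D triangulation, and landmark file I/O.

Global frame convention (used everywhere downstream):
+x anterior, +y patient-left, +z superior, origin at the pelvis/base center.
The frontal view is the (y, z) plane, the lateral view the (x, z) plane.
Units are millimetres.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np

log = logging.getLogger(__name__)

#: Ordered vertebral levels, cranial to caudal.
LEVELS: Tuple[str, ...] = (
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
)

#: The nine landmark identifiers per vertebra: four frontal vertebral-body
#: corners, four sagittal body corners, and the body centroid.
LANDMARK_IDS: Tuple[str, ...] = (
    "sup_left", "sup_right", "inf_left", "inf_right",
    "sup_ant", "sup_post", "inf_ant", "inf_post",
    "centroid",
)

Key = Tuple[str, str]


@dataclass(frozen=True)
class LandmarkSchema:
    """Complete landmark naming schema: 17 levels x 9 landmarks = 153 points."""

    levels: Tuple[str, ...] = LEVELS
    landmark_ids: Tuple[str, ...] = LANDMARK_IDS

    def __post_init__(self) -> None:
        if len(self.levels) != 17:
            raise ValueError(f"schema requires 17 levels, got {len(self.levels)}")
        if len(self.landmark_ids) != 9:
            raise ValueError(
                f"schema requires 9 landmark ids, got {len(self.landmark_ids)}"
            )

    @property
    def size(self) -> int:
        return len(self.levels) * len(self.landmark_ids)

    def keys(self) -> Iterable[Key]:
        for level in self.levels:
            for lid in self.landmark_ids:
                yield (level, lid)


DEFAULT_SCHEMA = LandmarkSchema()


def _validate_key(level: str, lid: str) -> None:
    if level not in LEVELS:
        raise ValueError(f"unknown vertebral level {level!r}")
    if lid not in LANDMARK_IDS:
        raise ValueError(f"unknown landmark id {lid!r}")


@dataclass
class BiplanarLandmarks:
    """Per-view 2D landmark coordinates.

    ``frontal[(level, id)] = (y, z)`` and ``lateral[(level, id)] = (x, z)``,
    both in mm.  Both views must cover the same keys for triangulation.
    """

    frontal: Dict[Key, Tuple[float, float]] = field(default_factory=dict)
    lateral: Dict[Key, Tuple[float, float]] = field(default_factory=dict)
    z_tolerance: float = 10.0

    def check_consistency(self) -> None:
        fk, lk = set(self.frontal), set(self.lateral)
        if fk != lk:
            missing = sorted(fk ^ lk)
            level, lid = missing[0]
            raise ValueError(
                f"views do not cover the same keys; first mismatch at "
                f"level={level} id={lid} ({len(missing)} keys differ)"
            )


@dataclass
class LandmarkSet3D:
    """3D landmark coordinates: ``coords[(level, id)]`` -> (x, y, z) mm."""

    coords: Dict[Key, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, key: Key) -> np.ndarray:
        return self.coords[key]

    def is_complete(self, schema: LandmarkSchema = DEFAULT_SCHEMA) -> bool:
        return set(self.coords) == set(schema.keys())

    def missing_keys(self, schema: LandmarkSchema = DEFAULT_SCHEMA):
        return sorted(set(schema.keys()) - set(self.coords))

    def centroid(self, level: str) -> np.ndarray:
        return self.coords[(level, "centroid")]

    def array(self, keys: Iterable[Key] | None = None) -> np.ndarray:
        keys = list(keys) if keys is not None else sorted(self.coords)
        return np.array([self.coords[k] for k in keys], dtype=float)

    def check_monotonic_z(self) -> bool:
        """True when centroid z strictly decreases from T1 down to L5."""
        zs = [self.coords[(lv, "centroid")][2] for lv in LEVELS
              if (lv, "centroid") in self.coords]
        return all(a > b for a, b in zip(zs, zs[1:]))


def triangulate(biplanar: BiplanarLandmarks,
                z_tolerance: float | None = None) -> LandmarkSet3D:
    """Register two orthographic views into 3D landmarks.

    x is taken from the lateral view, y from the frontal view, and z as the
    mean of the two per-view z values.  Disagreement in z beyond the
    tolerance is logged as a warning; the mean is still used.
    """
    biplanar.check_consistency()
    tol = biplanar.z_tolerance if z_tolerance is None else z_tolerance
    coords: Dict[Key, np.ndarray] = {}
    for key in biplanar.frontal:
        y, zf = biplanar.frontal[key]
        x, zl = biplanar.lateral[key]
        if abs(zf - zl) > tol:
            level, lid = key
            warnings.warn(
                f"z disagreement {abs(zf - zl):.2f} mm > {tol} mm at "
                f"level={level} id={lid}; using the mean",
                stacklevel=2,
            )
        coords[key] = np.array([x, y, 0.5 * (zf + zl)], dtype=float)
    return LandmarkSet3D(coords)


def project(landmarks: LandmarkSet3D) -> BiplanarLandmarks:
    """Exact orthographic projection; inverse of :func:`triangulate`."""
    frontal: Dict[Key, Tuple[float, float]] = {}
    lateral: Dict[Key, Tuple[float, float]] = {}
    for key, p in landmarks.coords.items():
        x, y, z = (float(v) for v in p)
        frontal[key] = (y, z)
        lateral[key] = (x, z)
    return BiplanarLandmarks(frontal=frontal, lateral=lateral)


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: header "level,id,view,c1,c2,c3"; biplanar rows use
# view in {frontal, lateral} with (c1, c2) and an empty c3; 3D rows use
# view "3d" with (c1, c2, c3) = (x, y, z).
# ---------------------------------------------------------------------------

_HEADER = ["level", "id", "view", "c1", "c2", "c3"]


def write_landmarks(obj: BiplanarLandmarks | LandmarkSet3D, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        if isinstance(obj, LandmarkSet3D):
            for (level, lid) in sorted(obj.coords):
                x, y, z = obj.coords[(level, lid)]
                w.writerow([level, lid, "3d", repr(float(x)), repr(float(y)),
                            repr(float(z))])
        else:
            for (level, lid) in sorted(obj.frontal):
                c1, c2 = obj.frontal[(level, lid)]
                w.writerow([level, lid, "frontal", repr(float(c1)),
                            repr(float(c2)), ""])
            for (level, lid) in sorted(obj.lateral):
                c1, c2 = obj.lateral[(level, lid)]
                w.writerow([level, lid, "lateral", repr(float(c1)),
                            repr(float(c2)), ""])


def read_landmarks(path) -> BiplanarLandmarks | LandmarkSet3D:
    """Read a landmark CSV, returning the object matching its ``view`` column."""
    coords3d: Dict[Key, np.ndarray] = {}
    frontal: Dict[Key, Tuple[float, float]] = {}
    lateral: Dict[Key, Tuple[float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != _HEADER[:3]:
            raise ValueError(f"{path}: missing or malformed header")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                level, lid, view = row[0].strip(), row[1].strip(), row[2].strip()
                _validate_key(level, lid)
                if view == "3d":
                    vals = np.array([float(row[3]), float(row[4]),
                                     float(row[5])])
                    if (level, lid) in coords3d:
                        raise ValueError("duplicate key")
                    coords3d[(level, lid)] = vals
                elif view in ("frontal", "lateral"):
                    pair = (float(row[3]), float(row[4]))
                    target = frontal if view == "frontal" else lateral
                    if (level, lid) in target:
                        raise ValueError("duplicate key")
                    target[(level, lid)] = pair
                else:
                    raise ValueError(f"unknown view {view!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    if coords3d and (frontal or lateral):
        raise ValueError(f"{path}: mixes 3d and biplanar rows")
    if coords3d:
        return LandmarkSet3D(coords3d)
    return BiplanarLandmarks(frontal=frontal, lateral=lateral)
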