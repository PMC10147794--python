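"""Dual-kriging morph of the template mesh onto patient landmark geometry.

The transform interpolates the control-point pairing exactly and reproduces
affine maps through its linear drift.  Kernel K(h) = h by default (h^3
available); an optional ridge term regularizes ill-conditioned control sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .landmarks import LEVELS, LANDMARK_IDS, LandmarkSet3D
from .template import HexMeshModel, check_quality, extract_landmarks, mesh_quality

log = logging.getLogger(__name__)

_KERNELS = {
    "h": lambda h: h,
    "h3": lambda h: h ** 3,
}


@dataclass
class KrigingTransform:
    source_controls: np.ndarray  # (n, 3)
    dual_coeffs: np.ndarray      # (n, 3)
    drift_coeffs: np.ndarray     # (4, 3): constant + linear per output coord
    kernel: str = "h"

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_kriging(self, points)


def fit_kriging(src: np.ndarray, dst: np.ndarray, kernel: str = "h",
                ridge: float = 0.0) -> KrigingTransform:
    """Solve the (n+4) dual system per output coordinate.

    Side conditions: dual coefficients sum to zero and are orthogonal to the
    source coordinates, so the drift alone carries any affine content.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must both be (n, 3)")
    n = src.shape[0]
    if n < 4:
        raise ValueError("need at least 4 control points")
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")

    d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    if np.any(d[~np.eye(n, dtype=bool)] == 0.0):
        raise ValueError("duplicate source control points")
    K = _KERNELS[kernel](d)
    if ridge:
        K = K + ridge * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])  # (n, 4)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst

    cond = np.linalg.cond(A)
    if not np.isfinite(cond):
        raise ValueError("singular kriging system (coplanar or degenerate "
                         "control points)")
    if cond > 1e12:
        warnings.warn(f"kriging system ill-conditioned (cond={cond:.3g}); "
                      "consider a ridge term", stacklevel=2)
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging system (coplanar or degenerate "
                         f"control points): {exc}") from exc
    return KrigingTransform(source_controls=src, dual_coeffs=sol[:n],
                            drift_coeffs=sol[n:], kernel=kernel)


def apply_kriging(t: KrigingTransform, points: np.ndarray) -> np.ndarray:
    """f(x) = drift(x) + sum_i b_i K(|x - s_i|), per output coordinate."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = np.linalg.norm(pts[:, None, :] - t.source_controls[None, :, :], axis=2)
    k = _KERNELS[t.kernel](h)           # (p, n)
    drift = np.hstack([np.ones((pts.shape[0], 1)), pts]) @ t.drift_coeffs
    out = drift + k @ t.dual_coeffs
    return out[0] if np.asarray(points).ndim == 1 else out


def landmark_control_arrays(src_lm: LandmarkSet3D, dst_lm: LandmarkSet3D):
    """Paired (src, dst) control arrays in canonical (level, id) order."""
    keys = [(lvl, lid) for lvl in LEVELS for lid in LANDMARK_IDS
            if (lvl, lid) in src_lm.coords and (lvl, lid) in dst_lm.coords]
    if not keys:
        raise ValueError("no common landmark keys between source and target")
    return src_lm.array(keys), dst_lm.array(keys)


def morph_model(template: HexMeshModel, patient: LandmarkSet3D,
                kernel: str = "h", ridge: float = 0.0,
                quality_floor: float = 0.97) -> HexMeshModel:
    """Morph every template node through the fitted landmark transform.

    Labels, springs, constraints, and node groups are preserved.  A mesh
    quality report is computed on the result; falling below the floor is a
    warning, not an error.
    """
    src_lm = extract_landmarks(template)
    src, dst = landmark_control_arrays(src_lm, patient)
    transform = fit_kriging(src, dst, kernel=kernel, ridge=ridge)
    morphed = template.copy()
    morphed.nodes = apply_kriging(transform, template.nodes)
    result = check_quality(mesh_quality(morphed), floor=quality_floor)
    if not result["pass"]:
        warnings.warn(
            "post-morph mesh quality below floor "
            f"{quality_floor}: fractions={result['fractions']}", stacklevel=2)
    log.info("morph quality fractions: %s", result["fractions"])
    return morphed
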