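"""Region-specific orthotropic growth engine.

Growth is represented as per-element eigenstrain rates (the thermal
expansion analog): 17 levels x 13 regions x 3 directions = 663 coefficients.
Vertical body-quadrant coefficients are modulated by the matching IVD
quadrant stress through the linear Hueter-Volkmann law
G = G_m [1 + beta (sigma - sigma_m)], with the stress sensitivity beta
decaying with Risser sign: beta = beta0 - risser * slope (floored at 0).

Sign convention inside the law is tension-positive; compression lowers
sigma below sigma_m and inhibits growth.  Growth is floored at zero (no
resorption).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import defaults, fem, metrics
from .landmarks import LEVELS, LandmarkSet3D
from .materials import FlexibilityParams
from .template import (BODY_QUADRANTS, HexMeshModel, QUADRANTS, REGION_IDS)

log = logging.getLogger(__name__)

DIRECTIONS: Tuple[str, ...] = ("vertical", "lateral", "ap")

DEFAULT_BETA0 = 0.4        # MPa^-1 at Risser 0
DEFAULT_BETA_SLOPE = 0.08  # MPa^-1 per Risser grade


class GrowthCoefficients:
    """Eigenstrain rate (strain/year) per (level, region, direction)."""

    def __init__(self, values: np.ndarray | None = None) -> None:
        if values is None:
            values = np.zeros((len(LEVELS), len(REGION_IDS), len(DIRECTIONS)))
        values = np.asarray(values, dtype=float)
        if values.shape != (len(LEVELS), len(REGION_IDS), len(DIRECTIONS)):
            raise ValueError("coefficient array must be (17, 13, 3)")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite growth coefficient")
        self.values = values

    @property
    def count(self) -> int:
        return self.values.size

    def _idx(self, level: str, region: str, direction: str):
        return (LEVELS.index(level), REGION_IDS.index(region),
                DIRECTIONS.index(direction))

    def get(self, level: str, region: str, direction: str) -> float:
        return float(self.values[self._idx(level, region, direction)])

    def set(self, level: str, region: str, direction: str, v: float) -> None:
        self.values[self._idx(level, region, direction)] = v

    def copy(self) -> "GrowthCoefficients":
        return GrowthCoefficients(self.values.copy())


@dataclass
class GrowthLawParams:
    beta0: float = DEFAULT_BETA0
    beta_slope: float = DEFAULT_BETA_SLOPE
    sigma_m_mode: str = "quadrant_mean"   # or "zero"
    floor_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.beta0 < 0:
            raise ValueError("beta0 must be >= 0")


@dataclass
class PatientProfile:
    age: float                 # years at ITP
    sex: str                   # 'M' | 'F'
    risser: float              # 0-5 at ITP
    weight: float              # kg
    flexibility: Optional[FlexibilityParams] = None
    timepoints: List[float] = field(default_factory=lambda: [0.0])
    risser_final: Optional[float] = None   # at the last timepoint
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        if not 0 <= self.risser <= 5:
            raise ValueError("Risser sign must be in [0, 5]")
        if self.sex.upper() not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.risser_final is not None and self.risser_final < self.risser:
            raise ValueError("Risser sign may not decrease")

    def risser_at(self, t_years: float) -> float:
        """Linear interpolation between documented Risser values, clamped."""
        final = self.risser if self.risser_final is None else self.risser_final
        span = self.timepoints[-1] - self.timepoints[0]
        if span <= 0:
            return self.risser
        frac = np.clip((t_years - self.timepoints[0]) / span, 0.0, 1.0)
        return float(min(5.0, self.risser + frac * (final - self.risser)))


def beta_from_risser(risser: float, beta0: float = DEFAULT_BETA0,
                     slope: float = DEFAULT_BETA_SLOPE) -> float:
    """Stress sensitivity (MPa^-1): beta0 - risser*slope, floored at 0."""
    if not 0 <= risser <= 5:
        raise ValueError(f"Risser sign must be in [0, 5], got {risser}")
    return max(0.0, beta0 - risser * slope)


def modulated_growth(g_m: float, beta: float, sigma: float,
                     sigma_m: float) -> float:
    """G = G_m [1 + beta (sigma - sigma_m)], floored at zero."""
    return max(0.0, g_m * (1.0 + beta * (sigma - sigma_m)))


def allocate_coefficients(
        baseline_table: Dict[str, float] | Dict[Tuple[str, str], float],
        profile: PatientProfile,
        risser: float | None = None) -> GrowthCoefficients:
    """Populate all 663 coefficients from the normative baseline table.

    ``baseline_table`` maps either direction -> strain/year (uniform over
    levels) or (level, direction) -> strain/year.  Age/sex/maturity scaling
    is applied through :func:`defaults.baseline_growth_rate` in the uniform
    case; explicit per-level entries are taken as-is.
    """
    risser = profile.risser if risser is None else risser
    coeffs = GrowthCoefficients()
    per_level = any(isinstance(k, tuple) for k in baseline_table)
    for li, level in enumerate(LEVELS):
        for di, direction in enumerate(DIRECTIONS):
            if per_level:
                key = (level, direction)
                if key not in baseline_table:
                    raise KeyError(f"baseline table missing {key}")
                rate = float(baseline_table[key])
            else:
                if direction not in baseline_table:
                    raise KeyError(
                        f"baseline table missing direction {direction!r}")
                rate = defaults.baseline_growth_rate(
                    direction, risser, profile.sex, dict(baseline_table))
            coeffs.values[li, :, di] = rate
    return coeffs


def modulate_quadrants(coeffs: GrowthCoefficients,
                       quadrant_stresses: Dict[str, Dict[str, float]],
                       params: GrowthLawParams,
                       profile: PatientProfile,
                       risser: float | None = None) -> GrowthCoefficients:
    """Scale vertical body-quadrant coefficients by matching IVD stresses.

    ``quadrant_stresses[level][quadrant]`` is the tension-positive axial
    stress (MPa) in the IVD region adjacent to that body quadrant.  Only
    (body quadrant, vertical) entries change.
    """
    risser = profile.risser if risser is None else risser
    beta = beta_from_risser(risser, params.beta0, params.beta_slope)
    out = coeffs.copy()
    for level in LEVELS:
        if level not in quadrant_stresses:
            raise KeyError(f"missing quadrant stresses for level {level}")
        qs = quadrant_stresses[level]
        missing = [q for q in QUADRANTS if q not in qs]
        if missing:
            raise KeyError(f"missing quadrant stress {missing[0]} at {level}")
        if params.sigma_m_mode == "quadrant_mean":
            sigma_m = float(np.mean([qs[q] for q in QUADRANTS]))
        elif params.sigma_m_mode == "zero":
            sigma_m = 0.0
        else:
            raise ValueError(f"unknown sigma_m mode {params.sigma_m_mode!r}")
        for q in QUADRANTS:
            region = f"body_{q}"
            g = out.get(level, region, "vertical")
            g_new = g * (1.0 + beta * (qs[q] - sigma_m))
            if params.floor_at_zero:
                g_new = max(0.0, g_new)
            out.set(level, region, "vertical", g_new)
    return out


# ---------------------------------------------------------------------------
# Interval stepping
# ---------------------------------------------------------------------------


def _voigt_from_local(R: np.ndarray, diag: Sequence[float]) -> np.ndarray:
    """Rotate a diagonal local strain into a global Voigt vector."""
    E = R @ np.diag(diag) @ R.T
    return np.array([E[0, 0], E[1, 1], E[2, 2],
                     2 * E[0, 1], 2 * E[1, 2], 2 * E[0, 2]])


def growth_eigenstrain(model: HexMeshModel, coeffs: GrowthCoefficients,
                       dt: float,
                       baseline: Dict[str, float] | None = None,
                       profile: PatientProfile | None = None,
                       risser: float | None = None) -> np.ndarray:
    """Per-hex Voigt eigenstrain for one growth step of ``dt`` years.

    Vertebral hexes use their level's modulated (level, region, direction)
    rates in the level-local frame.  IVD hexes grow with the unmodulated
    baseline vertical rate along the disc axis so the discs keep pace with
    the bodies (they are not stress-modulatable).
    """
    eps = np.zeros((model.n_hexes, 6))
    if dt == 0:
        return eps
    frames = {lv: fem.level_frame(model, lv) for lv in LEVELS}
    if baseline is not None and profile is not None:
        r = profile.risser if risser is None else risser
        ivd_rates = [defaults.baseline_growth_rate(d, r, profile.sex, baseline)
                     for d in DIRECTIONS]
    else:
        ivd_rates = [0.0, 0.0, 0.0]
    for e in range(model.n_hexes):
        if model.structure[e] == "vertebra":
            level, region = model.level[e], model.region[e]
            rates = [coeffs.get(level, region, d) for d in DIRECTIONS]
            R = frames[level]
        else:
            upper, lower = model.level[e].split("/")
            zl = fem.ivd_axis(model, upper, lower)
            y = np.array([0.0, 1.0, 0.0])
            yl = y - (y @ zl) * zl
            yl /= np.linalg.norm(yl)
            R = np.column_stack([np.cross(yl, zl), yl, zl])
            rates = ivd_rates
        # local order (ap, lateral, vertical) matches frame columns
        eps[e] = _voigt_from_local(
            R, (rates[2] * dt, rates[1] * dt, rates[0] * dt))
    return eps


@dataclass
class IntervalReport:
    t_start: float
    dt: float
    risser: float
    beta: float
    quadrant_stresses: Dict[str, Dict[str, float]]
    coeffs: GrowthCoefficients


def advance_interval(model: HexMeshModel, profile: PatientProfile,
                     params: GrowthLawParams, t_years: float, dt: float,
                     gravity_table: Dict[str, float] | None = None,
                     baseline_table: Dict[str, float] | None = None,
                     ) -> IntervalReport:
    """One staggered growth step, mutating the model geometry.

    (1) two-pass gravity stress at the current geometry, (2) quadrant
    modulation of the vertical body coefficients, (3) eigenstrain solve,
    (4) commit displaced nodes as the new reference and zero stresses.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    gravity_table = gravity_table or defaults.default_gravity_table()
    baseline_table = baseline_table or dict(defaults.DEFAULT_BASELINE_GROWTH)
    risser = profile.risser_at(t_years)
    beta = beta_from_risser(risser, params.beta0, params.beta_slope)
    state = fem.apply_gravity_two_pass(model, profile.weight, gravity_table)
    qs = {lv: fem.quadrant_stresses(model, state, lv) for lv in LEVELS}
    coeffs = allocate_coefficients(baseline_table, profile, risser=risser)
    coeffs = modulate_quadrants(coeffs, qs, params, profile, risser=risser)
    if dt > 0:
        eps = growth_eigenstrain(model, coeffs, dt, baseline_table, profile,
                                 risser=risser)
        case = fem.LoadCase(eigenstrain=eps)
        u, _ = fem.resolve_tension_only(model, case)
        model.nodes = model.nodes + u.reshape(-1, 3)
    return IntervalReport(t_start=t_years, dt=dt, risser=risser, beta=beta,
                          quadrant_stresses=qs, coeffs=coeffs)


@dataclass
class TimepointRecord:
    t: float
    indices: metrics.ClinicalIndices
    quadrant_stress: Dict[str, float]   # apical IVD, compression-positive
    apex: str
    convex_side: Optional[str]


@dataclass
class Trajectory:
    records: List[TimepointRecord]
    final_model: HexMeshModel
    reports: List[IntervalReport] = field(default_factory=list)


def simulate(model: HexMeshModel, profile: PatientProfile,
             params: GrowthLawParams | None = None,
             gravity_table: Dict[str, float] | None = None,
             baseline_table: Dict[str, float] | None = None,
             max_step_years: float = 0.5) -> Trajectory:
    """Step stress-modulated growth over the profile's timepoints.

    Materials must already be assigned to ``model`` (which is mutated).
    Indices and apical quadrant stresses are recorded at every documented
    timepoint; intervals longer than ``max_step_years`` are subdivided.
    """
    from .template import extract_landmarks  # local to avoid cycle noise

    params = params or GrowthLawParams()
    gravity_table = gravity_table or defaults.default_gravity_table()
    baseline_table = baseline_table or dict(defaults.DEFAULT_BASELINE_GROWTH)
    records: List[TimepointRecord] = []
    reports: List[IntervalReport] = []

    def record(t: float) -> None:
        lm = extract_landmarks(model)
        idx = metrics.measure_indices(lm)
        apex = idx.thoracic.apex
        convex = idx.thoracic.convex_side or "left"
        state = fem.apply_gravity_two_pass(model, profile.weight,
                                           gravity_table)
        qstress = fem.ivd_quadrant_stress(model, state, apex, convex)
        records.append(TimepointRecord(
            t=t, indices=idx, quadrant_stress=qstress, apex=apex,
            convex_side=idx.thoracic.convex_side))

    timepoints = list(profile.timepoints)
    record(timepoints[0])
    for t0, t1 in zip(timepoints, timepoints[1:]):
        span = t1 - t0
        n_sub = max(1, int(np.ceil(span / max_step_years - 1e-9)))
        sub_dt = span / n_sub
        for k in range(n_sub):
            reports.append(advance_interval(
                model, profile, params, t0 + k * sub_dt, sub_dt,
                gravity_table, baseline_table))
        record(t1)
    return Trajectory(records=records, final_model=model, reports=reports)


def trajectory_tables(traj: Trajectory):
    """(indices, quadrant stress) DataFrames mirroring the output CSV layout."""
    import pandas as pd

    idx_rows, qs_rows = [], []
    for rec in traj.records:
        row = {"timepoint": rec.t}
        row.update(rec.indices.as_dict())
        row["apex"] = rec.apex
        idx_rows.append(row)
        for quadrant, value in rec.quadrant_stress.items():
            qs_rows.append({"timepoint": rec.t, "level": rec.apex,
                            "quadrant": quadrant,
                            "stress_MPa": round(value, 4)})
    return pd.DataFrame(idx_rows), pd.DataFrame(qs_rows)
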