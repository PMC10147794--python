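"""Shipped default configuration tables.

All values here are literature-typical pediatric placeholders behind config:
vertebral dimensions interpolated over levels, adult material cards with an
age scale hook, per-level bodyweight fractions for gravity loading, and
baseline growth strain rates.  Every table can be overridden from YAML.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .landmarks import LEVELS

# --- vertebral dimension table (mm) ---------------------------------------
# width = left-right (y), depth = antero-posterior (x), height = cranio-caudal.
# Linear interpolation from T1 to L5, ~10-year-old scale.


def default_dimension_table() -> Dict[str, Dict[str, float]]:
    n = len(LEVELS)
    table: Dict[str, Dict[str, float]] = {}
    for i, level in enumerate(LEVELS):
        t = i / (n - 1)
        table[level] = {
            "width": 26.0 + t * (42.0 - 26.0),
            "depth": 16.0 + t * (32.0 - 16.0),
            "height": 14.0 + t * (24.0 - 14.0),
        }
    return table


def default_ivd_heights() -> Dict[str, float]:
    """IVD heights keyed by the upper adjacent level (e.g. 'T1' = T1/T2 disc)."""
    n = len(LEVELS) - 1
    return {LEVELS[i]: 4.0 + (i / (n - 1)) * (9.0 - 4.0) for i in range(n)}


# --- material cards --------------------------------------------------------

#: Adult elastic moduli (MPa) / stiffnesses (N/mm) and Poisson ratios.
#: age_scale_factor defaults to 1.0 and is set per patient via age_scale().
DEFAULT_MATERIAL_CARDS = {
    "vertebra": {"E": 350.0, "nu": 0.3},
    "ivd": {"E": 20.0, "nu": 0.45},
    "ligament": {"k": 20.0},
    "posterior": {"k": 60.0},
    "costovertebral": {"k": 48.9},
}


def age_scale(age_years: float) -> float:
    """Chronological-age modulus scale factor, clamped to (0, 1].

    Linear ramp chosen so a 16-year-old maps to 0.95 and an 18-year-old to
    adult properties.
    """
    return float(np.clip(0.55 + 0.025 * age_years, 0.2, 1.0))


# --- gravity table ---------------------------------------------------------


def default_gravity_table() -> Dict[str, float]:
    """Per-level applied bodyweight fractions.

    Cumulative load ramps linearly from 0.14 of bodyweight carried at T1
    (head, neck, arms) to 0.55 at L5; each level below T1 contributes the
    increment.
    """
    n = len(LEVELS)
    cumulative = np.linspace(0.14, 0.55, n)
    fractions = {LEVELS[0]: float(cumulative[0])}
    for i in range(1, n):
        fractions[LEVELS[i]] = float(cumulative[i] - cumulative[i - 1])
    return fractions


# --- baseline growth strain rates (strain / year) --------------------------

#: Vertical body growth strain per year at Risser 0, declining linearly to 0
#: at Risser 5; lateral and antero-posterior rates are smaller.  Uniform over
#: levels; sex factor applied on top.
DEFAULT_BASELINE_GROWTH = {
    "vertical": 0.040,
    "lateral": 0.015,
    "ap": 0.015,
}

DEFAULT_SEX_GROWTH_FACTOR = {"F": 1.0, "M": 1.05}


def baseline_growth_rate(direction: str, risser: float, sex: str = "F",
                         table: Dict[str, float] | None = None) -> float:
    """Baseline growth strain/year for one direction at a given maturity."""
    table = table or DEFAULT_BASELINE_GROWTH
    if direction not in table:
        raise KeyError(f"no baseline growth entry for direction {direction!r}")
    maturity = max(0.0, 1.0 - float(risser) / 5.0)
    sex_factor = DEFAULT_SEX_GROWTH_FACTOR.get(sex.upper(), 1.0)
    return table[direction] * maturity * sex_factor
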