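"""Patient-specific material assignment.

Adult material cards are scaled by a chronological-age factor; the IVD
modulus is additionally scaled down with the spine flexibility ratio
SFR = (CAS - CALB) / CAS via E_scaled = E_baseline * (1 - C * SFR) with
C = 0.3 by default.  Age scaling is applied first, flexibility scaling
second.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import defaults
from .template import HexMeshModel

log = logging.getLogger(__name__)

DEFAULT_C = 0.3


@dataclass
class MaterialCard:
    structure: str
    E: Optional[float] = None      # MPa (hex structures)
    k: Optional[float] = None      # N/mm (spring structures)
    nu: float = 0.3
    age_scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.E is None and self.k is None:
            raise ValueError(f"card {self.structure!r} needs E or k")
        for v, name in ((self.E, "E"), (self.k, "k")):
            if v is not None and v <= 0:
                raise ValueError(f"card {self.structure!r}: {name} must be > 0")
        if not 0.0 < self.age_scale_factor <= 1.2:
            raise ValueError("age_scale_factor must be in (0, 1.2]")


@dataclass
class FlexibilityParams:
    cas: float                 # standing Cobb at final timepoint, deg
    calb: float                # Cobb during lateral bending into convexity, deg
    c: float = DEFAULT_C

    sfr: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("C must be >= 0")
        self.sfr = compute_sfr(self.cas, self.calb)


def compute_sfr(cas: float, calb: float) -> float:
    """Spine flexibility ratio (CAS - CALB) / CAS."""
    if cas <= 0:
        raise ValueError(f"standing Cobb angle must be > 0, got {cas}")
    sfr = (cas - calb) / cas
    if not 0.0 <= sfr <= 1.0:
        warnings.warn(f"SFR {sfr:.3f} outside [0, 1]; check CAS/CALB inputs",
                      stacklevel=2)
    return sfr


def scale_by_age(card: MaterialCard) -> float:
    """Adult modulus/stiffness times the age scale factor."""
    value = card.E if card.E is not None else card.k
    return value * card.age_scale_factor


def scale_ivd_modulus(e_baseline: float, sfr: float, c: float = DEFAULT_C) -> float:
    """Flexibility-scaled IVD modulus E_baseline * (1 - C * SFR)."""
    if e_baseline <= 0:
        raise ValueError("baseline modulus must be > 0")
    if c * sfr >= 1.0:
        raise ValueError(f"C*SFR = {c * sfr:.3f} >= 1 gives a nonphysical "
                         "modulus")
    return e_baseline * (1.0 - c * sfr)


def default_cards(age: float | None = None) -> Dict[str, MaterialCard]:
    """Default card set; if an age is given the age scale factor is applied."""
    factor = defaults.age_scale(age) if age is not None else 1.0
    raw = defaults.DEFAULT_MATERIAL_CARDS
    return {
        "vertebra": MaterialCard("vertebra", E=raw["vertebra"]["E"],
                                 nu=raw["vertebra"]["nu"],
                                 age_scale_factor=factor),
        "ivd": MaterialCard("ivd", E=raw["ivd"]["E"], nu=raw["ivd"]["nu"],
                            age_scale_factor=factor),
        "ligament": MaterialCard("ligament", k=raw["ligament"]["k"],
                                 age_scale_factor=factor),
        "posterior": MaterialCard("posterior", k=raw["posterior"]["k"],
                                  age_scale_factor=factor),
        "costovertebral": MaterialCard("costovertebral",
                                       k=raw["costovertebral"]["k"],
                                       age_scale_factor=factor),
    }


def assign_materials(model: HexMeshModel, cards: Dict[str, MaterialCard],
                     flexibility: FlexibilityParams | None = None) -> HexMeshModel:
    """Set per-hex (E, nu) and per-spring k on the model, in place.

    Hexes take the age-scaled card modulus; IVD hexes are additionally
    flexibility-scaled.  Springs take the age-scaled stiffness of the card
    matching their label.
    """
    E = np.zeros(model.n_hexes)
    nu = np.zeros(model.n_hexes)
    for structure in np.unique(model.structure):
        if structure not in cards:
            raise KeyError(f"no material card for structure {structure!r}")
        card = cards[structure]
        mask = model.structure == structure
        e_scaled = scale_by_age(card)
        if structure == "ivd" and flexibility is not None:
            e_scaled = scale_ivd_modulus(e_scaled, flexibility.sfr,
                                         flexibility.c)
        E[mask] = e_scaled
        nu[mask] = card.nu
        log.info("assigned %s: E=%.1f MPa nu=%.2f (%d elements)",
                 structure, e_scaled, card.nu, int(mask.sum()))
    for spring in model.springs:
        if spring.label not in cards:
            raise KeyError(f"no material card for spring label "
                           f"{spring.label!r}")
        spring.stiffness = scale_by_age(cards[spring.label])
    model.elem_E = E
    model.elem_nu = nu
    return model
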