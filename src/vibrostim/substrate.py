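"""Small substrate-preparation calculations.

Only the arithmetic that defines the adhesion conditions lives here; gel
casting and crosslinking chemistry are wet-lab protocol, not computation.
"""

from __future__ import annotations

import math

__all__ = ["coating_surface_density"]


def coating_surface_density(mass_ug: float, well_diameter_mm: float) -> float:
    """Protein surface density (µg/cm²) of a coating on a circular well.

    E.g. 3 µg of fibronectin on a 14 mm well is about 2 µg/cm².
    """
    if not (mass_ug >= 0 and well_diameter_mm > 0):
        raise ValueError("mass must be >= 0 and diameter > 0")
    area_cm2 = math.pi * (well_diameter_mm / 20.0) ** 2  # mm diameter -> cm radius
    return mass_ug / area_cm2
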