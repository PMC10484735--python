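"""Physical constants shared across the package.

All lengths are nm, forces pN, energies pN·nm, times s, concentrations nM.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Constants:
    """Thermal energy and canonical DNA dimensions.

    Attributes
    ----------
    kBT : thermal energy in pN·nm (4.11 at 298 K).
    dsdna_rise : helical rise of B-form dsDNA, nm per base pair.
    dsdna_radius : radius of the dsDNA cylinder, nm.
    ssdna_contour_per_nt : contour length of bare ssDNA, nm per nucleotide.
    """

    kBT: float = 4.11
    dsdna_rise: float = 0.34
    dsdna_radius: float = 1.0
    ssdna_contour_per_nt: float = 0.56

    def __post_init__(self) -> None:
        for name in ("kBT", "dsdna_rise", "dsdna_radius", "ssdna_contour_per_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONSTANTS = Constants()
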