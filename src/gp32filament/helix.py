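"""Ideal-helix geometry of a cooperative SSB–ssDNA filament.

A protein filament winding ssDNA into an ideal helix of radius R shortens
the apparent contour length per nucleotide from L (bare ssDNA) to L'
(length along the helical axis).  Arc-length conservation on one turn gives

    R/rho = (1/2pi) * sqrt((L/L')^2 - 1)

with rho the helical pitch.  From the ratio and the measured filament
radius follow the pitch, the nucleotides wound per turn (rho/L'), the
number of proteins per turn, the twist angle between neighbours, and the
occluded binding-site size bss = h/L' when the axial length per protein h
is fixed.  The module also carries the cylinder-volume radius estimate used
to calibrate R against dsDNA, and the replication-turnover arithmetic that
converts a fork rate into the per-protein dissociation rate required to
clear the template.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

from .constants import Constants, DEFAULT_CONSTANTS
from .errors import DomainError

__all__ = [
    "HelixInputs",
    "HelixParameters",
    "VolumeComparison",
    "TurnoverRequirement",
    "radius_pitch_ratio",
    "contour_ratio_from_pitch_ratio",
    "helix_parameters",
    "helix_sweep",
    "filament_radius_from_volumes",
    "turnover_requirement",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class HelixInputs:
    """Inputs of the ideal-helix model.

    R : filament radius, nm.
    L : bare ssDNA contour length per nucleotide, nm/nt.
    L_prime : contour of the complex along the helical axis, nm/nt.
    h : axial length of one protein along the filament, nm (optional; when
        given, turn occupancy uses the axial convention N = pitch/h and the
        binding-site size shrinks as bss = h/L').
    bss_ref : reference occluded site size, nt per protein (7 for the
        relaxed, optimally wound filament).
    """

    R: float
    L: float
    L_prime: float
    h: Optional[float] = None
    bss_ref: float = 7.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if not (0 < self.L_prime <= self.L):
            raise ValueError("require 0 < L_prime <= L")
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be > 0")
        if self.bss_ref <= 0:
            raise ValueError("bss_ref must be > 0")


@dataclass(frozen=True)
class HelixParameters:
    """Derived descriptors of the filament helix.

    ``pitch`` is infinite (and ``turns_defined`` False) in the fully
    unwound limit L' = L, where the defined limits ratio = 0 and twist = 0
    are reported.
    """

    ratio: float                 # R/rho, dimensionless
    pitch: float                 # rho, nm per turn
    nt_per_turn: float           # rho / L'
    proteins_per_turn: float     # N
    twist_per_protein: float     # alpha = 360/N, degrees
    bss: float                   # occluded site size, nt per protein
    axial_per_protein: float     # h, nm along the axis
    arc_per_protein: float       # L * bss_ref, nm of ssDNA contour
    density_per_nt: float        # proteins per nucleotide = 1/bss
    density_per_nm: float        # proteins per nm of ssDNA contour
    turns_defined: bool = True


def radius_pitch_ratio(L: float, L_prime: float) -> float:
    """Radius-to-pitch ratio (1/2pi) sqrt((L/L')^2 - 1) of the ideal helix."""
    if L_prime <= 0 or L <= 0:
        raise DomainError("contour lengths must be > 0")
    if L_prime > L:
        raise DomainError("L_prime > L describes an unwindable geometry")
    return math.sqrt((L / L_prime) ** 2 - 1.0) / TWO_PI


def contour_ratio_from_pitch_ratio(ratio: float) -> float:
    """Inverse relation: L/L' = sqrt((2pi * ratio)^2 + 1)."""
    if ratio < 0:
        raise DomainError("ratio must be >= 0")
    return math.sqrt((TWO_PI * ratio) ** 2 + 1.0)


def helix_parameters(inputs: HelixInputs) -> HelixParameters:
    """All helix descriptors from radius, contour lengths and site size.

    Two conventions for proteins per turn: the relaxed-filament convention
    nt_per_turn / bss_ref (used when ``h`` is not given, appropriate for the
    optimally wound low-concentration state) and the axial convention
    pitch / h (used when ``h`` is supplied, appropriate for titration sweeps
    where the protein's axial footprint stays constant while its ssDNA
    footprint shrinks).
    """
    ratio = radius_pitch_ratio(inputs.L, inputs.L_prime)
    arc = inputs.L * inputs.bss_ref
    if ratio == 0.0:
        # fully unwound: straight filament, infinite pitch
        bss = inputs.h / inputs.L_prime if inputs.h is not None else inputs.bss_ref
        axial = inputs.h if inputs.h is not None else inputs.L_prime * bss
        return HelixParameters(0.0, math.inf, math.inf, math.inf, 0.0,
                               bss, axial, arc,
                               1.0 / bss, 1.0 / (bss * inputs.L),
                               turns_defined=False)
    pitch = inputs.R / ratio
    nt_per_turn = pitch / inputs.L_prime
    if inputs.h is not None:
        proteins_per_turn = pitch / inputs.h
        bss = inputs.h / inputs.L_prime
        axial = inputs.h
    else:
        proteins_per_turn = nt_per_turn / inputs.bss_ref
        bss = inputs.bss_ref
        axial = (inputs.L_prime / inputs.L) * arc
    twist = 360.0 / proteins_per_turn
    return HelixParameters(ratio, pitch, nt_per_turn, proteins_per_turn,
                           twist, bss, axial, arc,
                           1.0 / bss, 1.0 / (bss * inputs.L))


def helix_sweep(l_prime_table: Mapping[float, float], R: float, L: float,
                h: float, bss_ref: float = 7.0) -> Dict[float, HelixParameters]:
    """Helix parameters vs free-protein concentration at fixed R and h.

    ``l_prime_table`` maps concentration (nM) to the measured complex
    contour L' (nm/nt).  As L' grows with concentration the pitch and
    proteins per turn increase while twist and binding-site size decrease.
    A non-monotone L' table is processed as-is with a warning.
    """
    concs = sorted(l_prime_table)
    lps = [l_prime_table[c] for c in concs]
    if any(b < a for a, b in zip(lps, lps[1:])):
        warnings.warn("L' is not monotone in concentration; processed as-is",
                      stacklevel=2)
    return {c: helix_parameters(HelixInputs(R, L, l_prime_table[c], h, bss_ref))
            for c in concs}


@dataclass(frozen=True)
class VolumeComparison:
    """Integrated AFM volumes and lengths of dsDNA and ssDNA complexes."""

    V_ds: float
    V_ss: float
    L_ds: float
    L_ss: float
    r_ds: float

    def __post_init__(self) -> None:
        for name in ("V_ds", "V_ss", "L_ds", "L_ss", "r_ds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def filament_radius_from_volumes(vc: VolumeComparison) -> float:
    """Filament radius from cylinder-volume comparison with dsDNA.

    Treating both molecules as uniform cylinders, V = L pi r^2 gives
    r_ss = sqrt(V_ss L_ds / (V_ds L_ss)) * r_ds.
    """
    return math.sqrt(vc.V_ss * vc.L_ds / (vc.V_ds * vc.L_ss)) * vc.r_ds


def dsdna_length_from_bp(n_bp: int,
                         constants: Constants = DEFAULT_CONSTANTS) -> float:
    """dsDNA reference length n_bp * 0.34 nm for the volume comparison."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return n_bp * constants.dsdna_rise


@dataclass(frozen=True)
class TurnoverRequirement:
    """Protein turnover needed to keep pace with a replication fork."""

    proteins_per_s: float    # fork_rate / bss
    per_protein_rate: float  # fork_rate / fragment_len, s^-1


def turnover_requirement(fork_rate: float, bss: float,
                         fragment_len: float) -> TurnoverRequirement:
    """Dissociation demand imposed by a fork synthesizing fork_rate nt/s.

    A fork consuming ``fork_rate`` nucleotides of template per second must
    displace ``fork_rate/bss`` proteins per second; spread over the
    ``fragment_len/bss`` proteins saturating one Okazaki-fragment template,
    each protein must dissociate at ``fork_rate/fragment_len`` per second.
    """
    if fork_rate <= 0 or bss <= 0 or fragment_len <= 0:
        raise ValueError("all turnover inputs must be > 0")
    return TurnoverRequirement(fork_rate / bss, fork_rate / fragment_len)
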