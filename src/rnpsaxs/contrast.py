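"""Sucrose contrast conditions for X-ray contrast variation.

Sucrose raises the solvent electron density, selectively dimming the protein
phase (~0.425 e/A^3) relative to nucleic acid (~0.550 e/A^3).  The solvent
electron density is computed from a quadratic fit to standard 20 C
sucrose-solution mass densities combined with the electrons-per-gram mixture
rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import DomainError
from .io import NUCLEIC, PROTEIN, SOLVENT

AVOGADRO = 6.02214076e23

# Quadratic fit rho(w) = a + b*w + c*w^2 (g/cm^3) to 20 C sucrose-solution
# density tables (CRC), valid for weight fraction w in [0, 0.70].
SUCROSE_DENSITY_COEFFS = (0.99823, 0.3875, 0.1563)
MAX_SUCROSE_W = 0.70

WATER_ELECTRONS, WATER_MOLAR_MASS = 10.0, 18.015       # e-, g/mol
SUCROSE_ELECTRONS, SUCROSE_MOLAR_MASS = 182.0, 342.297  # C12H22O11

#: default phase electron densities (e-/A^3), standard literature values
PROTEIN_EDENSITY = 0.425
NUCLEIC_EDENSITY = 0.550


def sucrose_solution_density(sucrose_w: float) -> float:
    """Mass density (g/cm^3) of an aqueous sucrose solution at 20 C."""
    if not 0.0 <= sucrose_w <= MAX_SUCROSE_W:
        raise DomainError(f"sucrose weight fraction {sucrose_w} outside [0, {MAX_SUCROSE_W}]")
    a, b, c = SUCROSE_DENSITY_COEFFS
    return a + b * sucrose_w + c * sucrose_w ** 2


def solvent_electron_density(sucrose_w: float) -> float:
    """Electron density (e-/A^3) of a sucrose solution of weight fraction w."""
    rho_mass = sucrose_solution_density(sucrose_w)
    e_per_gram = ((1.0 - sucrose_w) * WATER_ELECTRONS / WATER_MOLAR_MASS
                  + sucrose_w * SUCROSE_ELECTRONS / SUCROSE_MOLAR_MASS)
    # e-/cm^3 -> e-/A^3 : 1 cm^3 = 1e24 A^3
    return rho_mass * e_per_gram * AVOGADRO / 1e24


@dataclass(frozen=True)
class ContrastCondition:
    """One solvent condition and the per-phase excess electron densities."""

    sucrose_w: float
    solvent_edensity: float
    protein_edensity: float
    nucleic_edensity: float
    delta_protein: float
    delta_nucleic: float

    def contrast_of(self, phase: int) -> float:
        if phase == PROTEIN:
            return self.delta_protein
        if phase == NUCLEIC:
            return self.delta_nucleic
        if phase == SOLVENT:
            return 0.0
        raise DomainError(f"unknown phase code {phase}")

    @property
    def deltas(self):
        """Contrast per phase code (solvent, protein, nucleic)."""
        return (0.0, self.delta_protein, self.delta_nucleic)


def make_condition(sucrose_w: float,
                   protein_edensity: float = PROTEIN_EDENSITY,
                   nucleic_edensity: float = NUCLEIC_EDENSITY) -> ContrastCondition:
    """Build a :class:`ContrastCondition` at the given sucrose weight fraction."""
    if protein_edensity <= 0 or nucleic_edensity <= 0:
        raise DomainError("phase electron densities must be positive")
    rho_s = solvent_electron_density(sucrose_w)
    return ContrastCondition(
        sucrose_w=sucrose_w,
        solvent_edensity=rho_s,
        protein_edensity=protein_edensity,
        nucleic_edensity=nucleic_edensity,
        delta_protein=protein_edensity - rho_s,
        delta_nucleic=nucleic_edensity - rho_s,
    )


def match_point(phase_edensity: float) -> float:
    """Sucrose weight fraction at which a phase of the given electron density
    becomes invisible (solvent density equals the phase density)."""
    lo, hi = 0.0, MAX_SUCROSE_W
    f = lambda w: solvent_electron_density(w) - phase_edensity
    if f(lo) * f(hi) > 0:
        raise DomainError(
            f"no match point for electron density {phase_edensity} within "
            f"w in [0, {MAX_SUCROSE_W}]")
    return brentq(f, lo, hi, xtol=1e-10)
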