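"""Bead-model hydrodynamics: Kirkwood friction, sedimentation coefficients,
s20,w standardization, Svedberg mass arithmetic and Perrin axial ratios.

All frictions are first-order Kirkwood estimates over the non-solvent bead
centers; hydration is excluded (anhydrous bead surfaces), which biases the
calculated frictional ratios slightly low relative to experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from .errors import DomainError, RangeError
from .io import SOLVENT, BeadModel

AVOGADRO = 6.02214076e23
SVEDBERG = 1e-13            # s
CM_PER_A = 1e-8

# water at 20 C, the s20,w standard state
WATER20_DENSITY = 0.99823       # g/cm^3
WATER20_VISCOSITY = 0.010020    # poise


@dataclass(frozen=True)
class SolventSpec:
    density: float = WATER20_DENSITY       # g/cm^3
    viscosity: float = WATER20_VISCOSITY   # poise
    temperature: float = 20.0              # C

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise DomainError("solvent density/viscosity must be positive")


WATER_20C = SolventSpec()


@dataclass
class HydroResult:
    friction: float         # g/s
    stokes_radius: float    # A
    s_buffer: float         # Svedberg, in the given solvent
    s20w: float             # Svedberg, standardized
    f_over_f0: float
    mass_used: float        # kD
    vbar_used: float        # cm^3/g


def surface_beads(model: BeadModel, full_shell: int = 12) -> np.ndarray:
    """Coordinates of the hydrodynamic surface: non-solvent beads whose
    neighbour shell (within 1.05 lattice spacings) is incomplete.

    Interior beads of a filled model are hydrodynamically shielded; keeping
    them in the Kirkwood sum biases the friction high (a filled sphere would
    converge to 5R/6 instead of R), so only the surface shell is summed.
    """
    from scipy.spatial import cKDTree
    ns = model.nonsolvent()
    coords = ns.centers if ns.n_beads else model.centers
    if len(coords) <= 2:
        return coords
    spacing = model.spacing_estimate()
    tree = cKDTree(coords)
    counts = np.array([len(tree.query_ball_point(x, spacing * 1.05)) - 1
                       for x in coords])
    surf = coords[counts < full_shell]
    return surf if len(surf) else coords


def kirkwood_friction(model: BeadModel, solvent: SolventSpec = WATER_20C,
                      surface_only: bool = True) -> float:
    """Kirkwood-Bloomfield translational friction (g/s) of the bead model.

    f = N * 6 pi eta sigma / (1 + (sigma/N) * sum_{i != j} 1/r_ij)

    summed over the surface shell by default (see :func:`surface_beads`).
    """
    if surface_only:
        coords = surface_beads(model)
    else:
        ns = model.nonsolvent()
        coords = ns.centers if ns.n_beads else model.centers
    n = len(coords)
    if n == 0:
        raise DomainError("no beads to compute friction for")
    sigma_cm = model.bead_radius * CM_PER_A
    if n == 1:
        return 6.0 * math.pi * solvent.viscosity * sigma_cm
    d = pdist(coords)
    if np.any(d <= 0):
        raise DomainError("coincident bead centers")
    inv_sum = 2.0 * float(np.sum(1.0 / (d * CM_PER_A)))
    f = n * 6.0 * math.pi * solvent.viscosity * sigma_cm \
        / (1.0 + (sigma_cm / n) * inv_sum)
    return f


def stokes_radius(friction: float, solvent: SolventSpec = WATER_20C) -> float:
    """Stokes radius (A) from a translational friction (g/s)."""
    return friction / (6.0 * math.pi * solvent.viscosity) / CM_PER_A


def sphere_friction(mass_kd: float, vbar: float,
                    solvent: SolventSpec = WATER_20C,
                    f_over_f0: float = 1.0) -> float:
    """Friction (g/s) of the equal-volume anhydrous sphere, times f/f0."""
    r0_cm = (3.0 * mass_kd * 1000.0 * vbar / (4.0 * math.pi * AVOGADRO)) ** (1.0 / 3.0)
    return f_over_f0 * 6.0 * math.pi * solvent.viscosity * r0_cm


def frictional_ratio(friction: float, mass_kd: float, vbar: float,
                     solvent: SolventSpec = WATER_20C) -> float:
    """f/f0 relative to the equal-volume anhydrous sphere."""
    return friction / sphere_friction(mass_kd, vbar, solvent)


def sedimentation_coefficient(friction: float, mass_kd: float, vbar: float,
                              solvent: SolventSpec = WATER_20C) -> float:
    """Svedberg equation: s = M (1 - vbar rho) / (N_A f), in Svedberg."""
    buoyancy = 1.0 - vbar * solvent.density
    if buoyancy == 0.0:
        raise DomainError("neutral buoyancy: sedimentation undefined")
    s = mass_kd * 1000.0 * buoyancy / (AVOGADRO * friction)
    return s / SVEDBERG


def s20w_correction(s_buffer: float, solvent: SolventSpec, vbar: float) -> float:
    """Standardize an observed s (Svedberg) to water at 20 C."""
    num = 1.0 - vbar * WATER20_DENSITY
    den = 1.0 - vbar * solvent.density
    if den == 0.0:
        raise DomainError("neutral buoyancy in the experimental buffer")
    return s_buffer * (solvent.viscosity / WATER20_VISCOSITY) * num / den


def svedberg_mass(s: float, f_over_f0: float, vbar: float,
                  solvent: SolventSpec = WATER_20C,
                  bracket_kd=(0.1, 1e6)) -> float:
    """Mass (kD) from s (Svedberg), f/f0 and vbar.

    Solves M (1 - vbar rho) = N_A s f,  f = 6 pi eta (f/f0) R0(M),
    by bracketed root-finding (R0 is the equal-volume sphere radius).
    """
    if s <= 0 or vbar <= 0:
        raise DomainError("s and vbar must be positive")
    if f_over_f0 < 1.0:
        raise DomainError("f/f0 < 1 is unphysical")
    buoyancy = 1.0 - vbar * solvent.density
    if buoyancy <= 0:
        raise DomainError("particle does not sediment (nonpositive buoyancy)")
    s_sec = s * SVEDBERG

    def g(m_kd):
        f = sphere_friction(m_kd, vbar, solvent, f_over_f0)
        return m_kd * 1000.0 * buoyancy - AVOGADRO * s_sec * f

    lo, hi = bracket_kd
    if g(lo) * g(hi) > 0:
        raise DomainError("no positive mass root in the bracket")
    return brentq(g, lo, hi, xtol=1e-6)


# ---------------------------------------------------------------------------
# Perrin ellipsoid friction factors

def perrin_factor(p: float, shape_class: str) -> float:
    """Perrin translational friction factor F(p) for ellipsoids of
    revolution, with p = (long axis)/(short axis) >= 1.

    prolate: F = sqrt(p^2-1) / (p^(1/3) ln(p + sqrt(p^2-1)))
    oblate:  F = sqrt(p^2-1) / (p^(2/3) arctan(sqrt(p^2-1)))
    """
    if p < 1.0:
        raise DomainError("axial ratio must be >= 1")
    if p == 1.0:
        return 1.0
    xi = math.sqrt(p * p - 1.0)
    if shape_class == "prolate":
        return xi / (p ** (1.0 / 3.0) * math.log(p + xi))
    if shape_class == "oblate":
        return xi / (p ** (2.0 / 3.0) * math.atan(xi))
    raise DomainError(f"unknown shape class {shape_class!r}")


def perrin_axial_ratio(f_over_f0: float, shape_class: str,
                       p_max: float = 1e4) -> float:
    """Invert the Perrin factor numerically to an axial ratio p >= 1."""
    if f_over_f0 <= 1.0:
        raise DomainError("f/f0 must exceed 1 to invert the Perrin factor")
    g = lambda p: perrin_factor(p, shape_class) - f_over_f0
    if g(p_max) < 0:
        raise RangeError(f"no axial ratio below {p_max} gives f/f0 = {f_over_f0}")
    return brentq(g, 1.0 + 1e-9, p_max, xtol=1e-8)


def volume_from_mass(mass_kd: float, vbar: float) -> float:
    """Anhydrous molecular volume (A^3) from mass (kD) and vbar (cm^3/g)."""
    if mass_kd <= 0 or vbar <= 0:
        raise DomainError("mass and vbar must be positive")
    return mass_kd * 1000.0 * vbar / AVOGADRO * 1e24


def hydro_report(model: BeadModel, mass_kd: float, vbar: float,
                 solvent: SolventSpec = WATER_20C) -> HydroResult:
    """Full hydrodynamic characterization of a bead model."""
    f = kirkwood_friction(model, solvent)
    rs_ = stokes_radius(f, solvent)
    s_b = sedimentation_coefficient(f, mass_kd, vbar, solvent)
    s20 = s20w_correction(s_b, solvent, vbar)
    ratio = frictional_ratio(f, mass_kd, vbar, solvent)
    return HydroResult(friction=f, stokes_radius=rs_, s_buffer=s_b,
                       s20w=s20, f_over_f0=ratio, mass_used=mass_kd,
                       vbar_used=vbar)
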