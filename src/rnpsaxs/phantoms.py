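"""Two-phase bead phantoms standing in for the undeposited beamline data.

The central object is a ~244 x 244 x 79 A oblate ribonucleoprotein phantom
with a lower-density protein ellipsoid at the center of mass and the nucleic
phase thinned into two lobes joined by a neck (a "bow-tie"), plus a variant
with an appended tRNA-sized distal lobe, and a family of single-phase and
concentric control shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, ResolutionError, SpecificationError
from .io import NUCLEIC, PROTEIN, BeadModel, Lattice

PHANTOM_KINDS = ("sphere", "oblate", "prolate", "two-phase-RNP",
                 "concentric-shell", "displaced-core", "RNP-plus-lobe")

# Bow-tie waist geometry (fractions of the envelope semi-axes).  The RNA
# envelope is thinned by removing beads inside an elliptical waist around the
# particle center, leaving two large lobes joined by a flattened neck.
WAIST_X_FRACTION = 0.30   # half-extent of the waist along the lobe axis
NECK_Y_FRACTION = 0.45    # neck half-width relative to the b semi-axis


@dataclass
class LobeSpec:
    offset: float    # displacement of lobe center from phantom center, A
    diameter: float  # A
    axis: int = 0    # unit axis along which the lobe is appended


@dataclass
class PhantomSpec:
    """Geometric recipe for a synthetic bead phantom."""

    kind: str
    dimensions: tuple          # full axis lengths, A
    lattice_spacing: float     # nearest-neighbour bead distance, A
    protein_fraction_volume: float = 0.40
    lobe: Optional[LobeSpec] = None
    core_offset: float = 0.0   # displaced-core: core displacement along x, A
    seed: int = 0

    def __post_init__(self):
        if self.kind not in PHANTOM_KINDS:
            raise SpecificationError(f"unknown phantom kind {self.kind!r}")
        dims = tuple(float(d) for d in np.atleast_1d(self.dimensions))
        if len(dims) == 1:
            dims = dims * 3
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise SpecificationError("dimensions must be 1 or 3 positive lengths")
        self.dimensions = dims
        if self.kind in ("two-phase-RNP", "concentric-shell", "displaced-core",
                         "RNP-plus-lobe"):
            if not 0.0 < self.protein_fraction_volume < 1.0:
                raise SpecificationError("protein_fraction_volume must be in (0,1)")


def hcp_lattice(half_extent: np.ndarray, spacing: float) -> np.ndarray:
    """Hexagonal-close-packed points filling [-h, h]^3 (per-axis half extents).

    Nearest-neighbour distance equals ``spacing``; volume per site is
    spacing^3 / sqrt(2).
    """
    a = spacing
    dy = a * math.sqrt(3.0) / 2.0
    dz = a * math.sqrt(2.0 / 3.0)
    hx, hy, hz = half_extent
    ni = int(math.ceil(hx / a)) + 2
    nj = int(math.ceil(hy / dy)) + 2
    nk = int(math.ceil(hz / dz)) + 2
    pts = []
    for k in range(-nk, nk + 1):
        zoff_x = a / 2.0 if k % 2 else 0.0
        zoff_y = a * math.sqrt(3.0) / 6.0 if k % 2 else 0.0
        z = k * dz
        for j in range(-nj, nj + 1):
            xoff = a / 2.0 if j % 2 else 0.0
            y = j * dy + zoff_y
            for i in range(-ni, ni + 1):
                x = i * a + xoff + zoff_x
                if abs(x) <= hx + a and abs(y) <= hy + a and abs(z) <= hz + a:
                    pts.append((x, y, z))
    return np.asarray(pts, dtype=float)


def _inside_ellipsoid(pts: np.ndarray, semi: np.ndarray, center=None) -> np.ndarray:
    d = pts if center is None else pts - center
    return np.sum((d / semi) ** 2, axis=1) <= 1.0


def build_phantom(spec: PhantomSpec) -> BeadModel:
    """Construct the bead model described by ``spec`` (deterministic)."""
    dims = np.asarray(spec.dimensions)
    a = spec.lattice_spacing
    if a > dims.min() / 6.0:
        raise ResolutionError(
            f"lattice spacing {a} too coarse for dimensions {spec.dimensions} "
            "(need spacing <= min(dimensions)/6)")
    semi = dims / 2.0
    rb = a / 2.0

    extra = np.zeros(3)
    if spec.kind == "RNP-plus-lobe" and spec.lobe is not None:
        extra[spec.lobe.axis] = abs(spec.lobe.offset) + spec.lobe.diameter / 2.0
    pts = hcp_lattice(semi + extra + a, a)

    if spec.kind in ("sphere", "oblate", "prolate"):
        inside = _inside_ellipsoid(pts, semi)
        centers = pts[inside]
        phases = np.full(len(centers), PROTEIN, np.int8)
        return BeadModel(centers, rb, phases, Lattice(a), label=spec.kind)

    if spec.kind in ("concentric-shell", "displaced-core"):
        inside = _inside_ellipsoid(pts, semi)
        body = pts[inside]
        offset = np.array([spec.core_offset, 0.0, 0.0])
        frac = spec.protein_fraction_volume
        # bisection on the core scale so the realized bead-count fraction
        # matches the requested volume fraction
        lo, hi = 0.02, 0.98
        for _ in range(50):
            s = 0.5 * (lo + hi)
            core = _inside_ellipsoid(body, s * semi, center=offset)
            f = core.sum() / len(body)
            if f < frac:
                lo = s
            else:
                hi = s
        core = _inside_ellipsoid(body, 0.5 * (lo + hi) * semi, center=offset)
        phases = np.where(core, PROTEIN, NUCLEIC).astype(np.int8)
        return BeadModel(body, rb, phases, Lattice(a), label=spec.kind)

    if spec.kind in ("two-phase-RNP", "RNP-plus-lobe"):
        inside = _inside_ellipsoid(pts, semi)
        body = pts[inside]
        frac = spec.protein_fraction_volume

        def carve_and_assign(s):
            core = _inside_ellipsoid(body, s * semi)
            x, y = body[:, 0], body[:, 1]
            in_waist = np.abs(x) <= WAIST_X_FRACTION * semi[0]
            in_neck = (y / (NECK_Y_FRACTION * semi[1])) ** 2 \
                + (body[:, 2] / semi[2]) ** 2 <= 1.0
            keep = core | ~in_waist | in_neck
            return core, keep

        lo, hi = 0.02, 0.98
        for _ in range(50):
            s = 0.5 * (lo + hi)
            core, keep = carve_and_assign(s)
            f = core[keep].sum() / max(keep.sum(), 1)
            if f < frac:
                lo = s
            else:
                hi = s
        core, keep = carve_and_assign(0.5 * (lo + hi))
        centers = body[keep]
        phases = np.where(core[keep], PROTEIN, NUCLEIC).astype(np.int8)

        if spec.kind == "RNP-plus-lobe":
            if spec.lobe is None:
                raise SpecificationError("RNP-plus-lobe requires a lobe spec")
            lc = np.zeros(3)
            lc[spec.lobe.axis] = spec.lobe.offset
            r_lobe = spec.lobe.diameter / 2.0
            in_lobe = np.sum((pts - lc) ** 2, axis=1) <= r_lobe ** 2
            overlap = (in_lobe & inside).sum()
            n_lobe = in_lobe.sum()
            if n_lobe and overlap / n_lobe > 0.10:
                raise SpecificationError(
                    f"lobe overlaps the body by {overlap / n_lobe:.0%} "
                    "of its volume (limit 10%)")
            lobe_pts = pts[in_lobe & ~inside]
            centers = np.vstack([centers, lobe_pts])
            phases = np.concatenate(
                [phases, np.full(len(lobe_pts), NUCLEIC, np.int8)])
        return BeadModel(centers, rb, phases, Lattice(a), label=spec.kind)

    raise SpecificationError(f"unhandled phantom kind {spec.kind!r}")


def rnp_phantom(lattice_spacing: float = 8.0,
                protein_fraction_volume: float = 0.40) -> BeadModel:
    """The default oblate RNP phantom: 244 x 244 x 79 A overall, protein at
    the center of mass, peripheral bow-tie nucleic envelope."""
    return build_phantom(PhantomSpec(
        kind="two-phase-RNP", dimensions=(244.0, 244.0, 79.0),
        lattice_spacing=lattice_spacing,
        protein_fraction_volume=protein_fraction_volume))


def rnp_plus_lobe_phantom(lattice_spacing: float = 8.0,
                          protein_fraction_volume: float = 0.40,
                          lobe_offset: float = 145.0,
                          lobe_diameter: float = 60.0) -> BeadModel:
    """RNP phantom with a tRNA-sized spherical lobe appended distally."""
    return build_phantom(PhantomSpec(
        kind="RNP-plus-lobe", dimensions=(244.0, 244.0, 79.0),
        lattice_spacing=lattice_spacing,
        protein_fraction_volume=protein_fraction_volume,
        lobe=LobeSpec(offset=lobe_offset, diameter=lobe_diameter)))


def coordinate_rg(model: BeadModel, weights=None) -> float:
    """Weighted radius of gyration of bead centers.

    With contrast weights w_i = delta_rho_i * v_i this is the Rg implied by
    the low-q limit of the scattering (bead form-factor term excluded).
    """
    w = np.ones(model.n_beads) if weights is None else np.asarray(weights, float)
    if np.sum(w) == 0:
        raise DomainError("zero total weight: Rg undefined")
    cm = np.average(model.centers, axis=0, weights=w)
    d2 = np.sum((model.centers - cm) ** 2, axis=1)
    return math.sqrt(np.average(d2, weights=w))
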