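"""Shared containers and file I/O for 1-D scattering profiles and bead models.

Profiles travel as 3-column whitespace text (q [1/A], I, sigma).  Bead models
travel as PDB files with one ATOM record per bead; the residue name encodes
the phase and ``REMARK 265`` lines carry the bead radius and lattice spacing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError

log = logging.getLogger(__name__)

# Integer phase codes used throughout (compact enough for numba kernels).
SOLVENT, PROTEIN, NUCLEIC = 0, 1, 2
PHASE_NAMES = ("solvent", "protein", "nucleic")

#: residue-name <-> phase map used in bead-model PDB files
DEFAULT_RESNAME_MAP = {"SOL": SOLVENT, "PRO": PROTEIN, "RNA": NUCLEIC}
#: chain identifiers per phase, for viewer convenience
PHASE_CHAINS = {SOLVENT: "S", PROTEIN: "A", NUCLEIC: "B"}

MIN_PROFILE_ROWS = 8

# Parameters of the Poisson-like placeholder sigma  k*sqrt(max(I,0)+c)
# used when a profile carries no uncertainties.
SIGMA_PLACEHOLDER_K = 0.01
SIGMA_PLACEHOLDER_C = 1e-12


@dataclass
class ScatteringProfile:
    """One 1-D scattering curve I(q) with optional 1-sigma uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    label: str = ""
    condition: object = None  # optional ContrastCondition

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise FormatError("q and intensity must be 1-D arrays of equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise FormatError("sigma must match q in length")
        if self.q.size < 2:
            raise FormatError("profile needs at least 2 points")
        if np.any(self.q <= 0):
            raise FormatError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise FormatError("q must be strictly increasing")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise FormatError("sigma must be positive where present")

    @property
    def n_points(self) -> int:
        return self.q.size

    def sigma_or_placeholder(self) -> np.ndarray:
        """Return sigma, substituting the documented Poisson-like fallback."""
        if self.sigma is not None:
            return self.sigma
        return placeholder_sigma(self.intensity)

    def truncated(self, q_min: float = 0.0, q_max: float = np.inf) -> "ScatteringProfile":
        m = (self.q >= q_min) & (self.q <= q_max)
        return ScatteringProfile(
            self.q[m], self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            label=self.label, condition=self.condition)


def placeholder_sigma(intensity, k=SIGMA_PLACEHOLDER_K, c=SIGMA_PLACEHOLDER_C):
    return k * np.sqrt(np.maximum(np.asarray(intensity, float), 0.0) + c)


@dataclass
class Lattice:
    """Descriptor of the bead-generating grid."""
    spacing: float          # nearest-neighbour center distance, A
    packing: str = "hcp"

    @property
    def cell_volume(self) -> float:
        """Volume per lattice site (A^3); a^3/sqrt(2) for close packing."""
        return self.spacing ** 3 / math.sqrt(2.0)


@dataclass
class BeadModel:
    """Equal-radius beads with per-bead phase labels.

    The universal shape representation: phantoms, annealing search grids,
    reconstructions and averaged envelopes all use it.
    """

    centers: np.ndarray                 # (N, 3) A
    bead_radius: float                  # A
    phases: np.ndarray                  # (N,) int codes from PHASE_NAMES
    lattice: Optional[Lattice] = None   # None means "free" (off-lattice)
    occupancy: Optional[np.ndarray] = None  # per-bead, from ensemble averaging
    label: str = ""

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.phases = np.asarray(self.phases, dtype=np.int8).reshape(-1)
        if self.centers.shape[0] != self.phases.shape[0]:
            raise FormatError("centers and phases must have equal length")
        if self.bead_radius <= 0:
            raise FormatError("bead_radius must be positive")
        if self.phases.size and (self.phases.min() < 0 or self.phases.max() > 2):
            raise FormatError("phase codes must be in {0,1,2}")
        if self.occupancy is not None:
            self.occupancy = np.asarray(self.occupancy, dtype=float).reshape(-1)
            if self.occupancy.shape[0] != self.phases.shape[0]:
                raise FormatError("occupancy must match bead count")

    @property
    def n_beads(self) -> int:
        return self.centers.shape[0]

    @property
    def bead_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.bead_radius ** 3

    def phase_mask(self, phase: int) -> np.ndarray:
        return self.phases == phase

    def nonsolvent(self) -> "BeadModel":
        """Copy containing only protein/nucleic beads."""
        m = self.phases != SOLVENT
        return replace(self, centers=self.centers[m], phases=self.phases[m],
                       occupancy=None if self.occupancy is None else self.occupancy[m])

    def spacing_estimate(self) -> float:
        """Lattice spacing, or the mean nearest-neighbour distance if free."""
        if self.lattice is not None:
            return self.lattice.spacing
        if self.n_beads < 2:
            return 2.0 * self.bead_radius
        d, _ = cKDTree(self.centers).query(self.centers, k=2)
        return float(np.mean(d[:, 1]))

    def validate_lattice(self, tol_frac: float = 0.05) -> None:
        """Check that no two centers are closer than one lattice spacing."""
        if self.lattice is None or self.n_beads < 2:
            return
        d, _ = cKDTree(self.centers).query(self.centers, k=2)
        if d[:, 1].min() < self.lattice.spacing * (1.0 - tol_frac):
            raise FormatError("bead centers closer than one lattice spacing")


# ---------------------------------------------------------------------------
# profile I/O

def read_profile(path, label: str = "", q_unit_scale: float = 1.0) -> ScatteringProfile:
    """Read a 2- or 3-column ASCII profile.

    Comment/header lines (any line whose first token is not numeric) are
    skipped.  ``q_unit_scale`` divides q on read (10.0 converts nm^-1 files
    to A^-1).
    """
    path = Path(path)
    rows = []
    ncols = None
    with open(path) as fh:  # may raise OSError for unreadable files
        for line in fh:
            tokens = line.split()
            if len(tokens) < 2:
                continue
            try:
                vals = [float(t) for t in tokens[:3]]
            except ValueError:
                continue
            if len(vals) == 2:
                vals.append(math.nan)
            rows.append(vals)
            ncols = max(ncols or 0, len(tokens[:3]))
    if len(rows) < MIN_PROFILE_ROWS:
        raise FormatError(f"{path}: fewer than {MIN_PROFILE_ROWS} parseable data rows")
    arr = np.asarray(rows, dtype=float)
    q, inten, sig = arr[:, 0] / q_unit_scale, arr[:, 1], arr[:, 2]
    if np.any(q <= 0):
        raise FormatError(f"{path}: q values must be positive")
    if np.any(np.diff(q) <= 0):
        raise FormatError(f"{path}: q must be strictly increasing")
    sigma = None
    if np.all(np.isfinite(sig)):
        sigma = sig
    else:
        log.warning("%s: no sigma column; uncertainties absent", path)
    return ScatteringProfile(q, inten, sigma, label=label or path.stem)


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column scientific-notation text."""
    if profile.q.size == 0:
        raise FormatError("refusing to write an empty profile")
    sigma = profile.sigma
    header = "# q I sigma"
    if sigma is None:
        sigma = placeholder_sigma(profile.intensity)
        header += (f"  (sigma synthetic: k*sqrt(max(I,0)+c), "
                   f"k={SIGMA_PLACEHOLDER_K}, c={SIGMA_PLACEHOLDER_C})")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for qi, ii, si in zip(profile.q, profile.intensity, sigma):
            fh.write(f"{qi:.8e} {ii:.8e} {si:.8e}\n")


# ---------------------------------------------------------------------------
# bead-model I/O (PDB dialect, REMARK 265 metadata)

PDB_COORD_LIMIT = 10000.0  # fixed-width field limit, A


def write_bead_model(model: BeadModel, path, resname_map: dict | None = None,
                     include_solvent: bool = False) -> None:
    """Write beads as fixed-width PDB ATOM records.

    Chain identifier distinguishes phases; occupancy column carries the
    per-bead ensemble occupancy when present; REMARK 265 lines carry bead
    radius and lattice spacing.
    """
    resname_map = resname_map or DEFAULT_RESNAME_MAP
    inv = {v: k for k, v in resname_map.items()}
    if np.any(np.abs(model.centers) >= PDB_COORD_LIMIT):
        raise FormatError("coordinates exceed the PDB fixed-width range")
    st = gemmi.Structure()
    st.name = model.label or "beads"
    gm = gemmi.Model("1")
    keep = np.ones(model.n_beads, bool) if include_solvent else (model.phases != SOLVENT)
    for phase in (PROTEIN, NUCLEIC, SOLVENT):
        idx = np.nonzero(keep & (model.phases == phase))[0]
        if idx.size == 0:
            continue
        chain = gemmi.Chain(PHASE_CHAINS[phase])
        for n, i in enumerate(idx, start=1):
            res = gemmi.Residue()
            res.name = inv[phase]
            res.seqid = gemmi.SeqId((n - 1) % 9999 + 1, " ")  # PDB field limit
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*model.centers[i])
            atom.occ = 1.0 if model.occupancy is None else float(model.occupancy[i])
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    remarks = [f"REMARK 265 BEAD RADIUS {model.bead_radius:.4f}"]
    if model.lattice is not None:
        remarks.append(f"REMARK 265 LATTICE SPACING {model.lattice.spacing:.4f} "
                       f"PACKING {model.lattice.packing.upper()}")
    body = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write("\n".join(remarks) + "\n")
        fh.write(body)


def read_bead_model(path, resname_map: dict | None = None) -> BeadModel:
    """Read a bead model written by :func:`write_bead_model` (or compatible)."""
    resname_map = resname_map or DEFAULT_RESNAME_MAP
    path = Path(path)
    radius = None
    spacing = None
    packing = "hcp"
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 265"):
                tokens = line.split()
                for key, nxt in (("RADIUS", "radius"), ("SPACING", "spacing")):
                    if key in tokens:
                        val = float(tokens[tokens.index(key) + 1])
                        if nxt == "radius":
                            radius = val
                        else:
                            spacing = val
                if "PACKING" in tokens:
                    packing = tokens[tokens.index("PACKING") + 1].lower()
    st = gemmi.read_pdb(str(path))
    centers, phases, occ = [], [], []
    for gm in st:
        for chain in gm:
            for res in chain:
                if res.name not in resname_map:
                    raise FormatError(
                        f"{path}: unknown residue name {res.name!r} "
                        f"(no phase mapping)")
                for atom in res:
                    centers.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    phases.append(resname_map[res.name])
                    occ.append(atom.occ)
    if not centers:
        raise FormatError(f"{path}: no bead records found")
    centers = np.asarray(centers)
    if radius is None:
        if len(centers) > 1:
            d, _ = cKDTree(centers).query(centers, k=2)
            radius = 0.5 * float(d[:, 1].min())
        else:
            radius = 1.0
        log.warning("%s: no REMARK 265 bead radius; inferred %.3f A", path, radius)
    lattice = Lattice(spacing, packing) if spacing is not None else None
    occ = np.asarray(occ)
    occupancy = occ if not np.allclose(occ, 1.0) else None
    return BeadModel(centers, radius, np.asarray(phases, np.int8), lattice,
                     occupancy=occupancy, label=path.stem)
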