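"""Ab initio two-phase shape restoration against a sucrose contrast series.

Beads on a fixed close-packed search grid are assigned phases {solvent,
protein, nucleic} by Metropolis simulated annealing of

    total = sum_profiles chi^2 + w_loose*L + w_disc*C + w_vol*V

where chi^2 compares the Debye intensity of the current assignment (with an
analytic per-profile scale factor) against each measured profile at its own
contrast, L penalizes non-solvent beads with fewer than six non-solvent
lattice neighbours (looseness), C counts connected components beyond one per
phase, and V the relative deviation of each phase's volume from its expected
value.  Replicate reconstructions are compared by normalized spatial
discrepancy (NSD), aligned by principal axes, and combined into an averaged
and occupancy-filtered envelope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .contrast import ContrastCondition
from .debye import sphere_form_amplitude
from .errors import DomainError, GridError, ResolutionError
from .io import NUCLEIC, PROTEIN, SOLVENT, BeadModel, Lattice, ScatteringProfile
from .phantoms import hcp_lattice
from .stuhrmann import ContrastSeries

log = logging.getLogger(__name__)

MIN_DIAMETER_RADIUS_RATIO = 12.0
DEFAULT_PENALTY_WEIGHTS = {"looseness": 1.0, "disconnect": 5.0,
                           "phase_volume": 2.0}


@dataclass
class AnnealConfig:
    """Annealing schedule and scoring weights.

    The schedule defaults (T0 from the spread of probe moves, geometric
    cooling by 0.95, 10*N moves per level, stop at T < 1e-4*T0) follow
    common practice for bead-model annealing at desk scale.
    """

    search_diameter: float
    bead_radius: float
    expected_volumes: Tuple[float, float]     # (protein, nucleic), A^3
    t_initial: Optional[float] = None         # None: from probe-move spread
    cooling_factor: float = 0.95
    moves_per_temperature: Optional[int] = None   # None: 10 * bead count
    t_min_factor: float = 1e-4
    weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PENALTY_WEIGHTS))
    seed: int = 0
    q_max_fit: float = 0.10       # only the low-q shape regime is fitted
    max_fit_points: int = 25

    def __post_init__(self):
        if not 0.0 < self.cooling_factor < 1.0:
            raise DomainError("cooling_factor must be in (0,1)")
        if any(w < 0 for w in self.weights.values()):
            raise DomainError("penalty weights must be nonnegative")


@dataclass
class ReconResult:
    model: BeadModel
    chi_per_profile: np.ndarray
    penalty_terms: Dict[str, float]
    accepted_moves: int
    seed: int
    diverged: bool = False


@dataclass
class AverageModel:
    reference: BeadModel
    occupancy: Dict[int, np.ndarray]     # phase -> per-site occupancy fraction
    filtered: BeadModel
    nsd_matrix: np.ndarray
    nsd_mean_sd: Tuple[float, float]


# ---------------------------------------------------------------------------
# search grid

def init_grid(search_diameter: float, bead_radius: float,
              expected_volumes: Tuple[float, float], seed: int = 0) -> BeadModel:
    """Close-packed bead grid filling a sphere, with seeded random phases in
    proportion to the expected phase volumes (remainder solvent)."""
    if search_diameter / bead_radius < MIN_DIAMETER_RADIUS_RATIO:
        raise ResolutionError(
            f"search_diameter/bead_radius = "
            f"{search_diameter / bead_radius:.1f} < {MIN_DIAMETER_RADIUS_RATIO}")
    spacing = 2.0 * bead_radius
    r = search_diameter / 2.0
    pts = hcp_lattice(np.full(3, r), spacing)
    pts = pts[np.sum(pts ** 2, axis=1) <= r ** 2]
    n = len(pts)
    cell = Lattice(spacing).cell_volume
    n_p = min(int(round(expected_volumes[0] / cell)), n)
    n_n = min(int(round(expected_volumes[1] / cell)), n - n_p)
    rng = np.random.default_rng(seed)
    phases = np.full(n, SOLVENT, np.int8)
    order = rng.permutation(n)
    phases[order[:n_p]] = PROTEIN
    phases[order[n_p:n_p + n_n]] = NUCLEIC
    return BeadModel(pts, bead_radius, phases, Lattice(spacing),
                     label="search-grid")


def _neighbor_table(centers: np.ndarray, spacing: float):
    tree = cKDTree(centers)
    pairs = tree.query_pairs(spacing * 1.05, output_type="ndarray")
    counts = np.zeros(len(centers), np.int64)
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    maxnb = max(int(counts.max(initial=0)), 1)
    nbr = np.full((len(centers), maxnb), -1, np.int64)
    fill = np.zeros(len(centers), np.int64)
    for a, b in pairs:
        nbr[a, fill[a]] = b
        fill[a] += 1
        nbr[b, fill[b]] = a
        fill[b] += 1
    return nbr, counts.astype(np.int64)


# ---------------------------------------------------------------------------
# numba scoring/annealing kernel

@njit(cache=False)
def _chi2_profile(iobs, sig, im):
    num = 0.0
    den = 0.0
    for i in range(iobs.size):
        num += iobs[i] * im[i] / sig[i] ** 2
        den += im[i] ** 2 / sig[i] ** 2
    c = num / den if den > 0 else 0.0
    if c < 0.0:
        c = 0.0
    out = 0.0
    for i in range(iobs.size):
        out += ((iobs[i] - c * im[i]) / sig[i]) ** 2
    return out / max(iobs.size - 1, 1)


@njit(cache=False)
def _compute_S(phases, drho, v, sinc_tab, S):
    P, Q = S.shape
    N = phases.size
    for p in range(P):
        for q in range(Q):
            S[p, q] = 0.0
    for p in range(P):
        for k in range(N):
            wk = drho[p, phases[k]] * v
            if wk == 0.0:
                continue
            for j in range(k, N):
                wj = drho[p, phases[j]] * v
                if wj == 0.0:
                    continue
                f = 2.0 if j != k else 1.0
                for q in range(Q):
                    S[p, q] += f * wk * wj * sinc_tab[k, j, q]


@njit(cache=False)
def _chis_from_S(S, phi2, iobs, sig, chis):
    P, Q = S.shape
    im = np.empty(Q)
    for p in range(P):
        for q in range(Q):
            im[q] = phi2[q] * S[p, q]
        chis[p] = _chi2_profile(iobs[p], sig[p], im)


@njit(cache=False)
def _penalties(phases, nbr, nbrcnt, n_expected, comp_buf):
    N = phases.size
    n1 = 0
    n2 = 0
    loose = 0.0
    for i in range(N):
        if phases[i] == 0:
            continue
        if phases[i] == 1:
            n1 += 1
        else:
            n2 += 1
        cnt = 0
        for t in range(nbrcnt[i]):
            if phases[nbr[i, t]] != 0:
                cnt += 1
        if cnt < 6:
            loose += 6.0 - cnt
    n_ns = n1 + n2
    if n_ns == 0:
        return 1e12, 0.0, 0.0, 0.0
    loose /= n_ns
    # connected components per phase
    extra = 0.0
    stack = np.empty(N, np.int64)
    for phase in (1, 2):
        ncomp = 0
        for i in range(N):
            comp_buf[i] = -1
        for i in range(N):
            if phases[i] != phase or comp_buf[i] >= 0:
                continue
            ncomp += 1
            # depth-first flood fill from i
            top = 0
            stack[top] = i
            top += 1
            comp_buf[i] = ncomp
            while top > 0:
                top -= 1
                u = stack[top]
                for t in range(nbrcnt[u]):
                    vtx = nbr[u, t]
                    if phases[vtx] == phase and comp_buf[vtx] < 0:
                        comp_buf[vtx] = ncomp
                        stack[top] = vtx
                        top += 1
        if ncomp > 1:
            extra += ncomp - 1
    vol = 0.0
    for k in range(2):
        n_act = n1 if k == 0 else n2
        if n_expected[k] > 0:
            vol += ((n_act - n_expected[k]) / n_expected[k]) ** 2
    return 0.0, loose, extra, vol


@njit(cache=False)
def _total_score(chis, loose, extra, vol, w_loose, w_disc, w_vol):
    out = w_loose * loose + w_disc * extra + w_vol * vol
    for p in range(chis.size):
        out += chis[p]
    return out


@njit(cache=False)
def _candidate_S(sinc_tab, phases, drho, v, S, S_new, G, k, old, new):
    """S after flipping bead k old->new, via per-phase partial sums G."""
    P, Q = S.shape
    N = phases.size
    for c in range(2):
        for q in range(Q):
            G[c, q] = 0.0
    for j in range(N):
        ph = phases[j]
        if ph != 0:
            for q in range(Q):
                G[ph - 1, q] += sinc_tab[k, j, q]
    for p in range(P):
        delta = (drho[p, new] - drho[p, old]) * v
        for q in range(Q):
            fq = v * (drho[p, 1] * G[0, q] + drho[p, 2] * G[1, q])
            S_new[p, q] = S[p, q] + 2.0 * delta * fq + delta * delta


@njit(cache=False)
def _anneal_kernel(sinc_tab, phi2, iobs, sig, drho, v, phases, nbr, nbrcnt,
                   n_expected, w_loose, w_disc, w_vol, t_initial, cooling,
                   t_min_factor, moves_per_level, max_levels, seed, greedy):
    np.random.seed(seed)
    N = phases.size
    P, Q = iobs.shape
    S = np.empty((P, Q))
    S_new = np.empty((P, Q))
    G = np.empty((2, Q))
    chis = np.empty(P)
    chis_new = np.empty(P)
    comp_buf = np.empty(N, np.int64)

    _compute_S(phases, drho, v, sinc_tab, S)
    _chis_from_S(S, phi2, iobs, sig, chis)
    bad, loose, extra, vol = _penalties(phases, nbr, nbrcnt, n_expected, comp_buf)
    total = bad + _total_score(chis, loose, extra, vol, w_loose, w_disc, w_vol)

    # probe moves to set the initial temperature from the spread of dScore
    t0 = t_initial
    if t0 <= 0.0:
        acc = 0.0
        acc2 = 0.0
        nprobe = 100
        for _ in range(nprobe):
            k = np.random.randint(N)
            old = phases[k]
            new = np.random.randint(3)
            while new == old:
                new = np.random.randint(3)
            _candidate_S(sinc_tab, phases, drho, v, S, S_new, G, k, old, new)
            _chis_from_S(S_new, phi2, iobs, sig, chis_new)
            phases[k] = new
            bad_n, loose_n, extra_n, vol_n = _penalties(
                phases, nbr, nbrcnt, n_expected, comp_buf)
            phases[k] = old
            tot_n = bad_n + _total_score(chis_new, loose_n, extra_n, vol_n,
                                         w_loose, w_disc, w_vol)
            d = tot_n - total
            acc += d
            acc2 += d * d
        var = acc2 / nprobe - (acc / nprobe) ** 2
        t0 = math.sqrt(var) if var > 0 else 1.0

    T = t0
    t_min = t0 * t_min_factor
    accepted_total = 0
    level = 0
    first_two_accepts = 0
    while T > t_min and level < max_levels:
        accepted_level = 0
        for _ in range(moves_per_level):
            k = np.random.randint(N)
            old = phases[k]
            new = np.random.randint(3)
            while new == old:
                new = np.random.randint(3)
            _candidate_S(sinc_tab, phases, drho, v, S, S_new, G, k, old, new)
            _chis_from_S(S_new, phi2, iobs, sig, chis_new)
            phases[k] = new
            bad_n, loose_n, extra_n, vol_n = _penalties(
                phases, nbr, nbrcnt, n_expected, comp_buf)
            tot_n = bad_n + _total_score(chis_new, loose_n, extra_n, vol_n,
                                         w_loose, w_disc, w_vol)
            d = tot_n - total
            accept = d < 0.0
            if not accept and not greedy and T > 0.0:
                if np.random.random() < math.exp(-min(d / T, 700.0)):
                    accept = True
            if accept:
                for p in range(P):
                    for q in range(Q):
                        S[p, q] = S_new[p, q]
                    chis[p] = chis_new[p]
                total = tot_n
                accepted_level += 1
            else:
                phases[k] = old
        accepted_total += accepted_level
        if level < 2:
            first_two_accepts += accepted_level
        # exact rescore to bound incremental drift
        _compute_S(phases, drho, v, sinc_tab, S)
        _chis_from_S(S, phi2, iobs, sig, chis)
        bad, loose, extra, vol = _penalties(phases, nbr, nbrcnt, n_expected,
                                            comp_buf)
        total = bad + _total_score(chis, loose, extra, vol, w_loose, w_disc,
                                   w_vol)
        if accepted_level == 0:
            break
        T *= cooling
        level += 1
    return chis, accepted_total, first_two_accepts, loose, extra, vol


# ---------------------------------------------------------------------------
# public scoring / annealing API

def _fit_arrays(series: ContrastSeries, config: AnnealConfig):
    """Common fit grid (q <= q_max_fit, at most max_fit_points) and the
    per-profile observed/sigma/contrast arrays."""
    qs, iobs, sig, drho = [], [], [], []
    for cond, prof, _g in series.entries:
        if prof is None:
            continue
        t = prof.truncated(q_max=config.q_max_fit)
        if t.n_points < 5:
            raise DomainError(
                f"profile {prof.label!r} has too few points below q_max_fit")
        stride = max(1, t.n_points // config.max_fit_points)
        idx = np.arange(0, t.n_points, stride)
        qs.append(t.q[idx])
        iobs.append(t.intensity[idx])
        sig.append(t.sigma_or_placeholder()[idx])
        drho.append([0.0, cond.delta_protein, cond.delta_nucleic])
    if not qs:
        raise DomainError("series contains no usable profiles")
    n = min(len(q) for q in qs)
    q0 = qs[0][:n]
    for k, q in enumerate(qs):
        if len(q) < len(q0) or not np.allclose(q[:n], q0, rtol=1e-6):
            # resample onto the first profile's grid (log-log interpolation)
            iobs[k] = np.exp(np.interp(np.log(q0), np.log(qs[k]),
                                       np.log(np.maximum(iobs[k], 1e-300))))
            sig[k] = np.interp(q0, qs[k], sig[k])
            qs[k] = q0
        else:
            qs[k], iobs[k], sig[k] = q[:n], iobs[k][:n], sig[k][:n]
    return (q0, np.asarray(iobs), np.asarray(sig),
            np.asarray(drho, dtype=float))


SINC_TABLE_BYTE_LIMIT = 600_000_000


def _sinc_table(centers: np.ndarray, q: np.ndarray) -> np.ndarray:
    n, nq = len(centers), len(q)
    if n * n * nq * 4 > SINC_TABLE_BYTE_LIMIT:
        raise ResolutionError(
            f"search grid of {n} beads x {nq} q-points exceeds the pair-table "
            "memory budget; use a coarser grid or fewer fit points")
    tab = np.empty((n, n, nq), np.float32)
    for i0 in range(0, n, 256):
        i1 = min(i0 + 256, n)
        d = np.linalg.norm(centers[i0:i1, None, :] - centers[None, :, :],
                           axis=2)
        tab[i0:i1] = np.sinc(d[:, :, None] * q[None, None, :] / np.pi)
    return tab


def model_score(model: BeadModel, series: ContrastSeries,
                config: AnnealConfig):
    """Exact (non-incremental) score of a phase assignment.

    Returns (total, chi_per_profile, penalties dict).  Uses the binned Debye
    engine, so it scales to fine-grained models.
    """
    from .debye import debye_intensity

    q, iobs, sig, drho = _fit_arrays(series, config)
    v = model.bead_volume
    phases = model.phases.astype(np.int8)
    P, Q = iobs.shape
    chis = np.empty(P)
    for p in range(P):
        w = drho[p][phases] * v
        im = debye_intensity(model.centers, w, model.bead_radius, q)
        num = float(np.sum(iobs[p] * im / sig[p] ** 2))
        den = float(np.sum(im ** 2 / sig[p] ** 2))
        c = max(num / den, 0.0) if den > 0 else 0.0
        chis[p] = float(np.sum(((iobs[p] - c * im) / sig[p]) ** 2)) \
            / max(Q - 1, 1)
    spacing = model.spacing_estimate()
    nbr, nbrcnt = _neighbor_table(model.centers, spacing)
    cell = Lattice(spacing).cell_volume
    n_exp = np.array([config.expected_volumes[0] / cell,
                      config.expected_volumes[1] / cell])
    bad, loose, extra, vol = _penalties(phases, nbr, nbrcnt, n_exp,
                                        np.empty(model.n_beads, np.int64))
    w = config.weights
    total = bad + float(np.sum(chis)) + w["looseness"] * loose \
        + w["disconnect"] * extra + w["phase_volume"] * vol
    return total, chis, {"looseness": loose, "disconnect": extra,
                         "phase_volume": vol}


def anneal(series: ContrastSeries, config: AnnealConfig,
           grid: Optional[BeadModel] = None, greedy: bool = False,
           max_levels: int = 400) -> ReconResult:
    """Run one seeded annealing reconstruction against the series."""
    q, iobs, sig, drho = _fit_arrays(series, config)
    if np.allclose(drho[:, 1:], 0.0):
        log.warning("all profiles sit at the match point; reconstruction "
                    "carries no shape information")
    if grid is None:
        grid = init_grid(config.search_diameter, config.bead_radius,
                         config.expected_volumes, seed=config.seed)
    phases = grid.phases.copy()
    sinc_tab = _sinc_table(grid.centers, q)
    phi2 = sphere_form_amplitude(q * grid.bead_radius) ** 2
    spacing = grid.lattice.spacing if grid.lattice else grid.spacing_estimate()
    nbr, nbrcnt = _neighbor_table(grid.centers, spacing)
    cell = Lattice(spacing).cell_volume
    n_exp = np.array([config.expected_volumes[0] / cell,
                      config.expected_volumes[1] / cell])
    w = config.weights
    moves = config.moves_per_temperature or 10 * grid.n_beads
    chis, accepted, first_two, loose, extra, vol = _anneal_kernel(
        sinc_tab, phi2, iobs, sig, drho, grid.bead_volume, phases,
        nbr, nbrcnt, n_exp, w["looseness"], w["disconnect"],
        w["phase_volume"], -1.0 if config.t_initial is None
        else config.t_initial, config.cooling_factor, config.t_min_factor,
        moves, max_levels, config.seed % (2 ** 31), greedy)
    diverged = first_two == 0 and float(np.max(chis)) > 10.0
    if diverged:
        log.warning("no accepted moves in the first two levels with chi >> 1;"
                    " the annealing likely diverged")
    model = BeadModel(grid.centers.copy(), grid.bead_radius, phases,
                      grid.lattice, label=f"recon-seed{config.seed}")
    return ReconResult(model=model, chi_per_profile=np.sqrt(chis),
                       penalty_terms={"looseness": loose, "disconnect": extra,
                                      "phase_volume": vol},
                       accepted_moves=int(accepted), seed=config.seed,
                       diverged=bool(diverged))


# ---------------------------------------------------------------------------
# NSD, alignment, averaging

def nsd(model_a: BeadModel, model_b: BeadModel,
        phase: Optional[int] = None) -> float:
    """Normalized spatial discrepancy between two bead models.

    Computed over non-solvent beads (phase-blind) unless ``phase`` selects a
    single phase.  0 for identical models; values around 1 mean the models
    differ by about one lattice spacing on average.
    """
    def coords(m):
        sel = (m.phases != SOLVENT) if phase is None else (m.phases == phase)
        return m.centers[sel]

    xa, xb = coords(model_a), coords(model_b)
    if len(xa) == 0 or len(xb) == 0:
        raise DomainError("NSD undefined for empty models")
    da = model_a.spacing_estimate()
    db = model_b.spacing_estimate()
    d_ab = cKDTree(xb).query(xa)[0]
    d_ba = cKDTree(xa).query(xb)[0]
    val = 0.5 * (np.mean(d_ab ** 2) / db ** 2 + np.mean(d_ba ** 2) / da ** 2)
    return float(math.sqrt(val))


_FLIPS = [np.diag(f) for f in
          ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]
_MIRROR_FLIPS = [np.diag(f) for f in
                 ((-1, 1, 1), (1, -1, 1), (1, 1, -1), (-1, -1, -1))]


def _principal_rotation(coords: np.ndarray):
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.linalg.det(evecs) < 0:
        evecs[:, -1] *= -1
    degenerate = evals[0] > 0 and (evals[0] - evals[-1]) / evals[0] < 0.05
    return evecs, degenerate


def align(models: Sequence[BeadModel], allow_mirror: bool = False):
    """Align models by centroid + principal axes, resolving axis-flip
    ambiguity by NSD against the first model.

    Returns (aligned models, notes).  A chirality note is attached when the
    mirror ambiguity cannot be searched (SAXS cannot break chirality).
    """
    if len(models) < 2:
        raise DomainError("alignment needs at least 2 models")
    aligned = []
    notes = []
    ref = None
    for m in models:
        ns = m.nonsolvent()
        cm = ns.centers.mean(axis=0)
        R, degenerate = _principal_rotation(ns.centers - cm)
        if degenerate:
            notes.append(f"{m.label}: near-spherical inertia tensor; "
                         "identity rotation kept")
            R = np.eye(3)
        base = (m.centers - cm) @ R
        if ref is None:
            out = replace(m, centers=base)
            aligned.append(out)
            ref = out
            continue
        best = None
        flips = _FLIPS + (_MIRROR_FLIPS if allow_mirror else [])
        for F in flips:
            cand = replace(m, centers=base @ F)
            val = nsd(ref, cand)
            if best is None or val < best[0]:
                best = (val, cand)
        aligned.append(best[1])
        if not allow_mirror:
            notes.append("mirror ambiguity not searched; enantiomorph "
                         "may fit equally well")
    return aligned, notes


def average_filter(models: Sequence[BeadModel],
                   occupancy_fraction: float = 0.0) -> AverageModel:
    """Average pre-aligned replicate models into a filtered envelope.

    Bead positions from all models are greedily clustered into shared sites
    (half-spacing tolerance); per-site, per-phase occupancies are computed,
    and each phase keeps its most-occupied sites (ties broken by occupancy,
    then by distance to the phase centroid) until the phase's median bead
    count across models is reached — a volume-targeted cut.
    ``occupancy_fraction`` optionally floors the occupancy a site needs to be
    eligible at all; the cut then stops early if too few sites qualify.
    """
    if len(models) < 2:
        raise DomainError("averaging needs at least 2 models")
    spacings = [m.spacing_estimate() for m in models]
    if max(spacings) / min(spacings) > 1.2:
        raise GridError("models do not share a consistent lattice spacing")
    spacing = float(np.median(spacings))
    tol = spacing / 2.0

    sites: List[np.ndarray] = []
    tree = None
    hits: List[List[Tuple[int, int]]] = []   # per site: (model idx, phase)
    for mi, m in enumerate(models):
        ns = m.nonsolvent()
        for x, ph in zip(ns.centers, ns.phases):
            idx = None
            if tree is not None:
                d, j = tree.query(x)
                if d <= tol:
                    idx = int(j)
            if idx is None:
                sites.append(x)
                hits.append([])
                tree = cKDTree(np.asarray(sites))
                idx = len(sites) - 1
            hits[idx].append((mi, int(ph)))
    sites_arr = np.asarray(sites)
    n_models = len(models)
    occ = {PROTEIN: np.zeros(len(sites)), NUCLEIC: np.zeros(len(sites))}
    for si, h in enumerate(hits):
        for _mi, ph in h:
            occ[ph][si] += 1.0 / n_models

    kept_centers, kept_phases, kept_occ = [], [], []
    claimed = np.zeros(len(sites), bool)
    for phase in (PROTEIN, NUCLEIC):
        counts = [int(np.sum(m.phases == phase)) for m in models]
        target = int(round(float(np.median(counts))))
        if target == 0:
            continue
        o = occ[phase].copy()
        o[claimed] = -1.0
        centroid = np.average(sites_arr, axis=0,
                              weights=np.maximum(occ[phase], 1e-12))
        dist = np.linalg.norm(sites_arr - centroid, axis=1)
        order = np.lexsort((np.arange(len(sites)), dist, -o))
        chosen = [i for i in order
                  if o[i] > 0 and o[i] >= occupancy_fraction][:target]
        for i in chosen:
            claimed[i] = True
            kept_centers.append(sites_arr[i])
            kept_phases.append(phase)
            kept_occ.append(occ[phase][i])

    ref = models[0]
    filtered = BeadModel(np.asarray(kept_centers), ref.bead_radius,
                         np.asarray(kept_phases, np.int8),
                         Lattice(spacing), occupancy=np.asarray(kept_occ),
                         label="averaged-filtered")
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = nsd(models[i], models[j])
    vals = mat[np.triu_indices(n, 1)]
    return AverageModel(reference=ref,
                        occupancy=occ,
                        filtered=filtered,
                        nsd_matrix=mat,
                        nsd_mean_sd=(float(vals.mean()),
                                     float(vals.std(ddof=1)) if len(vals) > 1
                                     else 0.0))
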