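"""Model-free single-profile analysis and composition arithmetic.

Covers Guinier fitting with automated q*Rg window selection, mid-q power-law
shape classification, Kratky / Porod-Debye flexibility diagnostics, a triaxial
ellipsoid form-factor fit, and the scalar composition relations (Flory Rg for
compact RNA, theoretical mass, mass-averaged dn/dc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .debye import sphere_form_amplitude
from .errors import DomainError, FitError, RangeError
from .io import ScatteringProfile

# Guinier window convention: q*Rg within [0.4, 1.3] unless overridden
GUINIER_QRG_MIN = 0.4
GUINIER_QRG_MAX = 1.3

#: Flory prefactor for compactly folded RNA, Rg = R0 * N^(1/3) (A)
FLORY_R0_RNA = 5.5

#: average ribonucleotide residue mass (Da); lariat termini contribute ~0
RNA_RESIDUE_MASS = 323.7


@dataclass
class GuinierResult:
    rg: float                   # A
    i0: float                   # intensity units
    qrg_window: tuple           # (qmin*Rg, qmax*Rg)
    fit_points: int
    residual_stat: float        # reduced chi^2 of the linear fit
    rg_err: float = math.nan    # 1-sigma, propagated from the fit covariance
    i0_err: float = math.nan


@dataclass
class EllipsoidFit:
    axes: tuple                 # full axis lengths, A, descending
    scale: float
    chi: float
    hydrated_volume: float      # A^3, (pi/6) a b c
    shape_class: str            # oblate | prolate | sphere-like


@dataclass
class FlexibilityReport:
    kratky_plateau: bool
    porod_exponent: float
    porod_debye_plateau: bool
    verdict: str                # compact | flexible | indeterminate


@dataclass
class Composition:
    """Protein/RNA composition of the particle (masses in kD)."""
    protein_mass: float         # per protein copy
    protein_copies: int
    rna_nt: int
    dndc_protein: float = 0.185     # ml/g
    dndc_nucleic: float = 0.170     # ml/g
    vbar: float = 0.630             # cm^3/g, mass-averaged
    rna_residue_mass: float = RNA_RESIDUE_MASS  # Da

    def __post_init__(self):
        if self.protein_mass < 0 or self.rna_nt < 0:
            raise DomainError("masses must be nonnegative")
        if not 0.5 < self.vbar < 0.8:
            raise DomainError("vbar outside the physically plausible (0.5, 0.8)")

    @property
    def rna_mass(self) -> float:
        """RNA mass in kD."""
        return self.rna_nt * self.rna_residue_mass / 1000.0


# ---------------------------------------------------------------------------
# Guinier

def _weighted_linfit(x, y, w):
    """Weighted least-squares line y = a + b x; returns (a, b, cov, chi2red)."""
    W = np.asarray(w, float)
    A = np.vstack([np.ones_like(x), x]).T * W[:, None]
    b, res, *_ = np.linalg.lstsq(A, y * W, rcond=None)
    cov = np.linalg.inv(A.T @ A)
    resid = (y - (b[0] + b[1] * x)) * W
    dof = max(len(x) - 2, 1)
    return b[0], b[1], cov, float(np.sum(resid ** 2) / dof)


def guinier_fit(profile: ScatteringProfile,
                qrg_max: float = GUINIER_QRG_MAX,
                qrg_min: float = GUINIER_QRG_MIN,
                max_iter: int = 20) -> GuinierResult:
    """Iterated weighted Guinier fit of ln I vs q^2.

    Starts from the first 15 points, estimates Rg, re-selects the window to
    satisfy qrg_min <= q*Rg <= qrg_max and repeats to a fixed point.  Ties are
    broken toward the lowest-q admissible window by construction (the window
    is the contiguous run of points satisfying the bounds).
    """
    q, inten = profile.q, profile.intensity
    sig = profile.sigma_or_placeholder()
    pos = inten > 0
    if pos.sum() < 5:
        raise FitError("too few positive intensities for a Guinier fit")

    def fit_window(mask):
        x = q[mask] ** 2
        y = np.log(inten[mask])
        w = inten[mask] / sig[mask]        # sigma_lnI = sigma/I
        return _weighted_linfit(x, y, w)

    mask = pos.copy()
    mask[np.cumsum(pos) > 15] = False      # first 15 positive points
    a, b, cov, chi2 = fit_window(mask)
    if b >= 0:
        raise FitError("non-Guinier behaviour: ln I does not decay with q^2")
    rg = math.sqrt(-3.0 * b)
    prev = None
    for _ in range(max_iter):
        window = pos & (q * rg >= qrg_min) & (q * rg <= qrg_max)
        if window.sum() < 5:
            raise FitError(
                f"fewer than 5 points satisfy {qrg_min} <= q*Rg <= {qrg_max}")
        key = window.tobytes()
        if key == prev:
            break
        prev = key
        a, b, cov, chi2 = fit_window(window)
        if b >= 0:
            raise FitError("non-Guinier behaviour inside the selected window")
        rg = math.sqrt(-3.0 * b)
    qw = q[window]
    # 1-sigma errors from the linear-fit covariance (scaled by chi2red)
    b_err = math.sqrt(cov[1, 1] * chi2)
    rg_err = 1.5 * b_err / rg if rg > 0 else math.nan
    i0_err = math.exp(a) * math.sqrt(cov[0, 0] * chi2)
    return GuinierResult(rg=rg, i0=math.exp(a),
                         qrg_window=(qw[0] * rg, qw[-1] * rg),
                         fit_points=int(window.sum()),
                         residual_stat=chi2, rg_err=rg_err, i0_err=i0_err)


# ---------------------------------------------------------------------------
# mid-q power law

def powerlaw_exponent(profile: ScatteringProfile, q_window: tuple) -> float:
    """Negated slope of log I vs log q over ``q_window``."""
    qlo, qhi = q_window
    m = (profile.q >= qlo) & (profile.q <= qhi)
    if m.sum() < 10:
        raise RangeError("power-law window must contain at least 10 points")
    inten = profile.intensity[m]
    sig = profile.sigma_or_placeholder()[m]
    q = profile.q[m]
    bad = inten <= 0
    if bad.any():
        if bad.mean() >= 0.20:
            raise DomainError("too many nonpositive intensities in window")
        q, inten, sig = q[~bad], inten[~bad], sig[~bad]
    _, slope, *_ = _weighted_linfit(np.log(q), np.log(inten), inten / sig)
    return -slope


def porod_envelope_exponent(profile: ScatteringProfile, rg: float,
                            qrg_min: float = 6.0) -> float:
    """Asymptotic power-law slope measured through the local maxima of the
    oscillating high-q decay (the Porod envelope)."""
    m = profile.q * rg >= qrg_min
    if m.sum() < 10:
        raise RangeError("profile does not reach the asymptotic regime")
    q, inten = profile.q[m], profile.intensity[m]
    peaks = np.nonzero((inten[1:-1] > inten[:-2]) & (inten[1:-1] > inten[2:]))[0] + 1
    if len(peaks) < 3:  # smooth decay, no oscillation: fit directly
        sel = slice(None)
        qs, isel = q, inten
    else:
        qs, isel = q[peaks], inten[peaks]
    slope = np.polyfit(np.log(qs), np.log(isel), 1)[0]
    return -slope


# ---------------------------------------------------------------------------
# Kratky / Porod-Debye flexibility

def kratky_porod(profile: ScatteringProfile,
                 kratky_return_fraction: float = 0.80,
                 pd_slope_threshold: float = 0.2,
                 rg: float | None = None) -> FlexibilityReport:
    """Flexibility diagnostics from q^2 I (Kratky) and q^4 I (Porod-Debye).

    * ``kratky_plateau``: q^2 I fails to fall back below
      ``kratky_return_fraction`` of its peak by the end of the support.
    * ``porod_debye_plateau``: the relative trend of q^4 I over the last third
      of the support is below ``pd_slope_threshold``.
    Verdict: compact = globular (no Kratky plateau, Porod-Debye plateau);
    flexible = Kratky plateau without a Porod-Debye plateau; anything else is
    indeterminate.
    """
    if rg is None:
        rg = guinier_fit(profile).rg
    if profile.q.max() * rg < 4.0:
        raise RangeError("support must reach q*Rg >= 4 for flexibility analysis")
    q, inten = profile.q, profile.intensity
    y2 = q ** 2 * inten
    tail = y2[int(0.9 * len(y2)):]
    kratky_plateau = bool(np.median(tail) > kratky_return_fraction * y2.max())

    y4 = q ** 4 * inten
    third = q >= q[0] + 2.0 / 3.0 * (q[-1] - q[0])
    qt, yt = q[third], y4[third]
    b = np.polyfit(qt, yt, 1)[0]
    rel_trend = abs(b) * (qt[-1] - qt[0]) / max(np.mean(yt), 1e-300)
    pd_plateau = bool(rel_trend < pd_slope_threshold)

    porod_exp = porod_envelope_exponent(profile, rg) if q.max() * rg >= 6 \
        else powerlaw_exponent(profile, (q[len(q) // 2], q[-1]))
    porod_exp = min(max(porod_exp, 1e-6), 4.5)

    if not kratky_plateau and pd_plateau:
        verdict = "compact"
    elif kratky_plateau and not pd_plateau:
        verdict = "flexible"
    else:
        verdict = "indeterminate"
    return FlexibilityReport(kratky_plateau, porod_exp, pd_plateau, verdict)


# ---------------------------------------------------------------------------
# triaxial ellipsoid form-factor fit

def ellipsoid_intensity(q, semi_axes, order: int = 32) -> np.ndarray:
    """Orientation-averaged form factor of a uniform triaxial ellipsoid.

    Gauss-Legendre quadrature over one octant (u = cos(theta), phi).
    """
    a, b, c = semi_axes
    q = np.atleast_1d(np.asarray(q, float))
    xu, wu = np.polynomial.legendre.leggauss(order)
    u = 0.5 * (xu + 1.0)          # cos(theta) in [0, 1]
    wu = 0.5 * wu
    phi = 0.5 * (xu + 1.0) * (math.pi / 2.0)
    # effective radius for each orientation
    s = np.sqrt(1.0 - u ** 2)
    reff = np.sqrt(
        (a ** 2 * np.cos(phi)[None, :] ** 2 + b ** 2 * np.sin(phi)[None, :] ** 2)
        * s[:, None] ** 2 + c ** 2 * u[:, None] ** 2)   # (order, order)
    amp2 = sphere_form_amplitude(q[:, None, None] * reff[None, :, :]) ** 2
    wgt = (wu[:, None] * wu[None, :])
    return np.einsum("quv,uv->q", amp2, wgt) / wgt.sum()


def ellipsoid_form_fit(profile: ScatteringProfile, q_max_fit: float = 0.15,
                       quad_order: int = 32,
                       oblate_ratio_min: float = 2.0,
                       equal_ratio_max: float = 1.5) -> EllipsoidFit:
    """Least-squares triaxial ellipsoid fit to the low-q data.

    Multistart from sphere, 3:3:1 oblate and 1:1:3 prolate seeds scaled to
    the Guinier Rg; parameters are log-transformed to keep axes positive.
    """
    prof = profile.truncated(q_max=q_max_fit)
    if prof.n_points < 8:
        raise RangeError("too few points below q_max_fit")
    sig = prof.sigma_or_placeholder()
    rg = guinier_fit(profile).rg

    def resid(p):
        a, b, c, scale = np.exp(p)
        model = scale * ellipsoid_intensity(prof.q, (a, b, c), order=quad_order)
        return (prof.intensity - model) / sig

    def seed(ratios):
        r = np.asarray(ratios, float)
        # scale so the seed matches the observed Rg: Rg^2 = (a^2+b^2+c^2)/5
        k = rg * math.sqrt(5.0 / np.sum(r ** 2))
        semi = r * k
        i0 = prof.intensity[0] / ellipsoid_intensity(prof.q[:1], semi,
                                                     order=quad_order)[0]
        return np.log(np.r_[semi, i0])

    best = None
    for ratios in ((1.0, 1.0, 1.0), (3.0, 3.0, 1.0), (1.0, 1.0, 3.0)):
        try:
            sol = least_squares(resid, seed(ratios), method="lm", max_nfev=400)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("ellipsoid fit failed from all starts")
    a, b, c, scale = np.exp(best.x)
    semi = np.sort([a, b, c])[::-1]
    chi = math.sqrt(2.0 * best.cost / max(prof.n_points - 4, 1))
    full = tuple(2.0 * s for s in semi)
    A, B, C = full
    if A / C >= oblate_ratio_min and A / B < equal_ratio_max:
        klass = "oblate"
    elif A / B >= oblate_ratio_min and B / C < equal_ratio_max:
        klass = "prolate"
    else:
        klass = "sphere-like"
    return EllipsoidFit(axes=full, scale=float(scale), chi=chi,
                        hydrated_volume=math.pi / 6.0 * A * B * C,
                        shape_class=klass)


# ---------------------------------------------------------------------------
# composition arithmetic

def flory_rg(n_nt: int, r0: float = FLORY_R0_RNA) -> float:
    """Flory-law Rg (A) of a compactly folded RNA of ``n_nt`` residues."""
    if n_nt < 1:
        raise DomainError("n_nt must be >= 1")
    return r0 * n_nt ** (1.0 / 3.0)


def theoretical_mass(comp: Composition, terminal_correction_kd: float = 0.0) -> float:
    """Theoretical particle mass in kD from the composition."""
    return (comp.protein_copies * comp.protein_mass
            + comp.rna_nt * comp.rna_residue_mass / 1000.0
            + terminal_correction_kd)


def mass_averaged_dndc(comp: Composition) -> float:
    """Mass-fraction-weighted refractive-index increment (ml/g)."""
    mp = comp.protein_copies * comp.protein_mass
    mn = comp.rna_mass
    total = mp + mn
    if total <= 0:
        raise DomainError("composition has zero mass")
    return (mp * comp.dndc_protein + mn * comp.dndc_nucleic) / total
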