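"""Pair-distance distribution functions: regularized indirect Fourier
transform of I(q), Dmax estimation, and direct P(r) from bead models.

The inversion solves

    min || (I - A p) / sigma ||^2  +  alpha || D2 p ||^2,   p(0)=p(Dmax)=0

on equidistant r-knots, with A the Fourier kernel 4*pi*dr*sinc(q r) and D2
the second-difference operator; nonnegativity (dilute-solution default) is
imposed through NNLS on the stacked system.  The regularization weight is
chosen by an L-curve corner criterion unless given explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import nnls

from .contrast import ContrastCondition
from .debye import _sinc, contrast_weights
from .errors import DegenerateError, DomainError, InversionError, RangeError
from .io import BeadModel, ScatteringProfile

N_KNOTS_DEFAULT = 101

# composite score weights for the Dmax scan (chi, terminal slope, negativity)
DMAX_SCORE_WEIGHTS = (0.5, 0.3, 0.2)
# reduced chi above which no candidate is considered to fit the data at all
CHI_CENSORED = 1.25


@dataclass
class PrFunction:
    """Real-space pair-distance distribution with derived parameters."""

    r: np.ndarray        # A, 0..dmax
    p: np.ndarray        # arbitrary units
    dmax: float          # A
    rg_real: float       # A
    i0_real: float       # intensity units
    alpha: float         # regularization weight used
    fit_chi: float       # reduced chi of the back-transform (nan for model_pr)

    @property
    def peak_r(self) -> float:
        return float(self.r[np.argmax(self.p)])

    def moments(self):
        area = simpson(self.p, x=self.r)
        r2 = simpson(self.r ** 2 * self.p, x=self.r)
        return area, r2


def _derived(r, p):
    area = simpson(p, x=r)
    if area <= 0:
        return math.nan, math.nan
    r2 = simpson(r ** 2 * p, x=r)
    rg = math.sqrt(max(r2 / (2.0 * area), 0.0))
    i0 = 4.0 * math.pi * area
    return rg, i0


def _kernel(q, r):
    """A[i,j] such that I(q_i) = sum_j A[i,j] p(r_j) (trapezoid weights)."""
    dr = r[1] - r[0]
    wts = np.full(r.size, dr)
    wts[0] = wts[-1] = dr / 2.0
    return 4.0 * math.pi * _sinc(np.outer(q, r)) * wts[None, :]


def _second_difference(n):
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i:i + 3] = (1.0, -2.0, 1.0)
    return d2


def _solve(profile, dmax, alpha, positivity, n_knots):
    q, inten = profile.q, profile.intensity
    sig = profile.sigma_or_placeholder()
    r = np.linspace(0.0, dmax, n_knots)
    A = _kernel(q, r)
    # endpoint constraints p(0)=p(dmax)=0: solve for interior knots only
    Ai = A[:, 1:-1]
    D2 = _second_difference(n_knots)[:, 1:-1]
    scale = np.median(np.abs(A).sum(axis=1) / sig) + 1e-300
    top = Ai / sig[:, None]
    bot = math.sqrt(alpha) * scale * D2
    M = np.vstack([top, bot])
    y = np.concatenate([inten / sig, np.zeros(D2.shape[0])])
    if positivity:
        p_int, _ = nnls(M, y, maxiter=10 * n_knots)
    else:
        p_int, *_ = np.linalg.lstsq(M, y, rcond=None)
    p = np.zeros(n_knots)
    p[1:-1] = p_int
    model = A @ p
    chi2 = float(np.sum(((inten - model) / sig) ** 2) / max(q.size, 1))
    return r, p, math.sqrt(chi2), model


def _lcurve_alpha(profile, dmax, positivity, n_knots,
                  grid=np.logspace(-10, 2, 25)):
    """Pick alpha at the corner (max curvature) of the L-curve."""
    rho, eta = [], []
    for al in grid:
        r, p, chi, _ = _solve(profile, dmax, al, positivity, n_knots)
        d2p = np.diff(p, 2)
        rho.append(math.log(max(chi, 1e-12)))
        eta.append(math.log(float(np.sum(d2p ** 2)) + 1e-300))
    rho, eta = np.asarray(rho), np.asarray(eta)
    # discrete curvature of the (rho, eta) curve
    k = np.zeros(len(grid))
    for i in range(1, len(grid) - 1):
        x1, y1 = rho[i] - rho[i - 1], eta[i] - eta[i - 1]
        x2, y2 = rho[i + 1] - rho[i], eta[i + 1] - eta[i]
        cross = x1 * y2 - y1 * x2
        denom = (math.hypot(x1, y1) * math.hypot(x2, y2)
                 * math.hypot(x1 + x2, y1 + y2)) or 1e-300
        k[i] = 2.0 * cross / denom
    return float(grid[int(np.argmax(k))])


def pr_transform(profile: ScatteringProfile, dmax: float,
                 alpha: Optional[float] = None, positivity: bool = True,
                 n_knots: int = N_KNOTS_DEFAULT) -> PrFunction:
    """Invert a profile to P(r) on [0, dmax] by regularized IFT."""
    if dmax <= 0:
        raise DomainError("dmax must be positive")
    if alpha is not None and alpha <= 0:
        raise DomainError("alpha must be positive")
    if alpha is None:
        alpha = _lcurve_alpha(profile, dmax, positivity, n_knots)
    r, p, chi, _ = _solve(profile, dmax, alpha, positivity, n_knots)
    if not np.any(p != 0.0):
        raise InversionError("inversion produced an identically zero P(r); "
                             "dmax is likely far too small")
    rg, i0 = _derived(r, p)
    return PrFunction(r=r, p=p, dmax=dmax, rg_real=rg, i0_real=i0,
                      alpha=alpha, fit_chi=chi)


def dmax_scan(profile: ScatteringProfile, dmax_grid,
              alpha: Optional[float] = None, n_knots: int = N_KNOTS_DEFAULT,
              score_weights=DMAX_SCORE_WEIGHTS):
    """Score candidate Dmax values and return (best, diagnostics table).

    Each candidate is inverted without the positivity constraint and scored
    by the composite  w_chi*chi + w_slope*slope + w_neg*negativity  where
    ``slope`` is the terminal |dp/dr| at dmax relative to the peak and
    ``negativity`` the relative area of the negative lobe; the true Dmax is
    the smallest value at which all three are simultaneously small.
    """
    w_chi, w_slope, w_neg = score_weights
    diagnostics = []
    for dm in np.asarray(dmax_grid, float):
        try:
            al = alpha if alpha is not None else \
                _lcurve_alpha(profile, dm, False, n_knots)
            r, p, chi, _ = _solve(profile, dm, al, False, n_knots)
        except Exception:
            diagnostics.append(dict(dmax=dm, score=math.inf, chi=math.inf,
                                    slope=math.inf, neg=math.inf))
            continue
        dr = r[1] - r[0]
        peak = np.abs(p).max() or 1e-300
        slope = abs(p[-2] - p[-1]) / dr * dm / peak / 10.0
        neg = float(-np.sum(np.minimum(p, 0.0)) / np.sum(np.abs(p)))
        score = w_chi * chi + w_slope * slope + w_neg * neg
        diagnostics.append(dict(dmax=dm, score=score, chi=chi,
                                slope=slope, neg=neg))
    finite = [d for d in diagnostics if math.isfinite(d["score"])]
    if not finite:
        raise InversionError("all Dmax candidates failed to invert")
    # candidates must first fit the data about as well as the best one does;
    # among those the score plateaus once dmax exceeds the true extent, so
    # take the smallest candidate within 10% of the plateau minimum
    chi_min = min(d["chi"] for d in finite)
    if chi_min > CHI_CENSORED:
        # no candidate fits the data: the whole grid is likely below the
        # true Dmax — take the least-censored (highest) value and warn
        best = max(finite, key=lambda d: d["dmax"])
        logging.getLogger(__name__).warning(
            "no Dmax candidate fits the data (best chi %.2f); selected the "
            "highest grid value %.1f — the true Dmax likely lies beyond the "
            "scanned range", chi_min, best["dmax"])
        return best["dmax"], diagnostics
    admissible = [d for d in finite
                  if d["chi"] <= max(1.1 * chi_min, chi_min + 0.05)]
    smin = min(d["score"] for d in admissible)
    best = min((d for d in admissible if d["score"] <= 1.10 * smin + 1e-12),
               key=lambda d: d["dmax"])
    if best["dmax"] == max(d["dmax"] for d in diagnostics):
        logging.getLogger(__name__).warning(
            "dmax_scan selected the highest grid value %.1f; the true Dmax "
            "may lie beyond the scanned range", best["dmax"])
    return best["dmax"], diagnostics


def model_pr(model: BeadModel, condition: ContrastCondition,
             n_bins: int = 200) -> PrFunction:
    """Contrast-weighted pair-distance distribution of a bead model.

    Center-distance histogram with weights w_i w_j, convolved with a Gaussian
    of the single-bead width (sigma = r_b*sqrt(2/5)); the exact intra-bead
    self term (support [0, 2 r_b]) is added separately.
    """
    if model.n_beads == 0:
        raise DomainError("empty bead model")
    w = contrast_weights(model, condition)
    if np.allclose(w, 0.0):
        raise DegenerateError("all contrast weights vanish")
    rb = model.bead_radius
    from scipy.spatial.distance import pdist
    if model.n_beads > 1:
        dists = pdist(model.centers)
        iu = np.triu_indices(model.n_beads, k=1)
        wprod = 2.0 * (w[:, None] * w[None, :])[iu]
        dmax = float(dists.max()) + 2.0 * rb
    else:
        dists = np.array([])
        wprod = np.array([])
        dmax = 2.0 * rb
    r = np.linspace(0.0, dmax, n_bins + 1)
    dr = r[1] - r[0]
    hist = np.zeros_like(r)
    if dists.size:
        idx = np.clip((dists / dr).astype(int), 0, n_bins)
        np.add.at(hist, idx, wprod)
        # Gaussian smear of the cross terms by the bead pair width
        sigma = rb * math.sqrt(2.0 / 5.0)
        ns = max(int(3 * sigma / dr), 1)
        kern = np.exp(-0.5 * (np.arange(-ns, ns + 1) * dr / sigma) ** 2)
        kern /= kern.sum()
        hist = np.convolve(hist, kern, mode="same")
    # exact intra-bead term: the distance pdf of two points in one bead is
    # the sphere P(r) with diameter 2*r_b, normalized to unit area
    pself = sphere_pr(r, 2.0 * rb)
    pself = pself / simpson(pself, x=r)
    hist = hist / dr + float(np.sum(w ** 2)) * pself
    hist[0] = 0.0
    rg, i0 = _derived(r, hist / (4.0 * math.pi))
    return PrFunction(r=r, p=hist / (4.0 * math.pi), dmax=dmax,
                      rg_real=rg, i0_real=i0, alpha=0.0, fit_chi=math.nan)


def sphere_pr(r, diameter: float):
    """Closed-form P(r) of a uniform sphere (unnormalized r^2 gamma(r))."""
    r = np.asarray(r, float)
    x = r / diameter
    p = r ** 2 * (1.0 - 1.5 * x + 0.5 * x ** 3)
    return np.where(r <= diameter, p, 0.0)
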