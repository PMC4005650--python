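"""Stuhrmann analysis of a sucrose contrast series.

The apparent radius of gyration of a two-phase particle varies with the
reciprocal mean contrast as

    Rg^2 = Rc^2 + alpha / drho_bar - beta / drho_bar^2

where Rc is the Rg at infinite contrast (the shape Rg), alpha > 0 indicates
that the denser phase lies peripherally, and beta > 0 a displacement of the
scattering-density centroid from the shape centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .analysis import GuinierResult, guinier_fit
from .contrast import ContrastCondition
from .errors import DomainError, FitError
from .io import ScatteringProfile

log = logging.getLogger(__name__)

MATCH_POINT_EPS = 1e-6  # |drho_bar| below this counts as the match point


@dataclass
class ContrastSeries:
    """Profiles measured at several sucrose contrasts, with Guinier results."""

    entries: List[Tuple[ContrastCondition, Optional[ScatteringProfile],
                        GuinierResult]]
    volumes: Tuple[float, float]      # (protein, nucleic) phase volumes, A^3

    def __post_init__(self):
        ws = [e[0].sucrose_w for e in self.entries]
        if len(set(ws)) != len(ws):
            raise DomainError("contrast conditions must be mutually distinct")

    @property
    def n_entries(self) -> int:
        return len(self.entries)


def build_series(profiles: Sequence[ScatteringProfile],
                 volumes: Tuple[float, float],
                 qrg_max: float = 1.3, qrg_min: float = 0.4) -> ContrastSeries:
    """Run Guinier analysis on each profile (which must carry its condition)."""
    entries = []
    for prof in profiles:
        if prof.condition is None:
            raise DomainError(f"profile {prof.label!r} has no contrast condition")
        g = guinier_fit(prof, qrg_max=qrg_max, qrg_min=qrg_min)
        entries.append((prof.condition, prof, g))
    return ContrastSeries(entries=entries, volumes=tuple(volumes))


def mean_contrast(condition: ContrastCondition,
                  volumes: Tuple[float, float]) -> float:
    """Volume-weighted mean contrast (e-/A^3) of the two-phase particle."""
    vp, vn = volumes
    if vp <= 0 or vn <= 0:
        raise DomainError("phase volumes must be positive")
    return (vp * condition.delta_protein + vn * condition.delta_nucleic) / (vp + vn)


@dataclass
class StuhrmannFit:
    rc: float                  # A, Rg at infinite contrast
    alpha_s: float             # A^2 (e-/A^3): inhomogeneity term
    beta_s: float              # A^2 (e-/A^3)^2: center-displacement term
    covariance: np.ndarray     # 3x3 for (rc^2, alpha_s, beta_s)
    n_points: int
    beta_constrained: bool = False
    rc_err: float = math.nan
    alpha_err: float = math.nan
    beta_err: float = math.nan


def stuhrmann_fit(series: ContrastSeries,
                  constrain_beta: bool = False) -> StuhrmannFit:
    """Weighted least-squares fit of Rg^2 against x = 1/drho_bar.

    Entries at the whole-particle match point are excluded with a warning;
    with exactly as many usable points as parameters the system is solved
    exactly.  Weights come from propagated Guinier Rg uncertainties where
    available, otherwise all points weigh equally.
    """
    xs, ys, ws = [], [], []
    for cond, _prof, g in series.entries:
        db = mean_contrast(cond, series.volumes)
        if abs(db) < MATCH_POINT_EPS:
            log.warning("entry at sucrose_w=%.3f sits at the particle match "
                        "point; excluded from the Stuhrmann fit", cond.sucrose_w)
            continue
        xs.append(1.0 / db)
        ys.append(g.rg ** 2)
        sig_y = 2.0 * g.rg * g.rg_err if math.isfinite(g.rg_err) else math.nan
        ws.append(1.0 / sig_y if (sig_y and math.isfinite(sig_y)) else math.nan)
    n_par = 2 if constrain_beta else 3
    if len(xs) < n_par:
        raise FitError(f"need at least {n_par} usable contrasts, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    w = np.asarray(ws)
    if not np.all(np.isfinite(w)):
        w = np.ones_like(x)
    cols = [np.ones_like(x), x] + ([] if constrain_beta else [x ** 2])
    A = np.vstack(cols).T * w[:, None]
    coef, *_ = np.linalg.lstsq(A, y * w, rcond=None)
    dof = max(len(x) - n_par, 1)
    resid = (y - (np.vstack(cols).T @ coef)) * w
    s2 = float(np.sum(resid ** 2)) / dof if len(x) > n_par else 1.0
    cov_small = np.linalg.inv(A.T @ A) * s2
    cov = np.zeros((3, 3))
    cov[:n_par, :n_par] = cov_small
    rc2 = coef[0]
    alpha_s = coef[1]
    beta_s = 0.0 if constrain_beta else -coef[2]
    if rc2 <= 0:
        raise FitError("fitted Rc^2 is nonpositive; series carries no "
                       "consistent infinite-contrast radius")
    rc = math.sqrt(rc2)
    return StuhrmannFit(
        rc=rc, alpha_s=float(alpha_s), beta_s=float(beta_s),
        covariance=cov, n_points=len(x), beta_constrained=constrain_beta,
        rc_err=math.sqrt(cov[0, 0]) / (2 * rc),
        alpha_err=math.sqrt(cov[1, 1]),
        beta_err=math.sqrt(cov[2, 2]))


def beta_f_test(series: ContrastSeries) -> dict:
    """Compare the full quadratic fit against the beta=0 restriction.

    Returns both fits plus an F-like statistic for the extra term; with few
    contrasts the comparison is indicative only, so conclusions should be
    drawn at the sign level when uncertainties straddle zero.
    """
    full = stuhrmann_fit(series, constrain_beta=False)
    restricted = stuhrmann_fit(series, constrain_beta=True)

    def rss(fit):
        out = 0.0
        for cond, _p, g in series.entries:
            db = mean_contrast(cond, series.volumes)
            if abs(db) < MATCH_POINT_EPS:
                continue
            pred = fit.rc ** 2 + fit.alpha_s / db - fit.beta_s / db ** 2
            out += (g.rg ** 2 - pred) ** 2
        return out
    rss_f, rss_r = rss(full), rss(restricted)
    dof = full.n_points - 3
    f_stat = (rss_r - rss_f) / (rss_f / dof) if dof > 0 and rss_f > 0 else math.inf
    return dict(full=full, restricted=restricted, f_stat=f_stat,
                alpha_sign_robust=abs(full.alpha_s) > 2 * full.alpha_err,
                beta_sign_robust=abs(full.beta_s) > 2 * full.beta_err)


def predict_rg(fit: StuhrmannFit, delta_rho_bar: float) -> float:
    """Rg (A) predicted at mean contrast ``delta_rho_bar``."""
    if delta_rho_bar == 0:
        raise DomainError("mean contrast must be nonzero")
    rg2 = fit.rc ** 2 + fit.alpha_s / delta_rho_bar \
        - fit.beta_s / delta_rho_bar ** 2
    if rg2 <= 0:
        raise DomainError("negative Rg^2: extrapolation outside the fit's "
                          "range of validity")
    return math.sqrt(rg2)
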