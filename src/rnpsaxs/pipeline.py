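"""End-to-end orchestration: synthesize (or load) a contrast series, run the
primary analyses, Stuhrmann fit, reconstruction ensemble and hydrodynamics,
and emit one structured, seed-reproducible report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from . import __version__
from .analysis import Composition, guinier_fit, mass_averaged_dndc, theoretical_mass
from .contrast import make_condition
from .debye import DEFAULT_Q_GRID, NoiseSpec, add_noise, noise_sigma, simulate_profile
from .errors import DomainError
from .hydro import SolventSpec, WATER_20C, hydro_report
from .io import (NUCLEIC, PROTEIN, BeadModel, ScatteringProfile,
                 write_bead_model, write_profile)
from .phantoms import PhantomSpec, build_phantom, coordinate_rg
from .pr import model_pr, pr_transform, dmax_scan
from .recon import AnnealConfig, align, anneal, average_filter, nsd
from .stuhrmann import build_series, mean_contrast, stuhrmann_fit

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to reproduce one synthetic-series analysis."""

    phantom: PhantomSpec
    conditions: Tuple[float, ...] = (0.0, 0.165, 0.325)
    noise: Optional[NoiseSpec] = None          # None: noise-free with 1% sigmas
    composition: Composition = field(
        default_factory=lambda: Composition(70.0, 2, 902))
    solvent: SolventSpec = WATER_20C
    n_replicates: int = 3
    seed: int = 0
    output_dir: Optional[str] = None
    q_grid: Optional[np.ndarray] = None
    guinier_qrg: Tuple[float, float] = (0.15, 0.9)
    recon_bead_radius: Optional[float] = None  # None: search_diameter / 18
    sigma_floor: float = 0.01                  # noise-free runs: assumed rel. error

    def __post_init__(self):
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)   # where, not what
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _phase_volumes(model: BeadModel) -> Tuple[float, float]:
    cell = model.lattice.cell_volume
    return (float((model.phases == PROTEIN).sum() * cell),
            float((model.phases == NUCLEIC).sum() * cell))


def synthesize_series(config: RunConfig):
    """Phantom + profiles at each condition, plus a ground-truth record."""
    phantom = build_phantom(config.phantom)
    q = np.asarray(config.q_grid if config.q_grid is not None
                   else DEFAULT_Q_GRID)
    vols = _phase_volumes(phantom)
    profiles = []
    truth = {"phase_volumes": vols,
             "shape_rg": coordinate_rg(phantom),
             "protein_centroid": phantom.centers[
                 phantom.phases == PROTEIN].mean(axis=0).tolist()
             if (phantom.phases == PROTEIN).any() else None,
             "rg_per_condition": {}}
    for i, w in enumerate(config.conditions):
        cond = make_condition(w)
        prof = simulate_profile(phantom, cond, q)
        from .debye import contrast_weights
        truth["rg_per_condition"][f"{w:g}"] = coordinate_rg(
            phantom, contrast_weights(phantom, cond))
        if config.noise is not None:
            spec = dataclasses.replace(config.noise,
                                       seed=(config.noise.seed + 1000 * i)
                                       % (2 ** 31))
            prof = add_noise(prof, spec)
        else:
            sig = noise_sigma(prof, NoiseSpec(config.sigma_floor, 1.0))
            prof = ScatteringProfile(prof.q, prof.intensity, sig,
                                     label=prof.label, condition=cond)
        profiles.append(prof)
    return phantom, profiles, truth


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to
    ``output_dir`` along with profile and model artifacts when set)."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    phantom, profiles, truth = synthesize_series(config)
    report = {"schema_version": REPORT_SCHEMA_VERSION,
              "package_version": __version__,
              "config_hash": config.config_hash(),
              "seed": config.seed,
              "truth": truth,
              "contrasts": [], "stages": {}}

    if out:
        write_bead_model(phantom, out / "phantom.pdb")
        for prof in profiles:
            write_profile(prof, out / f"{prof.label}.dat")

    # stage 1: per-contrast Guinier (P(r) on the lowest-sucrose profile)
    qrg_min, qrg_max = config.guinier_qrg
    series = build_series(profiles, truth["phase_volumes"],
                          qrg_max=qrg_max, qrg_min=qrg_min)
    for (cond, prof, g) in series.entries:
        report["contrasts"].append({
            "sucrose_w": cond.sucrose_w,
            "delta_protein": cond.delta_protein,
            "delta_nucleic": cond.delta_nucleic,
            "mean_contrast": mean_contrast(cond, series.volumes),
            "guinier_rg": g.rg, "guinier_rg_err": g.rg_err,
            "guinier_i0": g.i0, "qrg_window": list(g.qrg_window),
            "true_rg": truth["rg_per_condition"][f"{cond.sucrose_w:g}"]})
    try:
        prof0 = profiles[0]
        dmax_hint = 1.2 * max(config.phantom.dimensions)
        grid = np.linspace(0.6 * dmax_hint, 1.3 * dmax_hint, 12)
        best_dmax, _diag = dmax_scan(prof0, grid)
        pr0 = pr_transform(prof0, best_dmax)
        report["stages"]["pr"] = {
            "dmax": best_dmax, "rg_real": pr0.rg_real,
            "i0_real": pr0.i0_real, "fit_chi": pr0.fit_chi,
            "peak_r": pr0.peak_r}
    except Exception as exc:   # optional stage: record and continue
        log.warning("P(r) stage failed: %s", exc)
        report["stages"]["pr"] = {"error": str(exc)}

    # stage 2: Stuhrmann
    try:
        fit = stuhrmann_fit(series)
        report["stages"]["stuhrmann"] = {
            "rc": fit.rc, "alpha_s": fit.alpha_s, "beta_s": fit.beta_s,
            "alpha_err": fit.alpha_err, "beta_err": fit.beta_err,
            "n_points": fit.n_points,
            "rc_vs_shape_rg": fit.rc / truth["shape_rg"] - 1.0}
    except Exception as exc:
        log.warning("Stuhrmann stage failed: %s", exc)
        report["stages"]["stuhrmann"] = {"error": str(exc)}

    # stage 3: reconstruction ensemble
    search_d = 1.3 * max(config.phantom.dimensions)
    rb = config.recon_bead_radius or search_d / 18.0
    results = []
    for i in range(config.n_replicates):
        cfg = AnnealConfig(search_diameter=search_d, bead_radius=rb,
                           expected_volumes=truth["phase_volumes"],
                           seed=(config.seed + 17 * i) % (2 ** 31))
        res = anneal(series, cfg)
        results.append(res)
        if out:
            write_bead_model(res.model.nonsolvent(),
                             out / f"recon_{i:02d}.pdb")
    models = [r.model for r in results]
    recon_stage = {
        "n_replicates": config.n_replicates,
        "chi_max": float(max(r.chi_per_profile.max() for r in results)),
        "chi_per_replicate": [[float(c) for c in r.chi_per_profile]
                              for r in results],
        "diverged": [r.diverged for r in results]}
    centroid_errs = []
    for r in results:
        m = r.model
        if (m.phases == PROTEIN).any() and truth["protein_centroid"]:
            cen = m.centers[m.phases == PROTEIN].mean(axis=0)
            centroid_errs.append(float(np.linalg.norm(
                cen - np.asarray(truth["protein_centroid"]))))
    recon_stage["protein_centroid_error"] = centroid_errs
    recon_stage["bead_radius"] = rb
    if len(models) >= 2:
        aligned, notes = align(models)
        avg = average_filter(aligned)
        recon_stage["nsd_mean"], recon_stage["nsd_sd"] = avg.nsd_mean_sd
        recon_stage["alignment_notes"] = sorted(set(notes))
        filtered = avg.filtered
        if out:
            write_bead_model(filtered, out / "averaged_filtered.pdb")
    else:
        filtered = models[0].nonsolvent()
    report["stages"]["reconstruction"] = recon_stage

    # stage 4: hydrodynamics of the final envelope + composition arithmetic
    comp = config.composition
    mass = theoretical_mass(comp)
    hy = hydro_report(filtered, mass, comp.vbar, config.solvent)
    report["stages"]["hydrodynamics"] = {
        "mass_kd": mass, "vbar": comp.vbar,
        "dndc_mass_averaged": mass_averaged_dndc(comp),
        "friction_g_per_s": hy.friction, "stokes_radius": hy.stokes_radius,
        "s_buffer": hy.s_buffer, "s20w": hy.s20w,
        "f_over_f0": hy.f_over_f0}

    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def compare_shapes(model_a: BeadModel, model_b: BeadModel,
                   sucrose_w: float = 0.0, n_bins: int = 150) -> dict:
    """Compare two bead models: P(r) overlays, NSD after alignment, Dmax and
    volume differences.

    P(r) curves are peak-normalized; the divergence profile localizes where
    the shapes differ (e.g. an appended distal lobe shows up only in the
    top quartile of r).
    """
    cond = make_condition(sucrose_w)
    pa = model_pr(model_a, cond, n_bins=n_bins)
    pb = model_pr(model_b, cond, n_bins=n_bins)
    rmax = max(pa.dmax, pb.dmax)
    r = np.linspace(0.0, rmax, n_bins + 1)
    ya = np.interp(r, pa.r, pa.p, right=0.0)
    yb = np.interp(r, pb.r, pb.p, right=0.0)
    # smooth away the resolved lattice distance-shell structure (period one
    # lattice spacing) so the comparison reflects shape, not discretization
    smear = 0.5 * max(model_a.spacing_estimate(), model_b.spacing_estimate())
    dr = r[1] - r[0]
    ns = max(int(3 * smear / dr), 1)
    kern = np.exp(-0.5 * (np.arange(-ns, ns + 1) * dr / smear) ** 2)
    kern /= kern.sum()
    ya = np.convolve(ya, kern, mode="same")
    yb = np.convolve(yb, kern, mode="same")
    # scale b onto a over the shared body (lower half of r) so that localized
    # shape differences are not smeared over the whole distribution
    body = r < 0.5 * min(pa.dmax, pb.dmax)
    scale = float(np.dot(ya[body], yb[body]) / np.dot(yb[body], yb[body]))
    yb = yb * scale
    peak = max(ya.max(), yb.max())
    ya, yb = ya / peak, yb / peak
    div = np.abs(ya - yb)
    split = 0.75 * rmax
    lower = float(div[r < split].max())
    upper = float(div[r >= split].max())
    # mass that each shape carries beyond (almost) the smaller Dmax: the
    # signature of a distal appendage
    edge = 0.95 * min(pa.dmax, pb.dmax)
    area_a = float(np.trapezoid(ya, r)) or 1.0
    area_b = float(np.trapezoid(yb, r)) or 1.0
    tail_a = float(np.trapezoid(ya[r >= edge], r[r >= edge])) / area_a
    tail_b = float(np.trapezoid(yb[r >= edge], r[r >= edge])) / area_b

    grids_compatible = (model_a.lattice is not None
                        and model_b.lattice is not None
                        and abs(model_a.lattice.spacing
                                - model_b.lattice.spacing)
                        < 0.05 * model_a.lattice.spacing)
    try:
        aligned, _ = align([model_a, model_b])
        nsd_val = nsd(aligned[0], aligned[1])
    except DomainError:
        nsd_val = math.nan
    vol_a = model_a.nonsolvent().n_beads * model_a.bead_volume
    vol_b = model_b.nonsolvent().n_beads * model_b.bead_volume
    return {"dmax_a": pa.dmax, "dmax_b": pb.dmax,
            "dmax_difference": pb.dmax - pa.dmax,
            "nsd": nsd_val,
            "pr_divergence_lower_three_quartiles": lower,
            "pr_divergence_top_quartile": upper,
            "tail_fraction_a": tail_a, "tail_fraction_b": tail_b,
            "volume_a": vol_a, "volume_b": vol_b,
            "volume_difference": vol_b - vol_a,
            "volume_comparison_approximate": not grids_compatible,
            "r": r, "pr_a_normalized": ya, "pr_b_normalized": yb}
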