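# rnpsaxs

Contrast-variation small-angle X-ray scattering (SAXS) analysis of two-phase
protein–RNA particles, built around the case of a ~432 kD group II intron
ribonucleoprotein: a 140 kD maturase protein dimer bound to a 902-nt intron
lariat whose solution shape is a flat, oblate particle with the RNA arranged
peripherally around a central protein core.

Because raw beamline data for such native particles are rarely deposited,
the package pairs every analysis step with a synthetic-data generator: bead
phantoms with protein and nucleic phases, exact Debye-formula scattering at
any sucrose contrast, and seeded q-dependent noise. Every method is
therefore exercised end-to-end against known ground truth.

## What it computes

* **Primary analysis** (`rnpsaxs.analysis`) — Guinier fits of
  `ln I = ln I(0) − q²Rg²/3` with automated `q·Rg` window selection, mid-q
  power-law exponents (oblate particles decay ≈ q⁻², long prolate ≈ q⁻¹),
  Kratky / Porod–Debye flexibility verdicts, a triaxial ellipsoid
  form-factor fit, and composition arithmetic (theoretical mass, Flory's
  `Rg = 5.5·N^⅓` Å for compact RNA, mass-averaged dn/dc).
* **Real space** (`rnpsaxs.pr`) — smoothness-regularized indirect Fourier
  transform to the pair-distance distribution P(r) with optional
  nonnegativity, an L-curve choice of the regularization weight, a
  composite-scored Dmax scan, and P(r) computed directly from bead models.
* **Contrast variation** (`rnpsaxs.contrast`, `rnpsaxs.stuhrmann`) — solvent
  electron density of sucrose solutions, per-phase contrasts and match
  points, and the Stuhrmann decomposition
  `Rg² = Rc² + α/Δρ̄ − β/Δρ̄²`: α > 0 places the denser phase peripherally,
  β > 0 displaces the density centroid from the shape centroid.
* **Shape restoration** (`rnpsaxs.recon`) — multi-phase bead modeling:
  simulated annealing assigns {solvent, protein, nucleic} phases on a
  close-packed search grid against several contrasts simultaneously, with
  looseness / connectivity / phase-volume penalties; replicate runs are
  compared by normalized spatial discrepancy (NSD), aligned by principal
  axes and combined into an averaged, occupancy-filtered envelope.
* **Hydrodynamics** (`rnpsaxs.hydro`) — Kirkwood friction of bead models
  (surface-shell sum), Stokes radii, Svedberg sedimentation coefficients and
  s20,w standardization, mass from s and f/f₀, Perrin axial ratios.
* **Orchestration** (`rnpsaxs.pipeline`) — seed-reproducible end-to-end runs
  and bead-model shape comparison (Dmax shift, localized P(r) divergence,
  NSD) used for landmark experiments such as a tRNA fused into one RNA
  domain.

## Worked example

```python
import numpy as np
import rnpsaxs as rs
from rnpsaxs.stuhrmann import build_series, stuhrmann_fit
from rnpsaxs.io import PROTEIN, NUCLEIC

phantom = rs.rnp_phantom(lattice_spacing=8.0)       # 244 x 244 x 79 A
cell = phantom.lattice.cell_volume
vols = ((phantom.phases == PROTEIN).sum() * cell,
        (phantom.phases == NUCLEIC).sum() * cell)

q = np.logspace(np.log10(0.004), np.log10(0.32), 150)
profiles = [rs.simulate_profile(phantom, rs.make_condition(w), q)
            for w in (0.0, 0.165, 0.325, 0.488)]

series = build_series(profiles, vols, qrg_max=0.9, qrg_min=0.15)
for (cond, _p, g) in series.entries:
    print(f"w={cond.sucrose_w:5.3f}  Rg = {g.rg:5.1f} A")
fit = stuhrmann_fit(series)
print(f"Rc = {fit.rc:.1f} A, alpha = {fit.alpha_s:+.0f}, beta = {fit.beta_s:+.2f}")
```

prints

```
w=0.000  Rg =  83.2 A
w=0.165  Rg =  83.9 A
w=0.325  Rg =  85.1 A
w=0.488  Rg =  86.9 A
Rc = 77.3 A, alpha = +156, beta = -0.10
```

The radius of gyration rises as sucrose dims the protein's contrast, and the
positive α says the denser RNA lies at the periphery — the protein dimer
sits at the particle's center of mass. Rc, the radius at infinite contrast,
recovers the phantom's volume-weighted shape Rg (77.3 Å) exactly. With
noisy data the 4-point quadratic fit becomes ill-conditioned; use
`rnpsaxs.stuhrmann.beta_f_test` to compare it against the β = 0 restriction
and draw conclusions at the sign level.

## The analysis, step by step

Numbered drivers under `analysis/` rerun the full study on the synthetic
series (each writes tables under `results/`):

```
python analysis/01_simulate_contrast_series.py   # phantoms + 5-contrast data
python analysis/02_primary_analysis.py           # Guinier/Kratky/ellipsoid
python analysis/03_pr_inversion.py               # Dmax scan + P(r)
python analysis/04_stuhrmann.py                  # contrast-variation fit
python analysis/05_reconstruct.py                # two-phase bead ensemble
python analysis/06_hydrodynamics.py              # Rs, s20w, f/f0, Perrin
python analysis/07_compare_shapes.py             # tRNA-lobe localization
```

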