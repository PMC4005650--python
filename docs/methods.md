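# Methods

This note records the models, numerical choices and known limitations of the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The physical problem

A two-component particle (protein + RNA) in dilute solution scatters X-rays
with intensity

    I(q) = Σᵢ Σⱼ Δρᵢ Δρⱼ vᵢ vⱼ Φ(q r_b)² sinc(q rᵢⱼ)

over its volume elements, where Δρ is each element's electron-density excess
over the solvent (the contrast). Sucrose raises the solvent electron density
from 0.334 e⁻/Å³ (water) toward ~0.43 e⁻/Å³ at 65% w/w, selectively dimming
the protein phase (≈ 0.425 e⁻/Å³) relative to nucleic acid (≈ 0.550 e⁻/Å³).
How the apparent radius of gyration moves with contrast therefore encodes
which component is central and which peripheral — the core inference this
package automates, together with the model-free parameter extraction,
real-space inversion, two-phase shape restoration and hydrodynamic
back-calculation that surround it.

## Synthetic data: what the generator emulates

The study object is emulated by bead phantoms on a hexagonal-close-packed
lattice (nearest-neighbour distance = one spacing; volume per site
a³/√2; bead radius a/2):

* **two-phase-RNP** — an oblate envelope of 244 × 244 × 79 Å overall extent
  with a protein ellipsoid at the center of mass holding a requested volume
  fraction (default 0.40, the protein/total anhydrous volume of a 140 kD
  dimer + 292 kD RNA), and the nucleic remainder thinned into two lobes
  joined by a neck ("bow-tie"): beads in a waist |x| ≤ 0.30·A are removed
  unless inside an elliptical neck of half-width 0.45·B. The waist constants
  are package constants; only the qualitative bow-tie arrangement is
  prescribed by the source material.
* **RNP-plus-lobe** — the same body plus a distal sphere of nucleic phase.
  The default landmark lobe is 36 Å in diameter (the sphere holding a
  ~25 kD tRNA's anhydrous volume) at 152 Å from the center; construction
  fails if the lobe overlaps the body by more than 10% of its volume.
* **sphere / oblate / prolate / concentric-shell / displaced-core** —
  single-phase and two-phase controls with closed-form expectations.

Forward scattering uses the Debye sum above with pair distances binned at
r_b/2 (exact pairwise mode available for oracle tests); I(0) = (Σ Δρᵢvᵢ)² is
exact under binning. Noise is Gaussian with
σ(q) = floor · I(q) · (1 + (q/q_max)^p), defaults floor = 0.01 and p = 1 —
a 1% low-q error rising to 2% at the high-q edge, typical of well-exposed
synchrotron data. Recovery analyses that state their own error model
(noise-free intensities carrying the 1% σ) say so where they are run.

What the phantoms do **not** emulate: hydration shells (two-phase
vacuum-in-solvent contrast only), internal density fluctuations within each
phase, interparticle structure factors (dilute limit), and the temperature
dependence of contrast (solvent densities are 20 °C values from a quadratic
fit to standard sucrose tables, ρ(w) = 0.99823 + 0.3875 w + 0.1563 w²
g/cm³, valid to w = 0.70). Passing tests therefore demonstrate method
correctness on idealized two-phase particles, not robustness to every
systematic present in real beamline data.

## Numerical choices

* **Guinier** — iterated weighted fit of ln I vs q²; the window is the
  contiguous set with qrg_min ≤ q·Rg ≤ qrg_max (defaults 0.4–1.3), iterated
  to a fixed point from the first 15 points. For solid-sphere validation the
  window is capped at q·Rg ≤ 0.65: the Guinier approximation overestimates a
  sphere's Rg by ≈ 2% at q·Rg ≤ 1.3, ≈ 0.5% at ≤ 0.65, and the lattice
  discretization adds ≈ 0.26% at spacing 5 Å.
* **Mid-q power laws** — weighted log-log slope. The q⁻² (flat) and q⁻¹
  (rod) regimes exist only with strong axis separation; the package's
  reference windows are 1/R_long < q < 1/T (overall size to cross-section).
  An oblate *ellipsoid* (as opposed to an ideal disk) plateaus near 2.2–2.3
  because its thickness tapers; a 6.5:1 oblate measured over the full
  window gives ≈ 2.7 — consistent with flat-particle behaviour without
  reaching the ideal exponent.
* **Flexibility** — Kratky plateau: q²I fails to fall below 80% of its peak
  by the end of the support; Porod–Debye plateau: the relative linear trend
  of q⁴I over the last third is < 0.2 (oscillations of a globular particle
  average out of the fit). Verdict: compact = no Kratky plateau + Porod
  plateau; flexible = Kratky plateau without Porod plateau; otherwise
  indeterminate. Sphere Porod slopes are measured through the envelope of
  oscillation maxima, where the q⁻⁴ law holds.
* **Ellipsoid form factor** — orientation average by 32×32 Gauss–Legendre
  quadrature over one octant; fits run from sphere, 3:3:1 oblate and 1:1:3
  prolate seeds scaled to the observed Rg, in log-parameters, keeping the
  best of the three. Classification: oblate if a/c ≥ 2 and a/b < 1.5;
  prolate if a/b ≥ 2 and b/c < 1.5; else sphere-like.
* **P(r) inversion** — 101 knots on [0, Dmax], endpoint values pinned to
  zero, second-difference smoothness penalty with the weight chosen at the
  L-curve's maximum-curvature corner (manual override supported);
  nonnegativity (on by default; off for difference analyses and the Dmax
  scan) via NNLS on the stacked system. Moments by Simpson quadrature.
* **Dmax scan** — candidates scored by 0.5·χ + 0.3·(terminal slope) +
  0.2·(negative-lobe fraction). χ is non-monotonic in Dmax under censoring,
  so: if no candidate reaches χ ≤ 1.25 the grid is deemed censored and the
  highest value is returned with a warning; otherwise the smallest candidate
  within 10% of the plateau-minimum score among χ-admissible fits wins.
* **Stuhrmann** — weighted least squares of Rg² on [1, x, x²], x = 1/Δρ̄,
  with weights from propagated Guinier errors (equal weights when absent);
  match-point entries are excluded with a warning. The full quadratic and
  the β = 0 restriction are both available with an F-style comparison; with
   few contrasts the quadratic is ill-conditioned under noise and
  conclusions should be drawn at the sign level.
* **Annealing** — Metropolis over single-bead phase flips;
  T₀ = the standard deviation of 100 probe-move score changes, geometric
  cooling ×0.95, 10·N moves per level, stop at T < 10⁻⁴·T₀ or a level with
  no accepted moves; the score is recomputed exactly every level to bound
  incremental drift; fully reproducible from the seed. Score = Σ reduced χ²
  (analytic per-profile scale factor, no background term) + 1.0·looseness
  (mean shortfall below 6 non-solvent neighbours) + 5.0·(connected
  components beyond one per phase) + 2.0·(relative phase-volume deviation)².
  Only q ≤ 0.10 Å⁻¹ (≤ 25 points) is fitted: low-q carries the shape, high-q
  the internal structure the two-phase model does not represent. A
  pair-sinc lookup table makes each move O(N·N_q); grids are capped by a
  600 MB table budget (~1,250 beads at 25 q-points).
* **NSD / alignment / averaging** — Kozin–Svergun NSD over non-solvent
  beads (per-phase variants available), normalized by each model's lattice
  spacing. Alignment: centroid + principal axes + the best of four proper
  axis flips against the first model; mirror search is opt-in because SAXS
  cannot determine chirality, and a note is attached when it is off.
  Averaging clusters bead positions into shared sites at half-spacing
  tolerance, computes per-phase occupancies, and keeps each phase's
  most-occupied sites (ties: occupancy, then distance to the phase
  centroid) until the phase's median replicate bead count is reached.
* **Hydrodynamics** — Kirkwood friction
  f = N·6πησ / (1 + (σ/N)·Σ_{i≠j} 1/rᵢⱼ) summed over the *surface* beads
  (incomplete neighbour shells): interior beads are hydrodynamically
  shielded, and including them drives a filled sphere to Rs = 5R/6 instead
  of R. The surface-shell sum recovers a sphere's Stokes radius to 2–4%
  at spacings 5–10 Å. Hydration is excluded throughout (anhydrous bead
  surfaces), which biases calculated f/f₀ low against experiment. Perrin
  factors use F = √(p²−1)/(p^⅓ ln(p+√(p²−1))) (prolate) and
  √(p²−1)/(p^⅔ arctan√(p²−1)) (oblate), p = long/short ≥ 1.

## Problem sizes

Recovery studies run at desk scale: reconstruction grids of ~500 beads
(bead radius 8 Å in a 143 Å search sphere), 5 replicate anneals, phantoms of
3–6 thousand beads, 60–150 point profiles. The defaults in the library
(replicates = 10, grid radius = search diameter/18) reflect the full-scale
analysis; the tests, analysis drivers and the acceptance script state the
reduced sizes they use.

## Known limitations

* Annealed models underfill the expected phase volumes by ~20–30% on coarse
  grids — the χ² term (with its free scale factor) dominates the volume
  penalty at its default weight. Phase topology, the protein-phase centroid
  and ensemble NSD are robust; per-phase volumes from reconstructions should
  not be read quantitatively.
* The Stuhrmann quadratic needs either a wide contrast range or low-noise
  Rg values; with four contrasts and ≥1% noise only the sign of α is
  reliable.
* The sucrose density model is isothermal (20 °C); contrast at 4 °C differs
  in the third decimal and is not modelled.
* Bead-model P(r) smears cross terms with a Gaussian of the single-bead
  width (σ = r_b·√(2/5)); the intra-bead self term is exact. Lattice
  distance-shell structure survives at Δr below one spacing, so shape
  comparisons smooth both curves by half a spacing first.
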