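#!/usr/bin/env python
"""Hydrodynamic back-calculation: Kirkwood friction, Stokes radius,
sedimentation coefficient and frictional ratio of the averaged reconstruction
and of the phantom itself, against the composition's sphere reference, plus
the Svedberg-mass and Perrin axial-ratio arithmetic.

Reads results/series/ and results/recon/; writes results/hydrodynamics.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from rnpsaxs.analysis import Composition, theoretical_mass
from rnpsaxs.hydro import (WATER_20C, frictional_ratio, hydro_report,
                           perrin_axial_ratio, sedimentation_coefficient,
                           sphere_friction, svedberg_mass)
from rnpsaxs.io import read_bead_model

ROOT = Path(__file__).resolve().parent.parent
MASS_KD = theoretical_mass(Composition(70.0, 2, 902))
VBAR = 0.630


def block(model, label):
    rep = hydro_report(model, MASS_KD, VBAR)
    print(f"{label}: Rs = {rep.stokes_radius:.0f} A, "
          f"s = {rep.s20w:.1f} S, f/f0 = {rep.f_over_f0:.2f}")
    return {"stokes_radius_A": rep.stokes_radius, "s20w_S": rep.s20w,
            "f_over_f0": rep.f_over_f0, "friction_g_per_s": rep.friction}


def main():
    out = {"mass_kD": MASS_KD, "vbar_cm3_per_g": VBAR}
    phantom = read_bead_model(ROOT / "results" / "series" / "phantom_rnp.pdb")
    out["phantom"] = block(phantom, "phantom (244 x 244 x 79 A)")
    env_path = ROOT / "results" / "recon" / "averaged_filtered.pdb"
    if env_path.exists():
        out["averaged_reconstruction"] = block(read_bead_model(env_path),
                                               "averaged reconstruction")

    # forward references: the same mass as a compact sphere vs elongated form
    for f0, tag in ((1.2, "sphere_like"), (2.1, "elongated")):
        s = sedimentation_coefficient(
            sphere_friction(MASS_KD, VBAR, WATER_20C, f0), MASS_KD, VBAR)
        out[f"forward_s_{tag}_S"] = s
        print(f"forward c(S) reference (f/f0 = {f0}): {s:.1f} S")
    out["svedberg_mass_at_13p3S_f2p1_kD"] = svedberg_mass(13.3, 2.1, VBAR)
    out["perrin_axial_ratio_prolate_f2p1"] = perrin_axial_ratio(2.1, "prolate")
    out["perrin_axial_ratio_oblate_f2p1"] = perrin_axial_ratio(2.1, "oblate")
    print(f"Svedberg mass at 13.3 S, f/f0 = 2.1: "
          f"{out['svedberg_mass_at_13p3S_f2p1_kD']:.0f} kD")
    print(f"Perrin axial ratios at f/f0 = 2.1: "
          f"prolate {out['perrin_axial_ratio_prolate_f2p1']:.0f}, "
          f"oblate {out['perrin_axial_ratio_oblate_f2p1']:.0f}")

    path = ROOT / "results" / "hydrodynamics.json"
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    print(f"report -> {path}")


if __name__ == "__main__":
    main()
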