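"""Shared fixtures: phantoms, simulated profiles and a reconstruction
ensemble reused across test modules (session-scoped — the annealing ensemble
is the expensive part of the suite)."""

import numpy as np
import pytest

import rnpsaxs as rs
from rnpsaxs.debye import NoiseSpec, add_noise, noise_sigma
from rnpsaxs.io import NUCLEIC, PROTEIN, ScatteringProfile
from rnpsaxs.recon import AnnealConfig, anneal
from rnpsaxs.stuhrmann import build_series

SPHERE_DIAMETER = 100.0
CORE_SHELL_DIAMETER = 110.0
STUHRMANN_SUCROSE = (0.0, 0.165, 0.325, 0.488)
RECON_SUCROSE = (0.0, 0.165, 0.325)


@pytest.fixture(scope="session")
def water():
    return rs.make_condition(0.0)


@pytest.fixture(scope="session")
def sphere_model():
    return rs.build_phantom(rs.PhantomSpec("sphere", (SPHERE_DIAMETER,), 5.0))


@pytest.fixture(scope="session")
def sphere_profile(sphere_model, water):
    q = np.logspace(np.log10(0.006), np.log10(0.30), 120)
    return rs.simulate_profile(sphere_model, water, q)


@pytest.fixture(scope="session")
def noisy_sphere_profile(sphere_profile):
    return add_noise(sphere_profile, NoiseSpec(0.01, 1.0, seed=3))


def _noiseless_with_sigma(model, sucrose_w, q, rel=0.01):
    """Exact intensities carrying the sigma the noise model would assign."""
    cond = rs.make_condition(sucrose_w)
    p = rs.simulate_profile(model, cond, q)
    sig = noise_sigma(p, NoiseSpec(rel, 1.0))
    return ScatteringProfile(p.q, p.intensity, sig, label=p.label,
                             condition=cond)


def _phase_volumes(model):
    cell = model.lattice.cell_volume
    return ((model.phases == PROTEIN).sum() * cell,
            (model.phases == NUCLEIC).sum() * cell)


@pytest.fixture(scope="session")
def core_shell_phantom():
    """Low-density protein core inside a nucleic shell."""
    return rs.build_phantom(rs.PhantomSpec(
        "concentric-shell", (CORE_SHELL_DIAMETER,), 6.0,
        protein_fraction_volume=0.30))


@pytest.fixture(scope="session")
def stuhrmann_series(core_shell_phantom):
    q = np.logspace(np.log10(0.003), np.log10(0.25), 150)
    profs = [_noiseless_with_sigma(core_shell_phantom, w, q)
             for w in STUHRMANN_SUCROSE]
    return build_series(profs, _phase_volumes(core_shell_phantom),
                        qrg_max=0.9, qrg_min=0.15)


@pytest.fixture(scope="session")
def displaced_core_series():
    ph = rs.build_phantom(rs.PhantomSpec(
        "displaced-core", (CORE_SHELL_DIAMETER,), 6.0,
        protein_fraction_volume=0.30, core_offset=30.0))
    q = np.logspace(np.log10(0.003), np.log10(0.25), 150)
    profs = [_noiseless_with_sigma(ph, w, q) for w in STUHRMANN_SUCROSE]
    return ph, build_series(profs, _phase_volumes(ph),
                            qrg_max=0.9, qrg_min=0.15)


@pytest.fixture(scope="session")
def recon_series(core_shell_phantom):
    """3-contrast series fitted by the reconstruction tests."""
    q = np.logspace(np.log10(0.006), np.log10(0.12), 60)
    profs = [_noiseless_with_sigma(core_shell_phantom, w, q)
             for w in RECON_SUCROSE]
    return build_series(profs, _phase_volumes(core_shell_phantom),
                        qrg_max=1.0, qrg_min=0.3)


RECON_BEAD_RADIUS = 8.0
RECON_SEARCH_DIAMETER = 1.3 * CORE_SHELL_DIAMETER


@pytest.fixture(scope="session")
def recon_ensemble(recon_series, core_shell_phantom):
    """Five seeded annealing reconstructions of the protein-core phantom."""
    vols = _phase_volumes(core_shell_phantom)
    out = []
    for seed in (1, 2, 3, 4, 5):
        cfg = AnnealConfig(search_diameter=RECON_SEARCH_DIAMETER,
                           bead_radius=RECON_BEAD_RADIUS,
                           expected_volumes=vols, seed=seed)
        out.append(anneal(recon_series, cfg))
    return out
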