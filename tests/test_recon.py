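"""Multi-phase reconstruction: grid, scoring, annealing recovery, NSD,
alignment and ensemble averaging."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

import rnpsaxs as rs
from rnpsaxs.errors import DomainError, ResolutionError
from rnpsaxs.io import NUCLEIC, PROTEIN, SOLVENT, BeadModel, Lattice
from rnpsaxs.recon import (AnnealConfig, align, anneal, average_filter,
                           init_grid, model_score, nsd)

from conftest import RECON_BEAD_RADIUS, RECON_SEARCH_DIAMETER


def _phase_volumes(model):
    cell = model.lattice.cell_volume
    return ((model.phases == PROTEIN).sum() * cell,
            (model.phases == NUCLEIC).sum() * cell)


class TestInitGrid:
    def test_bead_count_matches_packing(self):
        g = init_grid(240.0, 10.0, (1e5, 2e5), seed=0)
        cell = Lattice(20.0).cell_volume
        expected = (4 / 3) * math.pi * 120.0 ** 3 / cell
        assert abs(g.n_beads / expected - 1.0) < 0.05

    def test_seeded_phase_assignment_is_deterministic(self):
        a = init_grid(200.0, 10.0, (1e5, 2e5), seed=3)
        b = init_grid(200.0, 10.0, (1e5, 2e5), seed=3)
        np.testing.assert_array_equal(a.phases, b.phases)
        c = init_grid(200.0, 10.0, (1e5, 2e5), seed=4)
        assert not np.array_equal(a.phases, c.phases)

    def test_phase_counts_proportional_to_volumes(self):
        g = init_grid(240.0, 10.0, (2e5, 4e5), seed=0)
        cell = Lattice(20.0).cell_volume
        assert (g.phases == PROTEIN).sum() == round(2e5 / cell)
        assert (g.phases == NUCLEIC).sum() == round(4e5 / cell)

    def test_resolution_floor(self):
        with pytest.raises(ResolutionError):
            init_grid(100.0, 10.0, (1e4, 1e4))


class TestModelScore:
    def test_phantom_scores_its_own_data_perfectly(self, core_shell_phantom,
                                                   recon_series):
        cfg = AnnealConfig(search_diameter=RECON_SEARCH_DIAMETER,
                           bead_radius=core_shell_phantom.bead_radius,
                           expected_volumes=_phase_volumes(core_shell_phantom))
        total, chis, pens = model_score(core_shell_phantom, recon_series, cfg)
        assert np.all(np.sqrt(chis) <= 1.0 + 0.05)
        assert pens["disconnect"] == 0.0
        assert pens["phase_volume"] == pytest.approx(0.0, abs=1e-9)

    def test_random_bead_deletion_scores_worse(self, core_shell_phantom,
                                               recon_series):
        cfg = AnnealConfig(search_diameter=RECON_SEARCH_DIAMETER,
                           bead_radius=core_shell_phantom.bead_radius,
                           expected_volumes=_phase_volumes(core_shell_phantom))
        base, _, _ = model_score(core_shell_phantom, recon_series, cfg)
        rng = np.random.default_rng(0)
        worse = 0
        trials = 20
        for _ in range(trials):
            phases = core_shell_phantom.phases.copy()
            kill = rng.choice(len(phases), size=len(phases) // 10,
                              replace=False)
            phases[kill] = SOLVENT
            mutant = BeadModel(core_shell_phantom.centers,
                               core_shell_phantom.bead_radius, phases,
                               core_shell_phantom.lattice)
            total, _, _ = model_score(mutant, recon_series, cfg)
            worse += total > base
        assert worse == trials

    def test_disconnected_phase_counts_components(self, recon_series,
                                                  core_shell_phantom):
        # two protein blobs far apart -> one extra component
        g = init_grid(RECON_SEARCH_DIAMETER, RECON_BEAD_RADIUS,
                      (1.0, 1.0), seed=0)
        phases = np.full(g.n_beads, SOLVENT, np.int8)
        left = np.argmin(g.centers[:, 0])
        right = np.argmax(g.centers[:, 0])
        phases[left] = phases[right] = PROTEIN
        m = BeadModel(g.centers, g.bead_radius, phases, g.lattice)
        cfg = AnnealConfig(search_diameter=RECON_SEARCH_DIAMETER,
                           bead_radius=RECON_BEAD_RADIUS,
                           expected_volumes=_phase_volumes(m))
        _, _, pens = model_score(m, recon_series, cfg)
        assert pens["disconnect"] == 1.0


class TestAnneal:
    def test_protein_core_recovered(self, recon_ensemble):
        # the contrast series, not any single profile, pins the topology
        for res in recon_ensemble:
            assert not res.diverged
            assert res.chi_per_profile.max() <= 1.5
        m = recon_ensemble[0].model
        cen = m.centers[m.phases == PROTEIN].mean(axis=0)
        assert np.linalg.norm(cen) <= 2 * RECON_BEAD_RADIUS

    def test_protein_phase_is_interior(self, recon_ensemble):
        # protein sits inside the nucleic shell: radially ordered phases
        for res in recon_ensemble:
            m = res.model
            rp = np.linalg.norm(m.centers[m.phases == PROTEIN], axis=1)
            rn = np.linalg.norm(m.centers[m.phases == NUCLEIC], axis=1)
            assert np.median(rp) < np.median(rn)

    def test_same_seed_bitwise_identical(self, recon_series,
                                         core_shell_phantom, recon_ensemble):
        cfg = AnnealConfig(search_diameter=RECON_SEARCH_DIAMETER,
                           bead_radius=RECON_BEAD_RADIUS,
                           expected_volumes=_phase_volumes(core_shell_phantom),
                           seed=1)
        rerun = anneal(recon_series, cfg)
        np.testing.assert_array_equal(rerun.model.phases,
                                      recon_ensemble[0].model.phases)

    def test_phase_swap_scores_worse(self, recon_ensemble, recon_series,
                                     core_shell_phantom):
        # falsifiability: the inverted topology cannot explain the series
        m = recon_ensemble[0].model
        swapped = np.where(m.phases == PROTEIN, NUCLEIC,
                           np.where(m.phases == NUCLEIC, PROTEIN,
                                    SOLVENT)).astype(np.int8)
        sw = BeadModel(m.centers, m.bead_radius, swapped, m.lattice)
        cfg = AnnealConfig(search_diameter=RECON_SEARCH_DIAMETER,
                           bead_radius=RECON_BEAD_RADIUS,
                           expected_volumes=_phase_volumes(core_shell_phantom))
        t_orig, _, _ = model_score(m, recon_series, cfg)
        t_swap, _, _ = model_score(sw, recon_series, cfg)
        assert t_swap > 1.5 * t_orig

    def test_greedy_mode_only_descends(self, recon_series,
                                       core_shell_phantom):
        vols = _phase_volumes(core_shell_phantom)
        cfg = AnnealConfig(search_diameter=RECON_SEARCH_DIAMETER,
                           bead_radius=RECON_BEAD_RADIUS,
                           expected_volumes=vols, seed=9,
                           moves_per_temperature=2000,
                           cooling_factor=0.5, t_min_factor=0.1)
        grid = init_grid(cfg.search_diameter, cfg.bead_radius, vols, seed=9)
        start, _, _ = model_score(grid, recon_series, cfg)
        res = anneal(recon_series, cfg, grid=grid, greedy=True)
        end, _, _ = model_score(res.model, recon_series, cfg)
        assert end < start


class TestNsd:
    def test_identical_models_zero(self, core_shell_phantom):
        assert nsd(core_shell_phantom, core_shell_phantom) == 0.0

    def test_single_beads_one_spacing_apart(self):
        d = 10.0
        a = BeadModel(np.zeros((1, 3)), 5.0, np.array([PROTEIN]), Lattice(d))
        b = BeadModel(np.array([[d, 0.0, 0.0]]), 5.0, np.array([PROTEIN]),
                      Lattice(d))
        assert nsd(a, b) == pytest.approx(1.0)

    def test_symmetry(self, recon_ensemble):
        a, b = recon_ensemble[0].model, recon_ensemble[1].model
        assert nsd(a, b) == pytest.approx(nsd(b, a), rel=1e-12)

    def test_empty_model_rejected(self, core_shell_phantom):
        empty = BeadModel(np.zeros((1, 3)), 5.0, np.array([SOLVENT]))
        with pytest.raises(DomainError):
            nsd(core_shell_phantom, empty)


class TestAlignAverage:
    def test_rigid_transform_recovered(self, core_shell_phantom):
        m = rs.rnp_phantom(lattice_spacing=12.0)
        rng = np.random.default_rng(1)
        R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        moved = BeadModel(m.centers @ R.T + np.array([40.0, -10.0, 25.0]),
                          m.bead_radius, m.phases.copy(), m.lattice)
        aligned, _notes = align([m, moved])
        assert nsd(aligned[0], aligned[1]) < 0.05

    def test_mirror_pair_flagged(self):
        m = rs.rnp_plus_lobe_phantom(lattice_spacing=12.0)
        mirrored = BeadModel(m.centers * np.array([1.0, 1.0, -1.0]),
                             m.bead_radius, m.phases.copy(), m.lattice)
        # an achiral-ish phantom aligns closely; the note must still warn
        _aligned, notes = align([m, mirrored])
        assert any("mirror" in n for n in notes)

    def test_identical_ensemble_reproduces_model(self, recon_ensemble):
        m = recon_ensemble[0].model.nonsolvent()
        avg = average_filter([m] * 5)
        assert avg.nsd_mean_sd == (0.0, 0.0)
        assert avg.filtered.n_beads == m.n_beads
        got = np.sort(np.round(avg.filtered.centers, 6), axis=0)
        want = np.sort(np.round(m.centers, 6), axis=0)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_deletion_ensemble_recovers_volume(self):
        sphere = rs.build_phantom(rs.PhantomSpec("sphere", (100.0,), 10.0))
        rng = np.random.default_rng(5)
        copies = []
        for _ in range(10):
            keep = rng.random(sphere.n_beads) > 0.05
            copies.append(BeadModel(sphere.centers[keep],
                                    sphere.bead_radius,
                                    sphere.phases[keep], sphere.lattice))
        avg = average_filter(copies)
        assert abs(avg.filtered.n_beads / sphere.n_beads - 1.0) < 0.05

    def test_replicate_ensemble_is_stable(self, recon_ensemble):
        models = [r.model for r in recon_ensemble]
        aligned, _ = align(models)
        avg = average_filter(aligned)
        assert avg.nsd_mean_sd[0] < 1.0
        assert np.allclose(avg.nsd_matrix, avg.nsd_matrix.T)
        assert np.all(np.diag(avg.nsd_matrix) == 0.0)
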