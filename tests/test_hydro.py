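"""Bead hydrodynamics: Kirkwood friction, Svedberg arithmetic, Perrin
inversions and volume/mass relations."""

import math

import numpy as np
import pytest

import rnpsaxs as rs
from rnpsaxs.errors import DomainError
from rnpsaxs.hydro import (SolventSpec, WATER_20C, frictional_ratio,
                           hydro_report, kirkwood_friction, perrin_axial_ratio,
                           perrin_factor, s20w_correction,
                           sedimentation_coefficient, sphere_friction,
                           stokes_radius, svedberg_mass, volume_from_mass)
from rnpsaxs.io import BeadModel, PROTEIN


class TestKirkwood:
    def test_single_bead_is_stokes_law(self):
        m = BeadModel(np.zeros((1, 3)), 10.0, np.array([PROTEIN]))
        f = kirkwood_friction(m)
        assert f == pytest.approx(6 * math.pi * WATER_20C.viscosity * 10e-8,
                                  rel=1e-12)

    def test_two_touching_beads(self):
        # sum over i != j of 1/r gives f = 8 pi eta sigma, Rs = 4/3 sigma
        m = BeadModel(np.array([[0, 0, 0], [0, 0, 20.0]]), 10.0,
                      np.array([PROTEIN, PROTEIN]))
        f = kirkwood_friction(m)
        assert f == pytest.approx(8 * math.pi * WATER_20C.viscosity * 10e-8,
                                  rel=1e-12)
        assert stokes_radius(f) == pytest.approx(40.0 / 3.0, rel=1e-9)

    def test_filled_sphere_stokes_radius(self, sphere_model):
        rs_ = stokes_radius(kirkwood_friction(sphere_model))
        assert abs(rs_ / 50.0 - 1.0) < 0.06

    def test_coincident_centers_rejected(self):
        m = BeadModel(np.zeros((2, 3)), 5.0, np.array([PROTEIN, PROTEIN]))
        with pytest.raises(DomainError):
            kirkwood_friction(m)


class TestSvedberg:
    def test_sphere_sedimentation_oracle(self):
        # 432 kD, vbar 0.63, f/f0 1.2 in 20C water: closed-form ~24.7 S
        f = sphere_friction(432.0, 0.63, WATER_20C, 1.2)
        s = sedimentation_coefficient(f, 432.0, 0.63)
        assert 24.0 <= s <= 25.5
        # and ~30 S for the ideal sphere (f/f0 = 1)
        s1 = sedimentation_coefficient(sphere_friction(432.0, 0.63), 432.0, 0.63)
        assert 29.0 <= s1 <= 30.5

    def test_doubling_friction_halves_s(self):
        f = sphere_friction(432.0, 0.63)
        s1 = sedimentation_coefficient(f, 432.0, 0.63)
        s2 = sedimentation_coefficient(2 * f, 432.0, 0.63)
        assert s2 == pytest.approx(s1 / 2, rel=1e-12)

    def test_neutral_buoyancy_rejected(self):
        f = sphere_friction(432.0, 0.63)
        dense = SolventSpec(density=1.0 / 0.63, viscosity=0.01)
        with pytest.raises(DomainError):
            sedimentation_coefficient(f, 432.0, 0.63, dense)

    def test_mass_round_trip(self):
        f = sphere_friction(432.0, 0.63, WATER_20C, 1.2)
        s = sedimentation_coefficient(f, 432.0, 0.63)
        assert svedberg_mass(s, 1.2, 0.63) == pytest.approx(432.0, rel=1e-3)

    def test_mass_scaling_law(self):
        # at fixed shape M ~ s^(3/2)
        f = sphere_friction(432.0, 0.63, WATER_20C, 1.2)
        s = sedimentation_coefficient(f, 432.0, 0.63)
        m2 = svedberg_mass(2 * s, 1.2, 0.63)
        assert m2 / 432.0 == pytest.approx(2 ** 1.5, rel=1e-3)

    def test_unphysical_shape_rejected(self):
        with pytest.raises(DomainError):
            svedberg_mass(13.3, 0.9, 0.63)


class TestS20w:
    def test_water_identity(self):
        assert s20w_correction(13.3, WATER_20C, 0.63) == pytest.approx(13.3)

    def test_buffer_correction_factor(self):
        # denser, more viscous buffer: the two-factor product by hand
        buf = SolventSpec(1.0086, 0.01007, 4.0)
        want = (0.01007 / 0.010020) \
            * (1 - 0.63 * 0.99823) / (1 - 0.63 * 1.0086)
        assert s20w_correction(1.0, buf, 0.63) == pytest.approx(want, rel=1e-12)

    def test_viscosity_monotonicity(self):
        thin = SolventSpec(1.0, 0.0100)
        thick = SolventSpec(1.0, 0.0120)
        assert s20w_correction(10.0, thick, 0.63) \
            > s20w_correction(10.0, thin, 0.63)


class TestPerrin:
    def test_sphere_limit(self):
        assert perrin_factor(1.0, "prolate") == 1.0
        assert perrin_axial_ratio(1.0 + 1e-6, "prolate") == pytest.approx(
            1.0, abs=0.05)

    def test_prolate_ratio_twenty_at_f_two(self):
        # hand-bracketed root of the prolate formula near f/f0 = 2
        assert perrin_factor(20.0, "prolate") == pytest.approx(2.0, abs=0.01)
        assert perrin_axial_ratio(2.0, "prolate") == pytest.approx(20.0,
                                                                   rel=0.02)

    @pytest.mark.parametrize("p", [2.0, 5.0, 20.0])
    @pytest.mark.parametrize("cls", ["prolate", "oblate"])
    def test_inversion_round_trip(self, p, cls):
        assert perrin_axial_ratio(perrin_factor(p, cls), cls) \
            == pytest.approx(p, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            perrin_axial_ratio(0.9, "prolate")
        with pytest.raises(DomainError):
            perrin_factor(2.0, "triaxial")


class TestVolumeAndReport:
    def test_calculated_volume_of_the_complex(self):
        assert volume_from_mass(432.0, 0.630) == pytest.approx(451900, rel=1e-3)
        assert volume_from_mass(432.0, 0.6277) == pytest.approx(450280,
                                                                rel=1e-3)

    def test_linearity(self):
        v = volume_from_mass(100.0, 0.6)
        assert volume_from_mass(200.0, 0.6) == pytest.approx(2 * v)
        assert volume_from_mass(100.0, 1.2 * 0.6) == pytest.approx(1.2 * v)

    def test_oblate_phantom_is_elongated_sphere_is_not(self, sphere_model):
        # the flat bow-tie particle drags far more than the equal-volume
        # sphere: f/f0 well above the ~1 sphere reference
        rnp = rs.rnp_phantom(lattice_spacing=10.0)
        mass, vbar = 432.0, 0.630
        f_rnp = frictional_ratio(kirkwood_friction(rnp), mass, vbar)
        # the sphere phantom's anhydrous volume corresponds to 432 kD at
        # vbar 0.73, so its equal-volume-sphere radius is its own radius
        f_sph = frictional_ratio(kirkwood_friction(sphere_model), 432.0, 0.73)
        assert f_rnp > 1.7
        assert f_sph < 1.1
        assert f_rnp > f_sph + 0.5

    def test_report_consistency(self, sphere_model):
        rep = hydro_report(sphere_model, 185.0, 0.73)
        assert rep.stokes_radius == pytest.approx(
            stokes_radius(rep.friction), rel=1e-12)
        assert rep.s20w == pytest.approx(rep.s_buffer)   # water-20C solvent
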