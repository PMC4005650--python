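"""Guinier fitting, shape power laws, flexibility diagnostics, ellipsoid
form-factor fits and composition arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnpsaxs.analysis import (Composition, ellipsoid_form_fit,
                              ellipsoid_intensity, flory_rg, guinier_fit,
                              kratky_porod, mass_averaged_dndc,
                              porod_envelope_exponent, powerlaw_exponent,
                              theoretical_mass)
from rnpsaxs.debye import sphere_form_amplitude
from rnpsaxs.errors import DomainError, FitError, RangeError
from rnpsaxs.io import ScatteringProfile


def analytic_sphere_profile(radius=50.0, qmax=0.3, n=400, rel_sigma=0.01):
    q = np.linspace(0.004, qmax, n)
    inten = 100.0 * sphere_form_amplitude(q * radius) ** 2
    return ScatteringProfile(q, inten, rel_sigma * inten + 1e-12)


class TestGuinier:
    def test_exact_guinier_curve(self):
        q = np.linspace(0.002, 0.05, 200)
        inten = 100.0 * np.exp(-q ** 2 * 50.0 ** 2 / 3.0)
        g = guinier_fit(ScatteringProfile(q, inten, 0.01 * inten))
        assert g.rg == pytest.approx(50.0, abs=0.01)
        assert g.i0 == pytest.approx(100.0, abs=0.1)
        assert g.qrg_window[1] <= 1.3 + 1e-9

    def test_debye_sphere_rg(self, sphere_profile):
        # sqrt(3/5)*R for a solid sphere; qRg <= 0.65 keeps the known
        # sphere truncation bias (plus lattice discretization) below 1%
        g = guinier_fit(sphere_profile, qrg_max=0.65, qrg_min=0.2)
        assert g.rg == pytest.approx(math.sqrt(3.0 / 5.0) * 50.0, rel=0.01)

    def test_window_too_small(self):
        q = np.linspace(0.05, 0.3, 50)     # window misses qRg <= 1.3 entirely
        inten = 100.0 * np.exp(-q ** 2 * 80.0 ** 2 / 3.0)
        with pytest.raises(FitError):
            guinier_fit(ScatteringProfile(q, inten, 0.01 * inten + 1e-30))

    def test_rising_intensity_is_non_guinier(self):
        q = np.linspace(0.002, 0.05, 50)
        inten = 100.0 * np.exp(+q ** 2 * 900.0)
        with pytest.raises(FitError):
            guinier_fit(ScatteringProfile(q, inten, 0.01 * inten))


class TestPowerLaw:
    def test_thin_oblate_decays_as_q2(self):
        semi = (250.0, 250.0, 15.0)
        window = (2.0 * math.pi / 500.0, 1.0 / 30.0)
        q = np.logspace(math.log10(window[0] * 0.8),
                        math.log10(window[1] * 1.2), 150)
        inten = ellipsoid_intensity(q, semi)
        prof = ScatteringProfile(q, inten, 0.01 * inten)
        assert powerlaw_exponent(prof, window) == pytest.approx(2.0, abs=0.3)

    def test_long_prolate_decays_as_q1(self):
        semi = (300.0, 20.0, 20.0)
        window = (2.0 * math.pi / 600.0, 1.0 / 40.0)
        q = np.logspace(math.log10(window[0] * 0.8),
                        math.log10(window[1] * 1.2), 150)
        inten = ellipsoid_intensity(q, semi)
        prof = ScatteringProfile(q, inten, 0.01 * inten)
        assert powerlaw_exponent(prof, window) == pytest.approx(1.0, abs=0.3)

    def test_sphere_porod_envelope_is_q4(self):
        q = np.logspace(math.log10(0.01), math.log10(1.0), 1200)
        inten = sphere_form_amplitude(q * 50.0) ** 2
        prof = ScatteringProfile(q, inten, 0.01 * inten + 1e-30)
        exp = porod_envelope_exponent(prof, math.sqrt(3 / 5) * 50.0)
        assert exp == pytest.approx(4.0, abs=0.3)

    def test_scale_invariance(self):
        prof = analytic_sphere_profile()
        w = (0.01, 0.05)
        a = powerlaw_exponent(prof, w)
        scaled = ScatteringProfile(prof.q, 37.0 * prof.intensity,
                                   37.0 * prof.sigma)
        assert powerlaw_exponent(scaled, w) == pytest.approx(a, rel=1e-9)


class TestFlexibility:
    def test_sphere_is_compact(self):
        rep = kratky_porod(analytic_sphere_profile())
        assert not rep.kratky_plateau
        assert rep.porod_debye_plateau
        assert rep.verdict == "compact"

    def test_gaussian_chain_is_flexible(self):
        rg = 50.0
        q = np.linspace(0.004, 0.3, 300)
        x = q ** 2 * rg ** 2
        inten = 2.0 * (np.exp(-x) + x - 1.0) / x ** 2
        rep = kratky_porod(ScatteringProfile(q, inten, 0.01 * inten + 1e-12))
        assert rep.kratky_plateau
        assert rep.verdict == "flexible"

    def test_truncated_support_rejected(self):
        rg = math.sqrt(3 / 5) * 50.0
        prof = analytic_sphere_profile(qmax=2.0 / rg)
        with pytest.raises(RangeError):
            kratky_porod(prof)


class TestEllipsoidFit:
    def test_oblate_round_trip(self):
        semi = (110.0, 110.0, 20.0)
        q = np.logspace(math.log10(0.006), math.log10(0.15), 80)
        inten = 50.0 * ellipsoid_intensity(q, semi)
        prof = ScatteringProfile(q, inten, 0.01 * inten)
        fit = ellipsoid_form_fit(prof)
        for got, want in zip(fit.axes, (220.0, 220.0, 40.0)):
            assert got == pytest.approx(want, rel=0.05)
        assert fit.shape_class == "oblate"
        a, b, c = fit.axes
        assert fit.hydrated_volume == pytest.approx(math.pi / 6 * a * b * c)

    def test_sphere_degenerate_case(self):
        q = np.logspace(math.log10(0.006), math.log10(0.15), 80)
        inten = 10.0 * ellipsoid_intensity(q, (50.0, 50.0, 50.0))
        prof = ScatteringProfile(q, inten, 0.01 * inten)
        fit = ellipsoid_form_fit(prof)
        for ax in fit.axes:
            assert ax == pytest.approx(100.0, rel=0.03)
        assert fit.shape_class == "sphere-like"

    def test_chi_near_one_with_matched_noise(self):
        from rnpsaxs.debye import NoiseSpec, add_noise
        semi = (110.0, 110.0, 20.0)
        q = np.logspace(math.log10(0.006), math.log10(0.15), 80)
        inten = 50.0 * ellipsoid_intensity(q, semi)
        noisy = add_noise(ScatteringProfile(q, inten, None),
                          NoiseSpec(0.02, 1.0, seed=5))
        fit = ellipsoid_form_fit(noisy)
        assert 0.7 <= fit.chi <= 1.5


class TestComposition:
    def test_flory_rg_of_the_intron(self):
        # 902 nt lariat: compact-RNA Flory law gives 53 A (2 s.f.)
        assert round(flory_rg(902), 0) == 53.0

    def test_flory_prefactor_and_exact_cube(self):
        assert flory_rg(1) == pytest.approx(5.5)
        assert flory_rg(4096) == pytest.approx(88.0, rel=1e-12)

    @given(st.integers(1, 10 ** 6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_flory_power_law_scaling(self, n):
        assert flory_rg(8 * n) == pytest.approx(2.0 * flory_rg(n), rel=1e-9)

    def test_theoretical_mass_of_the_2to1_complex(self):
        comp = Composition(70.0, 2, 902)
        assert theoretical_mass(comp) == pytest.approx(432.0, abs=0.5)

    def test_mass_linearity(self):
        assert theoretical_mass(Composition(70.0, 2, 0)) == pytest.approx(140.0)
        comp = Composition(0.0, 0, 1000, rna_residue_mass=320.0)
        assert theoretical_mass(comp) == pytest.approx(320.0)

    def test_dndc_weighted_mean(self):
        comp = Composition(100.0, 1, 0, dndc_protein=0.185, dndc_nucleic=0.170)
        assert mass_averaged_dndc(comp) == pytest.approx(0.185)
        # equal masses -> arithmetic mean
        comp = Composition(100.0, 1, 0, dndc_protein=0.185, dndc_nucleic=0.170,
                           rna_residue_mass=320.0)
        comp.rna_nt = int(round(100.0 * 1000 / 320.0))
        assert mass_averaged_dndc(comp) == pytest.approx(0.1775, abs=2e-4)

    def test_intron_composition_dndc(self):
        # 140/432 protein, 292/432 RNA: independent two-term weighted mean
        comp = Composition(70.0, 2, 902, dndc_protein=0.185,
                           dndc_nucleic=0.170)
        mp, mn = 140.0, 902 * 323.7 / 1000.0
        want = (mp * 0.185 + mn * 0.170) / (mp + mn)
        assert mass_averaged_dndc(comp) == pytest.approx(want, rel=1e-9)

    def test_vbar_range_enforced(self):
        with pytest.raises(DomainError):
            Composition(70.0, 2, 902, vbar=0.45)
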