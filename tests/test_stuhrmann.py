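"""Stuhrmann contrast-series analysis: mean contrast, quadratic fit in
reciprocal contrast, sign conventions and held-out prediction."""

import dataclasses
import math

import numpy as np
import pytest

import rnpsaxs as rs
from rnpsaxs.analysis import guinier_fit
from rnpsaxs.errors import DomainError, FitError
from rnpsaxs.io import NUCLEIC, PROTEIN, ScatteringProfile
from rnpsaxs.phantoms import coordinate_rg
from rnpsaxs.stuhrmann import (ContrastSeries, beta_f_test, build_series,
                               mean_contrast, predict_rg, stuhrmann_fit)


class TestMeanContrast:
    def test_equal_volumes(self):
        cond = dataclasses.replace(rs.make_condition(0.0),
                                   delta_protein=0.1, delta_nucleic=0.2)
        assert mean_contrast(cond, (100.0, 100.0)) == pytest.approx(0.15)

    def test_volume_weighting(self):
        cond = dataclasses.replace(rs.make_condition(0.0),
                                   delta_protein=0.0, delta_nucleic=0.216)
        assert mean_contrast(cond, (1.0, 2.0)) == pytest.approx(0.144)

    def test_match_point_cancellation(self):
        cond = dataclasses.replace(rs.make_condition(0.0),
                                   delta_protein=0.1, delta_nucleic=-0.05)
        assert mean_contrast(cond, (1.0, 2.0)) == pytest.approx(0.0)

    def test_volumes_must_be_positive(self):
        with pytest.raises(DomainError):
            mean_contrast(rs.make_condition(0.0), (0.0, 1.0))


class TestStuhrmannFit:
    def test_protein_core_gives_positive_alpha(self, stuhrmann_series,
                                               core_shell_phantom):
        # low-density protein at the center: Rg rises as sucrose dims the
        # protein -> positive inhomogeneity term
        fit = stuhrmann_fit(stuhrmann_series)
        assert fit.alpha_s > 0
        # centrosymmetric phantom: no density-centroid displacement
        xmax = max(abs(1.0 / mean_contrast(c, stuhrmann_series.volumes))
                   for c, _p, _g in stuhrmann_series.entries)
        assert abs(fit.beta_s) * xmax ** 2 < 0.02 * fit.rc ** 2

    def test_rc_matches_shape_rg(self, stuhrmann_series, core_shell_phantom):
        fit = stuhrmann_fit(stuhrmann_series)
        assert fit.rc == pytest.approx(coordinate_rg(core_shell_phantom),
                                       rel=0.02)

    def test_rg_increases_with_reciprocal_contrast(self, stuhrmann_series):
        # the +A-like sign anchor: higher sucrose -> smaller mean contrast ->
        # larger apparent Rg
        rgs = [g.rg for (_c, _p, g) in stuhrmann_series.entries]
        assert rgs == sorted(rgs)

    def test_displaced_core_gives_positive_beta(self, displaced_core_series,
                                                stuhrmann_series):
        _ph, series = displaced_core_series
        fit = stuhrmann_fit(series)
        centered = stuhrmann_fit(stuhrmann_series)
        assert fit.beta_s > 0
        assert fit.beta_s > 2.0 * abs(centered.beta_s)

    def test_homogeneous_phantom_is_flat(self):
        ph = rs.build_phantom(rs.PhantomSpec("sphere", (120.0,), 6.0))
        q = np.logspace(np.log10(0.003), np.log10(0.25), 150)
        profs = []
        for w in (0.0, 0.10, 0.20, 0.30):
            cond = rs.make_condition(w)
            p = rs.simulate_profile(ph, cond, q)
            profs.append(ScatteringProfile(
                p.q, p.intensity, 0.01 * p.intensity, condition=cond,
                label=p.label))
        vol = ph.n_beads * ph.lattice.cell_volume
        series = build_series(profs, (vol / 2, vol / 2),
                              qrg_max=0.9, qrg_min=0.15)
        fit = stuhrmann_fit(series)
        assert abs(fit.alpha_s) < 1.0          # A^2 e-/A^3, ~0 vs ~40 for
        assert abs(fit.beta_s) < 0.5           # genuinely two-phase shapes
        assert fit.rc == pytest.approx(coordinate_rg(ph), rel=0.02)

    def test_too_few_contrasts(self, stuhrmann_series):
        short = ContrastSeries(entries=stuhrmann_series.entries[:2],
                               volumes=stuhrmann_series.volumes)
        with pytest.raises(FitError):
            stuhrmann_fit(short)

    def test_beta_f_test_reports_both_fits(self, stuhrmann_series):
        res = beta_f_test(stuhrmann_series)
        assert res["restricted"].beta_s == 0.0
        assert res["full"].n_points == 4


class TestPredictRg:
    def test_infinite_contrast_limit(self, stuhrmann_series):
        fit = stuhrmann_fit(stuhrmann_series)
        assert predict_rg(fit, 1e9) == pytest.approx(fit.rc, rel=1e-6)

    def test_held_out_contrast(self, core_shell_phantom, stuhrmann_series):
        # fit on 4 contrasts, predict a 5th simulated condition
        fit = stuhrmann_fit(stuhrmann_series)
        cond = rs.make_condition(0.10)
        q = np.logspace(np.log10(0.003), np.log10(0.25), 150)
        p = rs.simulate_profile(core_shell_phantom, cond, q)
        prof = ScatteringProfile(p.q, p.intensity, 0.01 * p.intensity,
                                 condition=cond)
        g = guinier_fit(prof, qrg_max=0.9, qrg_min=0.15)
        pred = predict_rg(fit, mean_contrast(cond, stuhrmann_series.volumes))
        assert pred == pytest.approx(g.rg, rel=0.02)

    def test_constant_when_homogeneous(self, stuhrmann_series):
        fit = stuhrmann_fit(stuhrmann_series)
        flat = fit.__class__(rc=fit.rc, alpha_s=0.0, beta_s=0.0,
                             covariance=fit.covariance, n_points=4)
        assert predict_rg(flat, 0.05) == pytest.approx(fit.rc)
        assert predict_rg(flat, 0.5) == pytest.approx(fit.rc)

    def test_match_point_rejected(self, stuhrmann_series):
        fit = stuhrmann_fit(stuhrmann_series)
        with pytest.raises(DomainError):
            predict_rg(fit, 0.0)
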