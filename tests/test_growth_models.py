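"""Piecewise growth laws, numerical integration and the two-pass fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replom import (
    GrowthModelParams, ModelKind, Morphology, Phase, classify_morphology,
    extract_rates, fit_growth_curve, growth_rate, integrate_model,
)
from replom.area_growth import GrowthCurve

LIN = GrowthModelParams(0.01, 0.05, 400.0, 3000.0, 500.0, kind="A_lin")
PAR = GrowthModelParams(0.01, 0.0004, 400.0, 3000.0, 500.0, kind="A_par")


class TestGrowthRate:
    def test_lin_rate_at_saturation_onset(self):
        # at t = t1 the sigmoid factor is 1/(1+e^-5)
        assert growth_rate(LIN, 3000.0) == pytest.approx(
            0.05 / (1.0 + np.exp(-5.0)), rel=1e-12)

    def test_par_middle_branch_is_half_r2_t(self):
        for t in (400.0, 1000.0, 2999.0):
            assert growth_rate(PAR, t) == pytest.approx(0.5 * 0.0004 * t,
                                                        rel=1e-12)

    def test_lin_rate_fully_saturated(self):
        assert growth_rate(LIN, 3000.0 + 10 * 500.0) < 1e-15 * 0.05

    def test_first_phase_is_r1(self):
        assert growth_rate(LIN, 0.0) == 0.01
        assert growth_rate(PAR, 399.999) == 0.01

    @given(
        r1=st.floats(0.0, 1.0), r2=st.floats(0.0, 1.0),
        t0=st.floats(0.0, 2000.0), dt1=st.floats(0.0, 3000.0),
        tau=st.floats(1.0, 2000.0),
        kind=st.sampled_from([ModelKind.A_LIN, ModelKind.A_PAR]),
        t=st.floats(0.0, 10000.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_rate_is_nonnegative(self, r1, r2, t0, dt1, tau, kind, t):
        p = GrowthModelParams(r1, r2, t0, t0 + dt1, tau, kind=kind)
        assert growth_rate(p, t) >= 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GrowthModelParams(-0.1, 0.1, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            GrowthModelParams(0.1, 0.1, 2.0, 1.0, 1.0)  # t0 > t1
        with pytest.raises(ValueError):
            GrowthModelParams(0.1, 0.1, 0.0, 1.0, 0.0)  # tau = 0


class TestIntegrateModel:
    def test_single_phase_closed_form(self):
        # switches far beyond the data: A(t) = A0 + r1 (t - t_first)
        p = GrowthModelParams(0.02, 0.0, 1e9, 1e9, 1.0, A0=1.0, kind="A_lin")
        t = np.linspace(0.0, 1000.0, 51)
        np.testing.assert_allclose(integrate_model(p, t), 1.0 + 0.02 * t,
                                   rtol=1e-12)

    def test_parabolic_phase_closed_form(self):
        # from t0 the A_par branch integrates to A(t0) + r2 (t^2-t0^2)/4
        t = np.linspace(0.0, 2999.0, 120)
        A = integrate_model(PAR, t)
        a_t0 = 0.01 * 400.0
        mid = t >= 400.0
        expect = a_t0 + 0.0004 * (t[mid] ** 2 - 400.0**2) / 4.0
        np.testing.assert_allclose(A[mid], expect, rtol=1e-6)

    @pytest.mark.parametrize("params", [LIN, PAR], ids=["A_lin", "A_par"])
    def test_matches_fine_step_integrator(self, params):
        t = np.linspace(0.0, 6000.0, 150)
        coarse = integrate_model(params, t)
        fine = integrate_model(params, t, substeps=10_000)
        rel = np.abs(coarse[1:] - fine[1:]) / fine[1:]
        assert rel.max() < 1e-4

    @given(
        r1=st.floats(0.0, 0.1), r2=st.floats(0.0, 0.1),
        t0=st.floats(0.0, 3000.0), dt1=st.floats(0.0, 3000.0),
        tau=st.floats(10.0, 1000.0),
        kind=st.sampled_from([ModelKind.A_LIN, ModelKind.A_PAR]),
    )
    @settings(deadline=None, max_examples=50)
    def test_areas_nondecreasing(self, r1, r2, t0, dt1, tau, kind):
        p = GrowthModelParams(r1, r2, t0, t0 + dt1, tau, A0=0.1, kind=kind)
        A = integrate_model(p, np.linspace(0.0, 5000.0, 80))
        assert np.all(np.diff(A) >= -1e-12)


def _curve(params, n=200, t_max=5000.0, noise=0.0, seed=0):
    t = np.linspace(0.0, t_max, n)
    A = integrate_model(params, t)
    if noise:
        rng = np.random.default_rng(seed)
        A = A * (1.0 + noise * rng.standard_normal(n))
    return GrowthCurve(0, t, A)


class TestFitGrowthCurve:
    def test_noiseless_parameters_recovered_within_1pct(self):
        fit = fit_growth_curve(_curve(LIN), "A_lin")
        for name, truth in (("r1", 0.01), ("r2", 0.05), ("t0", 400.0),
                            ("t1", 3000.0), ("tau", 500.0)):
            assert getattr(fit.params, name) == pytest.approx(truth, rel=0.01)

    def test_scale_equivariance(self):
        c = _curve(PAR, noise=0.02, seed=1)
        f1 = fit_growth_curve(c, "A_par")
        scale = 3.7
        c2 = GrowthCurve(0, c.times, c.areas * scale)
        f2 = fit_growth_curve(c2, "A_par")
        assert f2.params.r1 == pytest.approx(scale * f1.params.r1, rel=5e-3)
        assert f2.params.r2 == pytest.approx(scale * f1.params.r2, rel=5e-3)
        assert f2.params.A0 == pytest.approx(scale * f1.params.A0, rel=0.05,
                                             abs=1e-3)
        assert f2.params.t0 == pytest.approx(f1.params.t0, abs=2.0)
        assert f2.params.t1 == pytest.approx(f1.params.t1, abs=2.0)
        assert f2.params.tau == pytest.approx(f1.params.tau, rel=0.01)

    def test_noisy_recovery_and_coverage(self):
        # 5% multiplicative noise, 20 replicates: median relative error
        # on the rates < 10% and ~truth within 2 SE most of the time
        errs_r1, errs_r2, covered = [], [], 0
        n_rep = 20
        for seed in range(n_rep):
            fit = fit_growth_curve(_curve(LIN, noise=0.05, seed=seed), "A_lin")
            errs_r1.append(abs(fit.params.r1 - 0.01) / 0.01)
            errs_r2.append(abs(fit.params.r2 - 0.05) / 0.05)
            se = fit.param_errors["r2"]
            if np.isfinite(se) and abs(fit.params.r2 - 0.05) <= 2 * se:
                covered += 1
        assert np.median(errs_r1) < 0.10
        assert np.median(errs_r2) < 0.10
        assert covered >= int(0.7 * n_rep)

    def test_flat_curve_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0.0, 2000.0, 60)
        A = 5.0 + 0.01 * rng.standard_normal(60)
        fit = fit_growth_curve(GrowthCurve(0, t, A), "A_lin")
        assert "degenerate_flat" in fit.flags
        total = fit.params.r1 * 400 + fit.params.r2 * 1600  # generous bound
        assert total < 0.1

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            fit_growth_curve(GrowthCurve(0, np.arange(5.0), np.ones(5)), "A_lin")


class TestClassifyAndExtract:
    def test_noiseless_curves_classified_by_construction(self):
        assert classify_morphology(_curve(LIN))[0] is Morphology.ANISOTROPIC
        assert classify_morphology(_curve(PAR))[0] is Morphology.ISOTROPIC

    def test_anisotropic_yields_two_rate_records(self):
        fit = fit_growth_curve(_curve(LIN), "A_lin")
        recs = extract_rates(fit, Morphology.ANISOTROPIC, temperature_c=37.0)
        assert [r.phase for r in recs] == [Phase.LINEAR, Phase.BRANCHING]
        assert all(r.temperature_c == 37.0 for r in recs)
        assert recs[0].rate == pytest.approx(0.01, rel=0.01)
        assert recs[1].rate == pytest.approx(0.05, rel=0.01)

    def test_isotropic_yields_one_rate_record(self):
        fit = fit_growth_curve(_curve(PAR), "A_par")
        recs = extract_rates(fit, Morphology.ISOTROPIC, temperature_c=45.0)
        assert len(recs) == 1 and recs[0].phase is Phase.ISOTROPIC
        assert recs[0].rate == pytest.approx(0.01, rel=0.01)
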