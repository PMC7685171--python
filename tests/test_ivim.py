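"""The three IVIM fitters and the phasor-projection geometry."""

import math

import numpy as np
import pytest

from dwiphasor import (
    IVIMParams,
    MixtureSpec,
    PhasorFitConfig,
    PhasorPoint,
    fit_nlls,
    fit_phasor,
    fit_segmented,
    fit_volume,
    ivim_signal,
    multiexp_signal,
    phasor_transform,
    project_through_point,
    reference_curve,
)
from dwiphasor.signals import IVIM_BVALUES_6, SamplingScheme, rician_magnitude

TRUTH = IVIMParams(S0=1.0, f=0.3, D=0.7, D_star=10.0)


class TestNLLS:
    def test_noise_free_recovery(self, ivim_scheme):
        fit = fit_nlls(ivim_signal(ivim_scheme, TRUTH), ivim_scheme)
        assert fit.converged
        assert fit.S0 == pytest.approx(1.0, rel=1e-6)
        assert fit.f == pytest.approx(0.3, rel=1e-6)
        assert fit.D == pytest.approx(0.7, rel=1e-6)
        assert fit.D_star == pytest.approx(10.0, rel=1e-6)

    def test_monoexponential_gives_zero_fraction(self, ivim_scheme):
        curve = multiexp_signal(ivim_scheme, MixtureSpec((0.7,), (1.0,)))
        fit = fit_nlls(curve, ivim_scheme)
        assert abs(fit.f) <= 1e-5
        assert fit.D == pytest.approx(0.7, rel=1e-5)

    def test_swap_rule_enforces_ordering(self, ivim_scheme, rng):
        # noisy fits must always come back with D <= D*, swapped or not
        clean = ivim_signal(ivim_scheme, TRUTH).values
        noisy = rician_magnitude(np.broadcast_to(clean, (50, 15)), 1 / 20, rng)
        for y in noisy:
            fit = fit_nlls(y, ivim_scheme)
            assert fit.D <= fit.D_star

    def test_unconstrained_f_variant(self, ivim_scheme):
        fit = fit_nlls(ivim_signal(ivim_scheme, TRUTH), ivim_scheme, constrain_f=False)
        assert fit.method == "nlls_unconstrained_f"
        assert fit.f == pytest.approx(0.3, rel=1e-5)

    def test_needs_b0(self):
        scheme = SamplingScheme((10, 20, 100, 500, 1000))
        with pytest.raises(ValueError):
            fit_nlls(np.ones(5), scheme)


class TestSegmented:
    def test_three_stage_oracle(self, ivim_scheme):
        # run the stages independently: high-b log-line, b=0 gap, residual line
        y = ivim_signal(ivim_scheme, TRUTH).values
        b = ivim_scheme.b_array
        tail = b > 300
        slope, intercept = np.polyfit(b[tail], np.log(y[tail]), 1)
        d_oracle = -slope * 1000
        f_oracle = (y[0] - math.exp(intercept)) / y[0]
        resid = y - math.exp(intercept) * np.exp(slope * b)
        keep = resid > 1e-12
        slope2, _ = np.polyfit(b[keep], np.log(resid[keep]), 1)

        fit = fit_segmented(y, ivim_scheme)
        assert fit.D == pytest.approx(d_oracle, rel=1e-12)
        assert fit.f == pytest.approx(f_oracle, rel=1e-12)
        assert fit.D_star == pytest.approx(-slope2 * 1000, rel=1e-12)
        # perfusion residue biases D slightly high, f close to truth
        assert 0.7 < fit.D < 0.75
        assert fit.f == pytest.approx(0.3, abs=0.02)

    def test_monoexponential(self, ivim_scheme):
        curve = multiexp_signal(ivim_scheme, MixtureSpec((0.7,), (1.0,)))
        fit = fit_segmented(curve, ivim_scheme)
        assert fit.D == pytest.approx(0.7, rel=1e-9)
        assert fit.f == pytest.approx(0.0, abs=1e-9)
        assert "dstar_undefined" in fit.flags
        assert np.isnan(fit.D_star)

    def test_increasing_residual_tail_gives_negative_dstar(self, ivim_scheme):
        # monoexponential tail plus a residual that grows with b at low b:
        # the stage-3 log-line has positive slope => negative D*
        b = ivim_scheme.b_array
        y = np.exp(-b * 0.7 / 1000.0) + 0.01 * np.exp(b / 1000.0) * (b <= 300)
        fit = fit_segmented(y, ivim_scheme)
        assert np.isfinite(fit.D_star)
        assert fit.D_star < 0

    def test_strict_threshold_uses_four_points(self, ivim_scheme):
        assert (ivim_scheme.b_array > 300).sum() == 4


class TestProjection:
    def test_point_on_curve_returns_itself(self, ivim_scheme):
        ref = reference_curve(ivim_scheme)
        l_d = ref.point_at(0.7)
        l_dstar = ref.point_at(10.0)
        proj = project_through_point(l_d, l_dstar, ref, d_max=10.0)
        assert proj.ok
        assert proj.d == pytest.approx(0.7, rel=1e-4)
        assert np.hypot(proj.point.g - l_d.g, proj.point.s - l_d.s) < 1e-8

    def test_mixture_chord_recovers_tissue_diffusivity(self, ivim_scheme):
        ref = reference_curve(ivim_scheme)
        curve = ivim_signal(ivim_scheme, IVIMParams(S0=1.0, f=0.5, D=0.7, D_star=10.0))
        l_s = phasor_transform(curve, ivim_scheme)
        proj = project_through_point(l_s, ref.point_at(10.0), ref, d_max=10.0)
        assert proj.ok
        assert proj.d == pytest.approx(0.7, rel=1e-4)

    def test_far_side_selection_on_constructed_geometry(self, ivim_scheme):
        # the returned intersection must lie beyond l_s as seen from l_dstar
        ref = reference_curve(ivim_scheme)
        l_dstar = ref.point_at(12.0)
        curve = ivim_signal(ivim_scheme, IVIMParams(S0=1.0, f=0.8, D=0.4, D_star=12.0))
        l_s = phasor_transform(curve, ivim_scheme)
        proj = project_through_point(l_s, l_dstar, ref, d_max=12.0)
        assert proj.ok
        v = np.array([l_s.g - l_dstar.g, l_s.s - l_dstar.s])
        w = np.array([proj.point.g - l_dstar.g, proj.point.s - l_dstar.s])
        t = (w @ v) / (v @ v)
        assert t >= 1.0 - 1e-6

    def test_point_above_curve_fails_cleanly(self, ivim_scheme):
        # negative-kurtosis territory: no far-side intersection exists
        ref = reference_curve(ivim_scheme)
        proj = project_through_point(PhasorPoint(0.4, 0.65), ref.point_at(10.0), ref,
                                     d_max=10.0)
        assert not proj.ok


class TestPhasorFit:
    def test_noise_free_recovery(self, ivim_scheme):
        fit = fit_phasor(ivim_signal(ivim_scheme, TRUTH), ivim_scheme)
        assert fit.converged
        assert fit.f == pytest.approx(0.3, rel=1e-3)
        assert fit.D == pytest.approx(0.7, rel=1e-3)
        assert fit.D_star == pytest.approx(10.0, rel=1e-3)

    def test_monoexponential_penalty_drives_f_to_zero(self, ivim_scheme):
        curve = multiexp_signal(ivim_scheme, MixtureSpec((0.7,), (1.0,)))
        fit = fit_phasor(curve, ivim_scheme)
        assert abs(fit.f) < 5e-3
        assert fit.D == pytest.approx(0.7, rel=1e-3)

    def test_scale_invariance(self, ivim_scheme):
        curve = ivim_signal(ivim_scheme, TRUTH)
        a = fit_phasor(curve.values, ivim_scheme)
        b = fit_phasor(curve.values * 137.0, ivim_scheme)
        assert a.f == pytest.approx(b.f, rel=1e-9)
        assert a.D == pytest.approx(b.D, rel=1e-9)
        assert a.D_star == pytest.approx(b.D_star, rel=1e-9)
        assert b.S0 == pytest.approx(137.0 * a.S0, rel=1e-12)

    def test_structural_d_ordering(self, ivim_scheme, rng):
        clean = ivim_signal(ivim_scheme, TRUTH).values
        noisy = rician_magnitude(np.broadcast_to(clean, (25, 15)), 1 / 20, rng)
        for y in noisy:
            fit = fit_phasor(y, ivim_scheme)
            assert fit.D <= fit.D_star + 1e-9

    def test_regularization_suppresses_spurious_fractions(self, ivim_scheme, rng):
        # near-monoexponential noisy curves: the penalty must not inflate the
        # typical |f| and must make large spurious fractions (the f~0.7 local
        # optimum) rarer than in the unregularized fit
        clean = ivim_signal(
            ivim_scheme, IVIMParams(S0=1.0, f=0.02, D=0.7, D_star=10.0)
        ).values
        noisy = rician_magnitude(np.broadcast_to(clean, (120, 15)), 1 / 30, rng)
        ref = reference_curve(ivim_scheme)
        f_reg, f_free = [], []
        for y in noisy:
            f_reg.append(abs(fit_phasor(y, ivim_scheme, PhasorFitConfig(lam=0.05), ref).f))
            f_free.append(abs(fit_phasor(y, ivim_scheme, PhasorFitConfig(lam=0.0), ref).f))
        f_reg, f_free = np.array(f_reg), np.array(f_free)
        assert f_reg.mean() < f_free.mean()
        assert (f_reg > 0.3).sum() <= (f_free > 0.3).sum()


class TestNoiseFreeIdentifiability:
    @pytest.mark.parametrize("f", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("d, dstar", [(0.7, 10.0), (1.2, 6.0)])
    def test_nlls_and_phasor_recover_exact_biexponentials(self, ivim_scheme, f, d, dstar):
        # the phasor fit runs unpenalized here: the low-f regularizer
        # deliberately biases near-curve points (tested separately)
        curve = ivim_signal(ivim_scheme, IVIMParams(S0=1.0, f=f, D=d, D_star=dstar))
        fits = [
            fit_nlls(curve, ivim_scheme),
            fit_phasor(curve, ivim_scheme, PhasorFitConfig(lam=0.0)),
        ]
        for fit in fits:
            assert fit.f == pytest.approx(f, rel=1e-3, abs=1e-3)
            assert fit.D == pytest.approx(d, rel=1e-3)
            assert fit.D_star == pytest.approx(dstar, rel=1e-3)


class TestFitVolume:
    def _volume(self, scheme):
        params = [
            IVIMParams(S0=1.0, f=0.1, D=0.7, D_star=10.0),
            IVIMParams(S0=2.0, f=0.3, D=0.9, D_star=8.0),
            IVIMParams(S0=1.5, f=0.2, D=0.5, D_star=12.0),
            IVIMParams(S0=1.0, f=0.05, D=1.1, D_star=15.0),
        ]
        vol = np.stack([ivim_signal(scheme, p).values for p in params]).reshape(2, 2, 1, -1)
        return vol, params

    def test_maps_equal_voxelwise_fits(self, ivim_scheme):
        vol, params = self._volume(ivim_scheme)
        maps = fit_volume(vol, ivim_scheme, method="segmented")
        for k, p in enumerate(params):
            i, j = divmod(k, 2)
            ref = fit_segmented(vol[i, j, 0], ivim_scheme)
            assert maps["f"][i, j, 0] == pytest.approx(ref.f, rel=1e-12)
            assert maps["D"][i, j, 0] == pytest.approx(ref.D, rel=1e-12)

    def test_zero_voxel_flagged_failed(self, ivim_scheme):
        vol, _ = self._volume(ivim_scheme)
        vol[0, 0, 0] = 0.0
        maps = fit_volume(vol, ivim_scheme, method="nlls")
        assert maps["failed"][0, 0, 0]
        assert not maps["failed"][1, 1, 0]

    def test_full_and_six_bvalue_subsets_share_geometry(self):
        full = SamplingScheme(tuple(sorted(set(IVIM_BVALUES_6) | {10, 20, 40, 60, 150,
                                                                  200, 250, 400, 800})))
        vol, _ = self._volume(full)
        maps15 = fit_volume(vol, full, method="segmented", b_max=1000)
        six = SamplingScheme(IVIM_BVALUES_6)
        vol6 = vol[..., np.isin(full.b_array, six.b_array)]
        maps6 = fit_volume(vol6, six, method="segmented")
        assert maps15["f"].shape == maps6["f"].shape == (2, 2, 1)
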