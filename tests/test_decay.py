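"""Leakage estimation, window selection and decay fitting oracles."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectspec.curve_io import IZCurve
from ectspec.decay import (DecayFit, FitError, WindowError, estimate_leakage,
                           fit_curve_set, fit_decay, select_fit_window,
                           summarize_beta)
from ectspec.synthetic import get_preset, make_curve_set, make_retraction_curve
from tests.conftest import noiseless


def make_fit(beta, flags=()):
    return DecayFit(beta=beta, I0=4e-10, leakage_est=2e-12, window=(0, 100),
                    r2=0.99, flags=frozenset(flags))


class TestLeakage:
    def test_noiseless_tail_recovers_generative_leakage(self, gold_noiseless):
        c = make_retraction_curve(gold_noiseless, seed=0)
        est = estimate_leakage(c)
        assert est.value == pytest.approx(2e-12, rel=0.01)
        assert not est.leakage_dominated

    def test_zero_leakage_curve_estimates_near_zero(self, protein_noiseless):
        c = make_retraction_curve(replace(protein_noiseless, leakage=1e-18), seed=0)
        assert estimate_leakage(c).value < 1e-15

    def test_constant_curve_is_leakage_dominated(self):
        z = np.linspace(0, 15, 64)
        c = IZCurve(z=z, I=np.full_like(z, 0.4e-9), U_P=0.6, U_S=-0.2)
        assert estimate_leakage(c).leakage_dominated

    def test_short_curve_rejected(self):
        z = np.linspace(0, 1, 10)
        c = IZCurve(z=z, I=np.full_like(z, 1e-10), U_P=0.0, U_S=0.0)
        with pytest.raises(FitError):
            estimate_leakage(c)


class TestWindow:
    @pytest.mark.parametrize("preset_name,beta", [("bare_gold", 9.0),
                                                  ("pCc1_hCc", 1.5)])
    def test_window_ends_at_three_times_leakage(self, preset_name, beta):
        p = noiseless(get_preset(preset_name))
        c = make_retraction_curve(p, seed=0)
        win = select_fit_window(c, p.leakage)
        # I(z) = leak + (set - leak) e^{-beta z} crosses 3*leak at
        # z = ln((set - leak) / (2 leak)) / beta
        z_end = np.log((p.set_point - p.leakage) / (2 * p.leakage)) / beta
        dz = c.z[1] - c.z[0]
        assert c.z[win.stop - 1] == pytest.approx(z_end, abs=2 * dz)
        assert win.start == 0
        assert not win.flags

    def test_all_saturated_curve_rejected(self):
        z = np.linspace(0, 15, 64)
        c = IZCurve(z=z, I=np.full_like(z, 10e-9), U_P=0.6, U_S=-0.2,
                    set_point=10e-9)
        with pytest.raises(WindowError):
            select_fit_window(c, 2e-12)

    def test_narrow_window_flagged(self):
        z = np.linspace(0, 15, 64)
        I = 2e-12 + 4e-10 * np.exp(-20.0 * z)  # decays within ~4 points
        c = IZCurve(z=z, I=I, U_P=0.6, U_S=-0.2)
        win = select_fit_window(c, 2e-12)
        assert "too_few_points" in win.flags


class TestFitDecay:
    @pytest.mark.parametrize("preset_name,beta", [("bare_gold", 9.0),
                                                  ("pCc1_hCc", 1.5)])
    def test_noiseless_oracle_round_trip(self, preset_name, beta):
        c = make_retraction_curve(noiseless(get_preset(preset_name)), seed=0)
        fit = fit_decay(c)
        assert fit.beta == pytest.approx(beta, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.I0 == pytest.approx(0.4e-9, rel=1e-6)

    @pytest.mark.parametrize("scale", [0.2, 1.0, 5.0])
    def test_scale_equivariance(self, protein_noiseless, scale):
        c = make_retraction_curve(protein_noiseless, seed=0)
        scaled = IZCurve(z=c.z, I=c.I * scale, U_P=c.U_P, U_S=c.U_S,
                         set_point=c.set_point * scale)
        assert fit_decay(scaled).beta == pytest.approx(fit_decay(c).beta,
                                                       rel=1e-9)

    def test_approach_retraction_symmetry(self, protein_noiseless):
        retr = make_retraction_curve(protein_noiseless, seed=0)
        appr = make_retraction_curve(
            replace(protein_noiseless, mode="approach", z_span=100.0,
                    n_points=4096), seed=0)
        assert fit_decay(appr).beta == pytest.approx(fit_decay(retr).beta,
                                                     rel=1e-6)
        assert "saturated_start" not in fit_decay(appr).flags

    def test_ensemble_mean_recovers_generative_beta(self, protein_preset):
        cs = make_curve_set(protein_preset, 150, seed=31)
        fits = fit_curve_set(cs)
        s = summarize_beta(fits)
        se = protein_preset.beta_sd / np.sqrt(s.n)
        assert abs(s.mean - 1.5) < 2 * se + 0.07  # 0.07: truncation-at-0.05 bias

    def test_nonlinear_refit_agrees_with_log_linear(self, protein_preset):
        c = make_curve_set(protein_preset, 5, seed=17)[2]
        ols = fit_decay(c, method="ols")
        nl = fit_decay(c, method="nonlinear")
        assert nl.beta == pytest.approx(ols.beta, rel=0.05)


class TestSummarize:
    def test_degenerate_identical_fits(self):
        s = summarize_beta([make_fit(2.0)] * 3)
        assert (s.mean, s.sd, s.n) == (2.0, 0.0, 3)

    def test_flagged_fits_excluded(self):
        fits = [make_fit(2.0), make_fit(2.0), make_fit(50.0, flags=["unfittable"])]
        s = summarize_beta(fits)
        assert s.mean == 2.0 and s.n == 2

    def test_fewer_than_two_usable_fits_rejected(self):
        with pytest.raises(FitError):
            summarize_beta([make_fit(2.0), make_fit(3.0, flags=["too_few_points"])])

    def test_default_bin_widths_follow_regime(self):
        lo = summarize_beta([make_fit(b) for b in (1.0, 1.5, 2.0)])
        hi = summarize_beta([make_fit(b) for b in (8.0, 9.0, 10.0)])
        assert lo.bin_edges[1] - lo.bin_edges[0] == pytest.approx(0.25)
        assert hi.bin_edges[1] - hi.bin_edges[0] == pytest.approx(1.0)

    def test_gaussian_histogram_method_close_to_mean_sd(self, gold_preset):
        cs = make_curve_set(gold_preset, 150, seed=8)
        fits = fit_curve_set(cs)
        a = summarize_beta(fits)
        g = summarize_beta(fits, method="gaussian")
        assert g.mean == pytest.approx(a.mean, abs=1.0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.1, 20.0), min_size=2, max_size=60),
           st.floats(0.1, 2.0))
    def test_histogram_counts_conserve_n(self, betas, bw):
        s = summarize_beta([make_fit(b) for b in betas], bin_width=bw)
        assert s.counts.sum() == s.n == len(betas)
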