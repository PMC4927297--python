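"""Titration mapping, recovery kernel, convolution forward model, and
least-squares recovery of the re-acidification kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import calyxcycle as cc
from calyxcycle import ReacidificationParams, TimeSeries, preset
from calyxcycle.reacidification import (estimate_flux, fit_delayed_exponential,
                                        fit_reacidification, hh_fluorescence,
                                        predict_quench, recovery_kernel)


class TestTitration:
    def test_midpoint_at_pka(self):
        assert hh_fluorescence(7.05) == pytest.approx(0.5)

    def test_frozen_endpoint_values(self):
        """phi(5.5) and phi(7.4) with pKa 7.05, Hill 1 (direct evaluation
        of 1/(1 + 10**(pH - pKa)))."""
        assert hh_fluorescence(5.5) == pytest.approx(0.97259, abs=1e-5)
        assert hh_fluorescence(7.4) == pytest.approx(0.30876, abs=1e-5)

    @given(st.floats(3.0, 10.0), st.floats(3.0, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_ph(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert hh_fluorescence(lo) > hh_fluorescence(hi)


class TestRecoveryKernel:
    def test_zero_during_delay(self):
        p = ReacidificationParams(delay_s=14.0, tau_acid_s=38.7)
        assert recovery_kernel(0.0, p) == 0.0
        assert recovery_kernel(13.999, p) == 0.0

    def test_full_reacidification_limit(self):
        p = ReacidificationParams(delay_s=14.0, tau_acid_s=38.7)
        assert recovery_kernel(1e5, p) == pytest.approx(1.0, abs=1e-9)

    def test_one_time_constant_after_delay(self):
        """At s = delay + tau the lumen pH is 5.5 + 1.9/e; mapping through
        the titration curve gives g = 0.8552 (direct evaluation)."""
        p = ReacidificationParams(delay_s=14.0, tau_acid_s=38.7)
        assert recovery_kernel(14.0 + 38.7, p) == pytest.approx(0.8552, abs=2e-4)

    @given(st.floats(0.0, 30.0), st.floats(1.0, 200.0),
           st.lists(st.floats(0.0, 300.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, delay, tau, ss):
        p = ReacidificationParams(delay_s=delay, tau_acid_s=tau)
        s = np.sort(np.asarray(ss))
        g = recovery_kernel(s, p)
        assert np.all((g >= 0) & (g <= 1))
        assert np.all(np.diff(g) >= -1e-12)


class TestPredictQuench:
    def test_infinite_delay_keeps_quench_at_one(self, rat_clean):
        p = ReacidificationParams(delay_s=1e6, tau_acid_s=38.7)
        q = predict_quench(rat_clean["cm_norm"], p)
        np.testing.assert_allclose(q.v, 1.0, atol=1e-12)

    def test_instantaneous_reacidification_tracks_membrane(self, rat_clean):
        """delay = 0 and tau -> 0: fluorescence recovers exactly with the
        membrane, so Q(t) equals the normalized capacitance (up to the 2-s
        bin-averaged representation of the recovery limb)."""
        p = ReacidificationParams(delay_s=0.0, tau_acid_s=1e-6)
        cm_norm = rat_clean["cm_norm"]
        q = predict_quench(cm_norm, p)
        truth = np.interp(q.t, cm_norm.t, cm_norm.v)
        np.testing.assert_allclose(q.v, truth, atol=0.012)

    def test_modes_agree_for_instantaneous_endocytosis(self):
        """With all retrieval at a single instant, per-organelle and global
        delay semantics coincide."""
        t = np.arange(0.0, 60.1, 0.5)
        step = TimeSeries(t, np.where(t < 0.25, 1.0, 0.0), "norm")
        p = ReacidificationParams(delay_s=10.0, tau_acid_s=20.0)
        qa = predict_quench(step, p, mode="per_organelle", bin_s=0.0)
        qb = predict_quench(step, p, mode="global_delay", bin_s=0.0)
        np.testing.assert_allclose(qa.v, qb.v, atol=2e-3)

    def test_bounded_and_non_increasing(self, rat_clean):
        q = predict_quench(rat_clean["cm_norm"], rat_clean["scn"].reacid)
        assert np.all((q.v >= 0.12 - 1e-6) & (q.v <= 1.0 + 1e-12))
        assert np.all(np.diff(q.v) <= 1e-9)

    def test_matches_generator_quench(self, rat_clean):
        """The analysis-side convolution reproduces the generator's quench
        trace from the capacitance trace alone."""
        q_gen = rat_clean["q"]
        q_pred = predict_quench(rat_clean["cm_norm"], rat_clean["scn"].reacid,
                                out_t=q_gen.t[q_gen.t >= 0])
        np.testing.assert_allclose(q_pred.v, q_gen.v[q_gen.t >= 0], atol=5e-3)


class TestFluxEstimate:
    def test_flux_integrates_to_retrieved_fraction(self, rat_clean):
        centers, flux, diag = estimate_flux(rat_clean["cm_norm"])
        total = np.trapezoid(flux, centers)
        expected = 1.0 - cc.endpoint_metric(rat_clean["cm_norm"], 60.0)
        assert total == pytest.approx(expected, abs=0.05)
        assert "warning" not in diag


class TestConvolutionFit:
    def test_rat_recovery(self, rat_clean):
        """Grid search + refinement recovers (14 s, 38.7 s) from the
        noise-free rat preset within 0.5 s / 2 %."""
        res = fit_reacidification(rat_clean["cm_norm"], rat_clean["q"].trace)
        assert res.delay_s == pytest.approx(14.0, abs=0.5)
        assert res.tau_acid_s == pytest.approx(38.7, rel=0.02)
        assert not res.boundary_flag

    def test_mouse_recovery(self, mouse_clean):
        """Same fit on the mouse preset recovers (12 s, 18.9 s)."""
        res = fit_reacidification(mouse_clean["cm_norm"], mouse_clean["q"].trace)
        assert res.delay_s == pytest.approx(12.0, abs=0.5)
        assert res.tau_acid_s == pytest.approx(18.9, rel=0.02)

    def test_sse_surface_minimum_at_truth(self, rat_clean):
        """On the default grid the sse surface bottoms out at the
        generating parameters (identifiability at grid resolution)."""
        res = fit_reacidification(rat_clean["cm_norm"], rat_clean["q"].trace)
        (d_grid, tau_grid) = min(res.grid_surface, key=res.grid_surface.get)
        assert d_grid == pytest.approx(14.0, abs=1.0)
        assert tau_grid == pytest.approx(38.7, rel=0.11)

    def test_flat_quench_flagged_unidentifiable(self):
        scn = preset("bafilomycin", noise_sd=0.0)
        cm_norm = cc.normalize_capacitance(cc.simulate_capacitance(scn))
        fl, _ = cc.simulate_reporter(scn)
        q = cc.normalize_invert(fl)
        res = fit_reacidification(cm_norm, q.trace)
        assert res.boundary_flag

    def test_noisy_parameter_recovery_medians(self):
        """3 % Gaussian noise, 50 seeds: median delay within ±2 s and
        median tau within ±15 % of the generating values."""
        delays, taus = [], []
        for seed in range(50):
            scn = preset("rat_control", noise_sd=0.03, seed=seed)
            cm = cc.simulate_capacitance(scn)
            cm_norm = cc.normalize_capacitance(cm)
            fl, _ = cc.simulate_reporter(scn, cm)
            q = cc.normalize_invert(fl)
            res = fit_reacidification(cm_norm, q.trace)
            delays.append(res.delay_s)
            taus.append(res.tau_acid_s)
        assert np.median(delays) == pytest.approx(14.0, abs=2.0)
        assert np.median(taus) == pytest.approx(38.7, rel=0.15)


class TestDelayedExponential:
    def test_exact_family_recovery(self):
        """A noise-free delayed exponential (d=16, tau=59.7, A=0.13) is
        recovered exactly."""
        t = np.arange(0.0, 190.0, 2.0)
        y = 0.13 + 0.87 * np.minimum(1.0, np.exp(-(t - 16.0) / 59.7))
        est = cc.DelayedExponential().fit(t, y)
        assert est.delay_ == pytest.approx(16.0, abs=0.05)
        assert est.tau_ == pytest.approx(59.7, rel=1e-3)
        assert est.asymptote_ == pytest.approx(0.13, abs=1e-3)

    def test_long_recording_forward_model(self):
        """The rat forward model over 190 s is summarized by a delayed
        exponential with parameters in the neighbourhood of (16 s, 55-60 s)
        — a qualitative consistency check."""
        scn = preset("rat_control", noise_sd=0.0, duration_s=190.0)
        fl, _ = cc.simulate_reporter(scn)
        q = cc.normalize_invert(fl)
        d, tau, a, sse = fit_delayed_exponential(q.trace)
        assert 10.0 < d < 22.0
        assert 45.0 < tau < 70.0
        assert a == pytest.approx(0.13, abs=0.05)

    def test_no_recovery_hits_bound(self):
        t = np.arange(0.0, 60.0, 2.0)
        est = cc.DelayedExponential().fit(t, np.ones_like(t))
        assert est.boundary_flag_
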