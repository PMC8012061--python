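import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poolkin as pk
from poolkin.pool_models import steady_state

from conftest import (
    KO_K1DP_AFTER,
    KO_MODEL1,
    RECOVERY_INTERVALS,
    WT_K1DP_AFTER,
    WT_MODEL1,
)

rates = st.floats(1e-3, 1.0)
pools = st.floats(1.0, 500.0)


class TestClosedForms:
    def test_empty_pool_starts_at_zero(self):
        assert pk.model1_pool(0.0, WT_MODEL1) == 0.0
        m2 = pk.Model2Params(k1dp=0.039, pp_max=82.4, k_minus1=0.0043)
        assert pk.model2_pool(0.0, m2) == 0.0

    def test_model1_steady_state(self):
        p = pk.Model1Params(k1dp=3.21, k_minus1=0.043)
        assert pk.model1_pool(1e6, p) == pytest.approx(3.21 / 0.043, rel=1e-9)
        assert steady_state(p) == pytest.approx(74.65, abs=0.01)

    def test_model2_steady_state_release_site_case(self):
        m2 = pk.Model2Params(k1dp=0.039, pp_max=82.4, k_minus1=0.0043)
        assert steady_state(m2) == pytest.approx(74.2, abs=0.05)

    @settings(deadline=None, max_examples=20)
    @given(k1dp=st.floats(0.1, 20.0), km1=rates, kf=st.floats(0.0, 0.5),
           pp0=st.floats(0.0, 100.0))
    def test_model1_matches_ode_integration(self, k1dp, km1, kf, pp0):
        p = pk.Model1Params(k1dp=k1dp, k_minus1=km1, k_f=kf)
        t, pp = pk.ode_oracle(p, 120.0, pp0=pp0, n_points=60)
        closed = pk.model1_pool(t, p, pp0=pp0)
        np.testing.assert_allclose(pp, closed, rtol=1e-8, atol=1e-10)

    @settings(deadline=None, max_examples=20)
    @given(k1dp=rates, pp_max=pools, km1=rates, kf=st.floats(0.0, 0.5),
           pp0=st.floats(0.0, 50.0))
    def test_model2_matches_ode_integration(self, k1dp, pp_max, km1, kf, pp0):
        p = pk.Model2Params(k1dp=k1dp, pp_max=pp_max, k_minus1=km1, k_f=kf)
        t, pp = pk.ode_oracle(p, 120.0, pp0=pp0, n_points=60)
        closed = pk.model2_pool(t, p, pp0=pp0)
        np.testing.assert_allclose(pp, closed, rtol=1e-8, atol=1e-10)

    @settings(deadline=None, max_examples=20)
    @given(k1dp=st.floats(0.1, 20.0), km1=rates)
    def test_recovery_from_empty_pool_is_monotone(self, k1dp, km1):
        t = np.linspace(0.0, 200.0, 500)
        p1 = pk.Model1Params(k1dp=k1dp, k_minus1=km1)
        assert np.all(np.diff(pk.model1_pool(t, p1)) >= 0)
        p2 = pk.Model2Params(k1dp=km1, pp_max=100.0, k_minus1=k1dp / 20)
        assert np.all(np.diff(pk.model2_pool(t, p2)) >= 0)

    def test_model2_reduces_to_model1_at_large_capacity(self):
        """With pp_max -> inf at fixed total forward flux the release-site
        model loses its capacity limit."""
        flux = 3.21  # fF/s
        t = np.linspace(0.0, 100.0, 50)
        m1 = pk.model1_pool(t, pk.Model1Params(k1dp=flux, k_minus1=0.043))
        big = 1e7
        m2 = pk.model2_pool(
            t, pk.Model2Params(k1dp=flux / big, pp_max=big, k_minus1=0.043))
        np.testing.assert_allclose(m2, m1, rtol=1e-5)


class TestRecoveryFitting:
    def test_noiseless_fit_is_identity(self):
        curve = pk.simulate_recovery(WT_MODEL1, WT_K1DP_AFTER,
                                     RECOVERY_INTERVALS)
        fit = pk.fit_recovery(curve)
        plateau_true = WT_K1DP_AFTER / WT_MODEL1.k1dp
        assert fit.plateau == pytest.approx(plateau_true, rel=1e-6)
        assert fit.rate == pytest.approx(WT_MODEL1.k_minus1, rel=1e-6)

    def test_degenerate_curve_rejected(self):
        curve = pk.RecoveryCurve(intervals=np.array([1.0, 2.0, 3.0]),
                                 ratios=np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValueError, match="degenerate"):
            pk.fit_recovery(curve)

    def test_too_few_intervals_rejected(self):
        curve = pk.RecoveryCurve(intervals=np.array([1.0, 2.0]),
                                 ratios=np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            pk.fit_recovery(curve)

    def test_means_mode_agrees_on_balanced_noiseless_data(self):
        curve = pk.generate_recovery_experiment(
            WT_MODEL1, RECOVERY_INTERVALS, WT_K1DP_AFTER,
            n_cells_per_interval=4, noise=pk.NoiseSpec(sigma_cm=0.0))
        a = pk.fit_recovery(curve, mode="points")
        b = pk.fit_recovery(curve, mode="means")
        assert a.rate == pytest.approx(b.rate, rel=1e-6)

    def test_ko_cohorts_fit_faster_rate_than_wt(self):
        """Faster depriming in the knock-out is recovered from noisy
        cohorts in nearly all replicates."""
        wins = 0
        n_rep = 25
        for rep in range(n_rep):
            wt = pk.generate_recovery_experiment(
                WT_MODEL1, RECOVERY_INTERVALS, WT_K1DP_AFTER, 6,
                pk.NoiseSpec(sigma_cm=2.0, seed=2 * rep))
            ko = pk.generate_recovery_experiment(
                KO_MODEL1, RECOVERY_INTERVALS, KO_K1DP_AFTER, 6,
                pk.NoiseSpec(sigma_cm=2.0, seed=2 * rep + 1))
            wins += pk.fit_recovery(ko).rate > pk.fit_recovery(wt).rate
        assert wins >= 24


class TestDerivedRates:
    def test_wt_forward_rate_from_pool_and_depriming(self):
        fit = pk.RecoveryFit(plateau=1.0, rate=0.043)
        rates_ = pk.derive_rates(74.2, fit)
        assert rates_.k1dp_before == pytest.approx(3.19, abs=0.01)

    def test_ko_600ms_forward_rate(self):
        fit = pk.RecoveryFit(plateau=1.0, rate=0.19)
        assert pk.derive_rates(85.4, fit).k1dp_before == pytest.approx(16.2, abs=0.05)

    def test_plateau_one_preserves_forward_rate(self):
        fit = pk.RecoveryFit(plateau=1.0, rate=0.05)
        r = pk.derive_rates(100.0, fit)
        assert r.k1dp_after == r.k1dp_before

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError):
            pk.derive_rates(-1.0, pk.RecoveryFit(plateau=1.0, rate=0.05))


class TestReleaseSiteTranslation:
    def test_wt_printed_values(self):
        m2 = pk.translate_to_release_site(74.2, 0.043, 0.9)
        assert m2.pp_max == pytest.approx(82.4, abs=0.05)
        assert m2.k1dp == pytest.approx(0.039, abs=0.0005)
        assert m2.k_minus1 == pytest.approx(0.0043, abs=0.00005)

    def test_600ms_pool_translation(self):
        m2 = pk.translate_to_release_site(145.0, 0.059, 0.9)
        assert m2.pp_max == pytest.approx(161.1, abs=0.05)
        assert m2.k1dp == pytest.approx(0.0531, abs=0.0001)
        assert m2.k_minus1 == pytest.approx(0.0059, abs=0.0001)

    def test_full_occupancy_limit(self):
        m2 = pk.translate_to_release_site(50.0, 0.1, occupancy=1.0)
        assert m2.k_minus1 == 0.0
        assert m2.k1dp == pytest.approx(0.1)

    @settings(deadline=None, max_examples=25)
    @given(pool=pools, rate=rates, occ=st.floats(0.05, 1.0))
    def test_translation_is_invertible(self, pool, rate, occ):
        m2 = pk.translate_to_release_site(pool, rate, occ)
        assert m2.k1dp + m2.k_minus1 == pytest.approx(rate, rel=1e-12)
        assert steady_state(m2) == pytest.approx(pool, rel=1e-12)

    def test_translated_recovery_identical_to_model1(self):
        m2 = pk.translate_to_release_site(74.2, 0.043, 0.9)
        iv = np.geomspace(0.5, 120.0, 30)
        c1 = pk.simulate_recovery(WT_MODEL1, WT_MODEL1.k1dp, iv)
        c2 = pk.simulate_recovery(m2, m2.k1dp, iv)
        np.testing.assert_allclose(c2.ratios, c1.ratios, rtol=1e-9)

    def test_bad_occupancy_rejected(self):
        with pytest.raises(ValueError):
            pk.translate_to_release_site(74.2, 0.043, 0.0)
        with pytest.raises(ValueError):
            pk.translate_to_release_site(74.2, 0.043, 1.1)


class TestSimulatedRecoveryScenarios:
    def test_unchanged_forward_rate_gives_plateau_one(self):
        curve = pk.simulate_recovery(WT_MODEL1, WT_MODEL1.k1dp,
                                     RECOVERY_INTERVALS)
        lam = WT_MODEL1.k_minus1
        expected = 1.0 - np.exp(-lam * RECOVERY_INTERVALS)
        np.testing.assert_allclose(curve.ratios, expected, rtol=1e-12)

    def test_ko_release_site_recovery_trails_wt_at_60ms(self):
        """Carrying the knock-out's rate changes into the release-site model
        (depriming up 2.12-fold, per-site forward rates rescaled by the
        measured flux ratios, same release-site count) delays recovery
        relative to wild type: the drop in post-stimulation priming
        dominates once forward rates enter the recovery time constant."""
        wt2 = pk.translate_to_release_site(74.2, 0.043, 0.9)
        wt_after = wt2.k1dp * (WT_K1DP_AFTER / WT_MODEL1.k1dp)
        ko_pre = pk.Model2Params(
            k1dp=wt2.k1dp * (KO_MODEL1.k1dp / WT_MODEL1.k1dp),
            pp_max=wt2.pp_max,
            k_minus1=wt2.k_minus1 * (KO_MODEL1.k_minus1 / WT_MODEL1.k_minus1))
        ko_after = wt2.k1dp * (KO_K1DP_AFTER / WT_MODEL1.k1dp)
        iv = np.geomspace(0.5, 120, 40)
        wt_curve = pk.simulate_recovery(wt2, wt_after, iv)
        ko_curve = pk.simulate_recovery(ko_pre, ko_after, iv)
        assert np.all(ko_curve.ratios <= wt_curve.ratios + 1e-12)
        assert ko_curve.ratios[-1] < wt_curve.ratios[-1]


class TestOdeOracle:
    def test_flat_trajectory_for_zero_forward_rate(self):
        p = pk.Model1Params(k1dp=0.0, k_minus1=0.1)
        _, pp = pk.ode_oracle(p, 10.0, pp0=0.0)
        np.testing.assert_allclose(pp, 0.0, atol=1e-12)

    def test_bad_t_end_rejected(self):
        with pytest.raises(ValueError):
            pk.ode_oracle(WT_MODEL1, -1.0)
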