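import numpy as np
import pytest

import poolkin as pk
from poolkin.kinetics import SingleExpKinetics

from conftest import DELAYED_KIN, WT_KIN


def _rel_err(fitted, truth):
    return abs(fitted - truth) / abs(truth)


def make_trace(kin, sigma=0.0, seed=0, grid=None):
    grid = grid or pk.TimeGrid()
    return pk.generate_flash_trace(kin, grid, pk.NoiseSpec(sigma_cm=sigma, seed=seed))


class TestNoiselessRoundTrips:
    def test_standard_fit_recovers_parameters(self):
        fit = pk.fit_standard(make_trace(WT_KIN))
        p = fit.params
        for name in ("A1", "tau1", "A2", "tau2", "A3"):
            assert _rel_err(getattr(p, name), getattr(WT_KIN, name)) < 1e-6
        assert fit.rss < 1e-12

    def test_delayed_fit_recovers_parameters(self):
        fit = pk.fit_delayed_srp(make_trace(DELAYED_KIN))
        p = fit.params
        for name in ("A1", "tau1", "SRP", "tau_slow_delay"):
            assert _rel_err(getattr(p, name), getattr(DELAYED_KIN, name)) < 1e-6
        assert abs(p.A3) < 1e-6

    def test_single_exponential_refit_recovers_parameters(self):
        kin = SingleExpKinetics(A=60.0, tau=0.02, A3=10.0)
        fit = pk.refit_single_exponential(make_trace(kin), "rrp")
        assert _rel_err(fit.params.A, 60.0) < 1e-6
        assert _rel_err(fit.params.tau, 0.02) < 1e-6
        assert _rel_err(fit.params.A3, 10.0) < 1e-6
        assert fit.assignment.rrp_size == pytest.approx(60.0, rel=1e-6)
        assert fit.assignment.srp_size == 0.0

    def test_flat_trace_gives_zero_amplitude(self):
        kin = SingleExpKinetics(A=0.0, tau=0.02, A3=0.0)
        fit = pk.refit_single_exponential(make_trace(kin), "rrp")
        assert fit.params.A == pytest.approx(0.0, abs=1e-6)
        assert fit.message == "zero-amplitude component"

    def test_time_shift_invariance(self):
        """Shifting flash and window together leaves the fit unchanged."""
        tr = make_trace(WT_KIN)
        shifted = pk.CapacitanceTrace(t=tr.t + 1.0, cm=tr.cm)
        fit = pk.fit_standard(tr, window=(0.0, 5.0))
        # shift back the time axis so the flash is at 0 again
        back = pk.CapacitanceTrace(t=shifted.t - 1.0, cm=shifted.cm)
        fit2 = pk.fit_standard(back, window=(0.0, 5.0))
        for name in ("A1", "tau1", "A2", "tau2", "A3"):
            assert getattr(fit2.params, name) == pytest.approx(
                getattr(fit.params, name), rel=1e-9)


class TestModelSelection:
    def test_standard_trace_selects_standard(self):
        assert pk.select_model(make_trace(WT_KIN)).model_id == "standard"

    def test_delayed_trace_selects_delayed(self):
        assert pk.select_model(make_trace(DELAYED_KIN)).model_id == "delayed_srp"

    def test_s_shaped_trace_better_fit_by_delayed_model(self):
        tr = make_trace(DELAYED_KIN, sigma=2.0, seed=5)
        std = pk.fit_standard(tr)
        dly = pk.fit_delayed_srp(tr)
        assert dly.rss < std.rss

    def test_selection_robust_to_noise(self):
        hits = sum(
            pk.select_model(make_trace(WT_KIN, sigma=2.0, seed=s)).model_id
            == "standard"
            for s in range(10)
        )
        assert hits >= 9

    def test_nested_models_rss_ordering(self):
        """The two-exponential fit can never do worse than its single-
        exponential special case on the same trace."""
        tr = make_trace(WT_KIN, sigma=2.0, seed=11)
        single = pk.refit_single_exponential(tr, "rrp")
        double = pk.fit_standard(tr)
        assert double.rss <= single.rss * (1 + 1e-9)


class TestClassification:
    def test_tau_boundaries(self):
        fit = pk.FlashFitResult(
            "standard", pk.FlashKinetics(50, 0.0134, 30, 0.5, 10), rss=0.0)
        a = pk.classify_components(fit)
        assert a.rrp_size == 50 and a.rrp_tau == 0.0134
        assert a.srp_size == 30 and a.srp_tau == 0.5
        assert a.sustained_rate == 10
        assert a.needs_refit is None

    def test_two_fast_components_trigger_refit(self):
        fit = pk.FlashFitResult(
            "standard", pk.FlashKinetics(50, 0.010, 30, 0.040, 10), rss=0.0)
        assert pk.classify_components(fit).needs_refit == "rrp"

    def test_slow_component_dropped(self):
        fit = pk.FlashFitResult(
            "standard", pk.FlashKinetics(50, 0.0134, 30, 2.0, 10), rss=0.0)
        a = pk.classify_components(fit)
        assert a.srp_size == 0.0 and a.srp_tau is None
        assert a.dropped == [(30, 2.0)]

    def test_srp_upper_configurable_for_delayed_datasets(self):
        # sqrt(1.44) = 1.2 s characteristic time: outside the default SRP
        # window but inside the 1.6 s window used for delayed-SRP data
        fit = pk.FlashFitResult(
            "delayed_srp", pk.DelayedSRPKinetics(40, 0.02, 300, 1.44, 0), rss=0.0)
        assert pk.classify_components(fit).srp_size == 0.0
        assert pk.classify_components(fit, srp_upper=1.6).srp_size == 300.0

    def test_analyze_flash_merges_double_fast_trace(self):
        """Two fast components are refitted as one RRP of combined size."""
        kin = pk.FlashKinetics(A1=40.0, tau1=0.010, A2=30.0, tau2=0.040, A3=5.0)
        res = pk.analyze_flash(make_trace(kin), model="standard")
        assert res.model_id == "single_exp"
        assert res.assignment.rrp_size == pytest.approx(70.0, rel=0.10)
        assert res.assignment.srp_size == 0.0


class TestReadouts:
    def test_flat_trace_reads_zero(self):
        t = np.linspace(-0.5, 5.0, 1000)
        tr = pk.CapacitanceTrace(t=t, cm=np.full_like(t, 3.0))
        vals = pk.readouts(tr)
        assert all(v == pytest.approx(0.0) for v in vals.values())

    def test_readout_matches_model_evaluation(self):
        tr = make_trace(WT_KIN)
        vals = pk.readouts(tr, times=[0.06])
        expected = WT_KIN.evaluate(np.array([0.06]))[0]
        assert vals[0.06] == pytest.approx(expected, rel=1e-6)

    def test_baseline_subtraction(self):
        tr = make_trace(WT_KIN)
        offset = pk.CapacitanceTrace(t=tr.t, cm=tr.cm + 100.0)
        assert pk.readouts(offset)[5.0] == pytest.approx(pk.readouts(tr)[5.0])

    def test_out_of_range_time_rejected(self):
        tr = make_trace(WT_KIN)
        with pytest.raises(ValueError):
            pk.readouts(tr, times=[10.0])

    def test_high_ca_cohort_burst_exceeds_low_ca(self):
        """Calcium-dependent priming: a WT-like cohort primed at higher
        prestimulation [Ca2+] shows a larger 0.5-s burst than a KO-like one."""
        high = pk.FlashKinetics(A1=80.0, tau1=0.015, A2=60.0, tau2=0.3, A3=20.0)
        low = pk.FlashKinetics(A1=17.0, tau1=0.015, A2=13.0, tau2=0.3, A3=10.0)
        bursts = {}
        for name, kin in (("high", high), ("low", low)):
            vals = [pk.readouts(make_trace(kin, sigma=2.0, seed=s))[0.5]
                    for s in range(8)]
            bursts[name] = np.mean(vals)
        assert bursts["high"] > bursts["low"]


class TestNoisyRecovery:
    def test_mean_fitted_rrp_amplitude_unbiased(self):
        """Monte-Carlo: the mean fitted fast amplitude over noisy replicates
        stays within 5% of the generating value."""
        a1 = [pk.fit_standard(make_trace(WT_KIN, sigma=2.0, seed=s)).params.A1
              for s in range(40)]
        assert np.mean(a1) == pytest.approx(WT_KIN.A1, rel=0.05)


class TestValidation:
    def test_trace_must_cover_window(self):
        t = np.linspace(-0.1, 0.5, 50)
        tr = pk.CapacitanceTrace(t=t, cm=np.zeros_like(t))
        with pytest.raises(ValueError):
            pk.fit_standard(tr, window=(0.0, 5.0))

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            pk.CapacitanceTrace(t=np.array([0.0, 2.0, 1.0]), cm=np.zeros(3))

    def test_rss_model_consistency_enforced(self):
        with pytest.raises(ValueError):
            pk.FlashFitResult("standard",
                              pk.DelayedSRPKinetics(1, 1, 1, 1, 0), rss=0.0)
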