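import numpy as np
import pandas as pd
import pytest

from nmalab import KMCurve, PseudoIPD, cox_loghr, km_from_ipd, reconstruct_ipd
from nmalab.km import cox_logpl, km_survival_at
from nmalab.simulate import simulate_km_trial


class TestReconstructIpd:
    def test_flat_curve_all_censored(self):
        curve = KMCurve(points=[(0, 1.0), (12, 1.0)],
                        risk_table=[(0, 100), (12, 100)])
        ipd = reconstruct_ipd(curve)
        assert len(ipd) == 100
        assert ipd.n_events == 0
        assert np.all(ipd.times == 12.0)

    def test_two_patient_hand_trace(self):
        # survival halves at t=1 with one of two patients remaining: the
        # only solution is a single event at t=1
        curve = KMCurve(points=[(0, 1.0), (1, 0.5)], risk_table=[(0, 2), (1, 1)])
        ipd = reconstruct_ipd(curve)
        assert len(ipd) == 2
        assert ipd.n_events == 1
        assert ipd.times[ipd.status == 1][0] == 1.0

    def test_inconsistent_inputs_error(self):
        with pytest.raises(ValueError):
            KMCurve(points=[(0, 1.0), (1, 0.5), (2, 0.8)],
                    risk_table=[(0, 10), (2, 5)]).validate()
        with pytest.raises(ValueError):
            KMCurve(points=[(0, 1.0), (1, 0.5)],
                    risk_table=[(0, 10), (1, 12)]).validate()

    def test_exponential_simulation_recovery(self):
        curve_a, curve_b, ipd_a, ipd_b, truth = simulate_km_trial(
            n_per_arm=200, true_hr=0.7, base_rate=0.1, censor_time=24.0,
            click_points=100, risk_interval=6.0, seed=7)
        rec_a = reconstruct_ipd(curve_a)
        rec_b = reconstruct_ipd(curve_b)
        assert len(rec_a) == 200
        assert rec_a.n_events == pytest.approx(truth["n_events_a"], rel=0.05)
        assert rec_b.n_events == pytest.approx(truth["n_events_b"], rel=0.05)

    def test_roundtrip_matches_curve_at_clicks(self):
        curve_a, *_ = simulate_km_trial(seed=3)
        rec = reconstruct_ipd(curve_a)
        times = np.array([p[0] for p in curve_a.points])
        surv = np.array([p[1] for p in curve_a.points])
        assert np.abs(km_survival_at(rec, times) - surv).max() <= 0.02

    def test_total_events_constraint(self):
        curve_a, *_ , truth = simulate_km_trial(seed=9)
        curve_a.total_events = truth["n_events_a"]
        rec = reconstruct_ipd(curve_a)
        assert rec.n_events == truth["n_events_a"]


class TestCoxLogHr:
    def test_identical_arms_give_zero(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 50)
        ipd = PseudoIPD(t, np.ones(50, int))
        log_hr, se = cox_loghr(ipd, PseudoIPD(t.copy(), np.ones(50, int)))
        assert log_hr == pytest.approx(0.0, abs=1e-6)

    def test_four_patient_toy_matches_grid_search(self):
        # alternating event times keep the partial likelihood non-monotone
        arm_a = PseudoIPD(np.array([1.0, 3.0]), np.array([1, 1]))
        arm_b = PseudoIPD(np.array([2.0, 4.0]), np.array([1, 1]))
        log_hr, se = cox_loghr(arm_a, arm_b)
        grid = np.arange(-5.0, 5.0, 1e-5)
        ll = np.array([cox_logpl(b, arm_a, arm_b) for b in grid[::100]])
        coarse = grid[::100][np.argmax(ll)]
        fine = np.arange(coarse - 0.01, coarse + 0.01, 1e-6)
        ll = np.array([cox_logpl(b, arm_a, arm_b) for b in fine])
        assert log_hr == pytest.approx(fine[np.argmax(ll)], abs=1e-4)

    def test_antisymmetric_under_arm_swap(self):
        *_, ipd_a, ipd_b, _ = simulate_km_trial(n_per_arm=80, seed=13)
        ab, se_ab = cox_loghr(ipd_a, ipd_b)
        ba, se_ba = cox_loghr(ipd_b, ipd_a)
        assert ab == pytest.approx(-ba, abs=1e-6)
        assert se_ab == pytest.approx(se_ba, abs=1e-6)

    def test_agrees_with_lifelines(self):
        from lifelines import CoxPHFitter

        *_, ipd_a, ipd_b, _ = simulate_km_trial(n_per_arm=500, seed=21)
        log_hr, se = cox_loghr(ipd_a, ipd_b)
        df = pd.DataFrame({
            "t": np.concatenate([ipd_a.times, ipd_b.times]),
            "e": np.concatenate([ipd_a.status, ipd_b.status]),
            "g": [1] * len(ipd_a) + [0] * len(ipd_b),
        })
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert log_hr == pytest.approx(cph.params_["g"], abs=1e-3)
        assert se == pytest.approx(cph.standard_errors_["g"], abs=1e-3)

    def test_no_events_errors(self):
        ipd = PseudoIPD(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(ValueError):
            cox_loghr(ipd, PseudoIPD(np.array([3.0]), np.array([0])))

    def test_monotone_likelihood_firth_fallback(self, caplog):
        import logging

        arm_a = PseudoIPD(np.array([5.0] * 30), np.zeros(30, int))
        arm_b = PseudoIPD(np.linspace(1, 4, 30), np.ones(30, int))
        with caplog.at_level(logging.WARNING, logger="nmalab"):
            log_hr, se = cox_loghr(arm_a, arm_b)
        assert np.isfinite(log_hr) and np.isfinite(se)
        assert any("Firth" in r.message or "monotone" in r.message
                   for r in caplog.records)


class TestKmFromIpd:
    def test_single_event_record(self):
        curve = km_from_ipd(PseudoIPD(np.array([5.0]), np.array([1])))
        assert curve.points[0] == (0.0, 1.0)
        assert curve.points[-1] == (5.0, 0.0)

    def test_all_censored_flat(self):
        curve = km_from_ipd(PseudoIPD(np.array([1.0, 2.0, 3.0]), np.zeros(3, int)))
        assert all(s == 1.0 for _, s in curve.points)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_from_ipd(PseudoIPD(np.array([]), np.array([], dtype=int)))
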