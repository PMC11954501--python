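import logging
import math

import numpy as np
import pytest

from nmalab import (AEArmRecord, build_network, fit_pl_cloglog,
                    relative_discrete_hazards)
from nmalab.simulate import SimulationScenario, simulate_ae_network


def two_arm(events_a, events_b, n=1000, f=12.0):
    return [AEArmRecord("t1", "B", events_a, n, f),
            AEArmRecord("t1", "A", events_b, n, f)]


class TestFitPlCloglog:
    def test_equal_proportions_give_zero(self):
        recs = two_arm(50, 50)
        net = build_network(recs, "ae", "A")
        fit = fit_pl_cloglog(net, recs, penalty="none")
        assert fit.converged
        assert fit.d_hat[0] == pytest.approx(0.0, abs=1e-8)

    def test_rate_ratio_identity_at_large_n(self):
        # constant hazards 0.1 vs 0.2 per month over 12 months: the discrete
        # hazard ratio converges to the rate ratio 2
        n, f = 10_000, 12.0
        p1 = 1.0 - math.exp(-f * 0.1)
        p2 = 1.0 - math.exp(-f * 0.2)
        recs = [AEArmRecord("t1", "B", round(n * p2), n, f),
                AEArmRecord("t1", "A", round(n * p1), n, f)]
        net = build_network(recs, "ae", "A")
        fit = fit_pl_cloglog(net, recs, penalty="none")
        assert math.exp(fit.d_hat[0]) == pytest.approx(2.0, abs=0.05)

    def test_zero_cell_firth_finite_mle_divergent(self):
        recs = [AEArmRecord("t1", "B", 0, 300, 12.0),
                AEArmRecord("t1", "A", 5, 300, 12.0)]
        net = build_network(recs, "ae", "A")
        firth = fit_pl_cloglog(net, recs, penalty="firth")
        assert firth.converged
        assert abs(firth.d_hat[0]) < 10
        mle = fit_pl_cloglog(net, recs, penalty="none")
        assert not mle.converged

    def test_offset_invariance(self):
        # doubling follow-up while halving the rate keeps d_hat unchanged
        recs1 = two_arm(60, 30, n=2000, f=12.0)
        recs2 = [AEArmRecord(r.trial_id, r.treatment, r.events, r.n, 24.0)
                 for r in recs1]
        net1 = build_network(recs1, "ae", "A")
        net2 = build_network(recs2, "ae", "A")
        d1 = fit_pl_cloglog(net1, recs1, penalty="none").d_hat[0]
        d2 = fit_pl_cloglog(net2, recs2, penalty="none").d_hat[0]
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_agrees_with_glm_oracle(self):
        import statsmodels.api as sm

        from nmalab.plnma import _design

        scenario = SimulationScenario(n_treatments=4, n_trials=6, seed=5,
                                      ae_rate_range=(0.01, 0.03), outcome="ae")
        recs, _ = simulate_ae_network(scenario, rare=False)
        net = build_network(recs, "ae", "T00")
        fit = fit_pl_cloglog(net, recs, penalty="none")
        treatments, trial_ids, A, r, n, off, _ = _design(net, recs)
        glm = sm.GLM(
            np.column_stack([r, n - r]), A,
            family=sm.families.Binomial(link=sm.families.links.CLogLog()),
            offset=off).fit()
        T = len(trial_ids)
        assert np.abs(glm.params[T:] - fit.d_hat).max() < 1e-4

    def test_missing_follow_up_imputed_with_warning(self, caplog):
        recs = [AEArmRecord("t1", "B", 10, 200, 12.0),
                AEArmRecord("t1", "A", 5, 200, None),
                AEArmRecord("t2", "C", 8, 200, 24.0),
                AEArmRecord("t2", "A", 6, 200, 24.0)]
        net = build_network(recs, "ae", "A")
        with caplog.at_level(logging.WARNING, logger="nmalab"):
            fit = fit_pl_cloglog(net, recs)
        assert fit.converged
        assert any("imputed" in w for w in fit.warnings)

    def test_cloglog_link_monotone(self):
        eta = np.linspace(-6, 3, 200)
        p = 1.0 - np.exp(-np.exp(eta))
        assert np.all(np.diff(p) > 0)
        assert p.min() > 0 and p.max() < 1


class TestRelativeDiscreteHazards:
    def test_self_comparison_is_unity(self):
        recs = two_arm(40, 20)
        net = build_network(recs, "ae", "A")
        fit = fit_pl_cloglog(net, recs)
        tab = relative_discrete_hazards(fit).set_index(["treatment", "comparator"])
        assert tab.loc[("A", "A"), "dhr"] == 1.0
        assert not tab.loc[("A", "A"), "significant"]

    def test_antisymmetric_under_swap(self):
        recs = two_arm(40, 20)
        net = build_network(recs, "ae", "A")
        fit = fit_pl_cloglog(net, recs)
        tab = relative_discrete_hazards(fit).set_index(["treatment", "comparator"])
        ab, ba = tab.loc[("B", "A")], tab.loc[("A", "B")]
        assert ab["dhr"] == pytest.approx(1 / ba["dhr"], rel=1e-9)
        assert ab["lo95"] == pytest.approx(1 / ba["hi95"], rel=1e-9)

    def test_firth_less_biased_than_mle_in_rare_events(self):
        # small-scale version of the bias-reduction study (the acceptance
        # suite runs the full 200 replicates)
        scenario = SimulationScenario(
            n_treatments=4, n_trials=8, true_d=(0.0, 0.0, 0.0, 0.0),
            ae_rate_range=(0.0003, 0.0008), seed=2, outcome="ae")
        firth_err, mle_err = [], []
        for rep in range(30):
            recs, _ = simulate_ae_network(
                SimulationScenario(
                    n_treatments=4, n_trials=8, true_d=(0.0, 0.0, 0.0, 0.0),
                    ae_rate_range=(0.0003, 0.0008), seed=1000 + rep,
                    outcome="ae"))
            net = build_network(recs, "ae", "T00")
            ff = fit_pl_cloglog(net, recs, penalty="firth")
            assert np.all(np.isfinite(ff.d_hat))
            firth_err.extend(np.abs(ff.d_hat))
            mm = fit_pl_cloglog(net, recs, penalty="none")
            if mm.converged:
                mle_err.extend(np.abs(mm.d_hat))
        assert np.mean(firth_err) < np.mean(mle_err)
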