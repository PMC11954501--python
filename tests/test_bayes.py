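import math

import numpy as np
import pytest

from nmalab import (ContrastRecord, EvidenceNetwork, McmcConfig, Priors,
                    Treatment, TrialArm, build_network, diagnostics,
                    fit_binary_nma, fit_contrast_nma, fit_contrast_replicates,
                    model_fit, relative_effects)
from nmalab.simulate import SimulationScenario, simulate_contrast_network


class TestContrastFixedEffect:
    def test_single_trial_posterior_tracks_likelihood(self, quick_mcmc):
        recs = [ContrastRecord("t1", "os", "B", "A", 0.2, 0.1)]
        net = build_network(recs, "os", "A")
        post = fit_contrast_nma(net, recs, model="fixed", mcmc=quick_mcmc)
        s = post.summaries.loc["d[B]"]
        assert s["mean"] == pytest.approx(0.2, abs=0.01)
        assert s["sd"] == pytest.approx(0.1, abs=0.01)

    def test_two_trial_inverse_variance_pooling(self, two_trial_records, quick_mcmc):
        net = build_network(two_trial_records, "os", "A")
        post = fit_contrast_nma(net, two_trial_records, model="fixed", mcmc=quick_mcmc)
        s = post.summaries.loc["d[B]"]
        # inverse-variance oracle: (0.2/0.01 + 0.4/0.04)/(1/0.01 + 1/0.04)
        assert s["mean"] == pytest.approx(0.24, abs=0.01)
        assert s["sd"] == pytest.approx(math.sqrt(1 / 125), abs=0.005)

    def test_null_triangle_centres_at_zero(self, triangle, triangle_records, quick_mcmc):
        post = fit_contrast_nma(triangle, triangle_records, model="fixed",
                                mcmc=quick_mcmc)
        assert np.all(np.abs(post.summaries.loc[["d[B]", "d[C]"], "median"]) < 0.02)

    def test_bit_reproducible_given_seed(self, two_trial_records, quick_mcmc):
        net = build_network(two_trial_records, "os", "A")
        a = fit_contrast_nma(net, two_trial_records, model="fixed", mcmc=quick_mcmc)
        b = fit_contrast_nma(net, two_trial_records, model="fixed", mcmc=quick_mcmc)
        assert np.array_equal(a.samples["d"], b.samples["d"])

    def test_contrast_outside_component_errors(self, triangle, quick_mcmc):
        bad = [ContrastRecord("tx", "os", "Z", "A", 0.1, 0.1)]
        with pytest.raises(ValueError, match="connected"):
            fit_contrast_nma(triangle, bad, model="fixed", mcmc=quick_mcmc)


class TestContrastRandomEffects:
    def test_gls_agreement_on_tree_network(self, quick_mcmc):
        # tau ~ 0 forces the random-effects fit toward the fixed-effect GLS
        recs = [
            ContrastRecord("t1", "os", "B", "A", 0.3, 0.1),
            ContrastRecord("t2", "os", "C", "B", -0.2, 0.15),
        ]
        net = build_network(recs, "os", "A")
        post = fit_contrast_nma(
            net, recs, model="random", mcmc=quick_mcmc,
            priors=Priors(tau2_lognormal=(-12.0, 0.1)))
        assert post.summaries.loc["d[B]", "mean"] == pytest.approx(0.3, abs=0.02)
        assert post.summaries.loc["d[C]", "mean"] == pytest.approx(0.1, abs=0.03)

    def test_heterogeneity_prior_roundtrip_without_data(self, quick_mcmc):
        # prior-only run: tau^2 must reproduce its LogNormal(-3.95, 1.79^2) prior
        net = EvidenceNetwork(
            outcome="os",
            treatments={t: Treatment(t) for t in "AB"},
            trials={}, reference="A")
        mcmc = McmcConfig(n_burn=500, n_sample=20_000, n_chains=4, seed=5)
        post = fit_contrast_nma(net, [], model="random", mcmc=mcmc)
        log_tau2 = 2.0 * np.log(post.samples["tau"].reshape(-1))
        assert log_tau2.mean() == pytest.approx(-3.95, abs=0.05)
        assert log_tau2.std() == pytest.approx(1.79, abs=0.05)

    def test_multi_arm_trial_accepted(self, quick_mcmc):
        recs = [
            ContrastRecord("t1", "os", "B", "A", 0.2, 0.1),
            ContrastRecord("t1", "os", "C", "A", 0.1, 0.1),
            ContrastRecord("t2", "os", "C", "B", -0.1, 0.1),
        ]
        net = build_network(recs, "os", "A")
        post = fit_contrast_nma(net, recs, model="random", mcmc=quick_mcmc)
        assert set(post.summaries.index) >= {"d[B]", "d[C]", "tau"}
        assert post.fit["n_datapoints"] == 3

    def test_replicates_match_single_fits(self, quick_mcmc):
        scenario = SimulationScenario(n_treatments=4, n_trials=6, seed=3)
        sets, _ = simulate_contrast_network(scenario, replicates=2)
        net = build_network(sets[0], "os", "T00")
        results = fit_contrast_replicates(net, sets, model="random", mcmc=quick_mcmc)
        assert len(results) == 2
        single = fit_contrast_nma(net, sets[0], model="random", mcmc=quick_mcmc)
        for name in ("d[T01]", "d[T02]", "d[T03]"):
            assert results[0].summaries.loc[name, "mean"] == pytest.approx(
                single.summaries.loc[name, "mean"], abs=0.03)


class TestBinary:
    def test_symmetric_trial_null(self, quick_mcmc):
        arms = [TrialArm("t1", "A", 20, 10), TrialArm("t1", "B", 20, 10)]
        net = build_network(arms, "orr", "A")
        post = fit_binary_nma(net, arms, model="fixed", mcmc=quick_mcmc)
        assert abs(post.summaries.loc["d[B]", "median"]) < 0.15

    def test_logistic_mle_oracle(self):
        arms = [TrialArm("t1", "A", 20, 5), TrialArm("t1", "B", 20, 15)]
        net = build_network(arms, "orr", "A")
        mcmc = McmcConfig(n_burn=3000, n_sample=10_000, n_chains=4, seed=7)
        post = fit_binary_nma(net, arms, model="fixed", mcmc=mcmc)
        assert post.summaries.loc["d[B]", "median"] == pytest.approx(
            math.log(9.0), abs=0.15)

    def test_small_network_recovery(self, quick_mcmc):
        from nmalab.simulate import simulate_binary_network

        scenario = SimulationScenario(n_treatments=3, n_trials=4, seed=9,
                                      tau=0.1, arm_n_range=(200, 400))
        arms, truth = simulate_binary_network(scenario)
        net = build_network(arms, "os", "T00")
        mcmc = McmcConfig(n_burn=4000, n_sample=12_000, n_chains=4, seed=1)
        post = fit_binary_nma(net, arms, model="random", mcmc=mcmc)
        for k in (1, 2):
            lo = post.summaries.loc[f"d[T0{k}]", "lo95"]
            hi = post.summaries.loc[f"d[T0{k}]", "hi95"]
            assert lo - 0.3 < truth["true_d"][k] < hi + 0.3


class TestRelativeEffects:
    def test_identity_and_reciprocity(self, two_trial_records, quick_mcmc):
        net = build_network(two_trial_records, "os", "A")
        post = fit_contrast_nma(net, two_trial_records, model="fixed", mcmc=quick_mcmc)
        tab = relative_effects(post).set_index(["treatment", "comparator"])
        assert tab.loc[("A", "A"), "median"] == 1.0
        ab = tab.loc[("B", "A")]
        ba = tab.loc[("A", "B")]
        assert ab["median"] == pytest.approx(1 / ba["median"], rel=1e-9)
        assert ab["lo95"] == pytest.approx(1 / ba["hi95"], rel=1e-9)
        assert ab["median"] == pytest.approx(math.exp(0.24), abs=0.02)


class TestModelFit:
    def test_pd_positive_and_resdev_calibrated(self, quick_mcmc):
        # data generated from a fixed-effect model: ResDev per datapoint
        # should hover near 1 on average over replicate datasets
        sets, _ = simulate_contrast_network(
            SimulationScenario(n_treatments=4, n_trials=8, tau=0.0, seed=0),
            replicates=16)
        net = build_network(sets[0], "os", "T00")
        results = fit_contrast_replicates(net, sets, model="fixed", mcmc=quick_mcmc)
        ratios = []
        for post in results:
            resdev, pd_, dic = model_fit(post)
            assert pd_ > 0
            ratios.append(resdev / post.fit["n_datapoints"])
        assert 0.7 < np.mean(ratios) < 1.3

    def test_dic_prefers_fixed_on_homogeneous_data(self, quick_mcmc):
        wins = 0
        for seed in range(5):
            recs, _ = simulate_contrast_network(SimulationScenario(
                n_treatments=4, n_trials=10, tau=0.0, seed=100 + seed))
            net = build_network(recs, "os", "T00")
            fixed = fit_contrast_nma(net, recs, model="fixed", mcmc=quick_mcmc)
            random = fit_contrast_nma(net, recs, model="random", mcmc=quick_mcmc)
            if fixed.fit["dic"] <= random.fit["dic"] + 3:
                wins += 1
        assert wins >= 4


class TestDiagnostics:
    def test_iid_chains_pass(self, rng):
        chains = rng.standard_normal((4, 2000))
        diag = diagnostics(chains)
        assert 0.99 <= diag["rhat"].iloc[0] <= 1.01
        assert diag["ess_bulk"].iloc[0] == pytest.approx(8000, rel=0.2)

    def test_offset_chains_fail(self, rng):
        chains = rng.standard_normal((2, 1000))
        chains[1] += 5.0
        diag = diagnostics(chains)
        assert diag["rhat"].iloc[0] > 1.05

    def test_single_chain_errors(self, rng):
        with pytest.raises(ValueError, match="two chains"):
            diagnostics(rng.standard_normal((1, 100)))

    def test_nonconverged_fit_flagged(self, two_trial_records):
        net = build_network(two_trial_records, "os", "A")
        mcmc = McmcConfig(n_burn=1, n_sample=30, n_chains=2, seed=0)
        post = fit_contrast_nma(net, two_trial_records, model="random", mcmc=mcmc)
        assert not post.converged
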