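import math

import numpy as np
import pytest

from mtbottleneck.config import MechanismConfig, build_schedule, default_schedule
from mtbottleneck.infer import (ABCError, abc_sample, default_priors,
                                default_weights, distance, evaluate_params,
                                mcmc_best_fit, model_select,
                                moment_match_start, params_to_model,
                                samples_to_frame, sigma_from_params,
                                summarize_matched)
from mtbottleneck.measurements import (COPY_MEAN, NORM_HET_VAR, MeasurementSet,
                                       SyntheticSpec, generate_measurements)
from mtbottleneck.simulate import EnsembleSummary


def small_data(default_truth, seed=21):
    """A reduced synthetic measurement set for fast inference tests."""
    cfg, sched = default_truth
    design = [(t, COPY_MEAN, 5) for t in (0.0, 8.5, 13.5, 30.0, 100.0)]
    design += [(t, NORM_HET_VAR, 25) for t in (13.5, 30.0, 61.0, 100.0)]
    ms, _, info = generate_measurements(SyntheticSpec(cfg, sched, design=design,
                                                      seed=seed))
    return ms, info


def fake_ensemble(h_values, t=10.0, m=100.0):
    n = len(h_values)
    h = np.asarray(h_values, dtype=float)
    m2 = m * h
    m1 = m - m2
    return EnsembleSummary(obs_times=np.array([t]),
                           m1=m1.reshape(1, -1), m2=m2.reshape(1, -1),
                           rejected=np.zeros(n, dtype=bool))


class TestSummarizeMatched:
    def test_full_sample_equals_ensemble_statistic(self):
        ens = fake_ensemble([0.4, 0.5, 0.6])
        data = MeasurementSet.from_records([
            {"source": "x", "t_dpc": 10.0, "statistic": NORM_HET_VAR,
             "value": 0.01, "n": 3}])
        sim = summarize_matched(ens, data, 0)
        # sample variance 0.01 over mean 0.5: V' = 0.01 / 0.25 = 0.04
        assert sim.df["value"].iloc[0] == pytest.approx(0.04)

    def test_copy_mean_subsampling(self):
        ens = fake_ensemble([0.0] * 6, m=100.0)
        data = MeasurementSet.from_records([
            {"source": "x", "t_dpc": 10.0, "statistic": COPY_MEAN,
             "value": 50.0, "n": 6}])
        sim = summarize_matched(ens, data, 0)
        assert sim.df["value"].iloc[0] == pytest.approx(100.0)

    def test_subsample_scatter_shrinks_with_sample_size(self, default_truth):
        cfg, sched = default_truth
        from mtbottleneck.simulate import simulate_ensemble
        ens = simulate_ensemble(cfg, sched, [100.0], 600, 3)
        rng = np.random.default_rng(0)
        spreads = []
        for n_i in (5, 20, 100):
            data = MeasurementSet.from_records([
                {"source": "x", "t_dpc": 100.0, "statistic": NORM_HET_VAR,
                 "value": 0.2, "n": n_i}])
            vals = [summarize_matched(ens, data, rng).df["value"].iloc[0]
                    for _ in range(60)]
            spreads.append(np.std(vals))
        assert spreads[0] > spreads[1] > spreads[2]


class TestDistance:
    def _sets(self):
        obs = MeasurementSet.from_records([
            {"source": "o", "t_dpc": 8.5, "statistic": COPY_MEAN,
             "value": 300.0, "n": 5},
            {"source": "o", "t_dpc": 100.0, "statistic": NORM_HET_VAR,
             "value": 0.25, "n": 40}])
        return obs

    def test_identical_sets_give_zero(self):
        obs = self._sets()
        assert distance(obs, obs) == 0.0

    def test_tenfold_copy_error_with_unit_weights(self):
        obs = self._sets()
        sim = MeasurementSet.from_records([
            {"source": "s", "t_dpc": 8.5, "statistic": COPY_MEAN,
             "value": 3000.0, "n": 5},
            {"source": "s", "t_dpc": 100.0, "statistic": NORM_HET_VAR,
             "value": 0.25, "n": 40}])
        assert distance(sim, obs, weights=(1.0, 1.0)) == pytest.approx(1.0)

    def test_symmetric_and_additive(self):
        obs = self._sets()
        sim = MeasurementSet.from_records([
            {"source": "s", "t_dpc": 8.5, "statistic": COPY_MEAN,
             "value": 600.0, "n": 5},
            {"source": "s", "t_dpc": 100.0, "statistic": NORM_HET_VAR,
             "value": 0.35, "n": 40}])
        w = (1.0, 1.0)
        assert distance(sim, obs, w) == pytest.approx(distance(obs, sim, w))
        expected = math.log10(2.0) ** 2 + 0.1 ** 2
        assert distance(sim, obs, w) == pytest.approx(expected)

    def test_mismatched_records_rejected(self):
        obs = self._sets()
        other = MeasurementSet.from_records([
            {"source": "s", "t_dpc": 9.5, "statistic": COPY_MEAN,
             "value": 300.0, "n": 5}])
        with pytest.raises(ValueError):
            distance(other, obs)

    def test_undefined_statistic_gets_finite_penalty(self):
        obs = self._sets()
        sim = summarize_matched(fake_ensemble([0.0, 0.0], t=8.5, m=0.0),
                                MeasurementSet.from_records([
                                    {"source": "o", "t_dpc": 8.5,
                                     "statistic": NORM_HET_VAR,
                                     "value": 0.25, "n": 2}]), 0)
        obs1 = MeasurementSet.from_records([
            {"source": "o", "t_dpc": 8.5, "statistic": NORM_HET_VAR,
             "value": 0.25, "n": 2}])
        d = distance(sim, obs1, weights=(1.0, 1.0))
        assert np.isfinite(d) and d == pytest.approx(4.0)  # capped at 2.0^2


class TestDerivedSummaries:
    def test_sigma_worked_example(self):
        # a turnover rate of 0.1/hr sustained for 30 days: sigma = 72
        sched = build_schedule([0, 8.5, 13.5, 20, 50, 60, 100], [7, 16])
        params = {"nu_3": 0.0, "nu_4": 2.4, "nu_5": 0.0, "nu_6": 0.0}
        assert sigma_from_params(params, sched) == pytest.approx(72.0)

    def test_params_round_trip_into_model(self, default_truth):
        cfg, sched = default_truth
        pri = default_priors("BDP")
        params = pri.sample(np.random.default_rng(0))
        cfg2, sched2 = params_to_model(params, cfg, sched)
        assert sched2.phases[0].lambda_w == pytest.approx(params["lambda_1"])
        assert sched2.phases[5].lambda_w == 0.0
        assert cfg2.m0 == int(round(params["m0"]))


class TestPriors:
    def test_samples_in_support(self):
        pri = default_priors("WAI_B")
        rng = np.random.default_rng(1)
        for _ in range(100):
            assert pri.in_support(pri.sample(rng))

    def test_moment_matched_start_in_support(self, default_truth):
        ms, _ = small_data(default_truth)
        pri = default_priors("BDP")
        rng = np.random.default_rng(2)
        for _ in range(20):
            assert pri.in_support(moment_match_start(ms, default_truth[1],
                                                     pri, rng))

    def test_proposal_returns_correction(self):
        pri = default_priors("BDP")
        rng = np.random.default_rng(3)
        params = pri.sample(rng)
        prop, corr = pri.propose(params, rng, 0.2)
        assert set(prop) == set(params)
        assert np.isfinite(corr)


class TestMetropolis:
    def test_zero_step_chain_stays_at_start(self, default_truth):
        cfg, sched = default_truth
        ms, _ = small_data(default_truth)
        pri = default_priors("BDP")
        start = moment_match_start(ms, sched, pri, np.random.default_rng(0))
        best, trace = mcmc_best_fit(cfg, sched, ms, 30, np.random.default_rng(1),
                                    pri, step=0.0, temperature=(1e-9, 1e-9),
                                    start=start, n_ensemble=60,
                                    reject_fraction=0.05)
        # zero-step proposals only re-evaluate the same parameters
        for name in pri.names():
            assert trace[name].nunique() == 1
            assert trace[name].iloc[0] == pytest.approx(start[name])

    def test_deterministic_replay(self, default_truth):
        cfg, sched = default_truth
        ms, _ = small_data(default_truth)
        outs = []
        for _ in range(2):
            best, _ = mcmc_best_fit(cfg, sched, ms, 40, np.random.default_rng(7),
                                    n_ensemble=60, n_starts=1,
                                    reject_fraction=0.05)
            outs.append(best.distance)
        assert outs[0] == outs[1]

    def test_best_fit_beats_noisy_truth_resimulation(self, default_truth):
        cfg, sched = default_truth
        ms, _ = small_data(default_truth)
        rng = np.random.default_rng(11)
        truth_params = {}
        for i, ph in enumerate(sched.phases, 1):
            if i <= 5:
                truth_params[f"lambda_{i}"] = max(ph.lambda_w, 1e-3)
            truth_params[f"nu_{i}"] = max(ph.nu, 1e-3)
        truth_params["m0"] = float(cfg.m0)
        d_truth = evaluate_params(truth_params, cfg, sched, ms, rng, 150,
                                  reject_fraction=0.02)[0]
        best, _ = mcmc_best_fit(cfg, sched, ms, 250, np.random.default_rng(12),
                                n_ensemble=150, n_starts=2,
                                reject_fraction=0.02)
        assert best.distance <= d_truth


class TestABC:
    def test_infinite_threshold_recovers_prior(self, default_truth):
        # in the epsilon -> infinity limit every proposal is accepted and the
        # ABC-MCMC chain must sample the prior (checked on a reduced
        # parameter space so n=500 thinned states are effectively iid)
        from scipy.stats import ks_2samp

        from mtbottleneck.infer import Priors

        cfg, sched = default_truth
        ms = MeasurementSet.from_records([
            {"source": "x", "t_dpc": 8.5, "statistic": COPY_MEAN,
             "value": 300.0, "n": 3},
            {"source": "x", "t_dpc": 30.0, "statistic": NORM_HET_VAR,
             "value": 0.2, "n": 5}])
        pri = Priors({"nu_3": (1e-3, 10.0, "log"),
                      "nu_4": (1e-3, 10.0, "log"),
                      "m0": (1e4, 5e5, "linear")})
        rng = np.random.default_rng(8)
        samples = abc_sample(cfg, sched, ms, 1e18, 500, rng, pri,
                             n_ensemble=5, burn_in=25, thin=60, step=0.8,
                             reject_fraction=1.0)
        post = samples_to_frame(samples)
        for name in pri.names():
            prior_draws = np.array([pri.sample(rng)[name] for _ in range(5000)])
            stat = ks_2samp(np.log(post[name]), np.log(prior_draws)).statistic
            assert stat < 0.05

    def test_posterior_respects_threshold_and_cap(self, default_truth):
        cfg, sched = default_truth
        ms, _ = small_data(default_truth)
        eps = 500.0
        samples = abc_sample(cfg, sched, ms, eps, 50, np.random.default_rng(6),
                             n_ensemble=100, pilot_budget=4000,
                             reject_fraction=0.02,
                             start=moment_match_start(
                                 ms, sched, default_priors("BDP"),
                                 np.random.default_rng(0)))
        assert all(s.distance <= eps for s in samples)
        assert all(np.isfinite(s.distance) for s in samples)

    def test_unreachable_threshold_aborts_with_diagnostics(self, default_truth):
        cfg, sched = default_truth
        ms, _ = small_data(default_truth)
        with pytest.raises(ABCError, match="epsilon"):
            abc_sample(cfg, sched, ms, 1e-6, 10, np.random.default_rng(7),
                       pilot_budget=30, n_ensemble=30)


class TestModelSelect:
    def test_single_model_gets_unit_posterior(self, default_truth):
        cfg, sched = default_truth
        ms, _ = small_data(default_truth)
        table = model_select({"BDP": MechanismConfig.bdp()}, ms,
                             [1e9, 1e6], np.random.default_rng(8),
                             base_sched=sched, n_draws=40, n_ensemble=30,
                             reject_fraction=0.05)
        assert (table["BDP"] == 1.0).all()

    def test_order_exchangeable(self, default_truth):
        cfg, sched = default_truth
        ms, _ = small_data(default_truth)
        kw = dict(base_sched=sched, n_draws=400, n_ensemble=50,
                  reject_fraction=0.05)
        a = model_select({"BDP": MechanismConfig.bdp(),
                          "CAO": MechanismConfig.cao()}, ms, [1e9],
                         np.random.default_rng(9), **kw)
        b = model_select({"CAO": MechanismConfig.cao(),
                          "BDP": MechanismConfig.bdp()}, ms, [1e9],
                         np.random.default_rng(10), **kw)
        assert abs(a["BDP"].iloc[0] - b["BDP"].iloc[0]) < 0.15
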