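import math

import numpy as np
import pytest

from mtbottleneck.config import MechanismConfig, Phase, build_schedule, default_schedule
from mtbottleneck.moments import (MomentState, UnsupportedMechanismError,
                                  copy_mean, copy_mean_closed_form,
                                  copy_variance, division_moments,
                                  exact_het_distribution, fit_truncated_normal,
                                  fixation_probs, het_distribution,
                                  het_moments, het_transform,
                                  mean_copy_profile, moment_trajectory,
                                  normalised_het_variance, pgd_posterior,
                                  phase_moments, selection_mean,
                                  threshold_crossing)
from mtbottleneck.simulate import sample_bd_interval

from conftest import variance_se


def quiescent(lam, nu):
    return Phase(index=3, kind="quiescent", lambda_w=lam, nu=nu,
                 start_dpc=0.0, end_dpc=100.0)


class TestPhaseMoments:
    def test_zero_rates_identity(self):
        ms = phase_moments(MomentState(100.0, 7.0), quiescent(0, 0), 5.0)
        assert (ms.mu, ms.var) == (100.0, 7.0)

    def test_critical_balance_variance_grows_linearly(self):
        r, d = 0.4, 3.0
        ms = phase_moments(MomentState(100.0, 0.0), quiescent(r, r), d)
        assert ms.mu == pytest.approx(100.0)
        assert ms.var == pytest.approx(2 * r * 100.0 * d)

    def test_general_case_matches_birth_death_sampling(self):
        lam, nu, d, m0, n = 0.9, 0.4, 2.5, 200, 100_000
        out = sample_bd_interval(np.full(n, m0, dtype=np.int64), lam, nu, d,
                                 np.random.default_rng(0))
        ms = phase_moments(MomentState(float(m0), 0.0), quiescent(lam, nu), d)
        assert abs(out.mean() - ms.mu) < 3 * out.std(ddof=1) / math.sqrt(n)
        assert abs(out.var(ddof=1) - ms.var) < 3 * variance_se(out)

    def test_deterministic_dynamics_add_no_noise(self):
        cfg = MechanismConfig.wai_b()
        ms = phase_moments(MomentState(100.0, 16.0), quiescent(0.5, 0.2), 1.0,
                           cfg=cfg)
        growth = math.exp(0.3)
        assert ms.var == pytest.approx(16.0 * growth * growth)


class TestDivisionMoments:
    @pytest.mark.parametrize("c, mu, var, exp_mu, exp_var", [
        (1, 100.0, 0.0, 50.0, 25.0),
        (5, 100.0, 0.0, 50.0, 125.0),
        (0, 100.0, 40.0, 50.0, 10.0),
    ])
    def test_partitioning_moment_maps(self, c, mu, var, exp_mu, exp_var):
        cfg = MechanismConfig(mechanism="CAO" if c > 1 else "BDP", S=1,
                              c=c, alpha=1.0)
        out = division_moments(MomentState(mu, var), cfg)
        assert out.mu == pytest.approx(exp_mu)
        assert out.var == pytest.approx(exp_var)

    def test_heteroplasmic_clusters_unsupported(self):
        cfg = MechanismConfig.cao(c=5, cluster_content="heteroplasmic_mixing")
        with pytest.raises(UnsupportedMechanismError):
            division_moments(MomentState(10.0, 0.0), cfg)


class TestCopyNumberMoments:
    def test_balanced_rates_mean_halves_per_division(self, default_truth):
        _, sched = default_truth
        sched = sched.with_rates([0.5] * 5 + [0.0], [0.5] * 5 + [0.0])
        cfg = MechanismConfig.bdp(m0=2 ** 20, h0=0.0)
        assert copy_mean(cfg, sched, 13.5) == pytest.approx(2 ** 20 / 2 ** 36)

    def test_quiescent_exponential_mean(self):
        sched = build_schedule([0, 1, 2, 3, 4, 50, 100], [24, 24],
                               lambdas=(0, 0, 0, 0, 0.1, 0),
                               nus=(0, 0, 0, 0, 0.02, 0))
        cfg = MechanismConfig.bdp(m0=1000, h0=0.0)
        # two divisions in the inert cycling phases, then quiescent growth
        expect = 1000 / 2 ** 2 * math.exp(0.08 * (47 - 4))
        assert copy_mean(cfg, sched, 47.0) == pytest.approx(expect)

    def test_product_formula_equals_iterated_propagation(self, default_truth):
        cfg, sched = default_truth
        for t in (3.0, 8.5, 13.5, 21.0, 47.3, 100.0):
            assert copy_mean_closed_form(cfg, sched, t) == \
                pytest.approx(copy_mean(cfg, sched, t), rel=1e-12)

    def test_mean_profile_matches_pointwise_mean(self, default_truth):
        cfg, sched = default_truth
        times = [0.0, 4.2, 8.5, 30.0, 100.0]
        prof = mean_copy_profile(cfg, sched, times)
        for t, v in zip(times, prof):
            assert v == pytest.approx(copy_mean(cfg, sched, t), rel=1e-12)

    def test_no_dynamics_deterministic_partition_zero_variance(self):
        sched = default_schedule().with_rates([0.0] * 6, [0.0] * 6)
        cfg = MechanismConfig(mechanism="BDP", S=1, c=0, m0=4096, h0=0.0)
        assert copy_variance(cfg, sched, 100.0) == pytest.approx(0.0)

    def test_binomial_thinning_variance_matches_exact_recursion(self):
        # no birth-death dynamics: the copy-number law after k divisions is
        # the k-fold binomial thinning, enumerated exactly by pmf convolution
        sched = default_schedule().with_rates([0.0] * 6, [0.0] * 6)
        m0 = 64
        cfg = MechanismConfig.bdp(m0=m0, h0=0.0)
        from scipy.stats import binom
        pmf = np.zeros(m0 + 1)
        pmf[m0] = 1.0
        k = sum(1 for e in sched.division_epochs() if e <= 2.0)
        for _ in range(k):
            new = np.zeros(m0 + 1)
            for n, p in enumerate(pmf):
                if p > 0:
                    new[: n + 1] += p * binom.pmf(np.arange(n + 1), n, 0.5)
            pmf = new
        support = np.arange(m0 + 1)
        exact_var = float((pmf * support ** 2).sum() - (pmf * support).sum() ** 2)
        assert copy_variance(cfg, sched, 2.0) == pytest.approx(exact_var, rel=1e-9)


class TestHeteroplasmyMoments:
    def test_symmetric_zero_variance(self):
        eh, vh = het_moments(MomentState(500.0, 0.0), MomentState(500.0, 0.0))
        assert (eh, vh) == (0.5, 0.0)

    def test_worked_ratio_expansion_example(self):
        eh, vh = het_moments(MomentState(500.0, 2500.0), MomentState(500.0, 2500.0))
        assert eh == pytest.approx(0.5)
        assert vh == pytest.approx(0.00125)
        assert normalised_het_variance(eh, vh) == pytest.approx(0.005)

    def test_ratio_expansion_against_direct_sampling(self):
        # independent species fluctuations; V(h) from 10^6 sampled ratios
        rng = np.random.default_rng(1)
        m1 = rng.normal(500.0, 50.0, 1_000_000)
        m2 = rng.normal(500.0, 50.0, 1_000_000)
        h = m2 / (m1 + m2)
        eh, vh = het_moments(MomentState(500.0, 2500.0), MomentState(500.0, 2500.0))
        # second-order expansion: accurate to ~(CV)^2 relative at CV = 0.1
        assert h.var() == pytest.approx(vh, rel=0.02)

    def test_degenerate_mutant_moments(self):
        assert het_moments(MomentState(10.0, 1.0), MomentState(0.0, 0.0)) == (0.0, 0.0)
        with pytest.raises(ValueError):
            het_moments(MomentState(10.0, 1.0), MomentState(0.0, 5.0))

    def test_normalised_variance_symmetric_under_relabelling(self, default_truth):
        cfg, sched = default_truth
        from mtbottleneck.moments import species_moments
        mw = species_moments(cfg, sched, 100.0, "wildtype")
        mm = species_moments(cfg, sched, 100.0, "mutant")
        e1, v1 = het_moments(mw, mm)
        e2, v2 = het_moments(mm, mw)  # swap mutant/wildtype labels
        assert normalised_het_variance(e1, v1) == \
            pytest.approx(normalised_het_variance(e2, v2), rel=1e-9)


class TestSelection:
    def test_neutral_and_absorbing_cases(self):
        assert selection_mean(0.3, 0.0, 50.0) == pytest.approx(0.3)
        assert selection_mean(0.0, 1.0, 50.0) == 0.0
        assert selection_mean(1.0, -1.0, 50.0) == 1.0

    def test_sigmoid_value(self):
        assert selection_mean(0.5, math.log(9), 1.0) == pytest.approx(0.9)

    def test_monotone_approach_to_fixation(self):
        vals = [selection_mean(0.2, 0.5, t) for t in (0, 5, 20, 100)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.999

    def test_consistent_with_moment_means(self):
        # mean heteroplasmy from the species means under a replication-rate
        # differential equals the sigmoid formula (quiescent single phase)
        sched = build_schedule([0, 1, 2, 3, 4, 54, 60], [24, 24],
                               lambdas=(0, 0, 0, 0, 1.0, 0),
                               nus=(0, 0, 0, 0, 0.4, 0))
        dlam = 0.07
        cfg = MechanismConfig(mechanism="BDP", m0=10_000, h0=0.3,
                              delta_lambda=dlam)
        from mtbottleneck.moments import species_moments
        t = 34.0  # 30 days inside the selective phase
        mw = species_moments(cfg, sched, t, "wildtype")
        mm = species_moments(cfg, sched, t, "mutant")
        eh = mm.mu / (mw.mu + mm.mu)
        assert eh == pytest.approx(selection_mean(0.3, dlam, 30.0), rel=1e-6)


class TestFixation:
    def test_inert_system_never_fixes(self):
        sched = build_schedule([0, 1, 2, 3, 4, 5, 10], [48, 48])
        cfg = MechanismConfig.bdp(m0=10, h0=0.5)
        z1, z2, p00 = fixation_probs(cfg, sched, 0.9)
        assert (z1, z2, p00) == (0.0, 0.0, 0.0)

    def test_pure_death_single_mutant_closed_form(self):
        nu, t = 0.3, 6.0
        sched = build_schedule([0, 1, 2, 3, 4, 5, 10], [48, 48],
                               nus=(0, 0, nu, nu, nu, nu))
        sched = sched.with_rates([0.0] * 6, [0.0, 0.0, nu, nu, nu, nu])
        cfg = MechanismConfig.bdp(m0=4000, h0=1 / 4000.0)
        assert cfg.m2_0 == 1
        z1, _, _ = fixation_probs(cfg, sched, 2.0 + t)
        p_expected = 1.0 - math.exp(-nu * t)  # quiescence starts at 2 dpc
        # wildtype extinction is essentially impossible with 3999 founders
        assert z1 == pytest.approx(p_expected, rel=1e-3)

    def test_non_bdp_mechanism_rejected(self, mini_system):
        _, sched, t = mini_system
        with pytest.raises(UnsupportedMechanismError):
            fixation_probs(MechanismConfig.cao(c=5, m0=40), sched, t)

    def test_enumeration_agrees_with_generating_function(self, mini_system):
        cfg, sched, t = mini_system
        z1, z2, p00 = fixation_probs(cfg, sched, t)
        ex = exact_het_distribution(cfg, sched, t)
        assert ex.p_h0 == pytest.approx(z1, abs=1e-10)
        assert ex.p_h1 == pytest.approx(z2, abs=1e-10)
        assert ex.p_extinct == pytest.approx(p00, abs=1e-10)


class TestHetDistribution:
    def test_truncated_normal_fit_narrow_symmetric(self):
        mu, s2, ok = fit_truncated_normal(0.5, 0.001)
        assert ok
        assert mu == pytest.approx(0.5, abs=1e-8)
        assert s2 == pytest.approx(0.001, rel=1e-4)

    def test_truncated_normal_fit_infeasible_flagged(self):
        # no [0,1]-truncated Normal attains variance 0.2 at mean 0.5
        _, _, ok = fit_truncated_normal(0.5, 0.2)
        assert not ok

    def test_mixture_moments_self_consistent(self, mini_system):
        cfg, sched, t = mini_system
        hd = het_distribution(cfg, sched, t)
        from scipy.stats import truncnorm
        sigma = math.sqrt(hd.sigma2)
        a, b = -hd.mu / sigma, (1 - hd.mu) / sigma
        m_tn = truncnorm.mean(a, b, loc=hd.mu, scale=sigma)
        recon = hd.continuous_mass * m_tn + hd.zeta2
        assert recon == pytest.approx(hd.mean, abs=1e-8)

    def test_mixture_mass_is_unity(self, mini_system):
        cfg, sched, t = mini_system
        hd = het_distribution(cfg, sched, t)
        edges = np.linspace(0.0, 1.0, 201)
        total = hd.zeta1 + hd.zeta2 + hd.binned(edges).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_exact_enumeration(self, mini_system):
        cfg, sched, t = mini_system
        hd = het_distribution(cfg, sched, t)
        ex = exact_het_distribution(cfg, sched, t)
        alive = 1.0 - ex.p_extinct
        edges = np.linspace(0.0, 1.0, 21)
        tv = 0.5 * (abs(ex.p_h0 / alive - hd.zeta1)
                    + abs(ex.p_h1 / alive - hd.zeta2)
                    + np.abs(ex.binned(edges) / alive - hd.binned(edges)).sum())
        assert tv < 0.05


class TestThresholdCrossing:
    def test_symmetric_threshold_at_mean(self):
        from mtbottleneck.moments import HetDistribution
        hd = HetDistribution(mean=0.4, var=0.01, zeta1=0.0, zeta2=0.0,
                             mu=0.4, sigma2=0.01)
        assert threshold_crossing(hd, 0.4) == pytest.approx(0.5)

    def test_certain_fixation_dominates(self):
        from mtbottleneck.moments import HetDistribution
        hd = HetDistribution(mean=1.0, var=0.0, zeta1=0.0, zeta2=1.0,
                             mu=0.5, sigma2=0.0)
        assert threshold_crossing(hd, 0.7) == pytest.approx(1.0)

    def test_tail_vanishes_near_one(self):
        from mtbottleneck.moments import HetDistribution
        hd = HetDistribution(mean=0.3, var=0.005, zeta1=0.0, zeta2=0.0,
                             mu=0.3, sigma2=0.005)
        assert threshold_crossing(hd, 0.999) < 1e-10

    def test_zero_variance_is_a_step(self):
        from mtbottleneck.moments import HetDistribution
        hd = HetDistribution(mean=0.3, var=0.0, zeta1=0.0, zeta2=0.0,
                             mu=0.3, sigma2=0.0)
        assert threshold_crossing(hd, 0.2) == 1.0
        assert threshold_crossing(hd, 0.4) == 0.0


class TestPgdPosterior:
    def test_normalised_to_unity(self, default_truth):
        cfg, sched = default_truth
        post = pgd_posterior(0.4, 30.0, cfg, sched, grid=101)
        assert np.trapezoid(post.density, post.h0_grid) == pytest.approx(1.0, abs=1e-6)

    def test_later_sampling_gives_wider_posterior(self, default_truth):
        cfg, sched = default_truth
        early = pgd_posterior(0.4, 10.0, cfg, sched, grid=101)
        late = pgd_posterior(0.4, 60.0, cfg, sched, grid=101)
        assert early.spread() < late.spread()

    def test_low_variance_limit_concentrates_at_measurement(self, default_truth):
        cfg, _ = default_truth
        # sampling almost immediately: essentially no variance accrued
        sched = default_schedule()
        post = pgd_posterior(0.35, 0.05, cfg, sched, grid=201)
        assert abs(post.mode() - 0.35) < 0.01
        assert post.spread() < 0.05

    def test_degenerate_grid_rejected(self, default_truth):
        cfg, sched = default_truth
        with pytest.raises(ValueError):
            pgd_posterior(0.4, 30.0, cfg, sched, grid=2)


class TestHetTransform:
    def test_zero_at_the_mean(self):
        assert het_transform(0.3, 0.3) == pytest.approx(0.0, abs=1e-12)
        assert het_transform(0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_increasing(self):
        h = np.linspace(0.01, 0.99, 200)
        y = het_transform(h, 0.37)
        assert np.all(np.diff(y) > 0)

    def test_endpoints_flagged_infinite(self):
        assert het_transform(0.0, 0.5) == -np.inf
        assert het_transform(1.0, 0.5) == np.inf


class TestAnalyticVsSimulationQuick:
    def test_default_truth_moments(self, default_truth):
        cfg, sched = default_truth
        from mtbottleneck.simulate import simulate_ensemble
        times = [8.5, 30.0, 100.0]
        ens = simulate_ensemble(cfg, sched, times, 3000, 12)
        an = moment_trajectory(cfg, sched, times)
        m = ens.m[:, ens.valid]
        se = m.std(axis=1, ddof=1) / math.sqrt(ens.n_valid)
        assert np.all(np.abs(ens.mean_m() - an.E_m.to_numpy()) < 3.5 * se)
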