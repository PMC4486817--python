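"""Inference: matched summary statistics, distance, MCMC and ABC.

Fitting compares simulated and observed developmental statistics through a
weighted sum-of-squares distance over mean copy number (in log10 space) and
normalised heteroplasmy variance.  Because each published statistic derives
from a small number of sampled oocytes, simulated statistics are computed
from random subsets of the trajectory ensemble of exactly the same size
(sample-size matching), which propagates the sampling noise of small-n
variance estimates into the fit instead of pretending the data measure the
population value.

Approximate Bayesian computation (ABC) is used both for parametric inference
(an MCMC flavour: log-space Gaussian proposals accepted when the simulated
distance falls below the threshold) and for model selection across the
birth-death-partition (BDP), clustered-partitioning (CAO) and
subset-replication (WAI_B) mechanisms (a rejection flavour with a uniform
model indicator).  Distance thresholds are configured by the user or derived
as quantiles of the prior-predictive distance distribution; posterior samples
carry two derived summaries, the minimum mean copy number reached during
development and the total quiescent turnover  sigma = sum_i nu_i tau'_i.
Parameterisations whose trajectories breach the copy-number cap receive an
infinite distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MechanismConfig, PhaseSchedule, default_schedule
from .measurements import COPY_MEAN, NORM_HET_VAR, MeasurementSet
from .moments import mean_copy_profile
from .simulate import EnsembleSummary, simulate_ensemble

__all__ = [
    "PosteriorSample",
    "Priors",
    "default_priors",
    "params_to_model",
    "sigma_from_params",
    "summarize_matched",
    "default_weights",
    "distance",
    "evaluate_params",
    "epsilon_from_prior",
    "mcmc_best_fit",
    "abc_sample",
    "model_select",
    "ABCError",
]

RATE_NAMES = tuple(f"lambda_{i}" for i in range(1, 6)) + tuple(f"nu_{i}" for i in range(1, 7))


class ABCError(RuntimeError):
    """Inference failure with diagnostics (no acceptances, stuck chain...)."""


@dataclass
class PosteriorSample:
    """One accepted parameterisation with its derived summaries."""

    params: dict
    distance: float
    min_Em: float
    sigma: float


def samples_to_frame(samples: Sequence[PosteriorSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = dict(s.params)
        row.update(distance=s.distance, min_Em=s.min_Em, sigma=s.sigma)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Priors and parameter-vector plumbing


@dataclass
class Priors:
    """Independent uniform priors, each on a linear or log scale.

    ``entries`` maps parameter name to ``(low, high, scale)`` with scale
    ``"log"`` (uniform in log) or ``"linear"``.  MCMC proposals are Gaussian
    in the scale coordinate, where the prior is flat, so the Metropolis
    ratio reduces to the support indicator.
    """

    entries: dict

    def names(self) -> list[str]:
        return list(self.entries)

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name, (lo, hi, scale) in self.entries.items():
            if scale == "log":
                out[name] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            else:
                out[name] = rng.uniform(lo, hi)
        return out

    def in_support(self, params: dict) -> bool:
        return all(self.entries[k][0] <= params[k] <= self.entries[k][1]
                   for k in self.entries)

    def propose(self, params: dict, rng: np.random.Generator,
                step: float) -> tuple[dict, float]:
        """Mixture proposal kernel tailored to the fitting landscape.

        Three symmetric-in-their-own-coordinate components: a small move of
        every coordinate; a large move of one random coordinate; and a
        "turnover" move adding the same increment to one phase's lambda and
        nu (sliding along the weakly identified constant-net-growth ridge).
        Returns the proposal plus the log Metropolis-Hastings correction
        (nonzero for additive moves of log-uniform-prior coordinates, whose
        prior density is not flat in the move's coordinate).
        """
        out = dict(params)
        names = list(self.entries)
        log_corr = 0.0
        u = rng.uniform()
        if u < 0.3:
            targets, mult = names, 1.0
        elif u < 0.7:
            targets, mult = [names[rng.integers(len(names))]], 5.0
        else:
            # joint additive move of (lambda_i, nu_i); phase 6 has no free
            # replication rate, so only nu_6 shifts there.  The increment
            # scale is itself drawn from a coarse grid so the chain can both
            # polish and traverse the ridge.
            i = int(rng.integers(1, 7))
            delta = rng.normal(0.0, (0.05, 0.3, 1.5, 5.0)[rng.integers(4)]
                               * step / 0.2)
            for name in ([f"lambda_{i}"] if i <= 5 else []) + [f"nu_{i}"]:
                if name in self.entries:
                    old = out[name]
                    out[name] = old + delta
                    if self.entries[name][2] == "log" and out[name] > 0:
                        log_corr += math.log(old) - math.log(out[name])
            return out, log_corr
        for name in targets:
            lo, hi, scale = self.entries[name]
            x = params[name]
            if scale == "log":
                out[name] = x * math.exp(rng.normal(0.0, mult * step))
            else:
                out[name] = x + rng.normal(0.0, 0.35 * mult * step * (hi - lo))
        return out, 0.0


def default_priors(mechanism: str = "BDP") -> Priors:
    """Uniform priors: per-phase rates on [1e-4, 10]/day, m0 on
    [1e4, 5e5], plus the mechanism-specific parameters (the replicating
    fraction alpha is log-scaled, being a scale-free proportion)."""
    entries: dict = {name: (1e-4, 10.0, "linear") for name in RATE_NAMES}
    entries["m0"] = (1e4, 5e5, "linear")
    if mechanism == "CAO":
        entries["c"] = (2.0, 200.0, "linear")
    elif mechanism == "WAI_B":
        entries["alpha"] = (1e-4, 0.9, "log")
        entries["T_cutoff"] = (8.5, 80.0, "linear")
    return Priors(entries)


def params_to_model(
    params: dict,
    base_cfg: MechanismConfig,
    base_sched: PhaseSchedule,
) -> tuple[MechanismConfig, PhaseSchedule]:
    """Instantiate a configuration/schedule pair from a parameter vector.

    Phase 6 replication stays pinned at zero; h0 is carried over from the
    template configuration (it is fixed to the data's mean heteroplasmy
    rather than inferred).
    """
    lambdas = [params.get(f"lambda_{i}", base_sched.phases[i - 1].lambda_w)
               for i in range(1, 6)] + [0.0]
    nus = [params.get(f"nu_{i}", base_sched.phases[i - 1].nu) for i in range(1, 7)]
    sched = base_sched.with_rates(lambdas, nus)
    kw: dict = {}
    if "m0" in params:
        kw["m0"] = int(round(params["m0"]))
    if "c" in params:
        kw["c"] = max(2, int(round(params["c"])))
    if "alpha" in params:
        kw["alpha"] = float(params["alpha"])
    if "T_cutoff" in params:
        kw["T_cutoff"] = float(params["T_cutoff"])
    cfg = MechanismConfig(**{**base_cfg.to_dict(), **kw})
    return cfg, sched


def sigma_from_params(params: dict, base_sched: PhaseSchedule) -> float:
    """Total quiescent turnover sigma = sum over phases 3-6 of nu_i tau'_i."""
    total = 0.0
    for i in range(3, 7):
        ph = base_sched.phases[i - 1]
        total += params.get(f"nu_{i}", ph.nu) * ph.duration
    return total


# ---------------------------------------------------------------------------
# Matched summary statistics and the distance


def summarize_matched(
    ensemble: EnsembleSummary,
    data: MeasurementSet,
    rng: np.random.Generator | int,
) -> MeasurementSet:
    """Compute the data's statistics from sample-size-matched subensembles.

    For each observed record with sample size ``n_i``, ``n_i`` trajectories
    are drawn without replacement (capped at the ensemble size with a
    warning) and the matching statistic is computed from that subset: the
    subsample mean copy number, or the subsample heteroplasmy variance
    normalised by the subsample mean.  A record whose subsample is entirely
    extinct gets a NaN value, which the distance treats as a maximal
    penalty.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    valid_idx = np.flatnonzero(ensemble.valid)
    if valid_idx.size == 0:
        raise ABCError("no valid (non-rejected) trajectories in the ensemble")
    max_n = int(data.df["n"].max()) if len(data) else 0
    if max_n > valid_idx.size:
        warnings.warn(
            f"sample size {max_n} exceeds ensemble size {valid_idx.size}; capping",
            stacklevel=2,
        )
    times = ensemble.obs_times
    obs_t = data.df["t_dpc"].to_numpy(dtype=float)
    obs_stat = data.df["statistic"].to_numpy()
    obs_n = data.df["n"].to_numpy(dtype=int)
    em = ensemble.m
    eh = ensemble.h
    values = np.empty(len(data))
    for i in range(len(data)):
        ti = np.flatnonzero(np.abs(times - obs_t[i]) < 1e-8)
        if ti.size == 0:
            raise ABCError(f"ensemble was not observed at t={obs_t[i]}")
        ti = int(ti[0])
        n_i = min(int(obs_n[i]), valid_idx.size)
        pick = rng.choice(valid_idx, size=n_i, replace=False) if n_i < valid_idx.size \
            else valid_idx
        if obs_stat[i] == COPY_MEAN:
            values[i] = em[ti, pick].mean()
        else:
            h = eh[ti, pick]
            h = h[~np.isnan(h)]
            if h.size < 2:
                values[i] = np.nan
            else:
                hbar = h.mean()
                values[i] = h.var(ddof=1) / (hbar * (1.0 - hbar)) \
                    if 0.0 < hbar < 1.0 else 0.0
    df = pd.DataFrame({
        "source": "simulated", "t_dpc": obs_t, "statistic": obs_stat,
        "value": values, "n": obs_n,
    })
    out = MeasurementSet.__new__(MeasurementSet)  # skip validation: NaN = penalty flag
    out.df = df
    return out


LOG10_COPY_SD = 0.1  # assumed sampling scale of a log10 mean-copy record


def default_weights(obs: MeasurementSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-record inverse-sampling-variance weights.

    Each residual is standardised by the sampling noise of its record, so
    both statistic types contribute comparably and every record is
    individually constraining:

    * a copy-number record (log10 scale) is assigned a fixed sampling s.d.
      of ``LOG10_COPY_SD`` decades (small-n means of cells whose
      copy-number CV is a few tens of percent);
    * a normalised-variance record uses the normal-theory variance of a
      sample variance, 2 V'^2/(n-1), with V' floored at 1e-3.

    Returns ``(w_copy, w_vprime)`` arrays aligned with the record order of
    each statistic subset; a plain ``(w_m, w_v)`` scalar pair is accepted
    everywhere weights are passed.
    """
    cm = obs.subset(COPY_MEAN)
    vh = obs.subset(NORM_HET_VAR)
    w_m = np.full(len(cm), 1.0 / LOG10_COPY_SD ** 2)
    v = np.maximum(vh["value"].to_numpy(dtype=float), 1e-3)
    n = np.maximum(vh["n"].to_numpy(dtype=float) - 1.0, 1.0)
    w_v = n / (2.0 * v ** 2)
    return w_m, w_v


def distance(
    sim: MeasurementSet,
    obs: MeasurementSet,
    weights: tuple[float, float] | None = None,
) -> float:
    """Weighted sum-of-squares residual between simulated and observed sets.

    D = w_m sum (log10 E_sim - log10 E_obs)^2 + w_v sum (V'_sim - V'_obs)^2.

    Symmetric in its arguments and additive over records.  Undefined
    records (NaN values, e.g. an all-extinct subsample) contribute a fixed
    maximal penalty residual instead of the unranked infinity reserved for
    cap violations: 5 decades for a copy-number record, 2.0 for a
    normalised-variance record.  Extinct copy means are floored at 0.1
    copies before taking logs.
    """
    if len(sim) != len(obs):
        raise ValueError("record sets differ in length")
    a, b = sim.df, obs.df
    if not (np.allclose(a["t_dpc"], b["t_dpc"]) and (a["statistic"] == b["statistic"]).all()):
        raise ValueError("record sets are not aligned")
    if weights is None:
        weights = default_weights(obs)
    w_m, w_v = weights
    d = 0.0
    for stat, w, log10, penalty in ((COPY_MEAN, w_m, True, 5.0),
                                    (NORM_HET_VAR, w_v, False, 2.0)):
        va = a.loc[a["statistic"] == stat, "value"].to_numpy(dtype=float)
        vb = b.loc[b["statistic"] == stat, "value"].to_numpy(dtype=float)
        if log10:
            va = np.log10(np.maximum(va, 0.1))
            vb = np.log10(np.maximum(vb, 0.1))
        resid = np.abs(va - vb)
        resid = np.where(np.isnan(resid), penalty, np.minimum(resid, penalty))
        d += float((np.asarray(w) * resid ** 2).sum())
    return d


# ---------------------------------------------------------------------------
# Proposal evaluation


def evaluate_params(
    params: dict,
    base_cfg: MechanismConfig,
    base_sched: PhaseSchedule,
    data: MeasurementSet,
    rng: np.random.Generator,
    n_ensemble: int = 1000,
    weights: tuple[float, float] | None = None,
    reject_fraction: float = 0.0,
) -> tuple[float, float, float]:
    """Simulate a parameterisation and return (distance, min E(m), sigma).

    The copy-number cap is enforced by rejecting any parameterisation whose
    ensemble rejection fraction exceeds ``reject_fraction`` (default: any
    rejected trajectory yields an infinite distance).  min E(m) is the
    minimum of the analytic mean copy number over a dense developmental
    grid.
    """
    cfg, sched = params_to_model(params, base_cfg, base_sched)
    obs_times = sorted(set(np.round(data.times, 9)))
    sigma = sigma_from_params(params, sched)
    # analytic mean over a dense developmental grid: yields min E(m) and a
    # cheap prescreen (a mean trajectory far above the cap means essentially
    # every trajectory is rejected)
    grid = sorted(set(np.round(np.linspace(0.0, sched.t_final, 81), 9)) | set(obs_times))
    try:
        profile = mean_copy_profile(cfg, sched, grid)
    except (OverflowError, FloatingPointError):
        return float("inf"), np.nan, sigma
    min_em = float(profile.min())
    if reject_fraction < 1.0 and profile.max() > 3.0 * cfg.copy_cap:
        return float("inf"), min_em, sigma
    try:
        ens = simulate_ensemble(cfg, sched, obs_times, n_ensemble, rng)
    except (OverflowError, FloatingPointError):
        return float("inf"), np.nan, sigma
    frac_rejected = float(ens.rejected.mean())
    if frac_rejected > reject_fraction:
        return float("inf"), np.nan, sigma
    try:
        sim = summarize_matched(ens, data, rng)
    except ABCError:
        # every trajectory cap-clamped (tolerated only at reject_fraction
        # >= 1): maximal penalty on every record
        sim = MeasurementSet.__new__(MeasurementSet)
        sim.df = data.df.assign(value=np.nan)
    d = distance(sim, data, weights)
    return d, min_em, sigma


def epsilon_from_prior(
    base_cfg: MechanismConfig,
    base_sched: PhaseSchedule,
    data: MeasurementSet,
    priors: Priors,
    rng: np.random.Generator | int,
    quantile: float = 0.01,
    n_draws: int = 300,
    n_ensemble: int = 200,
    weights: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Distance threshold as a quantile of the prior-predictive distances."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if weights is None:
        weights = default_weights(data)
    ds = np.empty(n_draws)
    for i in range(n_draws):
        params = priors.sample(rng)
        ds[i], _, _ = evaluate_params(params, base_cfg, base_sched, data, rng,
                                      n_ensemble, weights)
    finite = ds[np.isfinite(ds)]
    if finite.size == 0:
        raise ABCError("no finite prior-predictive distances; check priors/cap")
    # quantile taken over all draws, infinite distances counting as largest
    q_eff = min(quantile * ds.size / finite.size, 1.0)
    return float(np.quantile(finite, q_eff)), ds


def moment_match_start(
    data: MeasurementSet,
    base_sched: PhaseSchedule,
    priors: Priors,
    rng: np.random.Generator,
    nu_range: tuple[float, float] = (0.02, 10.0),
) -> dict:
    """Data-driven chain initialisation.

    The observed copy-number records pin each phase's net growth rate
    ``r_i = (log m(end) - log m(start) + n_i log 2) / duration`` by
    log-linear interpolation; turnover magnitudes (the nu_i) are drawn from
    the prior and the lambda_i set to ``r_i + nu_i``, so every restart
    starts on (a random point of) the constant-net-growth ridge that the
    copy data select.  Everything is clamped into the prior support.
    """
    cm = data.subset(COPY_MEAN).sort_values("t_dpc")
    params = priors.sample(rng)
    # draw the turnover component of the start from ``nu_range`` (clipped to
    # the prior support): stratifying this range across restarts brackets
    # the weakly identified sigma direction, which the log-uniform prior's
    # own mass (concentrated at negligible turnover) never would
    for name in (n for n in priors.entries if n.startswith("nu_")):
        lo, hi, _ = priors.entries[name]
        lo2 = min(max(lo, nu_range[0]), hi)
        hi2 = max(min(hi, nu_range[1]), lo2)
        params[name] = math.exp(rng.uniform(math.log(lo2), math.log(hi2)))
    if len(cm) >= 2:
        ts = cm["t_dpc"].to_numpy(dtype=float)
        logm = np.log(cm["value"].to_numpy(dtype=float))
        interp = lambda t: float(np.interp(t, ts, logm))
        for i, ph in enumerate(base_sched.phases, start=1):
            r = (interp(ph.end_dpc) - interp(ph.start_dpc)
                 + ph.n_divisions * math.log(2.0)) / ph.duration
            nu_lo, nu_hi, _ = priors.entries[f"nu_{i}"]
            if i <= 5:
                lam_lo, lam_hi, _ = priors.entries[f"lambda_{i}"]
                nu = params[f"nu_{i}"]
                lam = r + nu
                if lam > lam_hi:
                    nu = max(nu_lo, nu - (lam - lam_hi))
                    lam = lam_hi
                params[f"lambda_{i}"] = float(np.clip(lam, lam_lo, lam_hi))
                params[f"nu_{i}"] = float(np.clip(nu, nu_lo, nu_hi))
            else:
                # phase 6 replication is pinned to zero: nu_6 = -r if decaying
                params["nu_6"] = float(np.clip(max(-r, nu_lo), nu_lo, nu_hi))
        if "m0" in priors.entries:
            lo, hi, _ = priors.entries["m0"]
            params["m0"] = float(np.clip(math.exp(interp(0.0)), lo, hi))
    return params


# ---------------------------------------------------------------------------
# Metropolis MCMC best-fit search


def mcmc_best_fit(
    base_cfg: MechanismConfig,
    base_sched: PhaseSchedule,
    data: MeasurementSet,
    iterations: int,
    rng: np.random.Generator | int,
    priors: Priors | None = None,
    step: float = 0.25,
    temperature: float | tuple[float, float] | None = None,
    n_ensemble: int = 200,
    start: dict | None = None,
    n_starts: int = 3,
    pilot_draws: int = 15,
    init: str = "moment-match",
    nu_start_range: tuple[float, float] = (0.02, 10.0),
    reject_fraction: float = 0.0,
    weights: tuple[float, float] | None = None,
) -> tuple[PosteriorSample, pd.DataFrame]:
    """Metropolis search for the best-fit parameterisation.

    Gaussian proposals in log-rate space target exp(-D / T).  A
    ``(T0, T1)`` temperature pair anneals geometrically from permissive to
    strict over the chain (the default: a tenth of the median
    prior-predictive distance down to 1/200 of that), which lets chains
    descend from the prior's penalty plateau into the data-consistent
    region.  ``n_starts`` independent restarts are run (each seeded at the
    best of ``pilot_draws`` fresh prior draws) and the overall
    lowest-distance visited parameterisation is returned with the trace of
    the chain that found it.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    priors = priors or default_priors(base_cfg.mechanism)
    if weights is None:
        weights = default_weights(data)

    def ev(p):
        return evaluate_params(p, base_cfg, base_sched, data, rng,
                               n_ensemble, weights, reject_fraction)

    def draw_start():
        if start is not None:
            return (dict(start),) + ev(start)
        best = None
        for _ in range(pilot_draws):
            p = moment_match_start(data, base_sched, priors, rng,
                                   nu_start_range) \
                if init == "moment-match" else priors.sample(rng)
            d, mn, sg = ev(p)
            if best is None or d < best[1]:
                best = (p, d, mn, sg)
        return best

    n_chains = 1 if start is not None else max(n_starts, 1)
    starts = [draw_start() for _ in range(n_chains)]
    if temperature is None:
        finite = [s[1] for s in starts if np.isfinite(s[1])] or [100.0]
        t0 = max(0.25 * float(np.median(finite)), 10.0)
        # finish warm enough that independent chains stay dispersed along
        # the near-flat turnover ridge instead of collapsing onto one point
        temperature = (t0, max(t0 / 50.0, 5.0))
    if np.isscalar(temperature):
        temperature = (float(temperature), float(temperature))
    t0, t1 = temperature

    overall: PosteriorSample | None = None
    best_trace: list | None = None
    total_accepted = 0
    for cur, cur_d, cur_min, cur_sig in starts:
        chain_best = PosteriorSample(dict(cur), cur_d, cur_min, cur_sig)
        trace = []
        for it in range(iterations):
            temp = t0 * (t1 / t0) ** (it / max(iterations - 1, 1))
            prop, log_corr = priors.propose(cur, rng, step)
            if priors.in_support(prop):
                d, mn, sg = ev(prop)
                log_ratio = ((cur_d - d) if np.isfinite(cur_d) or np.isfinite(d)
                             else 0.0) / max(temp, 1e-12) + log_corr
                if np.isfinite(d) and math.log(max(rng.uniform(), 1e-300)) < log_ratio:
                    cur, cur_d, cur_min, cur_sig = prop, d, mn, sg
                    total_accepted += 1
                    if d < chain_best.distance:
                        chain_best = PosteriorSample(dict(prop), d, mn, sg)
            trace.append({**cur, "distance": cur_d, "iteration": it})
        if overall is None or chain_best.distance < overall.distance:
            overall = chain_best
            best_trace = trace
    if iterations * n_chains >= 50 and total_accepted == 0:
        raise ABCError(
            "Metropolis chain accepted no moves; decrease the proposal step "
            "or raise the temperature"
        )
    return overall, pd.DataFrame(best_trace)


def noise_floor_epsilon(
    params: dict,
    base_cfg: MechanismConfig,
    base_sched: PhaseSchedule,
    data: MeasurementSet,
    rng: np.random.Generator,
    factor: float = 1.5,
    n_reval: int = 15,
    n_ensemble: int = 200,
    weights: tuple[float, float] | None = None,
    reject_fraction: float = 0.0,
) -> float:
    """ABC threshold calibrated to the stochastic noise floor of the fit.

    A parameterisation's distance fluctuates between re-simulations (finite
    ensembles, sample-size-matched subsampling), so no threshold below that
    noise floor is meaningful.  This re-evaluates ``params`` ``n_reval``
    times and returns ``factor`` times the 95th percentile of the
    distances.
    """
    ds = [evaluate_params(params, base_cfg, base_sched, data, rng,
                          n_ensemble, weights, reject_fraction)[0]
          for _ in range(n_reval)]
    ds = [d for d in ds if np.isfinite(d)]
    if not ds:
        raise ABCError("parameterisation is cap-rejected at every re-simulation")
    return factor * float(np.quantile(ds, 0.95))


# ---------------------------------------------------------------------------
# ABC-MCMC posterior sampling


def abc_sample(
    base_cfg: MechanismConfig,
    base_sched: PhaseSchedule,
    data: MeasurementSet,
    epsilon: float,
    n_accept: int,
    rng: np.random.Generator | int,
    priors: Priors | None = None,
    step: float = 0.15,
    n_ensemble: int = 200,
    pilot_budget: int = 2000,
    burn_in: int = 60,
    thin: int = 8,
    acceptance_floor: float = 0.005,
    weights: tuple[float, float] | None = None,
    start: dict | None = None,
    reject_fraction: float = 0.0,
) -> list[PosteriorSample]:
    """ABC-MCMC posterior sample of size ``n_accept`` at threshold ``epsilon``.

    The chain starts from a randomly selected prior draw satisfying
    D <= epsilon (found by rejection within ``pilot_budget`` draws) and
    proposes log-space Gaussian moves accepted when the freshly simulated
    distance stays below the threshold.  The recorded samples are the chain
    states (including repeats) thinned by ``thin`` after ``burn_in``
    iterations; each carries its distance and the derived min E(m) and
    sigma.  Aborts with diagnostics when no starting point is found or the
    move acceptance rate collapses.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    priors = priors or default_priors(base_cfg.mechanism)
    if weights is None:
        weights = default_weights(data)

    cur = None
    best_seen = float("inf")
    if start is not None:
        for _ in range(10):
            d, mn, sg = evaluate_params(start, base_cfg, base_sched, data, rng,
                                        n_ensemble, weights, reject_fraction)
            best_seen = min(best_seen, d)
            if d <= epsilon:
                cur, cur_d, cur_min, cur_sig = dict(start), d, mn, sg
                break
    else:
        for _ in range(pilot_budget):
            cand = priors.sample(rng)
            d, mn, sg = evaluate_params(cand, base_cfg, base_sched, data, rng,
                                        n_ensemble, weights, reject_fraction)
            best_seen = min(best_seen, d)
            if d <= epsilon:
                cur, cur_d, cur_min, cur_sig = cand, d, mn, sg
                break
    if cur is None:
        raise ABCError(
            f"no prior draw reached epsilon={epsilon:.4g} within "
            f"{pilot_budget} draws (best distance {best_seen:.4g}); "
            "raise epsilon or the pilot budget"
        )

    samples: list[PosteriorSample] = []
    moves = 0
    it = 0
    max_iter = burn_in + thin * n_accept + 1
    while len(samples) < n_accept and it < 50 * max_iter:
        prop, log_corr = priors.propose(cur, rng, step)
        if priors.in_support(prop) and \
                math.log(max(rng.uniform(), 1e-300)) < min(log_corr, 0.0):
            d, mn, sg = evaluate_params(prop, base_cfg, base_sched, data, rng,
                                        n_ensemble, weights, reject_fraction)
            if d <= epsilon:
                cur, cur_d, cur_min, cur_sig = prop, d, mn, sg
                moves += 1
        it += 1
        if it > burn_in and (it - burn_in) % thin == 0:
            samples.append(PosteriorSample(dict(cur), cur_d, cur_min, cur_sig))
        if it == 10 * max_iter and moves / it < acceptance_floor:
            raise ABCError(
                f"ABC-MCMC acceptance rate {moves / it:.4f} below floor "
                f"{acceptance_floor}; adjust step size or epsilon"
            )
    return samples


# ---------------------------------------------------------------------------
# ABC model selection


def model_select(
    models: dict,
    data: MeasurementSet,
    epsilons: Sequence[float],
    rng: np.random.Generator | int,
    base_sched: PhaseSchedule | None = None,
    n_draws: int = 3000,
    n_ensemble: int = 200,
    weights: tuple[float, float] | None = None,
    init: str = "moment-match",
    reject_fraction: float = 0.0,
) -> pd.DataFrame:
    """Rejection-ABC model selection with a uniform model indicator.

    ``models`` maps model name to either a template :class:`MechanismConfig`
    (default priors) or a ``(config, priors)`` pair; every model gets the
    same prior mass.  Returns a DataFrame of posterior model probabilities
    (acceptance shares) per threshold, NaN where nothing was accepted.

    With ``init="moment-match"`` (default) each draw's kinetic rates come
    from the same data-informed construction for every model — net phase
    growth pinned by the copy-number records, turnover spread broadly (see
    :func:`moment_match_start`) — so acceptance shares compare how the
    mechanisms' *variance* machinery explains the data rather than which
    wide-prior draw happens to be least absurd.  ``init="prior"`` is plain
    rejection from the priors.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    base_sched = base_sched or default_schedule()
    if weights is None:
        weights = default_weights(data)
    names = list(models)
    norm: dict = {}
    for name in names:
        spec = models[name]
        if isinstance(spec, MechanismConfig):
            norm[name] = (spec, default_priors(spec.mechanism))
        else:
            norm[name] = spec

    dist = {name: [] for name in names}
    for _ in range(n_draws):
        name = names[rng.integers(len(names))]
        cfg, priors = norm[name]
        params = moment_match_start(data, base_sched, priors, rng) \
            if init == "moment-match" else priors.sample(rng)
        d, _, _ = evaluate_params(params, cfg, base_sched, data, rng,
                                  n_ensemble, weights, reject_fraction)
        dist[name].append(d)

    rows = []
    for eps in epsilons:
        counts = {name: int(np.sum(np.asarray(dist[name]) <= eps)) for name in names}
        total = sum(counts.values())
        rows.append({
            "epsilon": eps,
            **{name: (counts[name] / total if total else np.nan) for name in names},
            "n_accepted": total,
        })
    return pd.DataFrame(rows)
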