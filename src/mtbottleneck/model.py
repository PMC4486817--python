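"""Model/Results interface for fitting bottleneck mechanisms to data.

:class:`GermlineBottleneckModel` binds a measurement table to a mechanism
template, a developmental schedule and priors; ``fit()`` runs ABC-MCMC (or a
Metropolis best-fit search) and returns a :class:`BottleneckResults` holding
the posterior sample, credible intervals, derived bottleneck summaries and
posterior-predictive machinery.  Simulation and plotting hang off these two
objects; the functional layer in :mod:`mtbottleneck.infer`,
:mod:`mtbottleneck.simulate` and :mod:`mtbottleneck.moments` remains fully
usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import infer
from .config import MechanismConfig, PhaseSchedule, default_schedule, validate_config
from .measurements import MeasurementSet, load_measurements
from .moments import moment_trajectory
from .simulate import EnsembleSummary, simulate_ensemble

__all__ = ["GermlineBottleneckModel", "BottleneckResults"]


class GermlineBottleneckModel:
    """A bottleneck mechanism to be fitted to developmental mtDNA statistics.

    Parameters
    ----------
    data
        Measurement table (a :class:`MeasurementSet` or a DataFrame with
        columns ``source, t_dpc, statistic, value, n``).
    mechanism
        Template :class:`MechanismConfig` or a mechanism name
        (``"BDP" | "CAO" | "WAI_B"``); its ``h0`` is used as the (fixed)
        initial heteroplasmy.
    schedule
        Developmental :class:`PhaseSchedule`; the default timeline if None.
        Its rates serve only as placeholders for parameters the priors leave
        free.
    priors
        :class:`infer.Priors`; mechanism defaults if None.
    n_ensemble
        Trajectories per simulated proposal (sample-size matching draws
        subsets of this ensemble).
    """

    def __init__(
        self,
        data,
        mechanism: MechanismConfig | str = "BDP",
        schedule: PhaseSchedule | None = None,
        priors: "infer.Priors | None" = None,
        n_ensemble: int = 1000,
        weights: tuple[float, float] | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            data = MeasurementSet(data)
        if not isinstance(data, MeasurementSet):
            raise TypeError("data must be a MeasurementSet or DataFrame")
        if isinstance(mechanism, str):
            mechanism = {"BDP": MechanismConfig.bdp, "CAO": MechanismConfig.cao,
                         "WAI_B": MechanismConfig.wai_b}[mechanism]()
        self.data = data
        self.template = mechanism
        self.schedule = schedule or default_schedule()
        problems = validate_config(mechanism, self.schedule)
        if problems:
            raise ValueError("; ".join(problems))
        self.priors = priors or infer.default_priors(mechanism.mechanism)
        self.n_ensemble = n_ensemble
        self.weights = weights if weights is not None else infer.default_weights(data)

    @classmethod
    def from_csv(cls, path, **kw) -> "GermlineBottleneckModel":
        return cls(load_measurements(path), **kw)

    # -- forward machinery ------------------------------------------------

    def simulate(self, params: dict | None, obs_times: Sequence[float],
                 n_traj: int, seed) -> EnsembleSummary:
        """Ensemble simulation at a parameter vector (template if None)."""
        cfg, sched = self._instantiate(params)
        return simulate_ensemble(cfg, sched, obs_times, n_traj, np.random.default_rng(seed))

    def predict(self, params: dict | None, times: Sequence[float]) -> pd.DataFrame:
        """Analytic E(m), V(m), E(h), V(h), V'(h) trajectory at a parameter
        vector (supported mechanisms only)."""
        cfg, sched = self._instantiate(params)
        return moment_trajectory(cfg, sched, times)

    def distance_of(self, params: dict, seed) -> float:
        d, _, _ = infer.evaluate_params(
            params, self.template, self.schedule, self.data,
            np.random.default_rng(seed), self.n_ensemble, self.weights)
        return d

    def _instantiate(self, params: dict | None):
        if params is None:
            return self.template, self.schedule
        return infer.params_to_model(params, self.template, self.schedule)

    # -- fitting -----------------------------------------------------------

    def epsilon_quantile(self, quantile: float, seed, n_draws: int = 300,
                         n_ensemble: int | None = None) -> float:
        """Distance threshold as a prior-predictive quantile."""
        eps, _ = infer.epsilon_from_prior(
            self.template, self.schedule, self.data, self.priors,
            np.random.default_rng(seed), quantile, n_draws,
            n_ensemble or min(self.n_ensemble, 200), self.weights)
        return eps

    def fit(
        self,
        epsilon: float | None = None,
        n_accept: int = 200,
        seed=0,
        method: str = "abc-mcmc",
        epsilon_factor: float = 2.5,
        iterations: int = 330,
        step: float = 0.2,
        n_ensemble: int | None = None,
        reject_fraction: float = 0.01,
        **kw,
    ) -> "BottleneckResults":
        """Fit by ABC-MCMC (posterior sample) or Metropolis best-fit search.

        With ``method="abc-mcmc"`` and no explicit ``epsilon``, an annealed
        Metropolis search first locates the best-fit parameterisation; the
        threshold is then set to ``epsilon_factor`` times that fit's
        re-simulation noise floor (see :func:`infer.noise_floor_epsilon`)
        and the ABC chain starts from the best fit.  With an explicit
        ``epsilon`` the chain starts from a prior draw satisfying the
        threshold.  ``method="mcmc"`` returns the Metropolis best fit and
        its trace only.

        ``reject_fraction`` is the tolerated share of cap-breaching
        trajectories per ensemble before a parameterisation is discarded
        outright; the fitting default (0.01) tolerates the occasional tail
        trajectory in small ensembles, while 0.0 reproduces the strict
        any-rejection rule.
        """
        rng = np.random.default_rng(seed)
        n_ens = n_ensemble or self.n_ensemble
        if method == "abc-mcmc":
            start = kw.pop("start", None)
            n_chains = kw.pop("n_chains", 4)
            starts = [start] if start is not None else None
            if epsilon is None:
                # independent annealed searches give diverse footholds on the
                # weakly identified turnover ridge; the threshold is set from
                # the overall best fit's re-simulation noise floor
                strata = [(0.02, 0.25), (0.25, 1.2), (1.2, 4.0), (4.0, 10.0)]
                bests = []
                for k in range(n_chains):
                    try:
                        bests.append(infer.mcmc_best_fit(
                            self.template, self.schedule, self.data, iterations,
                            rng, self.priors, n_ensemble=n_ens,
                            weights=self.weights,
                            nu_start_range=strata[k % len(strata)],
                            reject_fraction=reject_fraction, n_starts=1)[0])
                    except infer.ABCError:
                        continue  # a chain stuck at an infeasible start
                if not bests:
                    raise infer.ABCError("every search chain failed to move")
                bests = [b for b in bests if np.isfinite(b.distance)] or bests
                overall = min(bests, key=lambda b: b.distance)
                epsilon = infer.noise_floor_epsilon(
                    overall.params, self.template, self.schedule, self.data, rng,
                    factor=epsilon_factor, n_ensemble=n_ens, weights=self.weights,
                    reject_fraction=reject_fraction)
                starts = [b.params for b in bests]
            samples: list = []
            per_chain = max(n_accept // len(starts), 1) if starts else n_accept
            failures = []
            for st in (starts or [None]):
                want = min(per_chain, n_accept - len(samples)) or 1
                try:
                    samples.extend(infer.abc_sample(
                        self.template, self.schedule, self.data, epsilon, want,
                        rng, self.priors, step=step, n_ensemble=n_ens,
                        weights=self.weights, start=st,
                        reject_fraction=reject_fraction, **kw))
                except infer.ABCError as exc:
                    failures.append(str(exc))
            if not samples:
                raise infer.ABCError("; ".join(failures))
            best = min(samples, key=lambda s: s.distance)
            return BottleneckResults(self, samples, best, epsilon, method)
        if method == "mcmc":
            best, trace = infer.mcmc_best_fit(
                self.template, self.schedule, self.data, iterations, rng,
                self.priors, step=step, n_ensemble=n_ens,
                weights=self.weights, **kw)
            res = BottleneckResults(self, [best], best, np.nan, method)
            res.trace = trace
            return res
        raise ValueError(f"unknown method {method!r}")


@dataclass
class BottleneckResults:
    """Posterior sample (or best fit) for a bottleneck mechanism."""

    model: GermlineBottleneckModel
    samples: list
    best: "infer.PosteriorSample"
    epsilon: float
    method: str
    trace: pd.DataFrame | None = None

    @property
    def posterior(self) -> pd.DataFrame:
        """One row per accepted sample: parameters + distance + min_Em + sigma."""
        return infer.samples_to_frame(self.samples)

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Central posterior credible interval for a parameter or derived
        summary ('sigma', 'min_Em', any parameter name)."""
        vals = self.posterior[name].to_numpy()
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(vals, lo)), float(np.quantile(vals, 1.0 - lo)))

    def summary(self, level: float = 0.95) -> str:
        """Plain-text summary table of the posterior."""
        post = self.posterior
        lines = [
            "Germline mtDNA bottleneck fit",
            "=" * 62,
            f"mechanism:        {self.model.template.mechanism}",
            f"method:           {self.method}",
            f"epsilon:          {self.epsilon:.4g}",
            f"n samples:        {len(self.samples)}",
            f"best distance:    {self.best.distance:.4g}",
            "-" * 62,
            f"{'quantity':>14} {'median':>12} {'ci low':>12} {'ci high':>12}",
        ]
        for name in list(self.model.priors.names()) + ["min_Em", "sigma"]:
            if name not in post.columns:
                continue
            vals = post[name].to_numpy()
            lo, hi = self.conf_int(name, level)
            lines.append(f"{name:>14} {np.median(vals):>12.4g} {lo:>12.4g} {hi:>12.4g}")
        lines.append("=" * 62)
        return "\n".join(lines)

    # -- posterior-predictive machinery -----------------------------------

    def predict_bands(self, times: Sequence[float], n_sample: int = 50,
                      seed=0, n_traj: int = 200, level: float = 0.95) -> pd.DataFrame:
        """Posterior-predictive bands of E(m) and V'(h) over time."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self.samples), size=min(n_sample, len(self.samples)),
                         replace=False)
        em = np.empty((idx.size, len(times)))
        vp = np.empty((idx.size, len(times)))
        for j, i in enumerate(idx):
            ens = self.model.simulate(self.samples[i].params, times, n_traj, rng)
            em[j] = ens.mean_m()
            vp[j] = ens.normalised_var_h()
        lo = (1.0 - level) / 2.0
        out = {"t_dpc": np.asarray(times)}
        for name, arr in (("E_m", em), ("Vprime_h", vp)):
            out[f"{name}_median"] = np.nanmedian(arr, axis=0)
            out[f"{name}_lo"] = np.nanquantile(arr, lo, axis=0)
            out[f"{name}_hi"] = np.nanquantile(arr, 1.0 - lo, axis=0)
        return pd.DataFrame(out)

    def plot_fit(self, times: Sequence[float] | None = None, ax=None, **kw):
        """Plot data overlaid with posterior-predictive bands."""
        import matplotlib.pyplot as plt

        from .measurements import COPY_MEAN, NORM_HET_VAR

        if times is None:
            tmax = self.model.schedule.t_final
            times = np.linspace(0.5, tmax, 40)
        bands = self.predict_bands(times, **kw)
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        obs = self.model.data
        cm = obs.subset(COPY_MEAN)
        vh = obs.subset(NORM_HET_VAR)
        ax[0].fill_between(bands["t_dpc"], bands["E_m_lo"], bands["E_m_hi"], alpha=0.3)
        ax[0].plot(bands["t_dpc"], bands["E_m_median"])
        ax[0].plot(cm["t_dpc"], cm["value"], "ko", ms=4)
        ax[0].set_yscale("log")
        ax[0].set_xlabel("t (dpc)")
        ax[0].set_ylabel("E(m)")
        ax[1].fill_between(bands["t_dpc"], bands["Vprime_h_lo"], bands["Vprime_h_hi"],
                           alpha=0.3)
        ax[1].plot(bands["t_dpc"], bands["Vprime_h_median"])
        ax[1].plot(vh["t_dpc"], vh["value"], "ko", ms=4)
        ax[1].set_xlabel("t (dpc)")
        ax[1].set_ylabel("V'(h)")
        return ax
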