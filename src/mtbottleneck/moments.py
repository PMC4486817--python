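"""Analytic theory of the bottleneck: moments, fixation, and clinical calculators.

Within a phase the mtDNA population of each species is a linear birth-death
process, which is solvable with generating functions; across divisions the
binomial-thinning generating function composes with the per-phase solutions.
Rather than carrying the closed-form variance expression (whose global form
is a lengthy function of all parameters), the implementation propagates the
per-founder mean and variance exactly through each phase segment and each
division — an algebraically equivalent scheme that is validated against
stochastic simulation in the test suite.

Provided here:

* copy-number mean and variance at any time (exact for the stochastic
  birth-death-partition mechanism);
* heteroplasmy mean and variance from the species moments (second-order
  ratio expansion) and the normalised variance V'(h) = V(h)/(E(h)(1-E(h)));
* the sigmoidal mean-heteroplasmy trajectory under a replication-rate
  selection differential;
* fixation probabilities (mass at h = 0 and h = 1) by backward composition
  of probability generating functions (binomial partitioning only);
* the truncated-Normal + fixation-mass approximation of the full
  heteroplasmy distribution, an exact small-system enumeration of that
  distribution for validation, the threshold-crossing probability, and the
  preimplantation-sampling posterior over embryonic heteroplasmy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .config import MechanismConfig, Phase, PhaseSchedule
from .simulate import _bd_ab, build_plan

__all__ = [
    "MomentState",
    "HetDistribution",
    "PgdPosterior",
    "phase_moments",
    "division_moments",
    "copy_mean",
    "copy_mean_closed_form",
    "copy_variance",
    "species_moments",
    "moment_trajectory",
    "het_moments",
    "normalised_het_variance",
    "selection_mean",
    "fixation_probs",
    "composed_pgf",
    "exact_het_distribution",
    "fit_truncated_normal",
    "het_distribution",
    "threshold_crossing",
    "pgd_posterior",
    "het_transform",
    "UnsupportedMechanismError",
]

_CRITICAL_TOL = 1e-8  # |lambda - nu| below which the critical limit is used


def _safe_exp(x: float) -> float:
    return math.exp(min(x, 700.0))


class UnsupportedMechanismError(ValueError):
    """Raised when an analytic result requires the binomial BDP mechanism."""


@dataclass(frozen=True)
class MomentState:
    """Mean and variance of one species' copy number at time ``t`` (dpc)."""

    mu: float
    var: float
    t: float = 0.0

    def __post_init__(self):
        if self.mu < 0 or self.var < -1e-9:
            raise ValueError("moments must be nonnegative")


def _species_lambda(phase: Phase, cfg: MechanismConfig | None, species: str) -> float:
    lam = phase.lambda_w
    if cfg is not None and species == "mutant" and lam > 0:
        lam = lam + cfg.delta_lambda
    return lam


def phase_moments(
    ms: MomentState,
    phase: Phase,
    duration: float,
    cfg: MechanismConfig | None = None,
    species: str = "wildtype",
) -> MomentState:
    """Propagate one species' (mean, variance) through an intra-phase interval.

    Stochastic dynamics (``S = 1``) add birth-death process noise
    ``mu * ((lam+nu)/(lam-nu)) * e^{r d} (e^{r d} - 1)`` on top of the
    multiplicative propagation; near-critical rates (|lam - nu| < 1e-8/day)
    use the series limit ``2 lam mu d``.  Deterministic dynamics (``S = 0``)
    propagate the variance multiplicatively with no noise term.
    """
    if duration < 0:
        raise ValueError("negative duration")
    lam = _species_lambda(phase, cfg, species)
    nu = phase.nu
    S = cfg.S if cfg is not None else 1
    r = lam - nu
    if abs(r) < _CRITICAL_TOL:
        growth = 1.0
        noise = 2.0 * lam * duration if S == 1 else 0.0
    else:
        growth = _safe_exp(r * duration)
        noise = ((lam + nu) / r) * growth * (growth - 1.0) if S == 1 else 0.0
    mu = ms.mu * growth
    var = ms.var * growth * growth + ms.mu * noise
    return MomentState(mu=mu, var=max(var, 0.0), t=ms.t + duration)


def division_moments(ms: MomentState, cfg: MechanismConfig) -> MomentState:
    """Propagate one species' moments through a cell division.

    Deterministic halving scales (mu, var) by (1/2, 1/4); binomial
    partitioning adds ``mu/4``; homoplasmic clusters of size ``c`` add
    ``c mu/4``.  Heteroplasmic clusters couple the two species and are
    handled by simulation only.
    """
    if cfg.c == 0:
        add = 0.0
    elif cfg.c == 1:
        add = ms.mu / 4.0
    elif cfg.cluster_content == "homoplasmic":
        add = cfg.c * ms.mu / 4.0
    else:
        raise UnsupportedMechanismError(
            "moment propagation through heteroplasmic clusters is not closed; "
            "use simulation"
        )
    return MomentState(mu=ms.mu / 2.0, var=ms.var / 4.0 + add, t=ms.t)


# ---------------------------------------------------------------------------
# Whole-schedule propagation


def _check_moment_support(cfg: MechanismConfig, t: float) -> None:
    if cfg.c >= 2 and cfg.cluster_content != "homoplasmic":
        raise UnsupportedMechanismError(
            "analytic variance requires deterministic, binomial, or "
            "homoplasmic-cluster partitioning"
        )
    if cfg.mechanism == "WAI_B" and cfg.alpha < 1.0 and t > cfg.T_cutoff:
        raise UnsupportedMechanismError(
            "analytic variance is not available once the subset-replication "
            "restriction is active; use simulation"
        )


def _founder_moments(cfg: MechanismConfig, sched: PhaseSchedule, t: float,
                     species: str) -> tuple[float, float]:
    """Per-founder (mean, variance) at time ``t`` for one species."""
    plan, _ = build_plan(cfg, sched, [float(t)])
    ms = MomentState(mu=1.0, var=0.0, t=0.0)
    for step in plan:
        if step[0] == "interval":
            _, t0, t1, phase = step
            ms = phase_moments(ms, phase, t1 - t0, cfg, species)
        elif step[0] == "divide":
            ms = division_moments(ms, cfg)
    return ms.mu, ms.var


def _founder_mean_waib(cfg: MechanismConfig, sched: PhaseSchedule, t: float,
                       species: str) -> float:
    """Per-founder mean with an active subset restriction (mean is exact)."""
    plan, _ = build_plan(cfg, sched, [float(t)])
    g_total, g_repl = 1.0, None
    for step in plan:
        if step[0] == "interval":
            _, t0, t1, phase = step
            d = t1 - t0
            lam = _species_lambda(phase, cfg, species)
            nu = phase.nu
            if g_repl is None:
                g_total *= _safe_exp((lam - nu) * d)
            else:
                grown = g_repl * _safe_exp((lam - nu) * d)
                g_total = grown + (g_total - g_repl) * math.exp(-nu * d)
                g_repl = grown
        elif step[0] == "divide":
            g_total /= 2.0
            if g_repl is not None:
                g_repl /= 2.0
        elif step[0] == "restrict":
            g_repl = cfg.alpha * g_total
    return g_total


def mean_copy_profile(cfg: MechanismConfig, sched: PhaseSchedule,
                      times: Sequence[float]) -> np.ndarray:
    """Mean total copy number at many times from one plan traversal.

    Equivalent to calling :func:`copy_mean` per time but an order of
    magnitude cheaper inside inference loops; supports the subset-replication
    restriction (the mean is exact for every mechanism).
    """
    times = sorted(float(t) for t in times)
    plan, n_obs = build_plan(cfg, sched, times)
    out = np.empty(n_obs)
    gw_tot, gw_rep = 1.0, None  # wildtype per-founder mean (total, replicating)
    gm_tot, gm_rep = 1.0, None
    for step in plan:
        if step[0] == "interval":
            _, t0, t1, phase = step
            d = t1 - t0
            nu = phase.nu
            for species in ("w", "m"):
                lam = _species_lambda(phase, cfg, "wildtype" if species == "w" else "mutant")
                tot, rep = (gw_tot, gw_rep) if species == "w" else (gm_tot, gm_rep)
                if rep is None:
                    tot *= _safe_exp((lam - nu) * d)
                else:
                    grown = rep * _safe_exp((lam - nu) * d)
                    tot = grown + (tot - rep) * math.exp(-nu * d)
                    rep = grown
                if species == "w":
                    gw_tot, gw_rep = tot, rep
                else:
                    gm_tot, gm_rep = tot, rep
        elif step[0] == "divide":
            gw_tot /= 2.0
            gm_tot /= 2.0
            if gw_rep is not None:
                gw_rep /= 2.0
                gm_rep /= 2.0
        elif step[0] == "restrict":
            gw_rep = cfg.alpha * gw_tot
            gm_rep = cfg.alpha * gm_tot
        elif step[0] == "observe":
            out[step[2]] = cfg.m1_0 * gw_tot + cfg.m2_0 * gm_tot
    return out


def species_moments(cfg: MechanismConfig, sched: PhaseSchedule, t: float,
                    species: str = "wildtype") -> MomentState:
    """Moments of one species' copy number at ``t`` from its founder count."""
    _check_moment_support(cfg, t)
    founders = cfg.m1_0 if species == "wildtype" else cfg.m2_0
    g, v = _founder_moments(cfg, sched, t, species)
    return MomentState(mu=founders * g, var=founders * v, t=float(t))


def copy_mean(cfg: MechanismConfig, sched: PhaseSchedule, t: float) -> float:
    """Mean total mtDNA copy number at ``t`` (iterated moment propagation)."""
    if cfg.mechanism == "WAI_B" and cfg.alpha < 1.0 and t > cfg.T_cutoff:
        gw = _founder_mean_waib(cfg, sched, t, "wildtype")
        gm = _founder_mean_waib(cfg, sched, t, "mutant")
        return cfg.m1_0 * gw + cfg.m2_0 * gm
    gw, _ = _founder_moments(cfg, sched, t, "wildtype")
    gm, _ = _founder_moments(cfg, sched, t, "mutant")
    return cfg.m1_0 * gw + cfg.m2_0 * gm


def copy_mean_closed_form(cfg: MechanismConfig, sched: PhaseSchedule, t: float) -> float:
    """Mean copy number as the per-phase product formula.

    E(m, t) = m0 e^{(t - tau*)(lam - nu)} prod_i e^{(n_i tau_i + tau'_i)(lam_i - nu_i)} / 2^{n_i}

    where the product runs over completed phase portions and ``t - tau*`` is
    the time since the last division, at the current phase's rates.  Kept as
    an independent formulation of the same quantity as :func:`copy_mean`
    (no selection, no subset restriction).
    """
    log_factor = 0.0
    ndiv = 0
    for ph in sched.phases:
        if t <= ph.start_dpc + 1e-12:
            break
        t_in = min(t, ph.end_dpc) - ph.start_dpc
        r = ph.lambda_w - ph.nu
        log_factor += r * t_in
        if ph.kind == "cycling":
            k = min(ph.n_divisions, int(math.floor(t_in / ph.doubling_time + 1e-9)))
            ndiv += k
    return cfg.m0 * math.exp(log_factor) / 2.0 ** ndiv


def copy_variance(cfg: MechanismConfig, sched: PhaseSchedule, t: float) -> float:
    """Variance of total copy number at ``t`` (species are independent)."""
    mw = species_moments(cfg, sched, t, "wildtype")
    mm = species_moments(cfg, sched, t, "mutant")
    return mw.var + mm.var


def moment_trajectory(cfg: MechanismConfig, sched: PhaseSchedule,
                      times: Sequence[float]):
    """Analytic E(m), V(m), E(h), V(h), V'(h) at each requested time."""
    import pandas as pd

    rows = []
    for t in times:
        mw = species_moments(cfg, sched, t, "wildtype")
        mm = species_moments(cfg, sched, t, "mutant")
        if mm.mu > 0:
            eh, vh = het_moments(mw, mm)
            vph = normalised_het_variance(eh, vh) if 0 < eh < 1 else np.nan
        else:
            eh, vh, vph = 0.0, 0.0, np.nan
        rows.append({
            "t_dpc": t, "E_m": mw.mu + mm.mu, "V_m": mw.var + mm.var,
            "E_h": eh, "V_h": vh, "Vprime_h": vph,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Heteroplasmy moments and selection


def het_moments(ms1: MomentState, ms2: MomentState) -> tuple[float, float]:
    """Heteroplasmy mean and variance from the two species' moments.

    E(h) = mu2 / (mu1 + mu2);
    V(h) = E(h)^2 (s2/mu2^2 - 2 s2/(mu2 (mu1+mu2)) + (s1+s2)/(mu1+mu2)^2),

    the second-order expansion of the ratio m2/(m1+m2) in the species
    fluctuations.
    """
    mu1, s1 = ms1.mu, ms1.var
    mu2, s2 = ms2.mu, ms2.var
    tot = mu1 + mu2
    if tot <= 0:
        raise ValueError("total mean copy number must be positive")
    if mu2 == 0:
        if s2 > 0:
            raise ValueError("mu2 = 0 with positive variance: formula singular")
        return 0.0, 0.0
    mu_h = mu2 / tot
    vh = mu_h ** 2 * (s2 / mu2 ** 2 - 2.0 * s2 / (mu2 * tot) + (s1 + s2) / tot ** 2)
    return mu_h, max(vh, 0.0)


def normalised_het_variance(E_h: float, V_h: float) -> float:
    """V'(h) = V(h) / (E(h)(1 - E(h))), the mean-controlled variance."""
    denom = E_h * (1.0 - E_h)
    if denom <= 0:
        raise ValueError("normalised variance undefined at h in {0, 1}")
    return V_h / denom


def selection_mean(h0: float, delta_lambda: float, t: float) -> float:
    """Mean heteroplasmy under a constant replication-rate differential.

    E(h, t) = 1 / (1 + ((1 - h0)/h0) e^{-delta_lambda t}): sigmoidal in
    time, monotone for a nonzero differential.  h0 of 0 or 1 is absorbing.
    """
    if h0 <= 0.0:
        return 0.0
    if h0 >= 1.0:
        return 1.0
    return 1.0 / (1.0 + ((1.0 - h0) / h0) * math.exp(-delta_lambda * t))


# ---------------------------------------------------------------------------
# Fixation probabilities via backward generating-function composition


def _require_bdp(cfg: MechanismConfig) -> None:
    if not (cfg.S == 1 and cfg.c == 1 and cfg.alpha == 1.0):
        raise UnsupportedMechanismError(
            "generating-function fixation probabilities require the binomial "
            "birth-death-partition mechanism; estimate by simulation instead"
        )


def composed_pgf(cfg: MechanismConfig, sched: PhaseSchedule, t: float,
                 s, species: str = "wildtype"):
    """Single-founder PGF of the copy number at ``t``, evaluated at ``s``.

    Composes, backwards through the schedule, each phase segment's
    birth-death PGF with the binomial-thinning PGF  B(s) = (1 + s)/2  at
    each division.  ``s`` may be scalar, array, or complex.
    """
    _require_bdp(cfg)
    plan, _ = build_plan(cfg, sched, [float(t)])
    x = np.asarray(s, dtype=complex) if np.iscomplexobj(s) else np.asarray(s, dtype=float)
    for step in reversed(plan):
        if step[0] == "interval":
            _, t0, t1, phase = step
            lam = _species_lambda(phase, cfg, species)
            a, b = _bd_ab(lam, phase.nu, t1 - t0)
            x = a + (1.0 - a) * (1.0 - b) * x / (1.0 - b * x)
        elif step[0] == "divide":
            x = (1.0 + x) / 2.0
    return x


def fixation_probs(cfg: MechanismConfig, sched: PhaseSchedule,
                   t: float) -> tuple[float, float, float]:
    """(zeta1, zeta2, p_total_extinction) at time ``t`` for the BDP mechanism.

    zeta1 = P(h = 0) (all mutant founders' clans extinct, wildtype alive);
    zeta2 = P(h = 1); the per-founder extinction probability is the composed
    PGF evaluated at 0.
    """
    qw = float(np.real(composed_pgf(cfg, sched, t, 0.0, "wildtype")))
    qm = float(np.real(composed_pgf(cfg, sched, t, 0.0, "mutant")))
    pw_ext = qw ** cfg.m1_0 if cfg.m1_0 > 0 else 1.0
    pm_ext = qm ** cfg.m2_0 if cfg.m2_0 > 0 else 1.0
    zeta1 = pm_ext * (1.0 - pw_ext)
    zeta2 = pw_ext * (1.0 - pm_ext)
    return zeta1, zeta2, pw_ext * pm_ext


# ---------------------------------------------------------------------------
# Exact small-system heteroplasmy distribution (enumeration oracle)


@dataclass
class ExactHetDistribution:
    """Exact heteroplasmy distribution of a small BDP system.

    Computed by extracting the copy-number distribution of each species from
    its composed generating function (Fourier inversion on the unit circle)
    and enumerating every (m1, m2) state.  ``h_values``/``weights`` carry the
    interior (0 < h < 1) states; the masses at 0, 1 and total extinction are
    separate.
    """

    p_h0: float
    p_h1: float
    p_extinct: float
    h_values: np.ndarray
    weights: np.ndarray

    def binned(self, edges: np.ndarray) -> np.ndarray:
        hist, _ = np.histogram(self.h_values, bins=edges, weights=self.weights)
        return hist

    def mean(self) -> float:
        alive = self.p_h0 + self.p_h1 + self.weights.sum()
        return (self.p_h1 + float(self.h_values @ self.weights)) / alive

    def var(self) -> float:
        alive = self.p_h0 + self.p_h1 + self.weights.sum()
        m = self.mean()
        e2 = (self.p_h1 + float((self.h_values ** 2) @ self.weights)) / alive
        return e2 - m * m


def exact_het_distribution(cfg: MechanismConfig, sched: PhaseSchedule, t: float,
                           n_max: int = 2048) -> ExactHetDistribution:
    """Enumerate the exact joint heteroplasmy distribution (small systems).

    ``n_max`` bounds the per-species copy number; a truncation leaving more
    than 1e-8 of probability beyond it raises.
    """
    _require_bdp(cfg)
    k = np.arange(n_max)
    s = np.exp(2j * np.pi * k / n_max)

    def species_pmf(species: str, founders: int) -> np.ndarray:
        if founders == 0:
            out = np.zeros(n_max)
            out[0] = 1.0
            return out
        g = composed_pgf(cfg, sched, t, s, species)
        pmf = np.fft.fft(g ** founders).real / n_max
        pmf = np.clip(pmf, 0.0, None)
        total = pmf.sum()
        if abs(total - 1.0) > 1e-8:
            raise ValueError(
                f"copy-number support exceeds n_max={n_max} (mass {total:.6f})"
            )
        return pmf / total

    p1 = species_pmf("wildtype", cfg.m1_0)
    p2 = species_pmf("mutant", cfg.m2_0)

    # trim negligible tails to keep the outer product small
    def trim(p: np.ndarray) -> np.ndarray:
        nz = np.nonzero(p > 1e-15)[0]
        return p[: nz[-1] + 1] if nz.size else p[:1]

    p1, p2 = trim(p1), trim(p2)
    p_extinct = p1[0] * p2[0]
    p_h0 = (1.0 - p1[0]) * p2[0]
    p_h1 = p1[0] * (1.0 - p2[0])

    a = np.arange(1, p1.size)
    b = np.arange(1, p2.size)
    W = np.outer(p1[1:], p2[1:])
    H = b[None, :] / (a[:, None] + b[None, :])
    return ExactHetDistribution(
        p_h0=float(p_h0), p_h1=float(p_h1), p_extinct=float(p_extinct),
        h_values=H.reshape(-1), weights=W.reshape(-1),
    )


# ---------------------------------------------------------------------------
# Truncated-Normal mixture approximation of the heteroplasmy distribution


def _truncnorm_stats(mu: float, sigma: float) -> tuple[float, float]:
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(v)


def fit_truncated_normal(mean_c: float, var_c: float,
                         tol: float = 1e-10) -> tuple[float, float, bool]:
    """Find (mu, sigma^2) of a [0,1]-truncated Normal with given moments.

    Solved by least squares on (mu, log sigma); returns the nearest-feasible
    fit with ``feasible=False`` when the requested variance exceeds what the
    family supports at that mean.
    """
    if not (0.0 < mean_c < 1.0):
        raise ValueError("continuous-part mean must lie in (0, 1)")
    if var_c <= 0.0:
        return mean_c, 0.0, True
    scale0 = math.sqrt(var_c)

    def resid(x):
        mu, logs = x
        m, v = _truncnorm_stats(mu, math.exp(logs))
        return [m - mean_c, v - var_c]

    sol = optimize.least_squares(
        resid, x0=[mean_c, math.log(scale0)], xtol=1e-15, ftol=1e-15, gtol=1e-15,
        bounds=([-20.0, math.log(1e-6)], [21.0, math.log(1e3)]),
    )
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    m, v = _truncnorm_stats(mu, sigma)
    feasible = abs(m - mean_c) < max(tol, 1e-9) and abs(v - var_c) < max(tol, 1e-9)
    return float(mu), float(sigma ** 2), bool(feasible)


@dataclass
class HetDistribution:
    """Truncated-Normal + fixation-mass mixture for the heteroplasmy law.

    P(h) = (1 - zeta1 - zeta2) N'(h | mu, sigma2) + zeta1 d(h) + zeta2 d(h-1)

    ``mean``/``var`` are the mixture moments the fit was built from (the
    model's E(h), V(h)); ``mu``/``sigma2`` are the fitted truncated-Normal
    parameters of the continuous part.
    """

    mean: float
    var: float
    zeta1: float
    zeta2: float
    mu: float
    sigma2: float
    feasible: bool = True

    @property
    def continuous_mass(self) -> float:
        return max(1.0 - self.zeta1 - self.zeta2, 0.0)

    def _tn(self):
        sigma = math.sqrt(self.sigma2)
        a, b = (0.0 - self.mu) / sigma, (1.0 - self.mu) / sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=sigma)

    def pdf(self, h):
        """Density of the continuous component, weighted by its mass."""
        h = np.asarray(h, dtype=float)
        if self.sigma2 == 0.0:
            return np.where(np.isclose(h, self.mu), np.inf, 0.0)
        return self.continuous_mass * self._tn().pdf(h)

    def cdf(self, h):
        h = np.asarray(h, dtype=float)
        cont = (np.clip(h, 0, 1) >= self.mu) * 1.0 if self.sigma2 == 0.0 \
            else self._tn().cdf(np.clip(h, 0.0, 1.0))
        out = self.zeta1 * (h >= 0) + self.continuous_mass * cont + self.zeta2 * (h >= 1)
        return out

    def likelihood(self, h_m: float) -> float:
        """Mixture likelihood of a measurement: density inside (0,1), the
        fixation mass exactly at the endpoints."""
        if h_m <= 0.0:
            return self.zeta1
        if h_m >= 1.0:
            return self.zeta2
        return float(self.pdf(h_m))

    def binned(self, edges: np.ndarray) -> np.ndarray:
        """Probability of each interior bin (endpoint masses not included)."""
        if self.sigma2 == 0.0:
            hist = np.zeros(len(edges) - 1)
            idx = np.searchsorted(edges, self.mu, side="right") - 1
            hist[np.clip(idx, 0, len(hist) - 1)] = self.continuous_mass
            return hist
        cdf = self._tn().cdf(edges)
        return self.continuous_mass * np.diff(cdf)


def het_distribution(cfg: MechanismConfig, sched: PhaseSchedule,
                     t: float) -> HetDistribution:
    """The mixture approximation of the heteroplasmy distribution at ``t``."""
    mw = species_moments(cfg, sched, t, "wildtype")
    mm = species_moments(cfg, sched, t, "mutant")
    eh, vh = het_moments(mw, mm)
    z1, z2, _ = fixation_probs(cfg, sched, t)
    return _build_het_distribution(eh, vh, z1, z2)


def _build_het_distribution(eh: float, vh: float, z1: float, z2: float) -> HetDistribution:
    cont = 1.0 - z1 - z2
    if cont <= 1e-12:
        return HetDistribution(mean=eh, var=vh, zeta1=z1, zeta2=z2,
                               mu=eh, sigma2=0.0, feasible=True)
    mean_c = (eh - z2) / cont
    var_c = (vh + eh * eh - z2) / cont - mean_c * mean_c
    mean_c = min(max(mean_c, 1e-9), 1.0 - 1e-9)
    mu, sigma2, feasible = fit_truncated_normal(mean_c, max(var_c, 0.0))
    return HetDistribution(mean=eh, var=vh, zeta1=z1, zeta2=z2,
                           mu=mu, sigma2=sigma2, feasible=feasible)


def threshold_crossing(hdist: HetDistribution, h_star: float,
                       use_fitted: bool = False) -> float:
    """Probability that heteroplasmy exceeds the threshold ``h_star``.

    P(h > h*) = (1 - z1 - z2)(1 - (1 + erf((h* - E(h)) / sqrt(2 V(h))))/2) + z2.

    By default the raw mixture moments E(h), V(h) enter the erf, as the
    formula is stated; ``use_fitted`` substitutes the fitted truncated-Normal
    parameters (upper tail of the actual continuous component) instead.
    """
    if not (0.0 < h_star < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if use_fitted:
        if hdist.sigma2 == 0.0:
            tail = 1.0 if hdist.mu > h_star else 0.0
        else:
            tail = float(hdist._tn().sf(h_star))
        return hdist.continuous_mass * tail + hdist.zeta2
    mean, var = hdist.mean, hdist.var
    if var <= 0.0:
        tail = 1.0 if mean > h_star else 0.0
    else:
        tail = 1.0 - 0.5 * (1.0 + special.erf((h_star - mean) / math.sqrt(2.0 * var)))
    return hdist.continuous_mass * tail + hdist.zeta2


# ---------------------------------------------------------------------------
# Preimplantation sampling posterior


@dataclass
class PgdPosterior:
    """Posterior over embryonic (initial) heteroplasmy given a measurement."""

    h0_grid: np.ndarray
    density: np.ndarray
    h_m: float
    t_sample: float

    def mean(self) -> float:
        return float(np.trapezoid(self.h0_grid * self.density, self.h0_grid))

    def mode(self) -> float:
        return float(self.h0_grid[np.argmax(self.density)])

    def cdf_values(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid
        c = cumulative_trapezoid(self.density, self.h0_grid, initial=0.0)
        return c / c[-1]

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        c = self.cdf_values()
        lo = (1.0 - level) / 2.0
        hi = 1.0 - lo
        return (float(np.interp(lo, c, self.h0_grid)),
                float(np.interp(hi, c, self.h0_grid)))

    def spread(self, level: float = 0.95) -> float:
        lo, hi = self.credible_interval(level)
        return hi - lo


def pgd_posterior(h_m: float, t_sample: float, cfg: MechanismConfig,
                  sched: PhaseSchedule, grid: int = 201) -> PgdPosterior:
    """Posterior P(h0 | h_m) for preimplantation-sampling diagnosis.

    Uniform prior over embryonic heteroplasmy h0; likelihood from the
    mixture heteroplasmy distribution of the model run forward from each h0
    to the sampling time (delta masses handle h_m of exactly 0 or 1);
    normalised by trapezoidal integration on the h0 grid.
    """
    if not (0.0 <= h_m <= 1.0):
        raise ValueError("h_m must lie in [0, 1]")
    if grid < 5:
        raise ValueError("degenerate h0 grid")
    h0s = np.linspace(0.0, 1.0, grid + 2)[1:-1]

    # Per-founder statistics do not depend on h0, so compute them once.
    gw, vw = _founder_moments(cfg, sched, t_sample, "wildtype")
    gm, vm = _founder_moments(cfg, sched, t_sample, "mutant")
    qw = float(np.real(composed_pgf(cfg, sched, t_sample, 0.0, "wildtype")))
    qm = float(np.real(composed_pgf(cfg, sched, t_sample, 0.0, "mutant")))

    like = np.empty_like(h0s)
    for i, h0 in enumerate(h0s):
        n2 = h0 * cfg.m0
        n1 = cfg.m0 - n2
        ms1 = MomentState(mu=n1 * gw, var=n1 * vw, t=t_sample)
        ms2 = MomentState(mu=n2 * gm, var=n2 * vm, t=t_sample)
        eh, vh = het_moments(ms1, ms2)
        pw_ext = math.exp(n1 * math.log(qw)) if qw > 0 else 0.0
        pm_ext = math.exp(n2 * math.log(qm)) if qm > 0 else 0.0
        z1 = pm_ext * (1.0 - pw_ext)
        z2 = pw_ext * (1.0 - pm_ext)
        hd = _build_het_distribution(eh, vh, z1, z2)
        like[i] = hd.likelihood(h_m)

    norm = np.trapezoid(like, h0s)
    if norm <= 0:
        raise ValueError("measurement has zero likelihood everywhere on the grid")
    return PgdPosterior(h0_grid=h0s, density=like / norm, h_m=h_m, t_sample=t_sample)


# ---------------------------------------------------------------------------
# Distribution-comparison transform


def het_transform(h, E_h):
    """Mean-standardising transform  h' = -ln| (1/h - 1) E(h)/(1 - E(h)) |.

    Maps heteroplasmy to a scale on which distributions with different means
    are comparable; h = E_h maps to 0 and the transform is monotone
    increasing on (0, 1).  Values at exactly 0 or 1 map to -inf/+inf.
    """
    h = np.asarray(h, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = (1.0 / np.clip(h, 1e-300, None) - 1.0) * E_h / (1.0 - E_h)
        out = -np.log(np.abs(ratio))
    out = np.where(h <= 0.0, -np.inf, out)
    out = np.where(h >= 1.0, np.inf, out)
    return out if out.ndim else float(out)
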