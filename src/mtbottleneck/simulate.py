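"""Stochastic and deterministic simulation of germline mtDNA populations.

A single germline lineage is followed from the fertilised oocyte: wildtype
(``m1``) and mutant (``m2``) copy numbers evolve within each cell cycle by
replication and degradation, and are partitioned into one followed daughter
at every division epoch of the developmental schedule.

Two statistically equivalent stochastic engines are provided for the
``S = 1`` (Poisson) dynamics:

* :func:`gillespie_phase` — the event-driven stochastic simulation algorithm,
  exact at every event, practical for small populations;
* exact interval sampling — the transition law of a linear birth-death
  process over an interval is known in closed form (binomial survival of the
  founders plus geometric offspring clans), so the state at the end of an
  interval can be drawn directly.  This is what :func:`simulate_trajectory`
  and :func:`simulate_ensemble` use, which makes ensembles of 10^4
  trajectories with ~2x10^5 molecules per cell tractable.  Both engines
  sample the same Markov jump process; tests cross-check them.

Partitioning at divisions follows the configured mechanism: deterministic
halving (``c = 0``), per-molecule binomial (``c = 1``), or clustered
(``c >= 2``) with homoplasmic or heteroplasmic cluster content.  The
subset-replication mechanism (``WAI_B``) restricts replication competence to
a hypergeometrically drawn pool of ``round(alpha * m)`` molecules at the
cutoff time ``T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, MechanismConfig, Phase, PhaseSchedule

__all__ = [
    "CellState",
    "Trajectory",
    "EnsembleSummary",
    "CapExceeded",
    "gillespie_phase",
    "deterministic_phase",
    "partition",
    "simulate_trajectory",
    "simulate_ensemble",
    "sample_bd_interval",
]

_TIME_DECIMALS = 9


def _safe_exp(x: float) -> float:
    """exp with the argument clamped below the double overflow point; growth
    this extreme always breaches the copy cap and is rejected downstream."""
    return math.exp(min(x, 700.0))


class CapExceeded(RuntimeError):
    """Signal that a trajectory breached the copy-number cap."""


@dataclass
class CellState:
    """Copy-number state of the followed cell at time ``t`` (dpc)."""

    m1: float
    m2: float
    t: float = 0.0
    replicating_m1: float | None = None
    replicating_m2: float | None = None

    @property
    def m(self) -> float:
        return self.m1 + self.m2

    @property
    def h(self) -> float:
        """Heteroplasmy; defined only for non-extinct cells."""
        tot = self.m1 + self.m2
        if tot <= 0:
            raise ValueError("heteroplasmy undefined for an extinct cell")
        return self.m2 / tot


@dataclass
class Trajectory:
    """One simulated lineage observed at ``times``."""

    times: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    divisions_crossed: int
    rejected: bool = False

    @property
    def m(self) -> np.ndarray:
        return self.m1 + self.m2

    @property
    def extinct(self) -> bool:
        return bool(self.m[-1] <= 0)

    @property
    def h(self) -> np.ndarray:
        tot = self.m1 + self.m2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.m2 / np.maximum(tot, 1e-300), np.nan)


@dataclass
class EnsembleSummary:
    """Per-observation-time state arrays over an ensemble of lineages.

    Heteroplasmy statistics condition on non-extinct cells (``m1 + m2 > 0``);
    the extinct fraction is reported separately.  Cap-breaching trajectories
    are flagged in ``rejected`` and excluded from all statistics.
    """

    obs_times: np.ndarray
    m1: np.ndarray  # shape (n_obs, n_traj)
    m2: np.ndarray
    rejected: np.ndarray  # shape (n_traj,)

    @property
    def n_traj(self) -> int:
        return self.m1.shape[1]

    @property
    def valid(self) -> np.ndarray:
        return ~self.rejected

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def m(self) -> np.ndarray:
        return self.m1 + self.m2

    @property
    def h(self) -> np.ndarray:
        """Heteroplasmy per (time, trajectory); NaN where extinct."""
        tot = self.m
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.m2 / np.maximum(tot, 1e-300), np.nan)

    def mean_m(self) -> np.ndarray:
        return self.m[:, self.valid].mean(axis=1)

    def var_m(self, ddof: int = 1) -> np.ndarray:
        return self.m[:, self.valid].var(axis=1, ddof=ddof)

    def extinct_fraction(self) -> np.ndarray:
        return (self.m[:, self.valid] <= 0).mean(axis=1)

    def mean_h(self) -> np.ndarray:
        return np.nanmean(self.h[:, self.valid], axis=1)

    def var_h(self, ddof: int = 1) -> np.ndarray:
        h = self.h[:, self.valid]
        out = np.full(h.shape[0], np.nan)
        for i in range(h.shape[0]):
            hi = h[i][~np.isnan(h[i])]
            if hi.size > ddof:
                out[i] = hi.var(ddof=ddof)
        return out

    def normalised_var_h(self, ddof: int = 1) -> np.ndarray:
        mh = self.mean_h()
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.var_h(ddof=ddof) / (mh * (1.0 - mh))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy export: one row per (trajectory, observation time)."""
        n_obs, n_traj = self.m1.shape
        h = self.h
        return pd.DataFrame({
            "run_id": np.repeat(np.arange(n_traj), n_obs),
            "t_dpc": np.tile(self.obs_times, n_traj),
            "m1": self.m1.T.reshape(-1),
            "m2": self.m2.T.reshape(-1),
            "h": h.T.reshape(-1),
            "rejected": np.repeat(self.rejected, n_obs),
        })


# ---------------------------------------------------------------------------
# Exact interval sampling of the linear birth-death process


def _bd_ab(lam: float, nu: float, d: float) -> tuple[float, float]:
    """Parameters (a, b) of the single-founder transition law over time ``d``.

    Starting from one molecule, after time ``d`` the clan is extinct with
    probability ``a`` and otherwise has a size that is geometric with
    parameter ``b``:  P(n) = (1-a)(1-b) b^(n-1) for n >= 1.
    """
    if d < 0:
        raise ValueError("negative duration")
    if d == 0.0 or (lam == 0.0 and nu == 0.0):
        return 0.0, 0.0
    if math.isclose(lam, nu, rel_tol=1e-12, abs_tol=1e-300):
        x = lam * d
        p = x / (1.0 + x)
        return p, p
    r = lam - nu
    rd = r * d
    if rd > 700.0:  # exp overflow: the supercritical limit
        return nu / lam, 1.0 - 1e-12
    E = math.exp(rd)
    denom = lam * E - nu
    a = nu * (E - 1.0) / denom
    b = lam * (E - 1.0) / denom
    return a, min(b, 1.0 - 1e-15)


def sample_bd_interval(
    m: np.ndarray | int,
    lam: float,
    nu: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the copy number after ``duration`` for each entry of ``m``.

    Exact sample of the linear birth-death transition distribution: the
    ``m`` founders survive independently (binomial) and each surviving clan
    contributes a geometric number of molecules, so the total is the survivor
    count plus a negative-binomial excess.
    """
    m = np.atleast_1d(np.asarray(m, dtype=np.int64))
    a, b = _bd_ab(lam, nu, duration)
    if a == 0.0 and b == 0.0:
        return m.copy()
    k = rng.binomial(m, 1.0 - a)
    out = k.astype(np.int64)
    if b > 0.0:
        kmax = int(k.max()) if k.size else 0
        if kmax > 0:
            odds = b / (1.0 - b)
            if kmax * odds < 1e12:
                pos = k > 0
                if pos.all():
                    out += rng.negative_binomial(k, 1.0 - b)
                else:
                    out[pos] += rng.negative_binomial(k[pos], 1.0 - b)
            else:
                # negative-binomial excess at extreme means (far beyond any
                # copy cap) overflows numpy's sampler; use its normal limit,
                # whose relative error is negligible there
                pos = k > 0
                kp = k[pos]
                mean_nb = kp * odds
                big = mean_nb > 1e12
                extra = np.empty(kp.shape, dtype=np.int64)
                if (~big).any():
                    extra[~big] = rng.negative_binomial(kp[~big], 1.0 - b)
                if big.any():
                    sd = np.sqrt(kp[big] * b) / (1.0 - b)
                    draw = np.clip(rng.normal(mean_nb[big], sd), 0.0, 4e18)
                    extra[big] = draw.astype(np.int64)
                out[pos] += extra
    return out


def _pure_death(m: np.ndarray, nu: float, d: float, rng: np.random.Generator) -> np.ndarray:
    if nu == 0.0 or d == 0.0:
        return m.copy()
    return rng.binomial(m, math.exp(-nu * d)).astype(np.int64)


# ---------------------------------------------------------------------------
# Event-driven stochastic simulation algorithm (small populations)


def gillespie_phase(
    state: CellState,
    phase: Phase,
    duration: float,
    rng: np.random.Generator,
    cfg: MechanismConfig | None = None,
) -> CellState:
    """Event-driven exact simulation of one intra-phase interval (``S = 1``).

    Per-molecule replication rates apply to the replicating pool (all
    molecules unless a subset restriction is active on ``state``); the
    degradation rate ``nu`` applies to every molecule.  Offspring inherit
    replication competence.  Raises :class:`CapExceeded` if the population
    exceeds the configured copy cap.
    """
    if duration < 0:
        raise ValueError("negative duration")
    cap = cfg.copy_cap if cfg is not None else np.inf
    dlam = cfg.delta_lambda if cfg is not None else 0.0
    lam_w = phase.lambda_w
    lam_m = lam_w + dlam if lam_w > 0 else lam_w
    nu = phase.nu

    m1, m2 = int(state.m1), int(state.m2)
    restricted = state.replicating_m1 is not None
    r1 = int(state.replicating_m1) if restricted else m1
    r2 = int(state.replicating_m2) if restricted else m2
    t = 0.0
    while True:
        # four channels: replication draws from the replicating pools,
        # degradation from all molecules; whether a degraded molecule was
        # replication-competent is resolved by a pool-proportional draw.
        rates = (lam_w * r1, lam_m * r2, nu * m1, nu * m2)
        total = rates[0] + rates[1] + rates[2] + rates[3]
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > duration:
            break
        u = rng.uniform(0.0, total)
        if u < rates[0]:  # wildtype replication
            m1 += 1
            if restricted:
                r1 += 1  # offspring inherit competence
            else:
                r1 = m1
        elif u < rates[0] + rates[1]:  # mutant replication
            m2 += 1
            if restricted:
                r2 += 1
            else:
                r2 = m2
        elif u < rates[0] + rates[1] + rates[2]:  # wildtype degradation
            if restricted and m1 > 0:
                if rng.uniform() < r1 / m1:
                    r1 -= 1
            m1 -= 1
            if not restricted:
                r1 = m1
        else:  # mutant degradation
            if restricted and m2 > 0:
                if rng.uniform() < r2 / m2:
                    r2 -= 1
            m2 -= 1
            if not restricted:
                r2 = m2
        if m1 + m2 > cap:
            raise CapExceeded(f"copy number {m1 + m2} exceeds cap {cap}")
    return CellState(
        m1=m1, m2=m2, t=state.t + duration,
        replicating_m1=r1 if restricted else None,
        replicating_m2=r2 if restricted else None,
    )


def deterministic_phase(
    state: CellState,
    phase: Phase,
    duration: float,
    cfg: MechanismConfig | None = None,
) -> CellState:
    """Deterministic (``S = 0``) intra-phase dynamics.

    Copy numbers are carried as reals: exponential growth/decay at net rate
    ``lambda - nu``.  Under an active subset restriction only the replicating
    pool grows; non-replicating molecules decay at ``nu``.
    """
    if duration < 0:
        raise ValueError("negative duration")
    dlam = cfg.delta_lambda if cfg is not None else 0.0
    lam_w = phase.lambda_w
    lam_m = lam_w + dlam if lam_w > 0 else lam_w
    nu = phase.nu
    restricted = state.replicating_m1 is not None

    def prop(m: float, r_pool: float | None, lam: float) -> tuple[float, float | None]:
        if r_pool is None:
            return m * _safe_exp((lam - nu) * duration), None
        grown = r_pool * _safe_exp((lam - nu) * duration)
        rest = (m - r_pool) * math.exp(-nu * duration)
        return grown + rest, grown

    m1, r1 = prop(state.m1, state.replicating_m1 if restricted else None, lam_w)
    m2, r2 = prop(state.m2, state.replicating_m2 if restricted else None, lam_m)
    return CellState(m1=m1, m2=m2, t=state.t + duration,
                     replicating_m1=r1, replicating_m2=r2)


# ---------------------------------------------------------------------------
# Partitioning at a division epoch (vectorised over trajectories)


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)


def _hypergeom_safe(rng, ngood, nbad, nsample):
    """Vectorised hypergeometric that tolerates empty draws."""
    ngood = np.asarray(ngood, dtype=np.int64)
    nbad = np.asarray(nbad, dtype=np.int64)
    nsample = np.asarray(nsample, dtype=np.int64)
    out = np.zeros(np.broadcast(ngood, nbad, nsample).shape, dtype=np.int64)
    ok = (nsample > 0) & (ngood + nbad > 0)
    if ok.any():
        g, b, n = np.broadcast_arrays(ngood, nbad, nsample)
        out[ok] = rng.hypergeometric(g[ok], b[ok], np.minimum(n[ok], g[ok] + b[ok]))
    return out


def _partition_homoplasmic(m: np.ndarray, c: int, rng) -> np.ndarray:
    k = m // c
    rem = m - k * c
    kept = c * rng.binomial(k, 0.5)
    if np.any(rem > 0):
        kept = kept + rem * rng.integers(0, 2, size=m.shape)
    return kept.astype(np.int64)


def _partition_counts(
    m1: np.ndarray,
    m2: np.ndarray,
    cfg: MechanismConfig,
    rng: np.random.Generator,
    r1: np.ndarray | None = None,
    r2: np.ndarray | None = None,
):
    """Partition integer count arrays into the followed daughter."""
    c = cfg.c
    if c < 0:
        raise ConfigurationError("cluster size c must be nonnegative")
    if c == 0:
        n1 = _round_half_even(m1 / 2.0)
        n2 = _round_half_even(m2 / 2.0)
    elif c == 1:
        n1 = rng.binomial(m1, 0.5).astype(np.int64)
        n2 = rng.binomial(m2, 0.5).astype(np.int64)
    elif cfg.cluster_content == "homoplasmic":
        n1 = _partition_homoplasmic(m1, c, rng)
        n2 = _partition_homoplasmic(m2, c, rng)
    elif cfg.cluster_content == "heteroplasmic_mixing":
        # Random grouping of the pooled population into clusters of size c,
        # each cluster retained with probability 1/2.  By exchangeability the
        # retained set is a uniform random subset of size c*J (+ remainder),
        # so the mutant share is hypergeometric.
        M = m1 + m2
        K = M // c
        rem = M - K * c
        n_ret = c * rng.binomial(K, 0.5)
        if np.any(rem > 0):
            n_ret = n_ret + rem * rng.integers(0, 2, size=M.shape)
        n2 = _hypergeom_safe(rng, m2, m1, n_ret)
        n1 = n_ret - n2
    else:
        raise ConfigurationError(
            "frozen heteroplasmic clusters require the explicit cluster "
            "trajectory path (simulate_trajectory)"
        )
    if r1 is not None:
        r1n = _hypergeom_safe(rng, r1, m1 - r1, n1)
        r2n = _hypergeom_safe(rng, r2, m2 - r2, n2)
        return n1, n2, r1n, r2n
    return n1, n2, None, None


def partition(
    state: CellState, cfg: MechanismConfig, rng: np.random.Generator
) -> CellState:
    """Partition a single cell at a division, returning the followed daughter."""
    restricted = state.replicating_m1 is not None
    m1 = np.array([int(round(state.m1))], dtype=np.int64)
    m2 = np.array([int(round(state.m2))], dtype=np.int64)
    r1 = np.array([int(round(state.replicating_m1))], dtype=np.int64) if restricted else None
    r2 = np.array([int(round(state.replicating_m2))], dtype=np.int64) if restricted else None
    if cfg.c == 0 and cfg.S == 0:
        # deterministic halving of real-valued counts
        return CellState(m1=state.m1 / 2.0, m2=state.m2 / 2.0, t=state.t,
                         replicating_m1=None if not restricted else state.replicating_m1 / 2.0,
                         replicating_m2=None if not restricted else state.replicating_m2 / 2.0)
    n1, n2, r1n, r2n = _partition_counts(m1, m2, cfg, rng, r1, r2)
    return CellState(
        m1=float(n1[0]), m2=float(n2[0]), t=state.t,
        replicating_m1=float(r1n[0]) if r1n is not None else None,
        replicating_m2=float(r2n[0]) if r2n is not None else None,
    )


# ---------------------------------------------------------------------------
# Segment plan: ordered intervals and actions between 0 and the last
# observation.  At a shared breakpoint the order is: subset restriction,
# then division, then observation (an observation at a division epoch sees
# the followed daughter).


def build_plan(cfg: MechanismConfig, sched: PhaseSchedule, obs_times: Sequence[float]):
    obs_times = [float(t) for t in obs_times]
    if any(t < 0 or t > sched.t_final for t in obs_times):
        raise ConfigurationError("observation times must lie within [0, t_final]")
    if sorted(obs_times) != obs_times:
        raise ConfigurationError("observation times must be sorted")
    t_end = max(obs_times) if obs_times else sched.t_final

    def q(t: float) -> float:
        return round(t, _TIME_DECIMALS)

    divisions = {q(t) for t in sched.division_epochs() if t <= t_end + 1e-9}
    restrict_at = (
        {q(cfg.T_cutoff)}
        if cfg.mechanism == "WAI_B" and cfg.alpha < 1.0 and cfg.T_cutoff <= t_end
        else set()
    )
    obs_map: dict[float, list[int]] = {}
    for i, t in enumerate(obs_times):
        obs_map.setdefault(q(t), []).append(i)
    bounds = {q(p.end_dpc) for p in sched.phases if p.end_dpc < t_end}

    breaks = sorted({0.0, q(t_end)} | divisions | restrict_at | set(obs_map) | bounds)
    plan: list[tuple] = []
    for i, t in enumerate(breaks):
        if t in restrict_at:
            plan.append(("restrict", t))
        if t in divisions:
            plan.append(("divide", t))
        for idx in obs_map.get(t, []):
            plan.append(("observe", t, idx))
        if i + 1 < len(breaks):
            t1 = breaks[i + 1]
            mid = 0.5 * (t + t1)
            plan.append(("interval", t, t1, sched.phase_at(mid)))
    return plan, len(obs_times)


# ---------------------------------------------------------------------------
# Vectorised ensemble engine


def _species_rates(phase: Phase, cfg: MechanismConfig) -> tuple[float, float, float]:
    lam_w = phase.lambda_w
    lam_m = lam_w + cfg.delta_lambda if lam_w > 0 else lam_w
    return lam_w, lam_m, phase.nu


def _run_vectorised(
    cfg: MechanismConfig,
    sched: PhaseSchedule,
    obs_times: Sequence[float],
    n_traj: int,
    rng: np.random.Generator,
):
    plan, n_obs = build_plan(cfg, sched, obs_times)
    cap = float(cfg.copy_cap)
    stochastic = cfg.S == 1

    if stochastic:
        m1 = np.full(n_traj, cfg.m1_0, dtype=np.int64)
        m2 = np.full(n_traj, cfg.m2_0, dtype=np.int64)
    else:
        m1 = np.full(n_traj, float(cfg.m1_0))
        m2 = np.full(n_traj, float(cfg.m2_0))
    r1 = r2 = None  # replicating pools (after a subset restriction)
    rejected = np.zeros(n_traj, dtype=bool)
    out1 = np.zeros((n_obs, n_traj))
    out2 = np.zeros((n_obs, n_traj))
    divisions_crossed = 0

    def check_cap():
        nonlocal m1, m2, r1, r2
        tot = m1 + m2
        over = tot > cap
        if over.any():
            rejected[over] = True
            # clamp to keep subsequent draws bounded; excluded from stats
            scale = cap / np.maximum(tot, 1)
            if stochastic:
                m1 = np.where(over, (m1 * scale).astype(np.int64), m1)
                m2 = np.where(over, (m2 * scale).astype(np.int64), m2)
            else:
                m1 = np.where(over, m1 * scale, m1)
                m2 = np.where(over, m2 * scale, m2)
            if r1 is not None:
                r1 = np.minimum(r1, m1)
                r2 = np.minimum(r2, m2)

    for step in plan:
        if step[0] == "interval":
            _, t0, t1, phase = step
            d = t1 - t0
            lam_w, lam_m, nu = _species_rates(phase, cfg)
            if stochastic:
                if r1 is None:
                    m1 = sample_bd_interval(m1, lam_w, nu, d, rng)
                    m2 = sample_bd_interval(m2, lam_m, nu, d, rng)
                else:
                    nr1 = sample_bd_interval(r1, lam_w, nu, d, rng)
                    nr2 = sample_bd_interval(r2, lam_m, nu, d, rng)
                    m1 = nr1 + _pure_death(m1 - r1, nu, d, rng)
                    m2 = nr2 + _pure_death(m2 - r2, nu, d, rng)
                    r1, r2 = nr1, nr2
            else:
                if r1 is None:
                    m1 = m1 * _safe_exp((lam_w - nu) * d)
                    m2 = m2 * _safe_exp((lam_m - nu) * d)
                else:
                    g1 = r1 * _safe_exp((lam_w - nu) * d)
                    g2 = r2 * _safe_exp((lam_m - nu) * d)
                    m1 = g1 + (m1 - r1) * math.exp(-nu * d)
                    m2 = g2 + (m2 - r2) * math.exp(-nu * d)
                    r1, r2 = g1, g2
            check_cap()
        elif step[0] == "divide":
            divisions_crossed += 1
            if not stochastic and cfg.c == 0:
                m1, m2 = m1 / 2.0, m2 / 2.0
                if r1 is not None:
                    r1, r2 = r1 / 2.0, r2 / 2.0
            else:
                i1 = _round_half_even(m1) if not stochastic else m1
                i2 = _round_half_even(m2) if not stochastic else m2
                ir1 = None if r1 is None else np.minimum(_round_half_even(r1), i1)
                ir2 = None if r2 is None else np.minimum(_round_half_even(r2), i2)
                n1, n2, nr1, nr2 = _partition_counts(i1, i2, cfg, rng, ir1, ir2)
                if stochastic:
                    m1, m2 = n1, n2
                    r1, r2 = nr1, nr2
                else:
                    m1, m2 = n1.astype(float), n2.astype(float)
                    if nr1 is not None:
                        r1, r2 = nr1.astype(float), nr2.astype(float)
            check_cap()
        elif step[0] == "restrict":
            i1 = m1 if stochastic else _round_half_even(m1)
            i2 = m2 if stochastic else _round_half_even(m2)
            tot = i1 + i2
            n_repl = np.rint(cfg.alpha * tot).astype(np.int64)
            nr2 = _hypergeom_safe(rng, i2, i1, n_repl)
            nr1 = n_repl - nr2
            if stochastic:
                r1, r2 = nr1, nr2
            else:
                m1, m2 = i1.astype(float), i2.astype(float)
                r1, r2 = nr1.astype(float), nr2.astype(float)
        elif step[0] == "observe":
            _, t, idx = step
            out1[idx] = np.rint(m1) if not stochastic else m1
            out2[idx] = np.rint(m2) if not stochastic else m2
    return np.asarray(obs_times, dtype=float), out1, out2, rejected, divisions_crossed


# ---------------------------------------------------------------------------
# Frozen heteroplasmic clusters: explicit per-cluster subpopulations


def _run_frozen_clusters(
    cfg: MechanismConfig,
    sched: PhaseSchedule,
    obs_times: Sequence[float],
    rng: np.random.Generator,
):
    """Single-lineage simulation with cluster contents frozen at first grouping.

    Clusters are formed once (multivariate-hypergeometric split of the pooled
    population into groups of ``c``); thereafter each cluster evolves as an
    independent birth-death subpopulation and whole clusters are retained
    binomially at divisions.
    """
    plan, n_obs = build_plan(cfg, sched, obs_times)
    c = cfg.c
    w = np.array([cfg.m1_0], dtype=np.int64)  # per-cluster wildtype counts
    mm = np.array([cfg.m2_0], dtype=np.int64)
    clustered = False
    rejected = False
    out1 = np.zeros(n_obs)
    out2 = np.zeros(n_obs)
    ndiv = 0
    for step in plan:
        if step[0] == "interval":
            _, t0, t1, phase = step
            d = t1 - t0
            lam_w, lam_m, nu = _species_rates(phase, cfg)
            w = sample_bd_interval(w, lam_w, nu, d, rng)
            mm = sample_bd_interval(mm, lam_m, nu, d, rng)
        elif step[0] == "divide":
            ndiv += 1
            if not clustered:
                tot_w, tot_m = int(w.sum()), int(mm.sum())
                M = tot_w + tot_m
                k = M // c
                sizes = [c] * k + ([M - k * c] if M - k * c else [])
                good = tot_m
                bad = tot_w
                mlist = []
                for s in sizes:
                    x = int(rng.hypergeometric(good, bad, s)) if s and good + bad else 0
                    mlist.append(x)
                    good -= x
                    bad -= s - x
                mm = np.array(mlist, dtype=np.int64)
                w = np.array(sizes, dtype=np.int64) - mm
                clustered = True
            keep = rng.random(w.shape[0]) < 0.5
            w, mm = w[keep], mm[keep]
            if w.size == 0:
                w = np.array([0], dtype=np.int64)
                mm = np.array([0], dtype=np.int64)
        elif step[0] == "observe":
            _, t, idx = step
            out1[idx] = w.sum()
            out2[idx] = mm.sum()
        if w.sum() + mm.sum() > cfg.copy_cap:
            rejected = True
    return np.asarray(obs_times, dtype=float), out1, out2, rejected, ndiv


# ---------------------------------------------------------------------------
# Public simulation API


def simulate_trajectory(
    cfg: MechanismConfig,
    sched: PhaseSchedule,
    obs_times: Sequence[float],
    rng: np.random.Generator | int,
) -> Trajectory:
    """Simulate one followed germline lineage, observed at ``obs_times``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if cfg.c >= 2 and cfg.cluster_content == "heteroplasmic_fixed":
        times, m1, m2, rej, ndiv = _run_frozen_clusters(cfg, sched, obs_times, rng)
        return Trajectory(times=times, m1=m1, m2=m2, divisions_crossed=ndiv, rejected=rej)
    times, out1, out2, rejected, ndiv = _run_vectorised(cfg, sched, obs_times, 1, rng)
    return Trajectory(
        times=times, m1=out1[:, 0], m2=out2[:, 0],
        divisions_crossed=ndiv, rejected=bool(rejected[0]),
    )


def simulate_ensemble(
    cfg: MechanismConfig,
    sched: PhaseSchedule,
    obs_times: Sequence[float],
    n_traj: int,
    rng: np.random.Generator | int,
) -> EnsembleSummary:
    """Simulate ``n_traj`` independent lineages and collect their states."""
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if cfg.c >= 2 and cfg.cluster_content == "heteroplasmic_fixed":
        outs = [_run_frozen_clusters(cfg, sched, obs_times, rng) for _ in range(n_traj)]
        times = outs[0][0]
        m1 = np.stack([o[1] for o in outs], axis=1)
        m2 = np.stack([o[2] for o in outs], axis=1)
        rejected = np.array([o[3] for o in outs])
        return EnsembleSummary(obs_times=times, m1=m1, m2=m2, rejected=rejected)
    times, m1, m2, rejected, _ = _run_vectorised(cfg, sched, obs_times, n_traj, rng)
    return EnsembleSummary(obs_times=times, m1=m1, m2=m2, rejected=rejected)
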