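"""Model configuration: developmental phase timeline and mechanism parameters.

The germline mtDNA population is modelled through six developmental phases
spanning conception (0 dpc) to the mature oocyte of the next generation
(conventionally 100 dpc).  The first two phases are cycling (cell divisions at
a fixed doubling time), the remaining four quiescent; the final phase carries
no mtDNA replication.  Each phase has its own per-molecule replication rate
``lambda`` and degradation rate ``nu`` (per day).

Three partitioning/replication mechanisms are supported:

``BDP``
    stochastic birth-death dynamics with binomial partitioning of individual
    molecules at each division (cluster size ``c = 1``);
``CAO``
    stochastic dynamics with clustered partitioning (``c >= 2`` molecules per
    segregating unit, homoplasmic by default);
``WAI_B``
    deterministic dynamics in which only a fraction ``alpha`` of molecules
    remains replication-competent after a cutoff time ``T``.

All times are carried in days post conception (dpc) and all rates per day;
hour-valued inputs (doubling times) are converted at parse time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "Phase",
    "PhaseSchedule",
    "MechanismConfig",
    "ConfigurationError",
    "build_schedule",
    "default_schedule",
    "default_bdp_config",
    "validate_config",
    "load_config",
    "save_config",
    "DEFAULT_BOUNDARIES",
    "DEFAULT_DOUBLING_TIMES_HR",
    "DEFAULT_LAMBDA",
    "DEFAULT_NU",
    "DEFAULT_M0",
    "DEFAULT_H0",
    "COPY_CAP",
]

COPY_CAP = 500_000

# Default developmental timeline: cycling with 7-hr doublings to 8.5 dpc,
# 16-hr doublings to 13.5 dpc, then four quiescent phases ending at 21, 30,
# 60 and t_final = 100 dpc (mature oocyte).
DEFAULT_BOUNDARIES = (0.0, 8.5, 13.5, 21.0, 30.0, 60.0, 100.0)
DEFAULT_DOUBLING_TIMES_HR = (7.0, 16.0)

# Default ground-truth rates (per day).  Chosen to reproduce the observed
# magnitudes of germline mtDNA dynamics: copy number falling from ~2e5 to a
# minimum of ~300 around 8.5 dpc, copy number staying low (~500-1000)
# through birth, recovery to ~2e5 by 60 dpc, and high random turnover while
# the population is small, so that normalised heteroplasmy variance stays
# low until ~7.5 dpc, reaches intermediate values (~0.1) by 21 dpc and
# becomes large (~0.25) in mature oocytes, with most of the rise occurring
# after the copy-number minimum.  See docs/methods.md.
DEFAULT_LAMBDA = (1.7, 1.2, 3.0449, 6.0396, 0.6596, 0.0)
DEFAULT_NU = (0.1, 0.1274, 3.0, 6.0, 0.5, 0.0)
DEFAULT_M0 = 200_000
DEFAULT_H0 = 0.3

MECHANISMS = ("BDP", "CAO", "WAI_B")
CLUSTER_CONTENTS = ("homoplasmic", "heteroplasmic_fixed", "heteroplasmic_mixing")


class ConfigurationError(ValueError):
    """Raised for invalid phase schedules or mechanism configurations."""


@dataclass(frozen=True)
class Phase:
    """One developmental phase with its mtDNA kinetic rates.

    ``lambda_w`` is the wildtype replication rate; the mutant rate is
    ``lambda_w + delta_lambda`` (see :class:`MechanismConfig`).  ``nu`` applies
    to both species.  ``n_divisions`` is derived from the phase duration and
    doubling time for cycling phases and is 0 for quiescent phases.
    """

    index: int
    kind: str  # "cycling" | "quiescent"
    lambda_w: float
    nu: float
    start_dpc: float
    end_dpc: float
    doubling_time: float | None = None  # days; cycling phases only
    n_divisions: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cycling", "quiescent"):
            raise ConfigurationError(f"phase {self.index}: unknown kind {self.kind!r}")
        if self.end_dpc <= self.start_dpc:
            raise ConfigurationError(
                f"phase {self.index}: end {self.end_dpc} <= start {self.start_dpc}"
            )
        if self.lambda_w < 0 or self.nu < 0:
            raise ConfigurationError(f"phase {self.index}: negative rate")
        if self.kind == "cycling":
            if not self.doubling_time or self.doubling_time <= 0:
                raise ConfigurationError(
                    f"phase {self.index}: cycling phase needs a positive doubling time"
                )

    @property
    def duration(self) -> float:
        return self.end_dpc - self.start_dpc

    def division_epochs(self) -> list[float]:
        """Absolute dpc times of the divisions inside this phase."""
        if self.kind != "cycling" or self.n_divisions == 0:
            return []
        dt = float(self.doubling_time)
        return [self.start_dpc + (k + 1) * dt for k in range(self.n_divisions)]


@dataclass(frozen=True)
class PhaseSchedule:
    """The ordered six-phase developmental timeline on [0, t_final] dpc."""

    phases: tuple[Phase, ...]
    t_final: float = 100.0

    def __post_init__(self) -> None:
        if len(self.phases) != 6:
            raise ConfigurationError(f"expected 6 phases, got {len(self.phases)}")
        prev_end = 0.0
        for ph in self.phases:
            if not math.isclose(ph.start_dpc, prev_end, abs_tol=1e-9):
                raise ConfigurationError(
                    f"phase {ph.index} starts at {ph.start_dpc}, expected {prev_end}"
                )
            prev_end = ph.end_dpc
        for ph in self.phases[:2]:
            if ph.kind != "cycling":
                raise ConfigurationError(f"phase {ph.index} must be cycling")
        for ph in self.phases[2:]:
            if ph.kind != "quiescent":
                raise ConfigurationError(f"phase {ph.index} must be quiescent")
        last = self.phases[-1]
        if last.lambda_w != 0.0:
            raise ConfigurationError("phase 6 must have zero replication rate")
        if self.t_final < last.start_dpc:
            raise ConfigurationError("t_final precedes the start of phase 6")
        if not math.isclose(last.end_dpc, self.t_final, abs_tol=1e-9):
            raise ConfigurationError("phase 6 must end at t_final")

    # -- queries ---------------------------------------------------------

    def phase_at(self, t: float) -> Phase:
        for ph in self.phases:
            if t < ph.end_dpc or math.isclose(t, ph.end_dpc):
                if t >= ph.start_dpc or math.isclose(t, ph.start_dpc):
                    return ph
        raise ConfigurationError(f"time {t} outside schedule [0, {self.t_final}]")

    def division_epochs(self) -> list[float]:
        out: list[float] = []
        for ph in self.phases:
            out.extend(ph.division_epochs())
        return out

    @property
    def total_divisions(self) -> int:
        return sum(ph.n_divisions for ph in self.phases)

    def total_turnover(self) -> float:
        """Total quiescent turnover  sigma = sum_i nu_i * tau'_i  (phases 3-6)."""
        return sum(ph.nu * ph.duration for ph in self.phases[2:])

    def with_rates(self, lambdas: Sequence[float], nus: Sequence[float]) -> "PhaseSchedule":
        """Return a copy of the schedule with new per-phase rates."""
        if len(lambdas) != 6 or len(nus) != 6:
            raise ConfigurationError("need 6 lambda and 6 nu values")
        phases = tuple(
            replace(ph, lambda_w=float(l), nu=float(n))
            for ph, l, n in zip(self.phases, lambdas, nus)
        )
        return PhaseSchedule(phases=phases, t_final=self.t_final)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "boundaries": [self.phases[0].start_dpc] + [p.end_dpc for p in self.phases],
            "doubling_times_hr": [p.doubling_time * 24.0 for p in self.phases[:2]],
            "lambda": [p.lambda_w for p in self.phases],
            "nu": [p.nu for p in self.phases],
            "t_final": self.t_final,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseSchedule":
        allowed = {"boundaries", "doubling_times_hr", "lambda", "nu", "t_final"}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown schedule keys: {sorted(unknown)}")
        return build_schedule(
            boundaries=d["boundaries"],
            doubling_times_hr=d["doubling_times_hr"],
            t_final=d.get("t_final", d["boundaries"][-1]),
            lambdas=d.get("lambda"),
            nus=d.get("nu"),
        )


@dataclass(frozen=True)
class MechanismConfig:
    """Mechanism choice plus its parameters and initial conditions.

    ``m0`` is the mtDNA copy number of the fertilised oocyte and ``h0`` its
    heteroplasmy; the initial mutant count is ``round(m0 * h0)``.
    ``delta_lambda`` is the replication-rate advantage of mutant over wildtype
    (selection); it applies in every phase with nonzero wildtype replication.
    """

    mechanism: str = "BDP"
    S: int = 1  # 1 = stochastic (Poisson) dynamics, 0 = deterministic
    alpha: float = 1.0  # replicating fraction after T_cutoff (WAI_B)
    T_cutoff: float = 0.0  # dpc at which the replicating subset is enforced
    c: int = 1  # cluster size at partitioning (0 = deterministic halving)
    cluster_content: str = "homoplasmic"
    m0: int = DEFAULT_M0
    h0: float = DEFAULT_H0
    delta_lambda: float = 0.0
    copy_cap: int = COPY_CAP

    @property
    def m2_0(self) -> int:
        """Initial mutant copy number."""
        return int(round(self.m0 * self.h0))

    @property
    def m1_0(self) -> int:
        """Initial wildtype copy number."""
        return self.m0 - self.m2_0

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "S": self.S,
            "alpha": self.alpha,
            "T_cutoff": self.T_cutoff,
            "c": self.c,
            "cluster_content": self.cluster_content,
            "m0": self.m0,
            "h0": self.h0,
            "delta_lambda": self.delta_lambda,
            "copy_cap": self.copy_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MechanismConfig":
        allowed = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown mechanism keys: {sorted(unknown)}")
        return cls(**d)

    # convenience constructors per mechanism ------------------------------

    @classmethod
    def bdp(cls, m0: int = DEFAULT_M0, h0: float = DEFAULT_H0, **kw) -> "MechanismConfig":
        return cls(mechanism="BDP", S=1, c=1, alpha=1.0, m0=m0, h0=h0, **kw)

    @classmethod
    def cao(
        cls, c: int = 50, m0: int = DEFAULT_M0, h0: float = DEFAULT_H0,
        cluster_content: str = "homoplasmic", **kw,
    ) -> "MechanismConfig":
        return cls(mechanism="CAO", S=1, c=c, alpha=1.0, m0=m0, h0=h0,
                   cluster_content=cluster_content, **kw)

    @classmethod
    def wai_b(
        cls, alpha: float = 0.006, T_cutoff: float = 21.0,
        m0: int = DEFAULT_M0, h0: float = DEFAULT_H0, c: int = 1, **kw,
    ) -> "MechanismConfig":
        # Deterministic dynamics; partition stochasticity defaults to binomial.
        return cls(mechanism="WAI_B", S=0, alpha=alpha, T_cutoff=T_cutoff,
                   c=c, m0=m0, h0=h0, **kw)


def build_schedule(
    boundaries: Sequence[float],
    doubling_times_hr: Sequence[float],
    t_final: float | None = None,
    lambdas: Sequence[float] | None = None,
    nus: Sequence[float] | None = None,
) -> PhaseSchedule:
    """Construct the six-phase schedule from phase boundaries.

    Parameters
    ----------
    boundaries
        Seven strictly increasing dpc values ``[0, b1, ..., b6]``; phase ``i``
        spans ``boundaries[i-1]`` to ``boundaries[i]``.
    doubling_times_hr
        Doubling times (in hours) of the two cycling phases.  The number of
        divisions in a cycling phase is ``floor(duration / doubling_time)``;
        any remaining partial cycle contributes birth-death dynamics but no
        division.
    t_final
        Observation horizon; defaults to the end of phase 6.
    lambdas, nus
        Per-phase replication/degradation rates (per day); default all zero.
    """
    boundaries = [float(b) for b in boundaries]
    if len(boundaries) != 7:
        raise ConfigurationError(f"need 7 boundaries for 6 phases, got {len(boundaries)}")
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ConfigurationError("boundaries must be strictly increasing")
    if len(doubling_times_hr) != 2:
        raise ConfigurationError("need doubling times for the two cycling phases")
    if any(dt <= 0 for dt in doubling_times_hr):
        raise ConfigurationError("doubling times must be positive")
    if t_final is None:
        t_final = boundaries[-1]
    lambdas = list(lambdas) if lambdas is not None else [0.0] * 6
    nus = list(nus) if nus is not None else [0.0] * 6
    if len(lambdas) != 6 or len(nus) != 6:
        raise ConfigurationError("need 6 lambda and 6 nu values")

    phases = []
    for i in range(6):
        start, end = boundaries[i], boundaries[i + 1]
        if i < 2:
            dt_days = doubling_times_hr[i] / 24.0
            ndiv = int(math.floor((end - start) / dt_days + 1e-9))
            phases.append(Phase(
                index=i + 1, kind="cycling", lambda_w=lambdas[i], nu=nus[i],
                start_dpc=start, end_dpc=end, doubling_time=dt_days,
                n_divisions=ndiv,
            ))
        else:
            phases.append(Phase(
                index=i + 1, kind="quiescent", lambda_w=lambdas[i], nu=nus[i],
                start_dpc=start, end_dpc=end,
            ))
    return PhaseSchedule(phases=tuple(phases), t_final=float(t_final))


def default_schedule(
    lambdas: Sequence[float] = DEFAULT_LAMBDA,
    nus: Sequence[float] = DEFAULT_NU,
) -> PhaseSchedule:
    """The default developmental timeline with the default rates."""
    return build_schedule(DEFAULT_BOUNDARIES, DEFAULT_DOUBLING_TIMES_HR,
                          lambdas=lambdas, nus=nus)


def default_bdp_config(m0: int = DEFAULT_M0, h0: float = DEFAULT_H0) -> MechanismConfig:
    return MechanismConfig.bdp(m0=m0, h0=h0)


def default_cao_truth(c: int = 50) -> tuple[MechanismConfig, PhaseSchedule]:
    """Ground truth for the clustered-partitioning story.

    Same mean copy-number trajectory as the default timeline, but with the
    heteroplasmy variance generated where this mechanism generates it — at
    the divisions, by segregating clusters of ``c`` molecules — rather than
    by random turnover, which is kept minimal throughout quiescence.
    """
    net = [l - n for l, n in zip(DEFAULT_LAMBDA, DEFAULT_NU)]
    nus = [DEFAULT_NU[0], DEFAULT_NU[1], 0.05, 0.05, 0.05, 0.0]
    lams = [DEFAULT_LAMBDA[0], DEFAULT_LAMBDA[1]] + \
        [r + nu for r, nu in zip(net[2:5], nus[2:5])] + [0.0]
    sched = build_schedule(DEFAULT_BOUNDARIES, DEFAULT_DOUBLING_TIMES_HR,
                           lambdas=lams, nus=nus)
    return MechanismConfig.cao(c=c), sched


def validate_config(cfg: MechanismConfig, sched: PhaseSchedule | None = None) -> list[str]:
    """Return a (possibly empty) list of invariant violations.

    Always returns a report rather than raising, so callers can surface every
    problem at once.
    """
    v: list[str] = []
    if cfg.mechanism not in MECHANISMS:
        v.append(f"mechanism: unknown mechanism {cfg.mechanism!r}")
        return v
    if cfg.S not in (0, 1):
        v.append(f"S: must be 0 or 1, got {cfg.S}")
    if not (0.0 < cfg.alpha <= 1.0):
        v.append(f"alpha: must be in (0, 1], got {cfg.alpha}")
    if cfg.c < 0:
        v.append(f"c: must be nonnegative, got {cfg.c}")
    if cfg.cluster_content not in CLUSTER_CONTENTS:
        v.append(f"cluster_content: unknown value {cfg.cluster_content!r}")
    if cfg.m0 <= 0:
        v.append(f"m0: must be positive, got {cfg.m0}")
    if not (0.0 <= cfg.h0 <= 1.0):
        v.append(f"h0: must be in [0, 1], got {cfg.h0}")
    if cfg.copy_cap <= 0:
        v.append(f"copy_cap: must be positive, got {cfg.copy_cap}")

    if cfg.mechanism == "BDP":
        if cfg.S != 1:
            v.append("S: BDP requires S=1")
        if cfg.c != 1:
            v.append("c: BDP requires c=1")
        if cfg.alpha != 1.0:
            v.append("alpha: BDP requires alpha=1")
    elif cfg.mechanism == "CAO":
        if cfg.S != 1:
            v.append("S: CAO requires S=1")
        if cfg.c < 2:
            v.append("c: CAO requires c>=2")
    elif cfg.mechanism == "WAI_B":
        if cfg.S != 0:
            v.append("S: WAI_B requires S=0")
        if not (cfg.alpha < 1.0):
            v.append("alpha: WAI_B requires alpha<1")
        if sched is not None and not (0.0 <= cfg.T_cutoff <= sched.t_final):
            v.append(f"T_cutoff: must lie in [0, {sched.t_final}], got {cfg.T_cutoff}")
    return v


# ---------------------------------------------------------------------------
# JSON configuration files: {"schedule": {...}, "mechanism": {...}, "seed": N}


def load_config(path) -> tuple[MechanismConfig, PhaseSchedule, int | None]:
    with open(path) as fh:
        d = json.load(fh)
    unknown = set(d) - {"schedule", "mechanism", "seed"}
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    sched = PhaseSchedule.from_dict(d["schedule"]) if "schedule" in d else default_schedule()
    cfg = MechanismConfig.from_dict(d.get("mechanism", {}))
    violations = validate_config(cfg, sched)
    if violations:
        raise ConfigurationError("; ".join(violations))
    return cfg, sched, d.get("seed")


def save_config(path, cfg: MechanismConfig, sched: PhaseSchedule,
                seed: int | None = None) -> None:
    d = {"schedule": sched.to_dict(), "mechanism": cfg.to_dict()}
    if seed is not None:
        d["seed"] = int(seed)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")
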