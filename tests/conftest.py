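import math

import numpy as np
import pytest

from mtbottleneck.config import (MechanismConfig, build_schedule,
                                 default_schedule)


@pytest.fixture(scope="session")
def default_truth():
    """The default ground-truth parameterisation used by the generator."""
    return MechanismConfig.bdp(), default_schedule()


@pytest.fixture(scope="session")
def mini_system():
    """A small-copy-number BDP system cheap enough for exact enumeration.

    Three divisions at constant mean copy number, then quiescent turnover;
    40 founders at 10% heteroplasmy give appreciable mutant-fixation mass.
    """
    sched = build_schedule(
        [0, 3, 4, 6, 7, 8, 10], [24, 48],
        lambdas=(0.9, 0.2, 0.2, 0.2, 0.2, 0.0),
        nus=(0.207, 0.2, 0.2, 0.2, 0.2, 0.0),
    )
    cfg = MechanismConfig.bdp(m0=40, h0=0.1)
    return cfg, sched, 9.0  # evaluation time (dpc)


def random_bdp_parameterisation(rng):
    """Draw a random biologically-bounded BDP parameterisation.

    Log-mean copy anchors at the phase boundaries follow a bounded random
    walk (fall through the cycling phases, recovery after), which fixes the
    net growth rates; turnover magnitudes are drawn log-uniformly and the
    replication rates set to net growth plus turnover.  Mean copy number
    stays within [~200, 3e5] so ensemble statistics are well defined.
    """
    sched = default_schedule()
    m0 = int(round(10 ** rng.uniform(3.4, 4.5)))
    bounds = [p.end_dpc for p in sched.phases]
    anchors = [math.log(m0)]
    anchors.append(anchors[0] + math.log(10) * rng.uniform(-1.0, -0.3))
    for _ in range(3):
        anchors.append(min(anchors[-1] + math.log(10) * rng.uniform(0.0, 0.5),
                           math.log(3e5)))
    anchors.append(anchors[-1])  # stable after 30 dpc
    anchors.append(anchors[-1] + math.log(10) * rng.uniform(-0.1, 0.0))
    lambdas, nus = [], []
    prev_t, prev_a = 0.0, anchors[0]
    for ph, a in zip(sched.phases, anchors[1:]):
        r = (a - prev_a + ph.n_divisions * math.log(2.0)) / ph.duration
        nu = 10 ** rng.uniform(math.log10(0.05), math.log10(1.5))
        lam = r + nu
        if lam < 0.01:
            nu += 0.01 - lam
            lam = 0.01
        if ph.index == 6:
            lam, nu = 0.0, max(-r, 0.0)
        lambdas.append(lam)
        nus.append(nu)
        prev_a = a
    cfg = MechanismConfig.bdp(m0=m0, h0=0.3)
    return cfg, sched.with_rates(lambdas, nus)


def variance_se(x, axis=-1):
    """Standard error of the sample variance via the fourth central moment."""
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    mu = np.nanmean(x, axis=axis, keepdims=True)
    m4 = np.nanmean((x - mu) ** 4, axis=axis)
    s2 = np.nanvar(x, axis=axis, ddof=1)
    return np.sqrt(np.maximum(m4 - (n - 3) / (n - 1) * s2 ** 2, 0.0) / n)
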