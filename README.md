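# mtbottleneck

Stochastic modelling and Bayesian inference of the germline mitochondrial
DNA bottleneck.

A fertilised oocyte carries ~2×10⁵ mtDNA molecules, some fraction of which
(the heteroplasmy, `h = m2/(m1+m2)`) may be mutant.  During germline
development the per-cell mtDNA population collapses and recovers — the
*bottleneck* — and the population of next-generation oocytes acquires a
spread of heteroplasmies from a single starting value.  How that variance
arises (drift at a low copy-number minimum, segregation of mtDNA clusters
at cell divisions, or replication of a small subset of molecules) has been
a long-running debate, and the answer controls clinical quantities: the
probability a child's heteroplasmy crosses a disease threshold, and what an
early embryonic biopsy says about the embryo.

This package is for quantitative biologists working on mtDNA population
dynamics.  It provides:

* a bottom-up model of a germline lineage: wildtype/mutant copy numbers
  `(m1, m2)` evolving by per-molecule replication (rate λ) and degradation
  (rate ν) through six developmental phases (two cycling, with divisions
  every 7 h then 16 h; four quiescent), partitioned at each division either
  deterministically, binomially, or in clusters of `c` molecules, with an
  optional replication-competent subset fraction α after a cutoff time —
  expressing the competing bottleneck mechanisms (`BDP`, `CAO`, `WAI_B`) in
  one parameterisation;
* exact stochastic simulation (event-driven, plus a closed-form
  interval sampler that makes 10⁴-trajectory ensembles at full copy number
  routine);
* analytic moment theory: E(m), V(m) by exact per-founder propagation,
  heteroplasmy moments E(h), V(h) and the normalised variance
  `V′(h) = V(h)/(E(h)(1−E(h)))`, the selection sigmoid
  `E(h) = 1/(1+((1−h0)/h0)e^{−Δλt})`, fixation probabilities ζ₁, ζ₂ by
  generating-function composition, and the truncated-Normal + fixation-mass
  approximation of the full heteroplasmy distribution, validated against
  exact enumeration;
* approximate Bayesian computation against developmental measurement
  tables (mean copy number and V′(h) per time point with sample sizes),
  with sample-size-matched summary statistics, Metropolis best-fit search,
  ABC-MCMC posteriors (derived summaries: minimum mean copy number and the
  total quiescent turnover σ = Σ νᵢτ′ᵢ), and ABC model selection across the
  three mechanisms;
* clinical calculators: threshold-crossing probability
  `P(h > h*) = (1−ζ₁−ζ₂)(1 − ½(1+erf((h*−E(h))/√(2V(h))))) + ζ₂` and the
  preimplantation-sampling posterior `P(h0 | h_m)` under a uniform prior;
* a synthetic-measurement generator with known ground truth, used by every
  inference test.

## Worked example

```python
import mtbottleneck as mb
from mtbottleneck.moments import (het_distribution, moment_trajectory,
                                  pgd_posterior, threshold_crossing)

cfg = mb.MechanismConfig.bdp(h0=0.3)   # binomial birth-death-partition
sched = mb.default_schedule()          # six phases, 36 divisions, 100 dpc

sched.total_turnover()                 # sigma = sum nu_i * tau'_i = 91.5
print(moment_trajectory(cfg, sched, [8.5, 21.0, 100.0]))
#  t_dpc         E_m          V_m  E_h    V_h  Vprime_h
#    8.5    300.3067 1.343236e+03  0.3 0.0031    0.0149
#   21.0    701.0114 5.766797e+04  0.3 0.0246    0.1174
#  100.0 120201.4237 3.678187e+09  0.3 0.0535    0.2546

hd = het_distribution(cfg, sched, 100.0)
threshold_crossing(hd, 0.6)            # 0.0914
post = pgd_posterior(0.4, 30.0, cfg, sched)
post.mean(), post.credible_interval()  # 0.4413, (0.105, 0.819)
```

Read: copy number bottoms out at E(m) ≈ 300 at 8.5 dpc and recovers to
1.2×10⁵ in the mature oocyte, while the normalised heteroplasmy variance
climbs from 0.015 to 0.25 — mostly after the copy-number minimum, driven by
random turnover.  A cell starting at 30% mutant load has a 9.1% chance of
exceeding the 60% disease threshold by 100 dpc; a biopsy reading
h_m = 0.4 at 30 dpc leaves a wide posterior (0.10–0.82) on the embryo's
initial heteroplasmy, because variance accrued before the sampling time.

Fitting a mechanism to a measurement table:

```python
from mtbottleneck import GermlineBottleneckModel

model = GermlineBottleneckModel.from_csv("measurements.csv", mechanism="BDP")
res = model.fit(n_accept=200, seed=1)  # annealed search + ABC-MCMC
print(res.summary())                   # rates, m0, min E(m), sigma with CIs
res.conf_int("sigma")                  # credible interval on total turnover
```

The measurement CSV schema (`source,t_dpc,statistic,value,n`) is documented
in `mtbottleneck/templates/literature_template.csv`, a transcription
template for published developmental datasets.  A command-line interface
(`mtbottleneck simulate|fit|select|clinic|synth`) wraps the same
functionality; see `mtbottleneck --help`.

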