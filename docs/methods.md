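# Methods

## The model

A single germline lineage is followed from the fertilised oocyte (0 days
post conception, dpc) to the mature oocyte of the next generation
(conventionally placed at 100 dpc).  The cell carries `m1` wildtype and `m2`
mutant mtDNA molecules; heteroplasmy is `h = m2/(m1+m2)`.  Development is
divided into six phases, each with its own per-molecule replication rate
λᵢ and degradation rate νᵢ (per day).  The first two phases are cycling —
cell divisions every 7 h until 8.5 dpc, then every 16 h until 13.5 dpc
(29 + 7 = 36 divisions with the default timeline) — and the remaining four
are quiescent, with the final phase carrying no replication.  The number of
divisions in a cycling phase is `floor(duration / doubling time)`; the
leftover partial cycle contributes dynamics but no division.

Three competing partitioning/replication mechanisms are expressed in one
parameterisation:

* **BDP** (birth–death–partition): Poisson replication/degradation of every
  molecule (`S = 1`) and independent binomial partitioning at divisions
  (`c = 1`).
* **CAO** (clustered partitioning): as BDP, but molecules segregate in
  clusters of `c ≥ 2` (homoplasmic by default; heteroplasmic cluster
  content with or without re-mixing is also implemented).
* **WAI_B** (subset replication): deterministic dynamics (`S = 0`), with
  replication restricted after a cutoff time `T` to a randomly chosen
  (hypergeometric) fraction α of molecules; offspring inherit competence.

Selection enters as a replication-rate differential Δλ for the mutant
(applied wherever wildtype replication is nonzero); degradation is shared.
Copy number is capped at 5×10⁵ throughout development; a trajectory that
would exceed the cap is flagged rejected.

Initial conditions are the copy number `m0` of the fertilised oocyte and
its heteroplasmy `h0` (initial mutant count `round(m0·h0)`).

## Simulation

Within a phase each species is a linear birth–death process.  Two engines
sample it:

* an event-driven stochastic simulation algorithm (per-molecule events),
  exact at every event but only practical for small populations;
* exact interval sampling: over an interval with constant rates the
  transition law is known in closed form — each founder's clan survives
  with probability `1−a` and, given survival, has geometric size with
  parameter `b` — so the end-of-interval state is drawn as a binomial
  survivor count plus a negative-binomial excess.  This samples the same
  Markov jump process exactly at every segment endpoint (segments are cut
  at phase boundaries, division epochs and observation times, where rates
  are piecewise constant) and makes 10⁴-trajectory ensembles at 2×10⁵
  copies per cell routine.  At negative-binomial means beyond 10¹² (far
  beyond the copy cap, reachable only by parameterisations that are then
  rejected) the sampler switches to the normal limit.

The two engines are cross-checked in the test suite.  Partition draws:
deterministic halving rounds half-to-even per species (real-valued counts
are halved exactly when both dynamics and partitioning are deterministic);
binomial partitioning thins each species `Binomial(m, 1/2)`; homoplasmic
clusters thin `c·Binomial(m//c, 1/2)` plus a Bernoulli remainder cluster;
heteroplasmic clusters with re-mixed content are sampled through their
exact marginal (by exchangeability, retaining `J` of the random clusters is
in law a uniform random subset of size `cJ`, so the mutant share is
hypergeometric); frozen heteroplasmic clusters are simulated as explicit
per-cluster subpopulations.  The followed lineage keeps one daughter per
division; the discarded daughter is never simulated.

## Analytic theory

Per-founder moments propagate exactly through the same segment plan: a
phase multiplies the mean by `e^{(λ−ν)d}` and maps the variance to
`σ²e^{2(λ−ν)d} + μ((λ+ν)/(λ−ν))e^{(λ−ν)d}(e^{(λ−ν)d}−1)` (the critical
limit `σ² + 2λμd` is used when |λ−ν| < 10⁻⁸/day); a division maps
`(μ, σ²) → (μ/2, σ²/4 + cμ/4)` with `c = 0` for deterministic halving.
This iterated recursion is algebraically equivalent to the closed-form
product expression for the mean (which is also implemented independently
and agrees to machine precision) and replaces the lengthy closed-form
variance prefactor; it is validated against simulation instead.
Heteroplasmy moments come from the second-order expansion of the ratio
`m2/(m1+m2)`; the normalised variance is `V′(h) = V(h)/(E(h)(1−E(h)))`.
Under selection the mean follows the sigmoid
`E(h) = 1/(1 + ((1−h0)/h0) e^{−Δλ t})`, which the moment pipeline
reproduces exactly.

Fixation probabilities (mass at `h = 0` and `h = 1`) are computed for the
BDP mechanism by composing, backwards through the schedule, each segment's
single-founder birth–death probability generating function with the
binomial-thinning PGF `(1+s)/2` at each division, and evaluating at
`s = 0`; species independence then gives the masses from the founder
counts.  The same composed PGF, evaluated on the unit circle and inverted
by FFT, yields the exact copy-number law of small systems, from which the
exact heteroplasmy distribution is enumerated — this is the oracle against
which the truncated-Normal approximation is tested (total variation ≲ 0.04
on the reference small system).  For non-binomial mechanisms fixation is
estimated by simulation.

The full heteroplasmy law is approximated by a mixture: fixation masses at
the endpoints plus a [0,1]-truncated Normal whose two parameters are found
numerically (least squares on (μ, log σ), tolerance ~10⁻¹⁰) so that the
mixture reproduces the model's E(h) and V(h).  When the requested variance
exceeds what the family supports at that mean, the nearest-feasible fit is
returned and flagged.  The threshold-crossing probability uses the printed
erf form with the raw moments E(h), V(h) by default (a flag substitutes the
fitted truncated-Normal tail — the two differ slightly because the erf form
ignores truncation).  The preimplantation-sampling posterior places a
uniform prior on embryonic heteroplasmy and evaluates the mixture
likelihood of the measurement on an h₀ grid (fixation masses handle
measurements of exactly 0 or 1), normalising by trapezoidal quadrature;
per-founder statistics are computed once and rescaled across the grid.
The distribution-comparison transform
`h′ = −ln|(1/h − 1)·E(h)/(1−E(h))|` maps `h = E(h)` to 0 and is monotone.

## Measurements, synthetic data, and the distance

Observed data are per-time-point statistics: mean copy number or
normalised heteroplasmy variance, each with the number of cells it was
computed from.  Mature oocytes carry the 100 dpc convention.  The
synthetic generator simulates independent surviving cells (extinct
lineages are resampled, with a count reported) under a known ground truth
and emits both summary statistics and raw per-cell heteroplasmies, with a
truth sidecar.

The default ground truth was chosen once to emulate the reported magnitudes
of mouse germline development: `m0 = 2×10⁵`, `h0 = 0.3`, copy number
falling to a minimum of ≈300 at 8.5 dpc, staying low (≈500–1000) through
birth, recovering to ≈1.2×10⁵ by 60 dpc, and strong random turnover while
the population is small (σ = Σ νᵢτ′ᵢ = 91.5 over the quiescent phases), so
that V′(h) is low (≈0.02) before 7.5 dpc, intermediate (≈0.1) by 21 dpc and
large (≈0.25) in mature oocytes, with most of the rise after the copy
minimum.  The default observation design samples copy means (n = 5 cells)
through development and V′(h) from oocyte sets of 40 cells at ages spanning
13.5–61 dpc plus the mature-oocyte point.  The clustered-partitioning
ground truth (`default_cao_truth`) keeps the same mean trajectory but
generates its variance at divisions (c = 50) with minimal turnover, as that
mechanism's own story requires.  What the generator does *not* emulate:
litter structure and between-animal variation, measurement (qPCR) error on
individual heteroplasmies, and any feedback control of copy number — so
passing tests demonstrate correctness of the inference machinery under the
model, not robustness to those real-data features.

Simulated statistics are sample-size matched: for each observed record the
matching statistic is recomputed from a random subset of the trajectory
ensemble of exactly the record's size, so the sampling noise of small-n
variance estimates (which systematically understate population variance)
enters the simulated summaries the same way it enters the data.  The
distance is a weighted sum of squared residuals over log₁₀ copy means and
V′ values.  Weights default to inverse sampling variances per record —
log-copy records are assigned a fixed 0.1-decade sampling scale, V′ records
the normal-theory variance `2V′²/(n−1)` — so each record contributes O(1)
at the truth and every record is individually constraining.  (Weighting by
the across-record spread instead makes the copy term inert — being a decade
off costs almost nothing when the trajectory itself spans decades — and
lets low-copy/low-turnover imposters through.)  Records whose simulated
statistic is undefined (all-extinct subsamples) contribute a fixed maximal
penalty (5 decades / 2.0 V′ units); residuals are capped at the same
penalty.  Only the copy cap is an absolute constraint: a parameterisation
whose ensemble rejection fraction exceeds a configurable threshold is
discarded with infinite distance (library default 0: any rejection; the
fitting pipeline tolerates 1%, since at ensembles of 200 even the ground
truth occasionally produces one tail trajectory).

## Inference

Priors are uniform: per-phase rates on [10⁻⁴, 10]/day (linear scale — a
log-uniform rate prior concentrates essentially all mass at negligible
turnover and predetermines the answer), `m0` on [10⁴, 5×10⁵], cluster size
on [2, 200]; the replicating fraction α is log-uniform on [10⁻⁴, 0.9] (a
scale-free proportion) and the cutoff `T` uniform on [8.5, 80] dpc.
Phase-6 replication is pinned at zero and `h0` is fixed to the data's mean
heteroplasmy rather than inferred.

Because draws from these wide priors essentially never produce a
data-consistent trajectory, fitting proceeds in two stages:

1. **Best-fit search.**  Independent annealed Metropolis chains (target
   `exp(−D/T)`, temperature decaying geometrically from a quarter of the
   median start distance to a warm floor) start from *moment-matched*
   parameterisations: the observed copy records pin each phase's net
   growth rate by log-linear interpolation, turnover magnitudes are drawn
   from stratified log-ranges across chains (0.02–0.25, 0.25–1.2, 1.2–4,
   4–10 per day) so the chains bracket the weakly identified
   constant-net-growth ridge, and replication rates are set to net growth
   plus turnover.
2. **ABC-MCMC.**  The threshold is calibrated to the fit's own noise floor
   — a parameterisation's distance fluctuates between re-simulations, so ε
   defaults to 2.5× the 95th percentile of the best fit's re-evaluated
   distances (no threshold below that floor is meaningful).  Each polished
   start seeds an ABC-MCMC chain that accepts proposals whose freshly
   simulated distance stays below ε; recorded samples are thinned chain
   states pooled across chains.

The proposal kernel is a symmetric mixture: a small move of every
coordinate, a large move of one random coordinate, and a joint additive
move of one phase's (λ, ν) pair — the direction that changes turnover at
fixed net growth, without which chains cannot traverse the σ ridge.  The
additive component carries the proper Metropolis–Hastings prior correction
for any log-scaled coordinate it touches.  In the ε → ∞ limit the chain
provably samples the prior (tested by Kolmogorov–Smirnov comparison).

Each posterior sample carries two derived summaries: the minimum mean copy
number over development (from the analytic mean on a dense grid) and the
total quiescent turnover σ = Σᵢ₌₃..₆ νᵢτ′ᵢ (e.g. 0.1/h sustained for 30
days gives σ = 0.1·24·30 = 72).

**Model selection** is rejection ABC with a uniform model indicator and a
decreasing threshold sequence (quantiles of the pooled draw distances).
Each draw's kinetic rates come from the same moment-matching construction
for every mechanism — identical across models, hence exchangeable with
equal prior mass — because raw wide-prior draws never reach the fitting
region and comparing them measures only which mechanism's penalties are
least absurd.  A plain-prior mode is retained.

**Predictive verification** splits sampled oocyte groups alternately in
time into train/test halves, simulates posterior-predictive cells at each
test group's age, and reports the fraction of withheld cells outside the
central 95% band of the mean-standardised transform plus a two-sample
Anderson–Darling p-value per group (scipy's test).

## Numerical choices and scaled-down problem sizes

Default experiment sizes are chosen for desk-scale reproducibility:
proposal ensembles of 200 trajectories, 200 accepted samples per fit, four
chains, 330 search iterations; model selection uses 3000 draws.  The
recovery study runs 20 replicate synthetic datasets; the spread-shrinkage
comparison 4.  Verification ensembles (analytic-vs-simulation, fixation)
use 10⁴–10⁵ trajectories.  Statistical tolerances in the tests follow the
estimator: 3 standard errors for moment comparisons (fourth-moment-based
standard errors for variances), binomial standard errors for frequencies.

Known limitations: heteroplasmy moments are a second-order expansion
(relative error ~(CV)², noticeable below ~100 copies); the truncated-Normal
mixture degrades when the continuous part is strongly bimodal; analytic
variance is unavailable for heteroplasmic clusters and for an active
subset restriction (simulation is used); the generating-function fixation
route requires binomial partitioning; ABC posteriors at ε well above the
noise floor are over-dispersed relative to the exact posterior, which is
the conservative direction for credible intervals.
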