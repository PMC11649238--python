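# Methods

## Model family

The package models binary population activity patterns **x** ∈ {0,1}ⁿ
(rows of a spike raster, one 20 ms bin each; the bin width is metadata
and enters no computation) with the Gibbs distribution

    p(x) = exp(−E(x)) / Z,    E(x) = Σ_i λ_i f_i(x),
    f_i(x) = σ(Σ_j a_ij x_j − θ_i).

This is the maximum-entropy distribution constrained on the means of the
projections f_i. Two nonlinearities are supported: the Heaviside step
(the classical random-projection choice) and the sigmoid
σ(u) = 1/(1+e^(−βu)), which interpolates between an independent
population model (β→0: every f_i is the constant 1/2, so the energy is
pattern-independent) and the Heaviside model (β→∞). Only the sigmoid is
differentiable in the weights, so reshaping requires it.

Conventions fixed once and used everywhere:

- Heaviside boundary **H(0) = 1**. For continuous N(1,1) weights the
  event u = 0 has measure zero; any fixed convention works, this one is
  documented and applied consistently (including in the closed-form
  two-neuron fixture, where it determines Z = 2).
- **Natural log** (nats), reported per sample. The uniform model scores
  −n·ln 2.
- **Gradient signs.** With p ∝ exp(−Σλf), the likelihood derivatives are
  dL/dλ_i = ⟨f_i⟩_model − ⟨f_i⟩_data and
  dL/da_ij = λ_i(⟨σ′_i x_j⟩_model − ⟨σ′_i x_j⟩_data),
  σ′(u) = βσ(u)(1−σ(u)). Both are *ascent* directions with the matching
  fixed point (model marginals = data marginals); both are verified
  against finite differences of the exact likelihood to ~1e−9 in the
  test suite.
- **Enumeration cap n ≤ 20** (2²⁰ ≈ 1.05M states) defines the regime in
  which Z, likelihoods and expectations are computed exactly and serve
  as the oracle for the samplers and trainers.

## Projection construction

Each of m projections connects to each neuron independently with
probability indegree/n (indegree = 5 by default; indegree = n gives the
fully connected mask). Rows that come out empty are redrawn — a
projection with no inputs is a constant and carries no constraint.
Nonzero weights are N(1,1) signed as drawn; thresholds are 1.

## Sampling and partition-function estimation

Metropolis–Hastings with uniformly chosen single-neuron flips; a
proposal x→x′ is accepted with min(1, exp(E(x)−E(x′))). Defaults:
burn-in 10·n flips, thinning n flips (one expected update per neuron
between retained samples). Preactivations are maintained incrementally,
so one flip costs O(m). The chain is a numba kernel seeded explicitly;
identical seeds give identical rasters. An acceptance rate below 1% is
logged as a slow-mixing warning.

ln Z for populations above the cap is estimated by annealed importance
sampling from the uniform distribution (ln Z₀ = n ln 2) along an
inverse-temperature ladder: rung 0 at t = 0, then geometric spacing from
1e−3 to 1 (default 100 rungs), a few MH sweeps per rung. The reported
standard error is a bootstrap over per-chain importance weights. Because
the ln-of-mean estimator is downward-biased when weight variance is
high, cross-validation against enumeration uses a finer ladder
(160 rungs, 4 sweeps, 128 chains); at λ = 0 the estimate is exact by
construction.

## Training

All three modes share one gradient-ascent loop (momentum, default
lr 0.25 and momentum 0.9, or Adam), full-batch data expectations
(computed once on the unique-pattern reduction of the raster), and
model expectations either exact (enumeration) or from a persistent MH
chain refreshed each iteration (PCD-style).

Convergence is declared when every projection's model marginal lies in
the two-sided Clopper–Pearson interval of its empirical marginal, at
ci_level 0.6827 — the two-sided Gaussian 1-SD coverage. The interval is
computed from Beta quantiles; sigmoid marginals give non-integer
"success counts" ⟨f⟩·N, to which the same Beta formula applies
unchanged. Coverage at p = 0.3, N = 1000 is 67.6–68.3% in simulation.

Reshaping updates only the nonzero weights (the mask never changes) and
holds λ fixed, at 1 by default — a good operating point for the
projection counts used here, though the optimum shifts with m.
Threshold tuning (∂σ/∂θ = −σ′) is available but off by default; it has
a small effect on likelihood. Constraints act through the
reparameterization a = g(ã): normalization (row/column/total
Σ|a| = φ) or clipping (|a| ≤ ω), with gradients pulled back to ã by the
exact chain rule. Subgradient conventions: sign(0) = 0 in the
normalizing kinds; the clip derivative is 1 on |ã| ≤ ω and 0 outside.
Each homeostatic budget holds to machine precision after every
iteration because the model only ever sees g(ã). The initial model is
likewise g(ã₀), i.e. the raw random weights normalized onto the
constraint surface — strengthening one synapse then necessarily weakens
the others sharing its budget.

λ-training is convex and monotone for small steps; reshaping and
backprop are non-convex and a local optimum is accepted.

## Synthetic data

No recordings ship with the package, so ground-truth models are
constructed directly in the regime of 20 ms-binned cortical rasters:
sparse projections (indegree 5) with λ = λ_scale·|N(0,1)|, which carry
weak pairwise correlations, plus — when the raw draw misses the target
rate range — one single-input "field" projection per neuron (identity
mask, weight 2, threshold 1) whose λ is adjusted by damped logit
matching until every per-neuron rate falls in the target range,
(0.01, 0.15) per bin by default. A global λ rescaling alone cannot do
this at n ≈ 10–20: per-neuron rates under a shared energy scale spread
from ~0 to ~0.5. The fields keep the model inside the RP family (they
are legitimate single-input projections). `target_rate_range=None`
skips the adjustment and returns the pure sparse RP model; the
connectivity experiments use this so that the generator's mask is a
plain indegree-5 random mask, structurally comparable to the
independently drawn one.

What the generator emulates: sparse per-bin firing, weak correlations,
stationarity. What it does not: refractoriness, burst structure,
nonstationary rates, stimulus locking, spatial topology. Tests passing
on these rasters therefore validate the machinery (estimators,
constraints, orderings between model classes), not the models' adequacy
for any particular real recording.

Rasters are drawn by MH and split into disjoint train/test segments,
4:1 by default (the 160k/40k convention).

## Experiment scales and design choices

The figure-level experiments run at desk scale: 10 neurons, 12–40
projections, 30k training / 7.5k test samples, 6–20 replicate seeds
(the original analyses used 100 groups of 50 neurons, 150 projections
and 200k samples). Specific choices:

- **Sampler/AIS cross-validation**: 20 models (n = 6–12), 40k samples
  thinned at 2n flips; standard errors by batch means over 40 batches —
  long enough batches to absorb autocorrelation, enough of them that the
  t-tails of the SE estimate are near-normal. With ~400 simultaneous
  marginal comparisons an isolated 3-SE excursion is expected under a
  correct sampler, so agreement is asserted as ≥99% of marginals within
  3 SE and none beyond 5 SE; AIS is held to 3·SE per model.
- **Class comparison** (RP vs reshape vs backprop): the backprop-vs-
  reshape margin is assessed on class means across seeds; per-seed the
  non-convex reshape variance occasionally inverts it.
- **Homeostatic vs bounded**: matched available budget at 40% of the
  initial set's total weight (scarce regime); φ = B/m, ω = B/#synapses.
- **Rate homeostasis**: β = 6 and φ ∈ {1, 3, 6} with 40 projections.
  The steep slope puts projections in the sparse-firing regime (the
  sigmoid floor σ(−β) must sit well below the working rates; at β = 2
  the floor is ≈0.12 and masks the narrowing of the rate distribution).
  40 projections give the across-projection SD enough resolution to
  show its monotone decrease with tighter φ.
- **Connectivity robustness**: homeo_input(φ=1) reshaping from the
  generator's mask, an independent sparse mask, and the full mask; the
  true-vs-random gap is measured on across-seed mean test LL.

## Known limitations

- Exact training is limited to n ≤ 20; beyond that, expectations come
  from MCMC and the likelihood trajectory is not tracked (AIS evaluates
  the final model instead).
- The bounded constraint freezes ã once |ã| > ω (exact subgradient 0),
  so a saturated synapse re-enters only if momentum carries it back.
- Clopper–Pearson applied to sigmoid marginals is heuristic (they are
  means of bounded values, not binomial counts); it serves as a
  per-projection stopping rule, not a calibrated test.
- AIS standard errors do not include annealing bias; use a finer ladder
  when the estimate feeds a downstream comparison.
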