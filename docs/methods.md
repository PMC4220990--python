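# Methods

This note documents the model implemented by `cssmkit`, the assumptions it
makes, the parameter defaults and why they were chosen, what the synthetic
data generator emulates, the numerical choices, and the known limitations.

## 1. Symbolic domain and transition system

A domain consists of typed object sets, *slots* (state variables with
finite value domains, optionally bounded integers), and *action schemata*
with parameters, preconditions (`==`, `<=`, `>=` atoms over slots), and
effects (`:=`, `+=`, `-=`). Grounding substitutes objects for parameters,
producing a deterministic labeled transition system over states represented
as canonical value tuples. Each schema carries an *action class* label —
the recognition target — so several ground actions (e.g. `put(cup)`,
`put(plate)`) share one class. A `wait` action (its own class) is always
applicable and acts as the identity; it models idle time and absorbs the
goal state.

Reachability analysis is a plain BFS with an exploration cap; goal
distances are unweighted shortest paths to the nearest goal state computed
on the reversed graph (wait self-loops excluded, unreachable states get
infinite distance). The *restricted* distance recomputes shortest paths on
the subgraph induced by a set of previously visited states, emulating a
heuristic trained only on observed behavior; the *script* feature maps
states to the remaining-steps value of the first matching entry of an
ordered condition list — a deliberately coarse, partially wrong heuristic.

## 2. Durations and hazard-based termination

Each class has a duration model. Parametric families: lognormal `(mu,
sigma)`, gamma `(shape, scale)`, Weibull `(shape, scale)`, exponential
`(rate)`, and a Cauchy truncated to positive support and renormalised (for
heavy-tailed durations); plus an empirical distribution (atoms with
weights). Between observation times `t` and `t+dt` an action started at
`st` terminates with hazard `q = (F(e+dt) - F(e)) / (1 - F(e))` at elapsed
time `e = t - st`. The per-step survival factors telescope, so the product
over steps reproduces the survival function exactly — a property the test
suite checks to 1e-9. When the remaining survival mass underflows the
hazard is defined as 1 (forced termination) to avoid 0/0.

Fitting is maximum likelihood (closed form where available, numerical
optimisation otherwise). `select_family` fits every candidate, reports
log-likelihood and Kolmogorov–Smirnov diagnostics, and picks the
maximum-likelihood family; it requires at least 8 samples and flags exact
ties.

## 3. Behavior model and simulator

On termination in state `s`, the successor action is drawn over the
applicable actions (wait included). The inference-side default is the
Boltzmann heuristic `p(a|s) ∝ exp(-λ h(apply(s, a)))`; `λ = 0` gives the
uniform policy. Infinite distances (livelocks, or states outside the
restricted subgraph) are capped at one more than the largest finite value
so the policy remains defined everywhere. The *simulator* deliberately
uses a different family — ε-greedy over the same distance (default
ε = 0.15) — so the inference heuristic never matches the generating
policy exactly; recognition must be robust to policy mismatch. Effects
apply at action start; each simulated segment spans
`max(1, round(duration · frame_rate))` frames; a run ends when the goal
holds (a final wait segment is appended) or a frame horizon is hit.

## 4. Observation models and the synthetic generator

Feature extraction turns multi-channel signals into windowed frames of six
statistics per channel (mean, variance, skewness, excess kurtosis, peak
absolute value, mean energy), optionally standardised and PCA-reduced.
Class-conditional observation models are full-covariance Gaussians (QDA)
with a small default covariance shrinkage of `1e-6 · trace/dim`. The
location-sensor model observes chosen slots through a categorical
confusion channel: correct with probability `1 - ε`, otherwise uniform
over the wrong values.

The synthetic generator emulates segment-structured sensor data: class
means are placed at `separation`-scaled random unit directions in feature
space with isotropic noise `σ` (default 1). The default `separation = 2.5`
was calibrated by Monte Carlo against the generating model itself to give
a frame-wise Bayes error of roughly 0.27 for the ten classes of the small
kitchen domain — hard enough that temporal models have room to improve on
frame-wise classification, easy enough that all methods stay usable. An
optional within-run *drift* adds a deterministic offset
`drift · 4(p - ½)² · u` at normalised run position `p` along a per-run
random unit direction `u`, creating non-i.i.d. within-segment structure
that within-class *scrambling* (a label-preserving permutation) destroys;
classifiers that treat frames as i.i.d. are invariant to scrambling by
construction.

## 5. Inference

The hidden state is the triple `x = (s, a, st)`: LTS state (already
containing the running action's effects), running ground action, and start
time. Start times are restricted to the observation grid, which maximises
hypothesis merging. The prediction step branches every hypothesis into
continuation (weight `1 - q`) and termination into each
positive-probability successor (`q · p(a'|s)`); the update step multiplies
by the observation likelihood (class-keyed Gaussian via the running
action's class, or state-keyed location likelihood).

- **Marginal filter**: duplicate successors are merged by summation
  (log-space `logsumexp`), the Bayes update is applied, the evidence
  increment is recorded *before* pruning, and the top-K entries by
  posterior weight are kept and renormalised (ties broken by a canonical
  state key for determinism). Links between retained entries form a
  lattice; smoothing is a backward recursion on that lattice (exact when
  nothing is pruned) and the MAP decoder is the max-product analogue with
  backpointers. With one-frame durations, a tabular policy equal to an HMM
  transition matrix, and class-keyed Gaussians, the filter reduces exactly
  to the HMM forward pass (checked to 1e-10 in the tests).
- **Particle filter**: bootstrap proposal from the same kernel, likelihood
  weighting, effective sample size `1/Σw²`, systematic resampling when the
  ESS drops below a threshold (default N/2). Propagation is grouped by
  running class (hazards) and current state (selection rows) for
  vectorisation.

Per-step *representation accounting* reports the number of distinct LTS
states and distinct hypotheses, normalised by the capacity (K or N).
Duplicated particles depress the particle filter's hypotheses-per-unit
ratio, which is the mechanism behind the marginal filter's advantage at
equal budgets.

`predicate_track` projects each step's belief onto an arbitrary state
predicate, yielding a probability track for symbolic facts that are never
observed directly; the output is clipped to [0, 1] to absorb rounding.

## 6. Baselines and evaluation

The HMM baseline counts class transitions in annotation sequences
(optional pseudocount, default 0; rows never observed fall back to
self-absorption to stay stochastic). Forward, forward–backward, and
Viterbi run in log space; impossible observations raise with the frame
index. QDA applies Bayes' rule independently per frame.

Metrics: confusion-matrix accuracy, per-class precision/recall/F1 with the
0/0 → 0 convention (flagged), Cohen's κ (defined as 0 when chance
agreement is 1), Jensen–Shannon *distance* (square root of the base-2
divergence, range [0, 1]) for predicate tracks, thresholded predicate
accuracy, unit-cost Levenshtein on run-collapsed sequences, DTW with 0–1
local cost, and auxiliary error probability / run-count difference /
combined Euclidean score.

## 7. Fixtures and experiment harness

Two kitchen domains: *tiny* (2 items, 18 reachable states, small enough
for brute-force reference computations) and *small* (7 items with freely
permutable set-table and clean-up subtasks, 10,284 reachable states,
livelock-free). Default generative durations use lognormal medians of
1–6 s per class at 2 Hz framing, so a routine spans on the order of a
hundred frames. The harness simulates replicates, generates (optionally
scrambled) observations, fits the QDA, HMM, and duration models on the
*pooled* replicates, builds the restricted distance from the union of
visited states, runs each configured method at its stated budget, and
scores it; per-method failures are recorded in the report rather than
aborting the run.

## 8. Numerical choices

- All weight arithmetic in log space; merging via `logsumexp`.
- Gaussian likelihoods via Cholesky factors precomputed per class.
- Deterministic tie-breaking everywhere (canonical state keys, first-max).
- All stochastic entry points accept either an integer seed or a
  `numpy.random.Generator`; derived seeds use `SeedSequence.spawn`.
- Hazards are cached per (class, elapsed, step) to avoid recomputing
  identical survival ratios across hypotheses.

## 9. Limitations

- Start times are restricted to the observation grid; sub-frame start-time
  uncertainty is collapsed. This is what makes merging effective, but it
  coarsens duration posteriors at low frame rates.
- The marginal smoother and MAP decoder operate on the pruned lattice, so
  they are exact only when K is not binding.
- The restricted goal distance assumes at least one goal state among the
  visited set; otherwise it degenerates to all-infinite and the policy
  falls back to the uniform cap.
- Transition rows are cached per state; domains whose reachable state
  count vastly exceeds memory are out of scope (the BFS cap guards this).
- The HMM baseline's self-absorption fallback for entirely unseen classes
  is a convention, not an estimate.
- The synthetic observation generator produces Gaussian class-conditional
  features by construction, so the QDA observation model is well-specified
  on generated data; real sensor features would add model mismatch that
  the drift option only partially emulates.
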