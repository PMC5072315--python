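# Methods

## The model

Each gene `X` in a network of N genes is modeled as driven by a single
dominant regulator `Y` through Hill kinetics:

    dX/dt = alpha * f(Y) - beta * X + gamma

with `f(Y) = Y^n / (K^n + Y^n)` for activation and
`f(Y) = K^n / (K^n + Y^n)` for repression. The parameters are
`theta = (alpha, beta, gamma, n, K)`: regulation strength
(expression units per time, > 0), first-order degradation rate (1/time,
>= 0), basal production (expression units per time, >= 0), Hill
cooperativity (dimensionless, >= 1), and half-saturation level
(expression units, > 0). A signed directed edge is a triple
(target, regulator, sign) with sign `a` (activation) or `r` (repression);
self-edges are allowed by default because autoregulation is common in
transcriptional networks.

The model deliberately restricts the inference class to single
regulation: time-series data at realistic lengths rarely support the
combinatorial explosion of multi-input regulatory functions. The
benchmark *simulator*, in contrast, does implement multi-input nodes (AND
= product of per-input Hill terms, OR = probabilistic sum
`1 - prod(1 - h_k)`), precisely to quantify how inference degrades under
this model mismatch.

## The local approximation and the loss

Inference is local: each target is scored independently, with the
observed trajectories of all genes treated as known inputs. This makes
the per-target computations embarrassingly parallel and keeps the
hypothesis space per node at 2N candidate edges.

For a candidate edge with parameters theta, the modeled derivative is
evaluated on the sample grid,

    F(t_j) = alpha * f(Y(t_j)) - beta * X(t_j) + gamma,

extended by linear interpolation and integrated from the first timepoint
(on the grid this is exactly the cumulative trapezoid; the grid need not
be uniform). The loss compares the observed series with this integrated
prediction up to an additive shift that absorbs the unknown integration
constant:

    l(theta) = min_c (1/T) sum_j (X(t_j) - Xhat(t_j) - c)^2,

with the minimizing shift available in closed form as the mean residual.
Working on the integral equation rather than on finite-difference
derivative estimates is what gives the method its noise robustness:
differentiation amplifies measurement noise, integration averages it.

## Prior, Gibbs posterior, Laplace evidence

Each candidate edge carries a box `R_E` of admissible parameters; the
prior over (edge, theta) is maximum-entropy subject to those bounds,
i.e. uniform with density `1 / (s * Vol(R_E))` where s is the number of
candidate edges for the target. The posterior over a target's candidate
edges is the Gibbs posterior

    p(E | D) proportional to integral_{R_E} exp(-l(theta)/lambda)
                             dtheta / (s * Vol(R_E)),

estimated by Laplace's method at the loss minimizer theta*: with H the
Hessian of the loss at theta* and d the number of free parameters, the
Gaussian integral contributes `(2 pi lambda)^{d/2} det(H)^{-1/2}`. Two
consequences worth noting: larger parameter boxes dilute evidence through
the prior density, and flatter optima (smaller Hessian determinant) gain
evidence — the method explicitly prefers models whose fit is robust to
parameter perturbation.

Numerical choices:

- **Hessian** by central finite differences with per-axis step 1e-4 of
  the box width; eigenvalues floored at 1e-8 of the largest.
- **Bounded Gaussian widths.** Each eigendirection's Gaussian width
  `sqrt(2 pi lambda / eig)` is capped at the box's support width along
  that direction. The exact integral over a bounded box cannot exceed the
  box width, and without the cap exactly-flat directions — e.g. n and K
  at a degenerate `alpha ~ 0` optimum, where the data impose no
  constraint at all — would receive arbitrarily inflated evidence. This
  single correction is what keeps degenerate "no regulation" fits from
  outranking genuine regulators on noisy data.
- **Gibbs temperature lambda.** Because the loss is a *mean* squared
  error, a Gaussian noise model with variance sigma^2 corresponds to
  `exp(-T l / (2 sigma^2))`, i.e. `lambda = 2 sigma^2 / T`. The default
  plugs in the classical second-difference estimator
  `sigma_hat^2 = mean(diff(x, 2)^2) / 6` per target trajectory, floored
  at 1e-8 so noiseless data remain well posed. Setting `lam=1` recovers
  the literal `exp(-l)` weighting; any positive value may be supplied.
- **Boundary optima** are scored with the same formula (the fit clips to
  the box); the quadrature comparisons in the test suite bound the
  resulting approximation error at under half a nat on two-parameter
  reductions.

## Normalization and default parameter box

Expression is min-max scaled to [0, 1] per gene before fitting (the loss
is not scale-free, and fixed default bounds are only meaningful on a
fixed scale). With W the window length, the default box is
alpha, beta in [0.01, 20]/W, gamma in [0, 5]/W, n in [1, 8], and K
spanning the regulator's observed range (floored at 1e-3; a constant
regulator widens the interval with a warning). All bounds can be
overridden. Reported parameters are mapped back to data units: alpha and
gamma scale with the target's range, beta and n are scale-free, K maps
through the regulator's affine normalization, and gamma absorbs
beta times the target's offset. The Hill nonlinearity makes this mapping
exact only when the regulator's minimum is zero; it is the natural
first-order report otherwise.

## Fitting

The loss is minimized per edge by bounded multi-start local search:
20 Latin-hypercube starts (seeded, deterministic) refined with L-BFGS-B
under the box bounds, plus three deterministic warm starts obtained by
solving the bounded linear least-squares problem in (alpha, beta, gamma,
shift) on a small (n, K) grid — for fixed Hill shape the integrated
prediction is affine in the remaining parameters, so these starts are
nearly free and reliably land in the right basin. Per-edge seeds are
derived from the base seed and the (target, candidate index) pair via a
CRC, so results do not depend on execution order or Python's hash
randomization.

## Network extraction and global dynamics

Per-node posteriors are collapsed to a network either by argmax (exactly
one edge per node, ties broken by candidate order) or by threshold
(default 0.4, possibly zero or several edges per node). Because each
node's posterior sums to one, probabilities are comparable across targets
and the pooled scores yield a network-wide edge ranking for ROC/PR
analysis.

The argmax network plus its fitted parameters form a complete ODE system;
integrating it from the data's initial values (in normalized space,
mapped back afterwards) regenerates the trajectories. On a one-period
window the per-gene range-normalized RMSE is about 0.08-0.11 on the
three-gene oscillator benchmarks. Over several periods the reconstruction
drifts in phase — a fitted oscillator's period is exquisitely sensitive
to parameters, so small calibrated parameter deviations accumulate into
phase error even when each node's fit is essentially exact.

## The benchmark simulator

`lemnet.simulate` integrates any `NetworkSpec` with LSODA (rtol 1e-8,
atol 1e-10 by default) and samples a uniform grid. The shipped catalog:

| fixture | nodes | behavior | notes |
|---|---|---|---|
| `repressilator3` | 3 | sustained oscillation | cyclic repression, n=3, period ~4.3 |
| `negfb3` | 3 | sustained oscillation | two activations + one repression closing the loop |
| `gated5/10/20` | 5/10/20 | sustained oscillation | repressilator core driving a cascade; 2-3 AND/OR nodes |
| `nonperiodic5` | 5 | relaxation to steady state | stable cascade started off equilibrium |

Default windows span roughly three oscillation periods at 40-48 samples
(24 samples over the transient for the non-periodic net) — enough points
per period that the trapezoid integral resolves the dynamics, matching
the sampling density a time-course experiment of this kind would aim
for. All fixture parameters are versioned constants; the larger gated
networks come from a deterministic seeded construction with regulators
drawn from the first six nodes so oscillation amplitude survives down the
cascade. Generating-network Hill exponents lie within the inference
box (n <= 8), so the single-regulator fixtures are realizable by the
inference model class; the gated fixtures are intentionally not.

Measurement noise is truncated Gaussian: per gene, i.i.d. draws with
variance equal to `variance_fraction` times that gene's empirical signal
variance; draws that would go negative are resampled rather than
clipped, avoiding a point mass at zero. The benchmark ceiling of 0.32
matches the harshest condition in the validation studies. Truncation is
one-sided (at zero) only.

What the synthetic benchmarks do *not* emulate: cell-to-cell
stochasticity (the model presumes population-averaged trajectories),
transcription/translation delays, unobserved regulators, and the
heavier-tailed, heteroscedastic noise of real expression measurements.
Passing these benchmarks shows the machinery is correct and robust under
its own assumptions, not that it will reach the same scores on
biological data.

## Evaluation protocol

The scoring universe is all signed directed edges over the gene list
(2N^2 with self-edges; both the self-edge and the sign-collapse behavior
are configurable). AUC-ROC uses the Mann-Whitney tie convention (half
credit for ties, so a constant ranking scores exactly 0.5); AUPR uses
step-wise interpolation (constant ranking scores the prevalence); MCC is
computed from the confusion matrix over the universe, with 0 returned
when a marginal is empty. For MCC the posterior is binarized by argmax
extraction — one edge per node — which deliberately weakens the ranking
to make it comparable with binary classifiers.

## Problem sizes and limitations

The shipped benchmarks run in seconds to minutes on one core: a 3-gene
inference is ~8 s (6 edges x 3 targets, 23 starts each), the 5-gene
non-periodic benchmark ~17 s. Cost grows as O(N^2) fits; targets
parallelize independently (`n_jobs`).

Known limitations: combinatorial regulation is never inferred, only its
dominant single-input projection; the Laplace evidence is an
approximation whose error is bounded in tests only on low-dimensional
reductions; parameters of non-identifiable model pairs (distinct
topologies generating identical dynamics) cannot be distinguished by any
method, and the posterior then simply prefers the more robust fit; and
the data-unit parameter report is approximate when a regulator's
observed minimum is far from zero.
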