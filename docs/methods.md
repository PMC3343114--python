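# Methods

`seqcap` studies how many input/output associations a binary neuron with
excitatory synapses can store when the associations form temporally
correlated sequences, and how intrinsic bistability of the neuron changes
that capacity.  The biological motivation is the cerebellar Purkinje cell:
it receives a large number N of weak excitatory parallel-fiber synapses
(weights constrained to be nonnegative), fires when the summed drive exceeds
a threshold, and is supervised by a climbing-fiber error signal; in some
conditions it behaves as a bistable (up/down state) unit.

## Model

**Patterns.**  A sequence of P patterns pairs a binary input vector
x^mu in {0,1}^N with a binary target y^mu.  Each input cell's activity along
the sequence is an independent stationary two-state Markov chain with coding
level f_in (probability of being active) and lag-1 Pearson correlation c_in;
the target sequence is an independent chain with (f_out, c_out).  The
transition probabilities

    P(1|1) = f + c (1 - f),        P(1|0) = f (1 - c)

define the unique two-state chain with stationary mean f and lag-1
correlation c.  The stationary pair probabilities of successive states are

    p11 = f (f + c(1-f)),  p10 = p01 = f (1-f)(1-c),  p00 = (1-f)((1-f) + c f).

The first state is drawn from the stationary distribution, so no burn-in is
needed.  Different input cells are uncorrelated; only temporal structure is
modelled.

**Neuron.**  The standard unit fires iff the drive h = sum_i w_i x_i strictly
exceeds a fixed threshold theta > 0.  The bistable unit has two thresholds
theta_up/down = theta ± Delta/2: from the down state it needs h > theta_up to
switch on, and from the up state it stays on until h <= theta_down.  Firing
always requires strictly exceeding the applicable threshold, so Delta = 0
reduces identically to the standard unit.  The bistable band is placed
symmetrically about theta; an asymmetric placement is equivalent to
re-choosing theta.

**Learning constraints.**  Pattern mu >= 2 is stored robustly when

    y^mu = 1:  h^mu >  theta_eff(mu) + kappa
    y^mu = 0:  h^mu <  theta_eff(mu) - kappa

with theta_eff = theta_up if y^{mu-1} = 0 and theta_down if y^{mu-1} = 1,
and kappa >= 0 a fixed robustness margin in current units.  The first
pattern has no predecessor and is constrained against theta (the
"midpoint" rule; an "unconstrained" variant is selectable — the difference
is a single constraint and vanishes as P grows).  kappa and Delta are fixed
offsets like theta: at large N with O(1) weights, theta scales as N while
kappa and Delta scale as sqrt(N).  A margin proportional to each weight
vector's own norm would define a different model; an exact identity of the
saddle-point equations (see below) shows that such a relative margin leaves
the silent-synapse fraction at 1/2 for every kappa, which is inconsistent
with the robustness phenomenology this model describes (silent fraction
rising towards ~80%), so the fixed-margin convention is used throughout.

**Learning rule.**  Weights start at zero.  On an error the perceptron rule

    w_i <- max(0, w_i + eta (y_target - y) x_i)

is applied (LTP when the teacher fires without the unit, LTD in the
converse case), with a hard floor at zero.  Three variants:

* `standard` — plain threshold unit;
* `bistable_switching` — the error signal also resets the unit's state to
  the target after each pattern, so during training the effective threshold
  of pattern mu is set by the *target* at mu-1 (teacher forcing).  When all
  constraints hold, free replay of the bistable dynamics from pattern 1
  reproduces the sequence exactly;
* `bistable_nss` — "no state switching" control: the unit's own previous
  output selects the threshold and errors are never corrected.  This rule
  sweeps the sequence in order; the other two present patterns uniformly at
  random (one epoch = P presentations), with a sequential option for
  deterministic tests.

Training stops at the first epoch whose exact constraint check finds no
violation, or at `max_epochs`; non-convergence is a reported outcome.

## Convergence guarantee

If some nonnegative w* satisfies every constraint with margin m (in current
units), at most a fraction F of inputs are active per pattern, and

    eta < 2 (m - Delta) / (F N)     and     eta < 2 theta_down / (F N),

then the rule converges after finitely many error-driven updates.  Sketch:
LTP errors occur at h <= theta^mu, so each one raises |w|^2 by at most
2 eta theta_up + eta^2 F N; LTD errors occur at h > theta^mu >= theta_down
and (clipping only helps) lower it by at least 2 eta theta_down - eta^2 F N.
Since |w|^2 >= 0, LTD steps number at most rho times the LTP steps, with
rho = (theta_up + eta F N/2)/(theta_down - eta F N/2).  Meanwhile w·w*
gains at least eta(theta_down + m) per LTP step and loses at most
eta(theta_up - m) per LTD step, so with g(rho) = theta_down + m -
rho(theta_up - m) > 0 (the condition above) the Cauchy-Schwarz inequality
bounds the update count by

    t  <=  (1 + rho) |w*|^2 (2 theta_up + eta F N (1 + rho)) / (eta g(rho)^2).

`safe_learning_rate` returns half the binding bound; `updates_bound`
evaluates the count bound.  The certified rate scales as 1/N at fixed
threshold and margin — individual synaptic changes must be O(1/N) of the
total drive for maximal capacity to be reachable.  The guarantee covers the
standard and teacher-forced bistable rules (whose constraint systems are
fixed); it requires m > Delta in the bistable case.

The practical default rate is eta = 0.01 theta / (N f_in): each update then
moves the drive by about 1% of the threshold.  Larger rates (10% of theta
per update) overshoot the shrinking margins near capacity and stall;
capacity protocols that probe very close to the edge use 0.3% or 0.1%.

## Capacity estimation (simulation)

A length P is *learnable* if training converges within the epoch budget.
Per trial, `estimate_capacity` brackets the largest learnable P by adaptive
expansion from `alpha_hint * N` and bisects to a resolution of
max(1, N/100) patterns; the estimate is the mean of P_max/N over seeded
trials with the standard deviation over trials as the error bar (10 trials
by default).  Budget-limited probes are counted and reported, so the
epoch budget's bias (toward underestimation) is visible.  An
unconstrained-weight mode (no clipping) reproduces the classical capacity
of 2 as a reference.

Desk scale is N = 200 (N = 400 for weight-distribution measurements),
10 trials, epoch budgets of 2000–10000; a sweep of one figure-style grid
takes minutes on one CPU.  Finite-size behaviour was checked at N = 100,
200 and 400 for the unbiased uncorrelated case: the trial-to-trial spread
shrinks with N (e.g. 0.08 at N = 100 vs 0.06 at N = 200 under one fixed
protocol) while the mean stays within a few percent of the large-N value 1,
with a slight downward bias from the epoch budget.

The exact feasibility oracle (`seqcap.oracle.feasible`) settles small and
medium systems by linear programming: maximize the minimal slack s over
w >= 0 under a generous total-weight cap and declare feasibility iff
s > 1e-9 * theta.  The constraint count equals P, so instances up to about
10^3 patterns are exact ground truth for the learner.

**Capacity-edge weight states.**  The theoretical weight distribution
describes the capacity *limit*, where the set of admissible weight vectors
shrinks to a point.  A training run below an instance's critical load stops
at an interior point of a still-large solution polytope and shows too few
silent synapses.  `capacity_edge_states` therefore locates each instance's
critical P exactly (resolution one pattern) with the LP oracle and trains
at that edge, stepping down one pattern at a time only if the epoch budget
is exhausted; the first error-free pass there is the state the theory
describes.  At N = 400 this yields silent fractions of roughly 0.43–0.50
against the theoretical 1/2 (kappa = 0).  The residual deficit has two
parts: finite size, and an entry-point bias — the learning rule enters the
solution polytope at a typical boundary point rather than its max-margin
center (the LP witness at the same instance edges reads 0.49–0.57,
bracketing the theoretical value); the bias is independent of the learning
rate and shrinks as the polytope concentrates with growing N.

**Silent threshold.**  With a finite learning rate, weights pressed against
zero by recurrent depression park a few update quanta above it rather than
exactly at it.  A weight counts as silent when it is below
max(relative_tol * mean nonzero weight, 5 eta); the relative cut defaults
to 1e-3 and the capacity-edge measurements use 1e-2, which sits inside the
clear gap observed between the near-zero population and the positive bulk
(sensitivity checked at 1e-3/1e-2/1e-4: at the edge the measured fraction
changes by < 0.03 between 1e-2 and 1e-1, while 1e-3 clips part of the
pinned population when eta is very small).

## Replica theory (uncorrelated inputs)

For c_in = 0 the quenched average over inputs factorizes over patterns, and
the targets enter only through the pair probabilities p_ab above, which
weight four constraint classes (stay-down, switch-up, switch-down, stay-up)
with effective thresholds theta ± Delta/2.  The Gardner volume of
nonnegative weight vectors satisfying all constraints is computed with the
replica method under the replica-symmetric ansatz, with order parameters
B = <w> (mean weight), Q = <w^2> (self-overlap, gauged to 1) and q (overlap
between replicas), plus conjugates.  In scaled units — margins measured in
units of the input-current fluctuation sigma_h = sqrt(N f_in (1-f_in) <w^2>)
— each class k contributes an offset

    a_k = kappa_s + eps_k (gamma + eta_k delta_s / 2),

where eps_k = ±1 is the constraint direction, eta_k = ±1 picks the upper or
lower threshold, and gamma (the gap between the midpoint threshold and the
mean drive, in sigma_h units) is fixed by the saddle point because the mean
weight adapts freely.  f_in is absorbed by the units, which is why the
capacity at the optimal bistable range cannot depend on it; at fixed
*physical* Delta it re-enters through the unit bridge below.

`solve_saddle` solves the six coupled equations at fixed load alpha: the
threshold balance (potentiating and depressing pressures cancel), the three
moment self-consistencies for (B, Q, q) and the two conjugate definitions.
They reduce to one monotone scalar problem in q with gamma and the
conjugates solved exactly inside (Gauss-Hermite quadrature with 301 nodes,
stabilised Mills ratios via erfcx); residuals at the fixed point are below
1e-10.  As alpha approaches capacity, q -> 1 and the conjugates diverge.

**Capacity.**  In the q -> 1 (vanishing-volume) limit the equations close
over (gamma, s0, alpha), where s0 is the truncation point of the weight
distribution.  With Phi/H the Gaussian CDF/tail, E1(s) and E2(s) the first
and second moments of the Gaussian tail above s, and I1(c) = c Phi(c) + phi(c):

    (balance)    sum_k p_k eps_k I1(a_k) = 0                       -> gamma
    (truncation) E2(s0)/H(s0) = sum_k p_k Phi(a_k) / sum_k p_k E2(-a_k) -> s0
    (capacity)   alpha_c = H(s0) / sum_k p_k Phi(a_k).

Both scalar equations are monotone, so `capacity_replica` solves them with
bracketed root finding to ~1e-12 — directly at the vanishing-volume
criterion, rather than bisecting the finite-q solver on alpha (the
finite-q route is retained in `solve_saddle` and cross-checked: q -> 1 and
r_hat diverges as alpha -> alpha_c).  Checks reproduced exactly: alpha_c = 1
at f_out = 1/2, kappa = delta = 0, for every c_out; alpha_c(f_out = 0.1) ~ 2;
alpha_c decreasing in kappa.

**Weight distribution.**  At capacity the single-synapse problem gives
w(t) = sigma_w (t - s0)_+ over a standard Gaussian field t, i.e.

    P(w) = Phi(s0) delta(w) + (w > 0) N(-sigma_w s0, sigma_w^2),

a delta mass of silent synapses plus a Gaussian truncated at zero, with
sigma_w = 1/sqrt(E2(s0)) in RMS-weight units.  At kappa = 0 the saddle sets
s0 = 0: half the synapses are silent, the positive branch is a zero-mean
half-Gaussian with std/mean = sqrt(pi/2 - 1) ~= 0.7555, independent of all
correlation and coding parameters — and, numerically, s0 = 0 also at the
capacity-maximizing bistable range for every c_out, so the optimum keeps
exactly 50% silent synapses.  kappa > 0 moves s0 > 0: fewer patterns are
marginal, more synapses silent (0.70 at kappa_s = 0.5, 0.87 at 1.0).

**Unit bridge.**  At capacity the mean weight is pinned by the threshold
(B = theta/(f_in N)), which fixes sigma_h through the distribution shape and
makes the scaled and physical parameters interconvertible:

    delta_s = (Delta sqrt(N)/theta) sqrt(f_in/(1-f_in)) E1(s0)/sqrt(E2(s0)),

and identically for kappa.  Because s0 depends (weakly) on delta_s and
kappa_s, the map is iterated to a fixed point.  This bridge is exact at the
capacity point for c_in = 0; for correlated inputs it is used as an
approximation when converting sweep grids.

**Bistability.**  With c_out > 0 the switch classes (01, 10) are rare and
the stay classes common; a positive delta_s makes the rare constraints
harder and the common ones easier, raising capacity.  `optimal_bistable_range`
maximizes alpha_c over delta_s >= 0 (bracketed scalar maximization, with the
boundary delta_s = 0 compared against the interior optimum so that c_out = 0
returns exactly zero).  The optimum and the capacity at it grow with c_out;
theory and the switching-rule simulation overlay within simulation error
bars (e.g. c_out = 0.6, delta_s = 1: theory 1.330, simulation 1.314 ± 0.088
at N = 100).  The correlated-input case has no factorizing replica average
and is handled by simulation only.

## What the generator does and does not emulate

The synthetic sequences realize exactly the statistical ensemble the theory
assumes: independent cells, stationary two-state Markov temporal structure,
input/output independence.  Real granule-cell populations have spatial
correlations, non-stationary rates and richer temporal structure; passing
tests therefore validate the method and its implementation under the
model's assumptions, not the model's fidelity to any particular dataset.

## Numerical choices and degenerate inputs

* Strict firing convention: equality with a threshold never fires; the
  LP oracle realizes open constraint sets as "max-min slack > 1e-9 theta".
* Constant streams (c = 1) have undefined lag-1 correlation; `empirical_stats`
  flags them instead of returning a number.
* All randomness flows from integer seeds through `numpy.random.SeedSequence`
  spawn keys (per-column, per-trial, per-probe), so any result is
  reproducible bit-for-bit and enlarging N or P preserves existing cells.
* The compiled training kernel (numba, optional) and the pure-NumPy fallback
  implement the same algorithm and are tested for exact agreement on
  dyadic-rate instances where floating-point ties cannot occur.

## Known limitations

* Replica symmetry is assumed; for continuous feasible sets of this type
  RS is expected to be exact, but no stability check is performed.
* The finite-q saddle solver loses accuracy within ~1e-4 of q = 1; capacity
  comes from the closed q -> 1 system instead.
* Simulated capacities are biased slightly downward by the epoch budget and
  the fixed learning rate (reported via the budget-limited probe count);
  simulated silent fractions carry a finite-size deficit of a few percent
  at N = 400.
* Learning with order-1 synaptic changes, weight upper bounds, stochastic
  plasticity, graded outputs and inhibitory inputs are out of scope.
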