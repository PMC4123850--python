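# Methods

## The management problem

A park manages `N = 25` golden-eagle nesting territories that hikers can
reach.  Each spring the number of occupied territories `S` is known (raptor
detection on repeat visits is close to perfect), and the manager chooses how
many occupied territories `A <= S` to close to hikers for the breeding
season.  Restricting helps fledging if hiker disturbance is real, but costs
recreation access.  The strength of the disturbance effect is the structural
unknown: three candidate models (none / moderate / strong) are carried with
a belief weight vector `B`, updated every year from what is observed.  The
problem is a mixed-observability Markov decision process: occupancy is
observed, the model index is not, and an informative signal — the number of
successful fledgings — is observed without being a state variable.

## Single-site model

Annual events at one site, conditional on its (occupancy, restriction):

* an empty site is colonized next year with probability `p_c`;
* an occupied site fledges successfully with probability `p_u(h)` if
  unrestricted and `p_r(h)` if restricted, with a logistic model

      p_r = logistic(b_INT + b_HARE * h)
      p_u = logistic(b_INT + b_DIST + b_HARE * h)

  where `h` is the arctic-hare abundance index (prey availability) and
  `b_DIST <= 0` is the disturbance effect;
* the site is re-occupied next year with probability `p_s` after a success
  and `p_n` after a failure.

The joint law of the success signals `(Y1, Y2)` (success at an
unrestricted / restricted site) and next-year occupancy is the 6 x 3 event
table of `model_core.site_event_table`.  Marginalizing over signals gives
the occupancy transition; conditioning on the outcome instead of the action
gives a two-row matrix whose product with the explicit garbling
`informativeness.action_garbling` reproduces the transition — the algebraic
statement that the success outcome Blackwell-dominates the action as a
source of information.

The logistic form of the success model is a reconstruction (the source
formulas are not machine-readable); it is pinned down by the requirement
that all nine published `(p_u, p_r)` pairs are reproduced to three decimals
at `h = 9.4`, which the test suite checks.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `p_c` | 0.2315 | colonization probability (per empty site, per year) |
| `p_n` | 0.9427 | re-occupancy probability after failure |
| `p_s` | 0.9573 | re-occupancy probability after success |
| `b_HARE` | 0.06 | hare-index coefficient |
| `h` | 9.4 | mean hare index; frozen in all belief-MDP solves |
| `N` | 25 | managed territories |
| `alpha` | 0.85 | utility exponent (success weight) |
| `delta` | 0.98 | annual discount factor |

Three packaged uncertainty cases fix `(b_INT, b_DIST)` per candidate model:
`pr_known` (restricted success known; models differ in `b_DIST`),
`pu_known` (unrestricted success pinned at 0.405 by holding
`b_INT + b_DIST` constant), and `both_uncertain` (intermediate).  Each case
carries its natural signal: unrestricted successes, restricted successes,
or both counts.

## Multi-site kernels

Sites are exchangeable and independent given `(S, A)`, so the `N`-site
state need only count sites: `S` occupied, `A` restricted, signals
`Y1, Y2`, next-year occupancy `S+`.  The exact joint kernel
`P(Y1, Y2, S+ | S, A)` is assembled group-wise: within the empty,
occupied-unrestricted and occupied-restricted groups the per-site outcome
categories are multinomial, the success count is binomial, and the
re-occupied count given successes is a sum of two binomials; group
convolutions then deliver the joint law.  Assignments of sites to outcome
categories that produce the same `(Y, S+)` value are summed.  An exhaustive
per-site enumerator (6^N outcome combinations) serves as the test oracle up
to `N = 4`; the convolution construction is exact, so agreement is required
at 1e-12.

Coarser signals are garblings of the full kernel: only `Y1`, only `Y2`,
the pooled total `Y1 + Y2`, or nothing (the plain occupancy transition).
Garbling is summation of kernel cells and is only allowed toward coarser
modes.

## Belief dynamics and the decision problem

After observing `(Y, S+)` from `(S, A)`, the belief is updated by Bayes
rule, `B+_i ∝ B_i P_i(Y, S+ | S, A)`.  Because `p_c, p_n, p_s` are common
to all candidate models, the likelihood ratio across models depends on the
observation only through the success counts; with no signal the update
works through the tiny `p_s - p_n` gap and is nearly the identity — the
degenerate case `p_n = p_s` makes it exactly the identity, which the tests
pin down.

The per-year utility trades expected breeding success against access:

    R(S, A, B) = E[Y | S, A, B]^alpha * (N - A)^(1 - alpha),  alpha = 0.85

with `E[Y]` the belief-averaged expected number of successes.  The
published utility formula is also image-only in the source; this
Cobb-Douglas placement of the exponent (on the expectation) is the package
default, and a `linear` form `alpha E[Y] + (1-alpha)(N-A)` is selectable
through `RewardSpec`.  A variant with the exponent inside the expectation
(`E[Y^alpha]`) was evaluated during development and moves the headline
value-of-information numbers by well under 0.1 percentage point, so the
choice among smooth increasing trade-offs is not load-bearing.

The infinite-horizon discounted objective is maximized over rules
`A(S, B)`.  Beliefs are discretized on a regular simplex grid with step
`1/m` (`BeliefGrid(order=m)`); posteriors falling between grid points are
valued by barycentric interpolation within the containing triangle, chosen
over nearest-neighbour snapping because it is exact for linear functions
and keeps the discretized problem a proper finite MDP.

### Solver numerics

* Bellman-improvement sweeps interleaved with fixed-policy evaluation
  sweeps (modified policy iteration, up to 60 evaluation sweeps per
  improvement with early exit).  Rewards are non-negative and the value is
  initialized at zero, so the iterates increase monotonically to the fixed
  point; iteration stops when an improvement sweep changes the surface by
  less than `tol = 1e-6` in sup norm (cap: 5000 sweeps, then an error).
* Argmax ties break toward the smallest `A` (least restrictive), in both
  the certain-model and belief solvers, which keeps vertex policies of the
  belief MDP exactly equal to the certain-model rules.
* Outcomes with proportional model-likelihood vectors yield the same
  posterior from every prior, so they are grouped (probabilities summed per
  `S+`) before posterior interpolation weights are cached.  For the full
  signal this provably collapses the outcome space to the distinct
  `(Y1, Y2)` pairs.  The grouping is exact, not an approximation.
* The inner gather-accumulate kernel is compiled with numba; everything
  else is vectorized numpy/BLAS.

The passive strategy solves, for every grid belief `B`, the occupancy MDP
whose transition is the `B`-averaged no-signal kernel with `B` held fixed,
and records that rule.  Its value surface is the frozen-belief value the
strategy itself assumes.  The probing map is the active rule minus the
passive rule.

The value of a signal is reported as the pointwise percent gain
`100 (V_signal - V_none) / V_none` between two active solves on the same
grid.  Whether the published comparison divided by the active or the
frozen-belief no-signal surface is not recorded; both surfaces are
available, and both were computed during development (they differ by at
most ~0.2 percentage point of gain).

## Simulation design

`simulate` draws replicate management histories: read the action from the
policy at the nearest grid belief, sample `(Y, S+)` from the true model's
kernel column by inverse CDF, update the belief exactly by Bayes rule.
Beliefs are carried exactly between years (the grid is only used for policy
lookup), a deliberate choice so that discretization error does not compound
in learning curves; whether the original analysis snapped beliefs between
years is unknown, and this is documented as a deviation of unknown (but
small) effect.  Randomness is one counter-based Philox stream per path
keyed by `(seed, path_index)`, one uniform per path-year, so ensembles are
bit-for-bit reproducible and independent of execution order or path
parallelism.

Defaults follow the study conditions: 10000 paths, 100 years, initial
occupancy 20 of 25, uniform initial beliefs.  The test suite runs a
scaled-down profile (2000 paths, policies solved at grid order 20) that
reproduces the qualitative learning-curve ordering within Monte-Carlo
error.

The generator emulates exactly the fitted occupancy/fledging process —
exchangeable sites, constant hare level, known occupancy, perfect
detection, year-invariant parameters.  It does not emulate hare-cycle
dynamics, site heterogeneity, observation error in occupancy, or trends in
disturbance pressure, so passing tests demonstrate internal consistency of
the decision analysis, not transferability of the fitted parameters to
field data.

## Problem sizes used by the tests and the acceptance script

Belief-MDP checks (vertex consistency, probing signs, value bounds) run at
grid order 50; policy stability is checked between orders 25 and 50;
learning-curve simulations use 2000 paths over 100 years with policies at
grid order 20; exhaustive kernel oracles run at `N <= 4`.  The acceptance
script solves all three cases with and without their best signal at grid
order 50.

## Known limitations

* The belief simplex is two-dimensional here (three candidate models); the
  grid-plus-interpolation solver would need point-based POMDP machinery to
  scale to many models, which is out of scope.
* The published maximum percent value gain from the best signal is stated
  as exceeding 4%; this implementation, at grid order 50 and with either
  utility reconstruction and either no-signal denominator, converges to a
  maximum near 3.6-3.9% (in the p_r-known case, at beliefs split between
  the no- and strong-disturbance models — the same region the original
  analysis highlights).  Grid refinement from order 10 to 75 moves the
  number by only ~0.1 point, so the residual gap most likely reflects
  unrecorded discretization/interpolation details of the original solver
  stack.  The corresponding acceptance check is left asserting the
  published bound.
* The no-restriction-of-empty-sites convention means the action space
  shrinks with `S`; rules are only defined for `A <= S`.
* The hare index enters the certain-model solver as a covariate but is
  frozen at its mean in all structural-uncertainty solves, as in the
  original analysis; a stochastic hare process would enlarge the state
  space and is not modelled.
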