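# Methods

## Model and design framework

Patient outcomes are Bernoulli responses X_i ~ Bern(π). A Gehan-type
two-stage design is determined by a stage-one size n₁ and a stage-two size
schedule n₂(s₁), s₁ = 0…n₁, where s₁ is the number of stage-one responses:

* **Stage one** screens for any activity: n₁ is the smallest integer with
  (1 − π₁)^{n₁} ≤ β₁, so that when the true rate is at least the
  interesting rate π₁ the probability of stopping with zero responses is at
  most β₁. The trial always stops for futility at s₁ = 0 (n₂(0) = 0).
* **Stage two** is sized for estimation precision, not power. Given an
  interim estimate π̂(s₁, n₁), each rule returns the *minimal* n₂ ≥ 0
  satisfying its constraint (minimality is re-checkable: the constraint
  fails at n₂ − 1 and holds at n₂):
  - **f_G** — estimated-standard-error bound:
    √(π̂(1 − π̂)/(n₁ + n₂)) ≤ γ.
  - **f_L** — worst-case exact-length bound:
    (0.5 / z_{1−α/2}) · max_{s₂} L(s₁ + s₂, n₁ + n₂) ≤ γ, with L the pooled
    Clopper-Pearson interval length at level α. The target corresponds to
    the length 2γ·z_{1−α/2} of the Wald interval the f_G precision aim
    implies, so the three rules chase the same nominal precision.
  - **f_EL** — expected exact-length bound: the same inequality with the
    maximum replaced by the expectation of L under S₂ ~ Bin(n₂, π̂).

Two interim estimators are provided. The **original** estimator is the
Wald-style upper confidence limit min{s₁/n₁ + z·√(s₁(n₁−s₁)/n₁³), 1} with z
the normal quantile at 1 − (1 − coverage)/2. The **conservative** estimator
replaces asymptotics with exact limits: for 1 ≤ s₁ ≤ n₁ − 1 it takes, among
the lower and upper Clopper-Pearson limits at the interim coverage and the
MLE s₁/n₁, the candidate closest to ½ (the variance-maximising direction);
at s₁ = n₁ it takes ((1 − coverage)/2)^{1/n₁}. It is undefined at s₁ = 0,
where the trial has already stopped.

## The embedded exact test

The test of H₀: π = π₀ is encoded by a discrete conditional error function
(DCEF): values D(s₁) ∈ [0, 1], with D = 0 / D = 1 futility/efficacy stops
and interior values conditional significance levels for the stage-two test,
which rejects when the binomial upper-tail p-value P(S₂ ≥ s₂ | n₂(s₁), π₀)
is at most D(s₁). Type-I error control at level α is exactly
Σ D(s₁) b(s₁ | n₁, π₀) ≤ α. A valid DCEF satisfies:

1. monotonicity in s₁ — enforced **non-strictly** (D(s₁) ≤ D(s₁+1)): the
   strict form stated alongside the framework excludes optimal designs that
   genuinely contain ties, and the worked optima here do contain them; a
   `strict=True` validation mode is available;
2. attainability — every interior D(s₁) is an upper-tail probability
   1 − B(k − 1 | n₂(s₁), π₀) for an integer cutoff k;
3. D(s₁) ∈ {0, 1} when n₂(s₁) = 0, with D(0) = 0;
4. D(s₁) ∈ (0, 1) when n₂(s₁) > 0.

DCEFs are stored as the integer cutoffs k(s₁) ("reject at stage two iff
s₂ ≥ k"), with the D values derived, so threshold matching is exact rather
than float-matched; the uniform convention k = 0 / k = n₂ + 1 encodes the
certain-reject / certain-accept stop decisions. Power at any rate π is the
exhaustive sum Σ P(S₂ ≥ k(s₁) | n₂(s₁), π) b(s₁ | n₁, π) — every quantity
in the package is an exact finite sum; nothing is simulated.

## Branch-and-bound optimisation

With the schedule fixed by the precision requirement, the free design
choice is the DCEF, optimised for power at π₁ subject to the level-α
constraint. The search assigns cutoffs stage by stage (s₁ ascending) and
prunes with two exact bounds on any completion of a partial assignment:

* **type-I lower bound** — error spent so far plus the current level
  carried over all remaining stage-one mass (monotonicity forbids smaller
  later levels); subtrees exceeding α are discarded;
* **power upper bound** — power accrued plus all remaining stage-one mass
  at π₁; subtrees that cannot beat the incumbent are discarded.

Candidates at each stage are iterated in decreasing order of conditional
error. Along that order the monotonicity constraint, the type-I bound and
the power bound are all monotone, so each stage's candidate loop skips its
infeasible head and exits at its unproductive tail. The incumbent is
initialised with the greedy least-rejecting valid DCEF (per-stage smallest
attainable level at or above the running level), which is also the exact
minimiser of the type-I error over valid DCEFs: if even it exceeds α the
design is infeasible and the search aborts, reporting that minimum. The
closed-form "most conservative" assignment (all stage-two successes
required at every continuation stage) is retained as a cheaper relaxed
lower bound, but it can violate monotonicity when the schedule is
non-monotone, so it does not serve as the incumbent.

Ties in power are broken towards smaller type-I error, then towards the
lexicographically smallest cutoff vector, making the result deterministic.
Equal-power optima can legitimately differ in their D values, so reported
designs are compared on power, error rates and ESS rather than on
individual conditional error values (the worked examples here nevertheless
reproduce the published D vectors digit for digit).

Correctness is tested by exhaustive enumeration of all valid DCEFs on 200+
randomised small instances (n₁ ≤ 4, n₂ ≤ 4), and the pruning bounds are
tested to bracket every enumerated completion.

## Operating characteristics

For any true rate π, with pmf b over the n₁ stage-one draws:

* ESS(π) = n₁ + Σ n₂(s₁) b(s₁ | n₁, π) — the pmf argument is n₁ (confirmed
  by ESS(0) = n₁ against the tabulated values).
* The futility boundary f₁ is the largest s₁ with D(s₁) = 0.
* EL(π | S₁ = s₁) = Σ_{s₂} L(s₁ + s₂, n₁ + n₂(s₁)) b(s₂ | n₂(s₁), π).
* CEL(π) = EL(π | S₁ > f₁): the b(s₁)-weighted average of the above with
  numerator *and* denominator over s₁ = f₁ + 1 … n₁. (The conditioning
  event is S₁ > f₁; a printed version of this display starts the two sums
  at different indices, which is read as a typo.)

`length_fn` is a pluggable contract (s, n) → length; the default is the
pooled exact Clopper-Pearson length on the combined data, with the
boundary convention L = 1 − (α/2)^{1/n} at s ∈ {0, n}. Ordering-adjusted
intervals for adaptive designs (e.g. compatible-estimator-ordered exact
intervals) can be supplied through the same contract; with the default,
CEL curves are comparable in shape but not digit-identical to analyses
that used adjusted intervals. Response-rate grids for curve export exclude
the endpoints {0, 1}, where the trial outcome is deterministic and
conditional quantities degenerate.

## γ calibration

Gehan's designs are estimation-driven and often badly mis-powered, so γ is
optionally treated as free: the calibrator scans a descending grid
(default step 10⁻⁴ from ceiling 0.2 down to floor 10⁻⁴, matching the
4-decimal precision at which calibrated values are reported) and returns
the **largest** grid value whose optimised design reaches the target
power. The scan does not assume power is monotone in γ (it is not, the
design being discrete); largest-first is preferred because ESS decreases
monotonically in γ, so the first qualifying γ is the cheapest design.
Grid points whose schedule admits no level-α DCEF are recorded with NaN
power and skipped. Many γ values induce identical integer schedules, so
optimisation results are memoised by schedule; the full fine-grid scan for
the worked example takes a couple of seconds.

## Simon comparator designs

The comparator search enumerates all (f₁, n₁, f₂, n₂) with
n₁ + n₂ ≤ n_max (default 100) under the decision convention *continue iff
s₁ > f₁, reject iff s₁ + s₂ > f₂* — strict inequalities throughout, which
differs by an index shift from tables stated as "reject iff s ≥ r". Exact
error rates are double binomial sums, vectorised over the (f₁, f₂) grid
per stage-size pair; rows violating the necessary condition
B(f₁ | n₁, π₁) ≤ β are pruned. The null-optimal design minimises ESS(π₀)
(ties: smaller maximal size, then smaller n₁, f₁, f₂); the minimax design
minimises n₁ + n₂ (ties: ESS(π₀), then smaller n₁ — the tie rule is this
package's own convention). Under the strict convention the reported
minimax f₂ sits one below r values quoted under the ≥ convention; stage
sizes are convention-robust. Simon designs expose
`as_gehan_schedule()` so every operating-characteristic routine applies to
them unchanged.

## Numerical conventions

* Binomial tails and beta quantiles are evaluated through scipy's
  regularised incomplete-beta machinery (stable to trial counts of
  hundreds, far beyond phase II needs); a log-space mass evaluation exists
  for cross-checks.
* Boundary comparisons (sizing constraints, level-α checks, monotonicity)
  use absolute tolerance 10⁻¹², guarding against float noise at exact
  boundaries. Matching a conditional error value to its attainable-tail
  cutoff uses a *relative* tolerance (factor 1 + 10⁻⁹), since attainable
  tails such as π₀^{n₂} can lie far below any sensible absolute tolerance.
* Stage-two size searches scan linearly from 0 with a configurable cap
  (default 10 000) and raise a capped-search error naming the cap if
  exhausted; f_G additionally has the closed form
  ⌈π̂(1 − π̂)/γ² − n₁⌉ clipped at 0, used as a cross-check.
* When the conservative estimator's candidates tie in distance to ½, the
  schedule builder evaluates all tied candidates and keeps the larger n₂
  (the conservative direction); for f_G ties are inert since equidistant
  candidates share the same variance.
* The tool is fully deterministic: identical configuration gives
  bit-identical output everywhere.

## Known limitations

* Interval lengths default to the pooled exact interval, which ignores the
  adaptive sampling rule; adjusted intervals must be supplied by the
  caller via `length_fn`.
* One published calibrated value sits a single 10⁻⁴ grid step away from
  the value computed here (conservative method, γ* = 0.0685 vs 0.0686):
  at the printed γ the sizing inequality holds at n₂ = 45 by a margin of
  about 2·10⁻⁷, so the exact minimal schedule differs from the printed one
  there, while the calibrated design itself (schedule, power 0.804)
  matches. The reproduction registry carries a one-grid-step tolerance for
  that label only.
* Discreteness can leave the optimal test with type-I error far below α
  (and hence low power) when stage-two sizes are small; the package
  reports infeasibility or the conservative optimum rather than relaxing
  monotonicity. Enlarging the n₂(s₁) beyond the precision requirement, or
  calibrating γ, are the supported remedies.
* Curtailment, high-response-rate stage-one modifications, expected-sample-
  size-optimal DCEFs, and prospective second-stage redesign are out of
  scope.
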