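# gehanflex

Exact design and testing machinery for Gehan-type two-stage single-arm
phase II trials, with Simon two-stage designs as comparators.

## The problem

Gehan's classic two-stage design screens a new regimen for activity: enrol
n₁ patients in stage one and stop for futility only if *no* responses are
seen; otherwise choose a stage-two sample size n₂(s₁), adaptively in the
observed response count s₁, so that the response rate π can be estimated to
a prescribed precision at the end of the trial. Its historical weakness is
that it tests no hypothesis — it controls neither the type-I error rate nor
power.

This package closes that gap by viewing Gehan's design as a *flexible
two-stage design* and embedding an exact test of H₀: π = π₀ through a
**discrete conditional error function (DCEF)**: values D(s₁) ∈ [0, 1] with
D(s₁) = 0 a futility stop, D(s₁) = 1 an efficacy stop, and interior values
meaning the trial continues and rejects H₀ when the stage-two p-value

&nbsp;&nbsp;&nbsp;&nbsp;p₂ = P(S₂ ≥ s₂ | n₂(s₁), π₀) = 1 − B(s₂ − 1 | n₂(s₁), π₀)

is at most D(s₁). The test is exact and controlled at level α whenever

&nbsp;&nbsp;&nbsp;&nbsp;Σ_{s₁} D(s₁) · b(s₁ | n₁, π₀) ≤ α,

where b and B are the Bin(n₁, π) mass and distribution functions. Because
the stage-two p-value is a binomial tail, each D(s₁) ranges over a *finite*
attainable set, and the package searches this discrete space exhaustively
by **branch-and-bound** for the DCEF maximising power P(π₁) — with exact
type-I-error and power bounds pruning subtrees that cannot contain the
optimum.

Around this core the package provides:

* **stage-one sizing** — smallest n₁ with (1 − π₁)^n₁ ≤ β₁;
* **interim estimators** — Gehan's Wald-style upper 75% confidence limit
  ("original") and an exact-interval alternative that takes, among the
  Clopper-Pearson limits and the MLE, the candidate closest to ½
  ("conservative");
* **three stage-two sizing rules** — f_G (bound the estimated standard
  error √(π̂(1−π̂)/(n₁+n₂)) by γ), f_L (bound the *worst-case* exact
  confidence-interval length), f_EL (bound the *expected* exact interval
  length under the interim estimate);
* **exact operating characteristics** — rejection-probability curves,
  expected sample size ESS(π), and conditional expected interval lengths
  (CEL), all by exhaustive summation, never simulation;
* **γ calibration** — a descending grid search for the largest precision
  parameter whose optimised design reaches a target power;
* **Simon design search** — exhaustive exact search for the null-optimal
  and minimax two-stage group-sequential comparators.

Intended users are trial statisticians designing single-arm binary-endpoint
studies, and methodologists comparing adaptive against group-sequential
two-stage designs.

## Worked example

A trial of bevacizumab in hereditary hemorrhagic telangiectasia used
Gehan's design with β₁ = 0.1, π₁ = 0.3 and γ = 0.1; we test at α = 0.05
against π₀ = 0.15:

```bash
$ gehan-flex design --pi0 0.15 --pi1 0.3 --alpha 0.05 --beta1 0.1 \
    --gamma 0.1 --method original --rule f_G --out design.csv
n1=7  type-I=0.0206  power=0.4035  ESS(pi0)=17.42  ESS(pi1)=20.83
```

Seven patients are enrolled in stage one; the exported table holds the
adaptive schedule n₂ = (0, 14, 18, 16, 10, 2, 0, 0) for s₁ = 0…7 together
with the optimal conditional error values D(s₁) and their integer rejection
cutoffs. The optimal test only reaches 40% power at π = 0.3 — Gehan's
precision-driven sizing is not power-calibrated. Asking for the largest γ
that yields 80% power:

```bash
$ gehan-flex calibrate --pi0 0.15 --pi1 0.3 --alpha 0.05 --beta1 0.1 \
    --method original --rule f_G --target-power 0.8
gamma*=0.0658  power=0.8001  ESS(pi0)=37.52
```

and the group-sequential comparators for the same error rates (type-II
budget β = 0.2):

```bash
$ gehan-flex simon --pi0 0.15 --pi1 0.3 --alpha 0.05 --beta 0.2
null-optimal: f1=3 n1=19 f2=12 n2=36  type-I=0.0477 type-II=0.1994 ESS(pi0)=30.37
minimax: f1=3 n1=23 f2=11 n2=25  type-I=0.0455 type-II=0.1965 ESS(pi0)=34.51
```

So the power-calibrated Gehan design needs 58 patients at most and about
37.5 on average under the null, against a maximum of 48–55 and a null ESS
of 30–35 for Simon's designs: the adaptive precision-driven design pays an
efficiency price for its estimation guarantee.

`gehan-flex oc` exports rejection-probability, ESS and CEL curves as CSV,
and `gehan-flex reproduce --all` recomputes every registered worked result
and compares it with its reference value.

## Layout

| module | contents |
| --- | --- |
| `gehanflex.binom` | exact binomial masses/tails, Clopper-Pearson intervals and lengths, normal quantile |
| `gehanflex.design` | stage-one sizing, interim estimators, the f_G / f_L / f_EL stage-two rules |
| `gehanflex.dcef` | DCEF representation (integer cutoffs), restrictions, exact type-I error and power |
| `gehanflex.optimise` | branch-and-bound power maximisation with exact pruning bounds |
| `gehanflex.oc` | ESS, futility boundary, conditional expected interval lengths, curve export |
| `gehanflex.calibrate` | γ search for a target power, memoised by induced schedule |
| `gehanflex.simon` | exact Simon null-optimal/minimax design search |
| `gehanflex.cli`, `gehanflex.report` | `gehan-flex` command line, CSV round-tripping, reproduction registry |

See `docs/methods.md` for the statistical model, conventions (decision
rules, tie-breaks, tolerances) and known limitations.
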