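# Methods

## Model and estimands

All inputs are aggregate binomial two-arm trial summaries: arm label,
participants `n`, responders `r`, response rate `p̂ = r/n`. Treatment contrasts
are response-rate ratios analysed on the natural-log scale, where a rate ratio
RR has approximate SE

    SE(ln RR) = sqrt(1/r₁ + 1/r₂ − 1/n₁ − 1/n₂),

the delta-method variance of a log binomial proportion summed over two
independent arms. Wald CIs for rates are `p̂ ± z·sqrt(p̂(1−p̂)/n)` and are not
truncated to [0, 1] by default (a `clip` flag exists); truncation would change
small-arm bounds that are conventionally reported untruncated.

The anchor-based indirect comparison estimates the effect of Reference (R)
vs Placebo (P) from two trials sharing an anchor arm (A):

    ln RR(R,P) = ln RR(A,P) − ln RR(A,R),
    Var = Var(ln RR(A,P)) + Var(ln RR(A,R)).

Validity rests on transitivity (effect modifiers balanced across the bridged
trials) and its statistical counterpart, consistency; neither is testable
without direct evidence, which is exactly why the sensitivity analyses below
exist.

The equivalence margin retains a preservation fraction `f` of the lower
95% CI bound `L` of the indirect effect (95-95 fixed-margin method):

    upper = exp((1 − f)·ln L),  lower = 1/upper.

The margin is symmetric on the log scale by construction. The inverse map
`preservation_of(U, L) = 1 − ln U / ln L` is exact and returned *signed*, so
sweeps can show retention dropping below zero rather than erroring. Margin
derivation requires `L > 1`; an effect that does not demonstrate superiority
has no derivable margin and raises a dedicated error (CLI exit code 3).
Effects supplied in the protective direction (RR < 1) are inverted internally.
The equivalence verdict uses strict CI containment (configurable to closed)
and flags the case where the CI is contained but excludes 1.

## Numerical conventions

* **z-multiplier.** The default is the exact two-sided 95% normal quantile
  (1.9599640). With the rounded 1.96 the 40%-preservation margin bound
  computes to 1.4534997, which sits a hair *below* the 3-decimal rounding
  boundary; the exact quantile gives 1.4535046, matching the conventionally
  reported 1.454. All other reported quantities agree to 3 decimals under
  either multiplier. 1.96 remains available as an explicit override
  everywhere (`z=` argument, `--z` flag, `z_multiplier` config key).
* **Rates** are carried at full floating precision; rounding to 3 decimals
  happens only in report output.
* **Zero responders.** The log-ratio SE is undefined with an empty cell.
  Direct estimation refuses by default; an opt-in continuity correction adds
  0.5 to all four cells of the affected comparison.

## Sensitivity analysis 1 — direct anchor margin

The 95-95 margin computed from the Anchor-vs-Placebo trial alone. It is
informative when Anchor ≈ Reference: a direct margin no tighter than the
indirect one supports the consistency assumption.

## Sensitivity analysis 2 — varying the assumed effects

**Deterministic sweeps.** The true Reference rate is varied across its 95% CI
(default grid: the CI endpoints rounded to 3 decimals, stepped by 0.001 —
139 points for the case study, endpoints included so grid minima are exact).
For each candidate rate the Trial-1 comparison is rebuilt at the original arm
sizes, the indirect CI recomputed, and the preservation the proposed margin
still achieves recorded. In the first variant the anchor rate stays at its
observed point estimate; in the second the Anchor-minus-Reference difference
is fixed (0.045 = observed, 0.060, 0.075, 0.090 by default) and the anchor
rate follows the reference rate. Candidate rates enter the SE formula through
expected responder counts `n·p`. These are fractional by default
(`sweep_mode=continuous`); `integer` rounds them to whole responders. The two
conventions differ by under 0.1 percentage point in the case-study minima
(e.g. 48.29% vs 48.19% at the 9-point difference); integer rounding matches
the conventionally quoted one-decimal values exactly, continuous is the
default because assumed true rates need not produce integer counts.

**Posterior-predictive Monte-Carlo.** Per replicate: draw the true Reference
rate from its Beta posterior under a non-informative prior, redraw the
observed rate as Binomial(n, μ*)/n, recompute the indirect CI (anchor arm and
the Anchor-vs-Placebo trial held fixed) and record the achieved preservation.
The exceedance curve P(preservation ≥ f) is the per-target count divided by
the full replicate count. A second variant redraws both Trial-1 arms from
independent posteriors (arms are independent binomials; no joint modelling).
Defaults: Beta(1,1) prior (`jeffreys` available — the choice moves exceedance
probabilities by less than Monte-Carlo noise at 1000 replicates), 1000
replicates in the CLI, mandatory explicit seed, one `numpy` generator per
call so fixed (seed, n_reps) is bit-reproducible. Replicates with zero
simulated responders or an indirect CI bound ≤ 1 are excluded and counted
(`n_excluded`); at case-study rates this is a ≲10⁻⁴ event and the exclusions
count as failures in the exceedance denominator.

At 100,000 replicates the reference-only exceedance converges to ≈48.4%
(f = 0.60) and ≈83.6% (f = 0.50), and the both-arm variant to ≈50.2% and
≈78.2% (test suite and acceptance script compute these at run time).
A 1000-replicate run — the resolution at which such probabilities are
conventionally quoted — has a Monte-Carlo SE of 1.2–1.6 percentage points, so
individual 1000-replicate estimates scatter by a couple of points around
these values.

## Sensitivity analysis 3 — heterogeneous extra trials

Additional Anchor-vs-Placebo trials from slightly different populations are
pooled per comparison *before* the indirect step. The primary pooling model is
DerSimonian–Laird random effects: Q from inverse-variance common-effect
residuals, `τ² = max(0, (Q − df)/C)` with `C = Σw − Σw²/Σw`, weights
`1/(SEᵢ² + τ²)`, normal-approximation CI (not Hartung–Knapp, matching the
conventional interval width at these sizes). `I² = max(0, (Q − df)/Q)` is
reported alongside. Common-effect alternatives: inverse-variance, and
Mantel–Haenszel on the 2×2 counts with the Greenland–Robins variance (the
usual common-effect line of a forest plot; it needs full counts, not summary
SEs). With a single trial every model reduces to that trial's estimate with
τ² = 0. The pooled estimate then feeds the ordinary indirect comparison and
margin derivation; the preservation an existing (legacy) margin retains under
the pooled effect is also reported.

## Synthetic data

`case_study_fixture()` returns the three worked-example trials with
hard-coded counts (Trial 1: Anchor 94/200 vs Reference 85/200; Trial 2:
Anchor 183/350 vs Placebo 64/350; Trial 3: Anchor 53/100 vs Placebo 5/50).
`simulate_trial` draws independent binomial responder counts from stated true
rates — exactly the generative model the estimators assume. Simulated tests
therefore validate internal consistency (estimator calibration, margin
parameter recovery), not robustness to real-data features the model excludes:
effect-modifier imbalance between trials, non-binomial overdispersion within
arms, or correlated arms. Parameter-recovery checks use true rates equal to
the case-study point estimates at the case-study sample sizes (2000
replicates; the median derived margin recovers the proposed one within 0.01).

## Problem sizes and runtime

Everything is desk-scale: deterministic analyses are closed-form on four to
six counts; Monte-Carlo checks use 100,000 replicates (vectorised, well under
a second) and recovery simulations 2000 replicates of the full pipeline.

## Known limitations

Binomial endpoints and rate ratios only (no risk differences, odds ratios,
continuous or time-to-event endpoints); star networks of exactly one anchor
and ≤ 3 treatments; no informative priors, no joint posterior across arms; no
meta-regression, alternative τ² estimators, or publication-bias diagnostics;
figures are exported as plot-ready CSV data, not rendered graphics.
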