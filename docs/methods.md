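# Methods

This note documents the generative model, the estimators, the screening
and inference procedures, and the numerical choices behind `remindersim`.
It states no empirical result that the test suite or the analysis scripts
do not themselves compute.

## Task model

A session is a sequence of symbolic trials. Each trial carries 10 target
positions drawn from sequence positions 7–25: the 19 admissible positions
are partitioned into 10 adjacent bins — nine of length two and one of
length one whose slot is uniform over the ten bins — and one position is
drawn uniformly within each bin. The graphical mechanics of the original
paradigm (dragging, fading, screen geometry) are deliberately absent: all
downstream measures depend only on per-target hit/miss counts and on which
strategy ran, so a trial outcome is a vector of independent Bernoulli hits
with probability `p_internal` or `p_external`.

The between-participants design runs one 17-trial block per participant
(9 free-choice trials carrying a random permutation of offers 1–9, shown
as −9..−1 under loss framing, interleaved with 8 forced trials alternating
internal/external from a uniformly random starting type). The
within-participants design runs two 13-trial blocks (7 choice trials over
offers 2–8 — under loss framing the offer is the number of points lost —
and 6 alternating forced trials), one block per framing, order
counterbalanced by deterministic alternation over participant index; the
second block starts on the opposite forced type from the first.

Practice trials and the 8-of-10 practice accuracy gate are not simulated;
agents are sampled past the gate (`p_external ≥ 0.8` enforced by
truncation).

## Agent model

An agent is parameterized by true accuracies (`p_internal`, `p_external`),
confidence reports in percent (`conf_internal`, `conf_external`), a
subjective indifference point on the gain-equivalent 1–9 scale, an additive
`framing_shift` applied under loss framing, a `choice_slope`, and a `lapse`
rate. On a free-choice trial with gain-equivalent offer *x* the probability
of choosing reminders is

    P(external) = lapse/2 + (1 − lapse) · logistic(slope · (x − s_f)),
    s_f = subjective_ip + framing_shift · [framing = loss].

A positive shift means fewer reminder choices under loss framing — the
risk-preference reversal the design measures, implemented as the smallest
mechanism that produces it. No learning, fatigue, serial-position or
effort-cost dynamics are modelled; memory success is i.i.d. Bernoulli per
target. These are documented extension points, not claims about real
behaviour.

### Population defaults

| parameter | default | rationale |
|---|---|---|
| `p_internal` | truncNormal(0.65, 0.12) on [0, 1] | internal accuracy near two-thirds |
| `p_external` | truncNormal(0.95, 0.04) on [0.8, 1] | near-ceiling with reminders; lower bound = practice-gate surrogate |
| `conf_internal` | 100·p_internal + truncNormal(−7, 25) clamped to [0, 100] | mean internal underconfidence ≈ −7 points |
| `conf_external` | 100·p_external + truncNormal(−11, 14) clamped | mean external underconfidence ≈ −11 points |
| `subjective_ip` | true OIP + truncNormal(−1.5, 1.2), clamped to [1, 9] | a ~1.5-point reminder bias in the gain condition |
| `framing_shift` | truncNormal(1.0, 0.8) on [0, ∞) | ~1-point bias reduction under loss framing |
| `choice_slope` | logNormal(log 1.5, 0.3) | moderate choice determinism (per point) |
| `lapse` | Beta(1, 19) on [0, 0.5] | ~5% random choices |

Group means are calibrated to the behavioural profile the task reliably
produces; the *spreads* have no published counterpart and are the
implementer's calibration. Setting any scale parameter to zero collapses a
field to its location, which the tests use for exact checks.

The default policy ties `subjective_ip` to the agent's *true* optimal point
(`10·p_internal/p_external`, clamped). An alternative policy
(`ip_policy="confidence"`) derives it from the confidence ratio instead,
which makes underconfidence causally drive reminder overuse. Note that
even under the default policy the measured internal metacognitive bias and
the measured reminder bias correlate negatively: both contain the
forced-internal accuracy estimate with opposite signs, so shared
measurement noise and accuracy heterogeneity induce the negative
relationship at the cohort level.

Confidence reports are noiseless by default (the report equals the
parameter); bounded Gaussian reporting noise is available.

## Indifference-point estimation

The optimal indifference point is `OIP = clamp(10 · ACC_FI / ACC_FE)` to
the offer range ([1, 9] or [2, 8]); `ACC_FE = 0` is an error (the normative
point is undefined). Clamping keeps OIP commensurable with the AIP, whose
support is bounded by the offered values.

The actual indifference point is the location parameter of a two-parameter
sigmoid (logistic by default; a cumulative-normal link is a configuration
switch) fitted by maximum likelihood to the binary choices on the
gain-equivalent offer scale, then clamped to the offer range. Numerical
choices:

- The likelihood uses softplus / log-CDF terms rather than clipped
  probabilities, so near-separable response patterns retain a resolvable
  surface instead of underflowing to a flat plateau.
- The slope is constrained to [0.01, 50] per point. Perfectly separable
  data (common with one observation per offer) are resolved analytically:
  slope at the cap, location at the likelihood-maximizing point there —
  the midpoint of the step interval.
- Degenerate all-reminders / all-memory patterns resolve to the lower /
  upper offer bound respectively.
- Otherwise a coarse likelihood grid over (location, log-slope) seeds an
  L-BFGS-B polish, keeping the fit effectively global; the grid winner is
  retained if the polish fails to improve on it. The fit reports both the
  raw and the clamped location, the slope, the log-likelihood and a
  convergence flag.

One caveat worth knowing: with the slope free, the MLE location is *not*
monotone in single choices. Adding a reminder choice at the lowest offer
can flatten the fitted curve and move the 50% crossing *up* (a dense-grid
counterexample is in the test suite). At any fixed slope the
likelihood-maximizing location is monotone (a monotone-likelihood-ratio
property), and the tests assert that version.

## Screening

Both preregistered pipelines run in one pass. Deterministic rules first:
(a) mean forced-internal accuracy < 10%; (b) mean forced-external accuracy
< 70% (both averaged over framings where two exist); (c) internal accuracy
exceeding external in either condition; (d) negative point-biserial
correlation between gain-equivalent offers and strategy choices —
a constant choice vector leaves the correlation undefined and the
participant is retained (the rule targets a *negative* correlation only).
In the within-participants design the choices from both blocks are pooled
on the gain-equivalent scale; transforming loss offers first is essential,
since the raw loss scale would flip the correlation's sign.

Distributional rules then score *every* participant against group
statistics computed over the (a)–(d) survivors (the rules are independent,
so a participant can carry several codes): the between-participants design
flags reminder-bias scores beyond 2.5 group SDs; the within-participants
design flags 3 scaled-MAD deviations on (e) the mean reminder bias, (f)
the gain−loss bias difference, and (g) the internal metacognitive bias.
MAD units use the 1.4826 consistency constant (raw MAD via
`mad_constant=1.0`); a zero MAD marks only exact-median scores as inliers.
The rules are applied once, non-iteratively (an `iterate` switch exists
for sensitivity checks); whether participants failing (a)–(d) enter the
group statistics is likewise a switch, off by default.

## Inference

All tests except the mixed models are formula-level implementations:

- One-sample / paired t-tests with configurable sidedness and effect sizes
  `d = mean/SD`, `d_z = mean difference / SD of differences` (equivalently
  `t/√n`; no small-sample correction). Zero-variance inputs return a
  flagged non-result rather than raising.
- 2×2 ANOVAs from sums of squares with partial η² = SS_effect /
  (SS_effect + SS_error). The mixed design accepts unequal group sizes
  (each subject must contribute both within-levels) and uses weighted
  (sequential) sums of squares, which coincide with every other type in
  the balanced case; the between-factor F equals the squared pooled
  two-sample t on subject means and the interaction F the squared t on
  difference scores. The fully within design requires complete 2×2 cells
  per subject.
- Pearson correlations with t-based p-values; Fisher's z for independent
  correlations.
- Dependent, non-overlapping correlation comparisons via the classical
  asymptotic covariance of two correlations sharing no variable
  (Pearson–Filon/Olkin–Siotani form). Two statistics are exposed: the raw
  Pearson–Filon z and a Fisher-transformed variant in which the covariance
  enters as the correlation between the two transformed estimates. The
  assembled 4×4 correlation matrix must be positive semi-definite. In the
  independence limit both reduce to the independent-samples comparison.
- Random-intercept linear mixed models through statsmodels `MixedLM`,
  fitted by full maximum likelihood so AICs and likelihood-ratio tests are
  comparable across fixed-effect structures (REML fits must not enter
  LRTs over fixed effects). AIC counts the fixed effects plus the two
  variance parameters; the LRT is `χ² = 2Δlog L` (floored at zero) with
  df = Δk and a χ² reference, and `χ² = ΔAIC + 2Δk` holds by construction.
  Optimizers fall back (lbfgs → bfgs → powell) when a boundary variance
  produces a singular Hessian.
- Paired-t power from the noncentral t distribution;
  `required_n_paired_t` returns the smallest n reaching the target power.

The orchestrated analysis mirrors each design's sequence (accuracy ANOVA,
bias tests, correlation structure, and — within-participants — the
metacognitive battery and the model-selection ladder intercept-only →
+metacognitive bias → +framing → +interaction). The between-participants
bias t-tests default to one-tailed, the within-participants battery to
two-tailed; sidedness is always an explicit parameter. Reports are
deterministic given (config, seed), and re-analyzing the emitted cohort
CSVs reproduces the report exactly (`%.17g` on write, round-trip float
parsing on read).

## What the simulation does and does not establish

The generator reproduces the *statistical structure* the analysis assumes:
accuracy levels, near-ceiling external performance, underconfident
metacognition, sigmoidal choice with a framing shift, and cohort-level
heterogeneity. Passing tests therefore establish that the estimators and
tests behave correctly for data of that structure — parameter recovery,
type-I error control, power — not that real participants satisfy the
model (real data have sequential dependencies, attention lapses correlated
across trials, order effects, and confidence dynamics that the generator
omits by design).

Problem sizes used by the tests and scripts: cohorts of 141
(between-participants) and 300 (within-participants) as in the modelled
designs; 200 agents × 200 choices per offer for psychometric recovery; 500
agents × 10 sessions for the unbiased-cohort null; 100 seeded replicate
runs at n = 300 each for the framing-effect power and type-I checks; 50
random balanced fixtures for the ANOVA oracle.

## Known limitations

- The AIP estimator with one observation per offer is noisy and bounded;
  clamping at the offer-range edges mildly compresses extreme biases (both
  OIP and AIP are clamped, by construction of the task).
- Weighted sums of squares in the unbalanced mixed ANOVA differ from
  Type-III conventions when group sizes differ; for the simulated designs
  the difference is immaterial, but comparisons with Type-III software
  output on strongly unbalanced data will not match exactly.
- The mixed-model AIC uses the ML parameter count including both variance
  components; software that drops the residual variance from k will report
  AICs offset by 2 (model *differences* are unaffected).
- The dependent-correlation statistics are asymptotic; at small n their
  type-I error is only approximately nominal (the test suite checks n =
  200).
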