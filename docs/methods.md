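# Methods

## Model

The benefit-risk model is an additive multi-criteria value function
`U(x) = Σᵢ wᵢ vᵢ(xᵢ)` over seven attributes of aortic-valve replacement.
Partial value functions are linear over each attribute's modelled
performance range — a deliberate simplification: eliciting the shape of
seven value functions would overburden respondents, and linearity is the
assumption under which the published threshold table is interpretable.
The ranges are the union of the two alternatives' 95% CIs (e.g. mortality
0.5%–5.3%), not each pair's observed span; the binary type-of-procedure
attribute (invasive = 0, minimally invasive = 1) participates like any
other attribute and anchors the weight scale at 1.

Internally all probabilities are proportions in [0, 1] and durations are
years; reports render percentages at one decimal.

### Weights

An indifference amount (MIR, maximum acceptable increase in risk; MRB,
maximum acceptable reduction in benefit) converts to a raw swing weight as
`w = range / MIR`. Group-level weights divide the range by the **group
mean MIR** rather than averaging individual weights: the reciprocal
transform is convex, so the two differ (Jensen), and only the former
reproduces the study's threshold table from its preference summary.
Individual weight vectors (range / individual MIR) are used when
resampling preferences in the Monte Carlo simulation. Missing items are
never imputed; each attribute's group mean uses whoever completed it, and
a respondent enters the panel at all only with at least one completed
exercise. Censored (straight-lined) indifference amounts are retained at
their censoring bound by default, with an exclusion switch for
sensitivity analysis.

### Threshold analysis

For attribute `a`, a unit of performance is worth `wₐ / rangeₐ` raw value
units, so the level displacement that exactly consumes the overall
advantage `ΔU = U(TAVR) − U(SAVR)` is `ΔU · rangeₐ / wₐ`. The sign is
direction-aware: risks rise (`MARₐ = TAVRₐ + displacement`) and benefits
fall (`MABₐ = TAVRₐ − displacement`) toward indifference, so the
threshold always moves toward worse TAVR performance when TAVR is ahead.
Thresholds are invariant to weight normalization (the scale cancels
between ΔU and wₐ). Solutions are clamped to feasible levels —
probabilities to [0, 1], durations floored at 0 years — with the
unclamped value retained; the self-consistency identity (substituting the
unclamped threshold yields `U(TAVR) = U(SAVR)` to 1e-9) is enforced by a
property test over random configurations.

## Elicitation engine

The adaptive swing-weighting exercise is a three-iteration pairwise
choice between improving the procedure's invasiveness and improving one
attribute by an offered amount. The engine implements a dyadic bisection
ladder on `(0, max_change]`: the first offer is half the maximum and each
subsequent offer moves toward the respondent's indifference point with
the step halving, which is the adaptive structure implied by three
iterations converging on an indifference point. The eight response
patterns partition the interval into eight cells of width
`max_change / 8`; point estimates are cell midpoints. One-sided patterns
are censored — all-procedure at the ladder maximum, all-attribute below
the smallest offer — and a respondent whose every completed exercise is
one-sided is classified a straight-liner. The offer schedule is
replaceable by an explicit per-history grid, so a published instrument
with display-rounded levels can be dropped in without touching the
estimator.

Simulated respondents choose deterministically (attribute improvement iff
the offer exceeds their latent indifference amount) or through a logistic
choice probability with a configurable scale; the deterministic rule is
the zero-scale limit.

## Synthetic panel generator

The generator emulates the observable structure of the preference survey:
219 respondents, 60.3% under 60; latent indifference amounts per
attribute drawn from age-group-specific truncated normals whose
parameters default to the published group summaries (older respondents
tolerate more risk on mortality, pacemaker and dialysis); per-attribute
item missingness matching the published per-attribute n (with an
alternative mode assigning each respondent 3–4 of the six exercises, as
the survey did); and an 8.68% straight-liner fraction planted as
respondents whose latent preference lies beyond the ladder on every
attribute (split evenly between the strongly-invasiveness-averse and the
strongly-attribute-prioritizing sides, the split being unreported).

Ladder maxima default to roughly twice the whole-sample mean indifference
amount (mortality 8 pp, stroke 14 pp, independence 28 pp, pacemaker
14 pp, dialysis 12 pp, proven-to-work 35 years). This keeps every group
mean interior to the offer range and makes the `(0, max]` truncation
nearly symmetric about the mean, so the truncated latent distribution
preserves the configured mean. It cannot preserve the configured SD: the
published dispersions (SD/mean ratios of 0.76–0.97) exceed what a
truncated normal on such an interval can attain, reflecting heaping of
real responses at instrument bounds. The generator therefore exposes its
analytic post-truncation moments (`latent_moments`) as the ground truth
that recovery tests check against, and a lognormal latent family is
available as an alternative shape. Between-attribute correlation of
indifference amounts is not modelled (independence by default; the true
correlation is unreported).

Consequences for interpretation: synthetic panels reproduce the study's
mean preferences — and hence its group-level weights and threshold
columns — but understate its preference heterogeneity, so the synthetic
Monte Carlo probability that TAVR ranks first is higher (≈0.9 at the
default conditions) than with real, more dispersed panels. Passing tests
demonstrate correctness of the pipeline and recovery of generator
parameters, not the dispersion of real respondents.

## Monte Carlo simulation

Each of the 10,000 default iterations draws every alternative × attribute
performance level from `Normal(mean, se)` — `se = CI width / (2·1.96)` —
truncated to feasible bounds by exact rejection sampling (attributes
without a CI are point masses), and one weight vector from the panel.
Weight resampling defaults to whole-respondent bootstrap, preserving
within-person correlation across attributes; an attribute-independent
bootstrap (each attribute's MIR resampled from its empirical marginal) is
selectable and recorded in the output metadata, since the original
analysis's scheme is ambiguous. Respondents missing an attribute get the
group-mean weight for it. Alternatives are ranked by U; exact ties split
first place evenly (measure-zero under continuous sampling). Results
carry the seed, scheme, subgroup and exclusion settings, and the binomial
Monte-Carlo standard error `√(p(1−p)/n)`; fixed seeds give bit-identical
results. Subgroup runs (<60 / ≥60) and straight-liner exclusion use the
same filter vocabulary as the weight derivation.

## Numerical choices and problem sizes

- Degenerate inputs raise typed errors naming the attribute or row:
  nonpositive MIRs, zero weights in a threshold, empty groups, malformed
  CSV/JSON.
- SDs use the n−1 denominator throughout.
- Tolerances: decomposition conservation and threshold self-consistency
  at 1e-9; published-value reproduction at the rounding of the printed
  inputs (±0.1 pp whole-sample, ±0.15 pp subgroup).
- Test problem sizes: moment-recovery panels use n = 2000 (standard
  errors small enough for 3-SE checks while the full suite stays fast);
  Monte Carlo tests use a few hundred to 2,500 iterations, the CLI
  default remaining 10,000.

## Limitations

- Linear partial values; no more than two alternatives exercised (the
  algebra supports more).
- The KCCQ-score → proportion transform is a normal tail probability at
  the cutoff (default 75), a minimal reading of the source procedure, and
  is pluggable; the all-stroke → non-fatal disabling stroke adjustment is
  multiplicative survival with the case-fatality fraction as an explicit
  config parameter (default 0, i.e. pass-through, since the packaged
  performance table is already on the non-fatal scale).
- Latent preference dispersion is understated by the truncated-normal
  family, as discussed above.
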