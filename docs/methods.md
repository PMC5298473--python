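# Methods

## Decision models

The package models a paired gloss/lightness comparison as a Gaussian
signal-detection decision. Each stimulus on a gloss × lightness lattice
evokes a noise-free internal estimate of the judged attribute —
independent model: the judged dimension's own scale value; additive
model: the sum of both dimensions' values; full model: the additive sum
plus a per-cell interaction term — and the trial outcome is determined
by the difference of the two estimates plus a single zero-mean Gaussian
error ε ~ N(0, σ²) attached to the difference (not one error per
stimulus). The response rule is "choose the first stimulus iff the noisy
difference is positive", so P(first) = Φ(δ/σ). A drawn difference of
exactly zero — a probability-zero event under continuous noise — is
resolved to the second stimulus in simulation; the probabilistic model
needs no tie-break. No lapse or guessing parameter is included.

## Identifiability and parameterization

The likelihood is invariant to adding a constant to either dimension's
scale and to rescaling all parameters together with σ. Identification
fixes σ = 1 (estimates are in noise units) and anchors one value per
dimension at zero — level 3 by default, chosen because mid-level stimuli
serve as a natural reference; anchoring at level 1 is available for
cross-checks. The full model is parameterized as one value per lattice
cell with the single cell (3, 3) anchored — numerically equivalent to
main effects plus interactions but free of redundant constraints — giving
4 / 8 / 24 free parameters for the independent / additive / full models
on a 5 × 5 lattice (6 / 11 / 26 before anchoring, σ included).

## Estimation

Each trial contributes a row of a signed indicator matrix (+1 for the
first stimulus's free parameters, −1 for the second's), reducing the fit
to a probit regression through the origin. The Bernoulli log-likelihood
is maximized by BFGS from a zero start with an analytic gradient
(gradient tolerance 1e-8); tail probabilities use `log_ndtr` so the
objective is stable for extreme decision values. The procedure is
deterministic given the data. Standard errors come from the inverse
observed information at the optimum (pseudo-inverse, so unidentified
directions report large-but-finite errors).

Complete separation — a level that sits on the chosen stimulus in every
trial where it appears — makes the corresponding estimate diverge. Such
parameters are detected directly from the data, flagged with a warning,
and represented at the boundary value ±10 (≈ a certainty of Φ(10) in a
single-level contrast) while the remaining parameters are refit with the
separated ones pinned. Penalized likelihood was deliberately avoided so
that the estimator is exactly maximum likelihood on well-behaved data.

## Model comparison

The three models form a nested chain, so twice the log-likelihood
improvement is referred to χ² with df equal to the difference in free
parameters (4 and 16 at the canonical design size). The asymptotic
reference is used without small-sample correction; at 900 trials per
observer the Monte-Carlo calibration study (500 null replicates) finds
the empirical null distribution within Kolmogorov distance ~0.04 of
χ²(4) and a type-I error of ~0.05 at α = .05. Decisions across a family
of observers use the Bonferroni level α/n (0.0083 for α = .05, n = 6).
A tiny negative log-likelihood improvement (< 1e-6) is treated as
round-off and clipped to zero; anything larger raises an optimization
error rather than silently producing a negative statistic.

## Contamination index

The summary statistic for cue intrusion is the signed end-to-end range
of the irrelevant dimension's fitted scale divided by the absolute
end-to-end range of the judged dimension's scale, computed from an
additive (or full, via row/column marginal means of the cell matrix)
fit. Negative values mean the irrelevant cue suppresses the judged
attribute. End-to-end ranges (last minus first level) rather than
max-minus-min are used so that the sign is meaningful for monotone
scales. Two cross-observer reducers are provided: the mean of
per-observer range ratios (default) and the ratio of ranges of the
observer-averaged normalized scales; at the simulated effect sizes the
two agree closely. Normalization divides all estimates of a fit by the
largest absolute estimate, so the strongest parameter becomes ±1 and
ratios are preserved.

## Synthetic observers

Because the package ships no human data, generative observers define the
study conditions. The default judged-dimension scale is linear over
levels — appropriate when stimulus levels have been equalized by a prior
MLDS calibration — with an end-to-end range of 4 σ-units, a
discriminability that yields choice proportions spanning roughly 0.02 to
0.98 across the lattice (neither floor/ceiling-saturated nor
noise-dominated). The contaminated observer sets the irrelevant scale to
a signed fraction w of the judged scale; w = −0.32 and w = −0.12 are the
canonical recovery targets. Center-surround (simultaneous-contrast)
displays reuse the same machinery with the lattice reinterpreted as the
background's (gloss, albedo): the contrast observer's center-lightness
scale decreases monotonically in background albedo, and the chained
observer composes that contrast shift with the lightness-on-gloss
contamination, making perceived center gloss increase with background
albedo. The chained observer's weights are configurable, not canonical.

What the simulations do not emulate: real observers' lapses,
sequential dependencies, criterion drift, inter-observer heterogeneity
in σ or scale shape, and any image-level cues (highlight structure,
luminance histograms). Passing recovery tests therefore demonstrate that
the estimator is unbiased and well-calibrated under the stated decision
model, not that the model is true of human data.

## MLDS calibration

The quadruple protocol with non-overlapping pairs (a < b ≤ c < d) is
used; trials are sampled uniformly from all such quadruples. The fit
maximizes the Bernoulli likelihood of
P(pair (a,b) chosen) = Φ(((ψb − ψa) − (ψd − ψc))/σ) under double
anchoring ψ₁ = 0, ψₙ = 1 with σ estimated — note the deliberate contrast
with the conjoint fits, where σ ≡ 1 and anchors are interior. Equal-step
selection inverts the fitted scale at equally spaced perceptual targets.
The interpolant is a cubic spline with Brent root-finding by default:
unlike piecewise-linear interpolation over ten calibration points
(available via `interpolation="linear"`), the spline reproduces smooth
polynomial scales exactly, so closed-form inversions (e.g. √0.5 for a
quadratic scale) are recovered to machine precision instead of O(h²)
error. Non-monotone fitted scales are rejected with an instruction to
inspect the data, since inversion is then ill-defined.

## Conjoint proportion matrices

The 25 × 25 matrix reports, for each ordered pair, the fraction of
trials in which the column stimulus was judged greater, pooling
repetitions and presentation order. One fixed block convention is used
for both tasks — gloss levels index the outer 5 × 5 blocks, lightness
levels the inner cells — so an uncontaminated gloss judge yields
constant inner blocks and any lightness dependence appears as an inner
gradient. Self-comparison cells are missing (the design excludes them),
not 0.5. Analytic expected matrices (Φ(δ/σ) per cell) are available for
any generative observer and are the convergence target of
simulate-then-aggregate.

## Problem sizes and numerical choices

Monte-Carlo studies run at the canonical design size (900 trials per
simulated observer): 200 observers per contamination-recovery study,
500 null replicates for type-I calibration, 200 for power, 1000
difference trials for MLDS recovery — sizes at which binomial error
bounds are tight enough to be informative while a full validation run
completes in well under a minute. Per-replicate seeds are spawned from a
single master seed, so every study is exactly reproducible. Schedules
randomize trial order and within-trial presentation order from one seed;
rebuilding with the same seed is bit-identical.

## Known limitations

- The asymptotic χ² reference is trusted at the canonical design size;
  no small-sample (e.g. bootstrap) calibration is provided.
- Standard errors ignore the anchoring constraint's sampling variability
  (standard practice for anchored scaling models).
- The full model at 24 parameters is fit but its per-cell estimates are
  noisy at 900 trials; the package reports them without shrinkage.
- No Bayesian estimation, bootstrap intervals, or AIC/BIC selection;
  inference is purely likelihood-ratio based.
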