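# Methods

## Measurement model

Each trial is a binary true/false judgment of a headline plus a 1–4
confidence rating. "True" is the signal class: a hit is a true headline
called true, a false alarm a false headline called true (type-1); a type-2
hit is a correct judgment made with high confidence (ratings 3–4), a type-2
false alarm an incorrect judgment made with high confidence.

Point estimates per subject use the classical equal-variance forms
*d′* = z(HR) − z(FAR) and *c* = −[z(HR) + z(FAR)]/2, with *c′* = *c*/*d′*
reported as missing when |*d′*| < 10⁻⁶. Hit or false-alarm rates of exactly
0 or 1 are adjusted before the inverse-normal transform; the default policy
replaces 0 with 1/(2N) and 1 with 1 − 1/(2N) per veracity class (a
log-linear +0.5-to-every-cell policy and a no-correction policy are
selectable, and the applied policy is recorded in the estimate). The
half-count rule is the package's default because it only touches degenerate
rates and keeps z finite; nothing downstream depends on the choice except
through the recorded flag.

## Bayesian meta-d′

The eight (stimulus × response × binarized confidence) cell counts are
multinomial. Cell probabilities factor as
P(s) · P(r | s; d′, c) · P(high | r, s; meta-d′, c, τ): type-1 response
probabilities come from the subject's real sensitivity and criterion, while
confidence conditionals come from a meta-level Gaussian observer with
sensitivity meta-d′ whose criterion sits at the same relative position,
c_meta = c · meta-d′/d′. Binarized confidence implies exactly two type-2
criteria, at c_meta + τ_true (for "true" responses) and c_meta − τ_false
(for "false" responses). Zero-count cells contribute nothing to the
likelihood and need no padding. P(s) is taken from the observed stimulus
margin (0.5 in the balanced designs here).

Priors: d′ ~ N(0, sd √2), c ~ N(0, sd 1/√2), meta-d′ ~ N(d′, sd √2). These
are the standard priors of the Bayesian meta-d′ framework, which states
them in JAGS precision form (precision 0.5, 2, 0.5); the package stores
them as standard deviations. The framework leaves the type-2 criterion
priors unstated; the package uses half-normal(sd 2) on the positive offsets
τ, one per response side — weakly informative and sign-constrained. All
five parameters (d′, c, meta-d′, τ_true, τ_false) are estimated jointly; a
fixed-type-1 mode (d′, c clamped at point estimates) exists for oracle
comparisons, and `fit_metad_map` returns the posterior mode by direct
optimization with optionally broadened priors.

The point estimate is the posterior mean of raw meta-d′ (not its
logarithm), and m-ratio is that mean divided by the jointly estimated
posterior-mean d′, so the reported m-ratio is internally consistent with
the model's own d′.

### Sampling

The sampler is an adaptive random-walk Metropolis kernel vectorized across
subjects and chains, so a whole cohort is fitted in one pass at essentially
the cost of one subject. Defaults follow the reference configuration:
3 chains × 10,000 iterations with the first 2,000 discarded as warm-up.
During warm-up the proposal covariance is re-estimated twice from the
chains' own draws (pooled across the chains of a subject, which share a
posterior) and the step size follows a Robbins–Monro recursion toward a
0.3 acceptance rate; adaptation stops at the end of warm-up, so retained
draws come from a fixed kernel. Chain starts are overdispersed around the
type-1 point estimates. Convergence is summarized by the classic
Gelman–Rubin potential scale reduction factor per parameter (between/within
chain variance ratio, no rank-normalization); any parameter with R̂ ≥ 1.01
flags the fit as non-converged. A flagged fit is surfaced — in the fit
record, the run manifest and the log — but never dropped or refitted
automatically. With the default configuration, well-posed subjects (d′
roughly 1–2.5, moderate bias, meta noise below ~1) converge comfortably;
heavily degraded observers (d′ near 0 at 140 trials) can flag, which is
informative in itself. Short exploratory configurations (e.g. 3 × 1,500)
produce usable posterior means but frequently trip the 1.01 threshold,
because the classic R̂ is a noisy statistic at small effective sample
sizes.

### Hierarchical variant

For group-level questions the hierarchical fit places subject log m-ratios
under a common Normal(μ, σ): subject blocks (d′, c, log m-ratio, τ, τ) are
updated by a vectorized Metropolis sweep (they are conditionally
independent given μ, σ), μ by its conjugate normal draw, and σ by a
Metropolis step on log σ with a half-normal(1) prior. The group summary is
exp(μ) — the group-typical m-ratio — with its posterior mean and central
95% credible interval. Pooling is over subjects within one group; callers
compare parties by fitting each party separately. The log parameterization
constrains subject m-ratios positive, which is what makes the hierarchical
variant robust at low trial counts; subjects whose data genuinely favor
negative meta-d′ belong to the non-hierarchical fit.

## Synthetic cohorts

The generator emulates the study design and supplies ground truth for every
recovery and calibration test. A subject is an equal-variance Gaussian
observer with a post-decisional confidence stage:

- decision evidence x ~ N(±d′/2, 1), response "true" iff x > c;
- confidence evidence x₂ = x + N(0, σ_meta): the same evidence corrupted by
  independent noise at the confidence stage;
- confidence 1–4 from two ordered thresholds offset from c on the
  response's side (defaults 0.5 and 1.5 in evidence units), so binarizing
  at 3-vs-2 recovers the low/high split at the first offset.

σ_meta is the single metacognition knob: at 0 the observer is ideal
(m-ratio 1); increasing it degrades confidence resolution. Because the
model fitted to data is not the generating process (post-decisional noise
is not a meta-level d′), the generator's implied meta-d′ is defined as the
meta-d′ that best fits the observer's *population* cell probabilities —
computed exactly via bivariate-normal orthant probabilities and a
minimum-KL fit with type-1 fixed at truth (`effective_meta_d`). This
pseudo-true value equals d′ exactly at σ_meta = 0 and decreases
monotonically in σ_meta; it is the recovery target and the quantity the
calibration inverts. `calibrate_meta_noise` bisects it: a target sample
m-ratio of 0.86 — the efficient-but-imperfect regime reported for this
task — gives σ_meta ≈ 0.33, the cohort default.

Stimulus sets reproduce the study compositions exactly: 140 items (70
true / 70 false; false items 54 pro-Republican / 16 pro-Democrat, true
items 39 pro-Democrat / 31 pro-Republican) and the politically equated
64-item subset (16 per veracity × favorability cell, a fixed subset of the
full set). Cohorts fill 16 demographic cells (2 parties × 2 partisanship
strengths × 4 age bins) with equal n per cell, or unequal party × strength
margins matching the recruited sample (166/84/144/104). Demographic effects
are additive shifts on generative parameters, matched on subject
demographics and optionally on item attributes (e.g. a "true bias" only for
politically congruent headlines), which is how crossover interactions and
congruence effects are expressed. Between-subject spread defaults: sd 0.55
on d′, 0.2 on c, 0.3 on σ_meta (truncated at 0) — chosen so the simulated
point-estimate d′ spread matches the ~0.6 observed in this task after
estimation noise is added. Defaults for the baseline observer: d′ = 1.8,
c = 0.1 (the sample-mean discernment and slight false bias regime).

What the generator does **not** model: item-level difficulty heterogeneity
beyond veracity/favorability means, response times, and any systematic
relation between demographics and metacognition unless one is configured.
Passing recovery tests therefore shows the estimation machinery is
faithful to this generative family, not that real confidence data obey it.

## Exclusion cascade

Stages in order: (1) self-reported lack of effort; (2) incomplete runs;
(3) the outlier labeling rule on d′ and m-ratio jointly — outside
[Q1 − g·IQR, Q3 + g·IQR] on either measure, with g = 2.2 (the multiplier
recommended in the outlier-labeling literature) and quartiles by linear
interpolation (numpy's default), bounds computed once on the sample passing
stages 1–2; (4) negative m-ratio. Each excluded subject carries exactly one
primary reason (the first stage that catches it), the log conserves counts,
and re-running with the frozen bounds is idempotent. With fewer than four
completing subjects the quartile stage is skipped (bounds infinite) rather
than extrapolated.

## Statistical battery

Standard routines stand behind the module surface: type-III
sum-to-zero-contrast OLS ANOVA (statsmodels) for the unbalanced 2×2
designs, one-way and mixed between-within ANOVA and t-tests (pingouin),
Spearman with average ranks and t-approximation p (scipy), OLS on z-scored
variables for standardized betas. Design choices: the "ordinal" age ANOVA
is a plain one-way ANOVA on the ordered four-level factor (the reported
degrees of freedom match that reading; group order is preserved for
reporting); t-tests are Welch by default with Cohen's d from the pooled
standard deviation; no multiple-testing adjustment is applied, matching the
unadjusted two-tailed reporting convention of this literature. The JZS
Bayes factor (BF01, default Cauchy scale 0.707) is provided for two-sample
t-tests only and is labelled approximate: reproducing any particular GUI
package's ANOVA Bayes factors is out of scope. The sensitivity analysis
inverts noncentral-F power (λ = f²·N, df1 = k−1, df2 = N−k) by bisection to
10⁻⁶; the 2×2 design is modelled as a 4-cell omnibus (df1 = 3), the only
reading consistent with f = 0.19 at N = 500.

The Dunning–Kruger check splits subjects into d′ quartiles by rank (stable
ties) and tests m-ratio across quartiles plus an explicit bottom-vs-top
contrast. The split-half robustness check re-estimates d′ and m-ratio on
even- and odd-presentation-order trials (order was randomized per subject,
so presentation parity is the natural split) and runs the quartile ANOVA
across halves in both directions.

## Pipeline

A run is one YAML-loadable config: exactly one input source (synthetic
cohort or an external trial CSV in the canonical schema, with a
column-rename adapter for external exports), MCMC settings, exclusion
multiplier, analysis toggles, seed. Analyses that directly examine biases —
response bias and political-favorability comparisons — are routed to the
politically equated item subset only, and the negative-m-ratio exclusion is
re-applied to the re-estimated equated values; discernment and
metacognition batteries run on the full set. The manifest records a config
hash, the seed, package versions, per-stage counts and the R̂ summary;
identical config and seed reproduce byte-identical trial tables and
exclusion logs. Age enters both binned (ANOVA) and continuous (Spearman),
and the demographic regression codes party, gender as 0/1 before
standardizing.

## Problem sizes in the validation suite

The suite validates at study scale where that is cheap (140 trials,
hundreds of subjects — the vectorized sampler fits 300 subjects in
seconds) and at reduced scale elsewhere: recovery uses 300 subjects with
3 × 2,500-draw chains; type-I calibration uses 2,200 null cohorts of 64
subjects with point-estimate d′ only; the crossover power check uses 40
replicate cohorts at the recruited cell sizes; hierarchical coverage uses
groups of 12 subjects. Monte-Carlo oracles use 10⁷ draws; closed-form rate
checks use 10⁶ trials.

## Known limitations

- The type-2 criterion priors are a documented stand-in; the reference
  implementation's exact parameterization is not published.
- The hierarchical pooling structure (subjects within one group) is one of
  the two plausible readings of a group-level fit; pooling across
  parties-within-cohort is not implemented.
- The classic R̂ at the 1.01 threshold is conservative for short chains;
  non-convergence flags at exploratory settings are expected and benign.
- The JZS Bayes factor covers t-tests only.
- m-ratio for subjects with d′ near zero is numerically fragile (the
  denominator is tiny); the exclusion cascade's outlier stage is the
  intended guard.
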