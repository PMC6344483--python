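# Methods

This note documents the models, procedures, parameter choices and known
limitations of the package, in the order the pipeline runs them.

## Task structure and trial timing

A trial begins at fixation onset (time 0).  Offers appear at 1.5 s and stay
on for 1 s; after a further 1-s memory delay the saccade targets appear; the
go signal follows a uniform 0.6–1.2 s delay; the saccade is placed at a
fixed 0.2 s after go (reaction times are not modeled further), and juice is
delivered 0.75 s after the saccade.  The recorded span ends 0.5 s after
juice delivery.  Nine 0.5-s analysis windows are anchored to these events
(pre/post-offer, late-delay = 0.5–1.0 s after offer onset, mem-delay,
pre/post-target, pre-go, pre-juice, post-juice).  All intervals are
half-open `[start, end)` with the boundary spike counted at the start — a
fixed convention that prevents double counting when adjacent windows share
an edge.  Saccade targets sit at one of four angles; 157.5°/202.5° define
the left hemifield and 22.5°/337.5° the right, and the two targets are
always diametrically opposite.

## Choice model

Choices are modeled as logistic in the difference of offer values plus
indicator terms for cost, history and space (see README for the formula).
Estimation is unpenalized maximum likelihood (statsmodels Logit, Wald
p-values).  When the optimizer fails or the data are separable — routine in
near-deterministic synthetic sessions — the fit falls back to a small ridge
penalty (λ = 1e-3 on the squared coefficients) solved with BFGS, with
standard errors from the penalized Hessian; the fit is flagged
`separation=True`.  The normalized indices are ratios with a0 in the
denominator, so when |a0| < 0.05 the fit is flagged degenerate and the
indices are reported as NaN rather than as numerically explosive values.
The simplified model (terms a3–a6 removed) provides the two cost-conditioned
sigmoids; the indifference point is the #B:#A ratio at which it predicts
P(B) = 0.5, which works out to ρ + ξ when A is the low-cost offer and ρ − ξ
when it is not.  Session screening excludes sessions whose target-side bias
coefficient has Wald p < 0.01; Wald was chosen because the source analyses
state a significance level but not a test, and a likelihood-ratio variant
would not change any decision on the synthetic cohorts.

## Synthetic data

The generator's defaults are the study conditions used throughout the tests:
a0 = 2, ρ = 2.5, ξ = 0.25, η = 0.2, φ = δ = ε = 0; a five-pair quantity menu
((1,1), (1,2), (1,3), (1,4), (2,3)) spanning #B:#A ratios 1–4 around the
indifference ratio, with forced choices excluded; full counterbalancing of
quantity pair × cost assignment × offer side × target hemifield (8 cells per
pair), 50 trials per cell giving exactly 2000 trials per session at the
default.  Hysteresis is causal: trial t's history indicators use trial
t−1's realized choice, so η is a genuinely recoverable parameter rather
than a label.

Neurons are homogeneous Poisson processes at a baseline rate (default
20 spikes/s, a typical OFC working range) whose rate inside tuned windows is
`max(0, baseline + sign·slope·v)` for a catalog variable v evaluated at the
generating ρ, ξ.  Tuning strength is parameterized as
SNR = slope·range(v)/√baseline, default 2.  The rate floor is truncation at
zero, which slightly biases strongly negative tunings (a rectified rate has
a higher mean than the linear target); this is documented rather than
corrected because the selection analyses operate on relative R², not rate
means.  Per-window overrides allow a neuron to encode different variants in
different windows (used by the integration benchmark).  What the generator
deliberately omits: non-Poisson spiking, rate adaptation, trial-history
firing effects, correlated noise across neurons, and response latencies.
Passing recovery tests therefore demonstrates that the *procedures* are
correct and calibrated, not that real OFC data satisfy their assumptions.

## ANOVA screen

Each response (neuron × window, rates = counts/duration) enters two
three-way main-effects ANOVAs; the trial-type factor is computed once and
shared.  Main effects only: the population tallies count factor-wise
modulation, and interaction terms would change the degrees of freedom
without contributing to any downstream decision.  Type-II sums of squares
(full model vs model dropping one factor) handle the unbalanced designs
that arise because choices are stochastic; trial-type levels with fewer
than two trials are dropped.  The implementation projects responses onto
precomputed orthonormal bases (SVD) of the shared design matrices, which
makes the thousands of response-wise ANOVAs cheap; it is verified against
statsmodels `anova_lm(typ=2)` to machine precision in the tests.  Analyzing
rates rather than counts matters only for late-delay (the one window whose
duration could differ under reconfiguration) but is applied uniformly.

## Variable catalog and regressions

The 19 variables follow the four-reference-frame scheme: commodity-based
offer values (offer value A = ρ#A + ξδ_A,+, offer value B = #B + ξδ_B,+ —
values in units of juice B, so B's quantity enters raw), cost-based values
attached to the low-/high-cost offer, location- and target-based values,
the binary choice outcomes in each frame, six frame-association binaries,
and the chosen value.  Collapsed families (offer value (juice)/(cost)/
(location)/(target)) are credited with the larger component R².

Responses are regressed at the trial-type level: trials are grouped and the
group-mean rate is regressed on the variable.  The grouping key is
(offer type, chosen juice, variable value): for commodity- and cost-based
variables this reduces to classic trial-type means, while spatial variables
— which vary within a trial type because sides are counterbalanced — split
each type by the spatial attribute instead of averaging it away.  A
trial-level regression is available (`level='trial'`).  R² is set to 0
whenever the slope is not significant at p < 0.05 ("effective R²").

## Selection procedures

Stepwise: at each step the variable with the highest number of best fits
within any single window is selected (ties: total best fits, then catalog
order), the responses it accounts for are removed, and the procedure stops
when the marginal explanatory power falls below 5%.  Two removal rules are
implemented.  The default removes the responses the variable *best-fits*;
the alternative (`removal='explained'`) removes every p < 0.05-explained
response.  The default was chosen after measuring, on ground-truth cohorts,
that the explained-removal rule cannot recover overlapping variable sets:
the catalog's value variables are strongly correlated across trial types
(chosen value correlates with both offer values by construction), so the
first selected value variable sweeps away nearly all responses of the
others and the procedure terminates after one or two value variables even
when four families are genuinely present.  Best-fit removal preserves each
family's own responses and recovers the generating set exactly.

Best-subset: exhaustive enumeration over collapsed variables; for each n the
subset maximizing explanatory power is optimal by construction.  The default
power measure is the summed best-member effective R² over responses
(`objective='total_r2'`; `'count'` gives the explained-response count with
R² as tie-break).  The same 5% rule, measured on the same power scale,
stops both procedures, which is what lets an optimal search and a greedy
search report identical sets when the data warrant it — with mismatched
gain scales (counts for one, R² for the other) the two could stop at
different sizes on identical data.  Both procedures are deterministic;
epochs are pre-target = {post-offer, late-delay, mem-delay, pre-target} and
post-target = {post-target, pre-go, pre-juice, post-juice}, with pre-offer
reserved as baseline.

A consequence worth knowing: a family whose responses are almost entirely
covered by other selected families (small unique R² contribution) can fall
below the 5% bar even if some neurons genuinely encode it — visible in the
demo cohort, where chosen value is dropped when five families compete at
n = 6 cells each, while the benchmark cohort (10 cells per family, four
families) retains all four.  That is a property of the stopping rule, not a
bug; classification is restricted to selected variables by design.

Cells are classified to the selected variable with the largest R² summed
over all nine windows; for chosen-juice and chosen-cost cells the encoded
level (juice E, preferred cost) is the sign of the R²-weighted slope on the
binary regressor.

## Choice probability

Quantity pairs are labeled cost-overt when the fraction of A-choices under
the two cost assignments differs by more than 0.10 in the direction of the
cheaper option, with each option chosen at least twice (pooled); the
comparison is across the two cost configurations of the same quantity pair,
which is the reading under which an always-one-option pair is covert.
"Consistently the same option" (covert) is operationalized as the same
modal option chosen in ≥90% of trials of each configuration — the source
text gives no number; 90% tolerates isolated lapses without admitting
genuinely mixed pairs.  Everything else is "insufficient" and excluded.

Spike-density functions convolve 1-ms binned trains with a Gaussian kernel,
σ = 40 ms ("40 ms width" read as σ, not FWHM; switchable by argument), with
the kernel truncated at the trial edges without renormalization — profile
mass equals spike count away from the edges, and the small edge bias is
shared by all conditions.  Profiles are normalized per cell by subtracting
the mean pre-offer rate and dividing by the mean rate across the other
eight windows; cells with a zero divisor are excluded.  The Ec/Eo/Oc/Oo
population traces require at least two trials in every group.

AUC is computed from midranks (identical to Mann–Whitney U/(n₁n₂), with
ties counted half) on raw spike counts in three non-overlapping post-offer
windows (0–250, 250–500, 500–750 ms), per cost-overt offer type with both
outcomes present, then averaged across offer types.  Population tests are
two-sided one-sample t-tests against 0.5; the zero-variance corner (every
AUC exactly 0.5) reports p = 1.

## Dimensional integration

ΔR² compares variant regressions per response: cost-affected vs
cost-independent for juice-based values and chosen value, commodity-affected
vs commodity-independent (ρ → 1) for cost-based values.  Identification is
unbiased: each family is credited with the maximum of the two variants'
effective R², responses are assigned by best fit under that rule, and only
then is ΔR² examined — raw R² of the two variant regressions, not the
zeroed effective values, since zeroing would make ΔR² jump by whole-R²
units at the significance boundary while the population means of interest
are of order 0.01.  Offer-value families are analyzed in the post-offer
window, chosen value in post-offer (early) and post-target (late); the
early-vs-late contrast uses a two-sample rank-sum test.  Variant
regressions reuse the same session's behavioral ρ̂, ξ̂.  The ANCOVA is the
parallel model (one slope, one intercept per cost or juice-type group) with
a type-II F-test on the group factor; with a single group it reduces
exactly to the simple regression.

## Problem sizes and numerical conventions

The recovery benchmarks use 50 sessions × 2000 trials (behavior), 200
untuned neurons × 9 windows (ANOVA calibration), a 50-neuron cohort at
SNR 2 (selection/classification), 500 untuned and 20 tuned neurons (ROC
calibration/power), and three 40-neuron cohorts on 2000-trial sessions
(ΔR² regimes) — sizes at which each check is decisive yet the whole suite
runs in a few minutes on one CPU.  Wilcoxon tests are two-sided throughout,
with all-zero inputs reporting p = 1; directional claims are read from the
sign of the mean or median.  All ties in selection break by catalog order,
making every procedure deterministic; all randomness flows from explicit
seeds via `numpy.random.default_rng`.

## Limitations

Poisson firing with piecewise-constant rates is an idealization; real
responses have latencies, adaptation and super-Poisson variability, which
would lower the screen's power and blur the ΔR² contrasts relative to the
benchmarks here.  The cost-overt margin (10%), covert consistency (90%) and
the SNR definition are conventions; results near those boundaries should be
read accordingly.  The best-subset search is exhaustive and exact for the
15-variable collapsed catalog but scales combinatorially beyond ~20
variables.
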