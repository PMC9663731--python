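# Methods

This note records the model, the estimation choices, and the reasoning
behind the defaults, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

The target of inference is the log-odds surface `g(x) = logit P(y=1 | x)`
of a binary clinical endpoint given a vector of mixed predictors. The
package's central object is the *anchored functional ANOVA decomposition*
(cut-type / Dirac-metric decomposition) of any fitted `g` at an anchor
point `c`:

- intercept `f_0 = g(c)`;
- main effects `f_i(t) = g(c; x_i → t) − f_0`;
- pairwise terms
  `f_ij(s,t) = g(c; x_i → s, x_j → t) − f_i(s) − f_j(t) − f_0`;
- higher orders by inclusion–exclusion over subsets.

Summed over all subsets the components reconstruct `g` exactly at every
point; the package verifies this identity against a brute-force subset
enumeration for small dimension in its test suite. The anchor is the
columnwise data median (mode for binary columns), so after median-anchored
standardization `c` is the zero vector and every component vanishes when
its variables are at their typical values — the property that makes a
component readable as "the additive contribution of this variable to the
patient's log-odds, relative to a typical patient".

The fitting procedure is a five-stage distillation:

1. fit a one-hidden-layer tanh network (the flexible but opaque estimate
   of `g`);
2. decompose its logit at the median into all univariate and bivariate
   partial responses;
3. treat each response, evaluated row-wise by direct cuts of the network
   (never by grid interpolation), as one feature of an L1-penalized
   logistic regression and select the responses that survive the penalty;
4. rebuild the selection as a modular network — one subnetwork per
   retained response, each a replica of the base hidden layer with
   non-member inputs clamped at the anchor, output-scaled by its Lasso
   coefficient and offset to be zero at the anchor — which reproduces the
   selected additive model exactly at initialization, and retrain it;
5. decompose and re-select on the retrained network. The final model is a
   sparse GAM `logit P = β₀ + Σ β_k f_k(x)`.

Stage 4 exists because uninformative inputs in the base network perturb
the cuts of the informative ones; retraining the modular network, which is
*structurally* unable to see the dropped variables, re-estimates the
retained responses free of that noise. The module construction satisfies
an exact contract — maximum absolute logit difference from the selected
GAM below 1e-8 at initialization, asserted on every build — via replicated
hidden-layer weights, clamped non-member inputs, coefficient-scaled output
weights and an additive anchoring offset. For a bivariate module the
inclusion–exclusion cut `m_ij − m_i − m_j` is encoded by three replicas of
the hidden layer inside one module, so the module still depends on its two
variables only.

## Estimation choices

**Standardization.** Centering is at the median (mode for binaries; an
exact 50/50 binary tie anchors at 0 by convention); the scale is the
sample standard deviation of observed entries. Only the zero-at-median
property is load-bearing; the SD scale keeps network training
well-conditioned. Constant columns are rejected.

**Missing data.** Two schemes, both exercised by the tests: (a) zero
imputation after standardization — a missing value sits at the anchor,
where every response vanishes, so it contributes exactly nothing to the
prediction (the scheme used when scoring external tables); (b) stacked
hot-deck multiple imputation for model development — each missing cell is
replaced m=10 times by a uniformly drawn observed donor from the same
column within the same stratum (default stratification by era), and the m
completed copies are concatenated. No Rubin's-rules variance pooling is
performed: the stacked table is treated as one development cohort.
Uniform-with-replacement donor sampling is one concrete choice among
several defensible hot-deck variants. Missing outcomes are rejected, not
imputed.

**Base network.** One hidden tanh layer; width chosen on the grid
{4, 8, 16} by held-out log-loss (ties to the narrower net); L2 penalty
1e-3; minibatch Adam (batch 512, learning rate 0.01); early stopping on a
seeded 20% validation split with patience 20, max 300 epochs, best-weights
restore. The trainer is deterministic per seed. A small-width, weight-
decayed network is deliberate: smooth cuts make stable partial responses.
The trainer early-stops on validation *log-loss* (not accuracy) because
the endpoint is rare (~12% prevalence) and accuracy is nearly constant
across useful models there.

**Grids.** Continuous responses are tabulated on 101 equally spaced
quantiles of the training data (deduplicated), binary responses on their
two observed standardized levels. Evaluation off the grid is
piecewise-linear with linear extrapolation from the terminal segments
(bilinear for pairs), which supports scoring forward in time on a drifting
era variable. Interpolated values are used only for serialization,
explanation and nomogram export; residuals, selection features and
per-patient explanations call the model directly, so the exactness
identities hold to machine precision. The anchor slices of bivariate
components, identically zero mathematically, are set to exactly zero
rather than left with cancellation residue.

**Penalized selection.** Features are *not* re-standardized before
penalization: each is already on the logit scale of the source model, so
equal penalization is comparable across features and a coefficient near 1
means "keep this component as estimated" (a flag enables standardization
for sensitivity analysis). The λ grid has 100 log-spaced values from
λ_max (the smallest λ with an all-zero solution, computed from the data)
down to 1e-4·λ_max. Selection is by 10-fold cross-validated deviance
(stratified, seeded folds); the minimum-deviance rule is the default, the
one-standard-error rule is available and is the appropriate choice when a
sparsest-defensible model is wanted. Min-CV deliberately over-selects a
few weak terms; the tests' recovery checks therefore assert that the true
active set is *contained in* the selection.

The solver is coordinate descent on a majorized objective: the logistic
Hessian is bounded by the constant matrix X'X/(4n) (since p(1−p) ≤ 1/4),
so the Gram matrix is computed once per path and each iteration needs one
exact-gradient pass over the data plus a cheap coefficient-space CD solve
with soft thresholding. Every surrogate solve decreases the true penalized
likelihood, and convergence is declared on its exact KKT conditions
(gradient tolerance 1e-5 on the full-data path, 1e-3 inside CV folds where
only the deviance curve matters; the λ→0 limit agrees with unpenalized
maximum likelihood to ~1e-6 per coefficient at tight tolerance, which the
tests verify against statsmodels and scikit-learn). Warm starts along the
decreasing grid make the whole 100-λ, 11-fit cross-validated path take a
few seconds at n = 20,000.

**Retraining the modular network.** Full parameter set of every module
plus the global intercept, minibatch Adam (learning rate 0.005, L2 1e-4,
batch 512), early stopping on a seeded 20% split (patience 20, max 500
epochs). The Lasso coefficients are absorbed into the module output
weights rather than kept as frozen scale factors. After training each
module is re-centred at the anchor and the shifts are absorbed into the
intercept, so the anchored-zero property survives exactly. The second
selection pass restricts candidates to the network's own variables — all
singletons appearing in any module plus exactly the pairs that exist as
modules (a config toggle admits all pairs of module variables); a network
built from selected responses cannot contain effects outside them, so
re-admitting foreign candidates would re-introduce the noise stage 4
removed.

**Evaluation statistics.** AUROC uses the mid-rank tie convention.
Confidence intervals and the paired comparison use the DeLong structural
components (positive-side and negative-side placement values), with the
normal approximation and truncation to [0,1]; identical score vectors
return p = 1 with a warning. The Hosmer–Lemeshow statistic uses
equal-count deciles of risk with tied probabilities kept in one group
(quantile-cutpoint convention) and df = groups − 2; that reference
distribution is derived for probabilities produced by a model fitted by
maximum likelihood, and the engine-calibration tests simulate exactly that
setting (with externally fixed true probabilities the statistic is closer
to χ² with g degrees of freedom and the test over-rejects — a property of
the statistic, not of this implementation). Calibration-in-the-large is
the intercept of a logistic recalibration with slope fixed at 1 (offset
fit); the recalibration slope is reported alongside but not used in CITL;
E/O is Σ predicted / Σ observed.

## The synthetic registry preset

The generator emulates the marginal structure of a transplant-registry
table: `recipient_age ~ N(52, 12)`, `donor_age ~ N(33, 11)`, creatinine
and ischemic time log-normal (medians 106 and 180, σ 0.45 and 0.33), a
diagnosis-like indicator at 35% prevalence, three rare flags (10%, 5%,
3%), and a uniform era column over 1997–2018. Active effects: a U-shape
in recipient age (amplitude 0.35 per squared SD), a linear donor-age
effect (0.5 per SD), a hinge in ischemic time (slope 0.8 per hour beyond
3.5 h), and a recipient-age × diagnosis interaction (0.5 per SD); the
other five predictors are nulls. The intercept −2.85 puts prevalence near
0.12 (checked by simulation). Amplitudes are sized so each active
response spans roughly ±1 logit over the observed range — the scale on
which such registry nomograms operate.

The interaction partner is the 35%-prevalence diagnosis indicator, not one
of the rare flags: an age-by-diagnosis effect is the kind of interaction
this class of model is meant to surface, and an interaction gated on a
≤10% flag is a small-subgroup problem that no desk-scale sample would
support. Columns are drawn independently; real registries have correlated
predictors and informative missingness, and the preset has neither — so
passing recovery tests show that the machinery recovers what it is built
to recover under MCAR, independent-predictor conditions, not that it
untangles confounded registry data. Missingness is MCAR on predictors
only.

`true_partial_responses` re-expresses the generating effects as anchored
components in closed form (subtracting each effect at the anchor;
inclusion–exclusion for the interaction, whose anchored slices also induce
small main-effect terms credited to the participating variables), giving
an exact oracle for the decomposition, the selection and the end-to-end
recovery tests.

## Problem sizes used by the checks

The recovery study in the test suite runs 20 end-to-end replicates at
n = 20,000 (75/25 train/test split) and measures: containment of the true
active set (including the interaction) in the final selection; the RMSE of
each recovered response against its generating component over the central
90% data mass of each variable (3-seed median); and the held-out AUROC gap
between the final sparse model and the base network (3-seed median).
Engine calibration uses 1,000 replicates (DeLong type-I at n = 200,
CI coverage at n = 500, Hosmer–Lemeshow null at n = 5,000).
`scripts/acceptance.py` reports the same quantities from 5 replicates and
400 calibration replicates, which reproduces the rates to the precision
the JSON reports.

## Numerical conventions and degenerate inputs

Binary responses are evaluated by exact level lookup (tolerance 1e-8);
off-level values are an error, not an interpolation. Ties in CV fold
assignment are broken by the seeded shuffle. Non-convergence of the path
solver raises an error naming the offending λ. Divergent network training
(non-finite loss) raises advising a smaller learning rate. Tables with a
constant column, a single outcome class, missing outcomes, unknown
categorical levels or non-numeric continuous cells are rejected with the
offending column (and row where relevant) named.

## Known limitations

No confidence bands on individual partial responses (sparse extremes of
skewed variables are visibly less certain but unquantified); no orders
above two in the final model; no group or hierarchy constraints linking an
interaction to its main effects; hot-deck imputation is uniform within
stratum (no donor weighting); the synthetic preset does not model
predictor correlation or informative missingness; decomposition cost grows
as d(d−1)/2 in the number of encoded columns (a config cap on candidate
pairs, ranked by response variance, is provided for wide tables).
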