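# Methods

This note documents the statistical models implemented in `bmx`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations of the procedures.

## Screening models and likelihood-ratio tests

All screening is maximum-likelihood logistic regression with
likelihood-ratio (LR) chi-square tests, df = 1 for the single tested term.
Four model forms are supported per biomarker: arm-wise (`pCR ~ biomarker`
within one arm, optionally within a receptor subset), interaction
(`pCR ~ treatment + biomarker + treatment:biomarker` on both arms, testing
the interaction), and the interaction model additionally adjusted for
additive HR and HER2 main effects. Screening p-values are descriptive by
design: no multiplicity correction is applied at this stage. The
Benjamini–Hochberg step-up procedure lives only in the enrichment module,
where sets of genes are tested jointly.

Fitting is Newton–Raphson with step-halving on an internally standardized
design (gradient max-norm tolerance 1e-8, at most 100 iterations).
Constant columns are dropped and logged. Separation is declared when the
fit fails to converge or any non-intercept coefficient exceeds 15 in
absolute value on the standardized scale; the model is then refit with a
ridge penalty of 1e-4 (on the standardized scale) and the result flagged
rather than discarded. This keeps small receptor subsets — where a handful
of events can separate perfectly — inside reports instead of erroring out;
the flag is propagated to every output table. Subsets with fewer than 10
patients or fewer than 3 events (or non-events) are flagged "underpowered"
with the p-value still reported.

Measured calibration (re-derived at run time by `scripts/acceptance.py`):
on null cohorts of 100 patients per arm the arm-wise screen rejects at
~0.050 and the interaction screen at ~0.053–0.060. The mild inflation of
the interaction test is the expected finite-sample behaviour of the
asymptotic chi-square reference with ~60 events and four parameters, not
an implementation artifact; it disappears as n grows.

## Cutpoint dichotomization

Candidate thresholds are the midpoints between consecutive distinct
observed values, restricted so each side retains at least `min_group = 5`
observations (the enumeration scheme and group floor are package choices;
they prevent degenerate fits in subsets of a few dozen patients). The
search is scale-free: every step depends on the data only through ranks,
so any strictly increasing transform of the biomarker yields the same
selected rank interval (a tested invariant).

Each of 500 repeats splits patients into two folds stratified on pCR
("balanced over" the outcome, read as stratified randomization — it
guarantees events in both folds). Both folds serve once as test, so each
candidate accrues up to 1000 test-fold p-values; the first configuration's
training fold contributes one argmin selection per repeat to the stability
count. For a single binary predictor the logistic LR statistic equals the
2x2 G-test statistic `2 * sum O log(O/E)`; the search evaluates it in
closed form for all candidates and folds with array arithmetic (the
identity is asserted against the full Newton fit in the test suite). A
candidate that empties a group in some fold contributes no p-value for
that fold (skipped, never imputed).

Test-fold p-values are combined per candidate with the Mudholkar–George
logit method. Comparisons across candidates run on the log scale: combining
1000 small p-values drives the combined p below the smallest double, and on
the raw scale the argmin would degenerate on a plateau of exact zeros.
Where `t.logsf` itself underflows, a first-order asymptotic tail expansion
(relative error O(T^-2)) takes over. p-values at the boundary are clipped
to [1e-15, 1 - 1e-15].

Selection follows the published procedure's wording: the global
minimum-combined-p candidate is selected only if it was itself the
training-fold argmin in at least `stability_min = 10` of the 500 repeats
(`stability_mode="filter"`, the default). The alternative reading —
minimize combined p among candidates whose training count reaches the
threshold — is available as `stability_mode="restrict"`. Ties anywhere
break toward the smaller cutpoint, for determinism.

Two properties of this procedure deserve emphasis, both measured by the
acceptance script rather than assumed:

- **Localization precision is bounded by rank information.** With a 2-logit
  step at n = 120, even the full-data maximum-likelihood split lands
  exactly between the two observations flanking the true threshold only
  ~28% of the time (the argmax wanders a few observations under outcome
  noise); the cross-validated selection matches this (~26–32%), and ~90%
  of selections fall within 8 rank positions. Exact-interval recovery is
  not an achievable contract for any rank-based method at this effect size
  and sample size; users should interpret a selected cutpoint as a
  neighborhood, not a point.
- **The 10/500 stability filter is a weak null control.** Because test and
  training selections are resplits of the same data, the minimum-combined-p
  candidate under a pure-noise biomarker almost always coincides with a
  candidate the training folds also favored (typical training counts
  30–130 of 500 at n = 60); the filter rejects only ~3–10% of null runs.
  It guards against fluke candidates the training folds never favored, not
  against dichotomizing noise. Combined test-set p-values are also strongly
  anti-conservative (the 1000 combined p-values are dependent), which is
  why the package reports them for ranking, not as evidence.

## Bayesian subgroup model

The dichotomized biomarker enters the fixed 8-term logistic model
(intercept, HR, HER2, biomarker, treatment, and the three treatment
interactions; all covariates coded 0/1, interactions as products).
Priors are independent normal(0, 3) on every logit-scale coefficient —
weakly informative: it keeps prior-dominated small subsets bounded while
being effectively flat over the plausible ±5-logit range. Prior sd, chain
count, iterations, burn-in, and seed are all configurable.

Sampling is adaptive random-walk Metropolis: the proposal covariance is
the Laplace approximation at the posterior mode scaled by 2.38^2/d, with
the global scale adapted toward ~25% acceptance during burn-in only (so the
retained chain is a valid fixed-kernel chain). Four chains run 20,000
iterations with 5,000 burn-in by default. Because all covariates are
binary, the likelihood is aggregated over at most 16 distinct covariate
rows, making each posterior evaluation O(16) regardless of cohort size.
Convergence contract: split-R-hat < 1.05 and ESS >= 400 for every
coefficient (computed with arviz), else the result is flagged
`nonconverged`. Zero-event designs are flagged `prior_dominated` but still
sampled; an empty design returns the prior.

A subgroup pCR estimate is the posterior predictive mean over the
subgroup's observed covariate rows: for each retained draw, the
inverse-logit linear predictor is averaged across the subgroup's patients,
yielding a posterior distribution for the subgroup rate (mean and central
95% interval reported). A subgroup such as "HER2+/biomarker-high/treated"
therefore averages over its empirical HR mix rather than fixing HR — the
estimand is the rate in that observed subpopulation. Flipping the 0/1
coding of the biomarker permutes coefficients but leaves every subgroup
estimate invariant (tested).

Note on interpretation: subgroup estimates track the *realized* cohort.
At n ≈ 75 per subgroup the cohort's empirical rate differs from the
generative rate by ~0.05 (one binomial SD), and the posterior mean follows
the former; end-to-end recovery tolerances must absorb both sources of
noise.

## RPPA standardization

Arrays (batches) are standardized independently and then recombined. Per
batch: draw `n_resamples = 5000` stratified samples, each of the batch's
own size, with replacement, with per-subtype quotas equal to
`round(size * target_props)` under largest-remainder rounding (ties broken
by the fixed subtype order HR+HER2-, TN, HR+HER2+, HR-HER2+); compute each
endpoint's mean and SD (ddof = 1) within every resample; average across
resamples to get the endpoint's mean-of-means and mean-of-SDs; z-score the
batch's values with those averages. The default target proportions
(0.384, 0.368, 0.158, 0.09) are the receptor-subtype balance of the
screened trial population the procedure is calibrated to. Resampling is
implemented through multinomial draw-count matrices, so a batch transformed
by v -> a*v + b (a > 0) reproduces identical standardized output at the
same seed (tested to 1e-12).

Choices the procedure's published description leaves open, fixed here:
resample size equals the batch size (keeps SD estimates on the batch's own
scale); sampling is with replacement (quotas may exceed a subtype's count
within a batch); a subtype with positive target proportion but no patients
in a batch has its quota redistributed proportionally with a warning;
endpoints constant within a batch (mean-of-SDs = 0) are flagged and set to
missing for that batch, never divided. Standardization operates on the
intensity scale it is handed; log-transforming first is the caller's
decision.

## Variant consensus and enrichment

The consensus filter keeps (patient, gene, variant) triples supported by at
least `min_support = 2` of the provided callers, counting duplicate calls
within one caller once; the retained set is monotone in `min_support`
(tested). Over-representation analysis is the upper-tail hypergeometric
probability per gene set (sets intersected with the user-supplied universe
first), Benjamini–Hochberg-adjusted across the tested sets; gene sets are
read from GMT files. This is a transparent generic ORA — it makes no
attempt to reproduce any specific annotation database's curation or
fuzzy-clustering scores, so enrichment outputs are structurally, not
numerically, comparable to tool-specific reports.

## Synthetic cohorts

The generator emulates a two-arm neoadjuvant trial: exactly `n_per_arm`
patients per arm; four receptor subtypes drawn at the default prevalences
above; a binary pCR outcome from the logistic model
`beta0 + beta_hr*HR + beta_her2*HER2 + beta_trt*T + biomarker terms`.
Default outcome coefficients — beta0 = logit(0.22) for TN controls,
beta_hr = -0.9, beta_her2 = +0.6, beta_trt = +0.4 — give control-arm pCR
rates of roughly 0.10 (HR+HER2-), 0.22 (TN), 0.17 (HR+HER2+), 0.34
(HR-HER2+), matching the ordering and magnitudes reported for high-risk
neoadjuvant breast-cancer populations (lower pCR in HR+ disease, higher in
HER2+ disease under trastuzumab), with a modest experimental-arm benefit.
MammaPrint class is simulated as annotation only, independent of outcome.

Biomarkers are log-normal intensities, `v = exp(mu_s + sigma_s * z)` with
per-subtype location/scale and z standard normal; correlated blocks share
one latent Gaussian factor per block (`z = sqrt(rho)*u + sqrt(1-rho)*e`),
which reproduces tight co-cluster structure cheaply. Linear effects are
parameterized on the standardized log scale (per SD of log-intensity), the
only scale on which a logit slope is interpretable for intensities spanning
thousands of units; step effects are a logit jump at a raw-scale threshold
theta, split into a main (`delta_bm`) and a treatment-interaction
(`delta_bm_trt`) component so treated-arm-only step effects are
expressible. Batch effects on the protein matrix are affine per batch
(v -> scale*v + shift), with the pre-batch matrix retained in the ground
truth.

What the generator does not emulate — and therefore what passing recovery
tests do not establish about real data: transcriptome-wide covariance
beyond simple blocks, platform-specific noise spectra, missingness
mechanisms, assay floor/saturation effects, and any dependence of
MammaPrint class or batch assignment on biology. Recovery results should
be read as correctness checks of the inference machinery, not as power
estimates for any particular trial.

## Problem sizes and determinism

Simulation-based checks use: 1000 replicates at n = 100/arm for screen
calibration; 50 runs of the 500-repeat cutpoint search at n = 120 (signal)
and n = 60 (noise); 5000 resamples for standardization; n = 5000 for
Bayesian recovery; n = 300 for the end-to-end chain — sizes at which each
check's Monte-Carlo error is small relative to its tolerance while the
whole suite completes in about a minute. Every stochastic stage takes an
explicit seed; the pipeline derives per-stage child seeds deterministically
from one master seed (stage-name hashing), so stage-level reruns reproduce
full-pipeline runs bit-identically.
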