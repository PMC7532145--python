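# bmx — predictive-biomarker analysis for two-arm neoadjuvant trial cohorts

`bmx` is a biostatistics toolkit for screening candidate predictive
biomarkers against a binary pathologic-complete-response (pCR) endpoint in a
two-arm (control vs experimental-agent) neoadjuvant trial, and for turning a
promising continuous biomarker into a dichotomized subgroup rule with
Bayesian subgroup pCR estimates. It is aimed at trial biostatisticians and
translational researchers working with expression, RPPA
(reverse-phase protein array), and mutation data alongside a per-patient
clinical table (arm, HR status, HER2 status, MammaPrint class, pCR).

## What it computes

**Pre-specified screening** (`bmx.association`). For a biomarker x with
outcome y = pCR and treatment indicator T, four logistic model forms are
screened, all tested by likelihood-ratio (LR) chi-square with 1 df:

- arm-wise: `logit P(y) = b0 + b1*x` within one arm (tests b1);
- interaction: `logit P(y) = b0 + bT*T + b1*x + b2*(T*x)` (tests b2);
- adjusted interaction: the interaction model plus additive HR and HER2
  main effects.

p-values are descriptive — no multiplicity correction at the screening
stage. Separated or nonconvergent fits in small subsets are refit with a
tiny ridge and flagged rather than dropped.

**Cross-validated cutpoint dichotomization** (`bmx.cutpoint`). Candidate
thresholds are midpoints between consecutive distinct biomarker values
(minimum group size 5 per side). Twofold cross-validation stratified on pCR
is repeated 500 times; per fold and candidate c, the LR p-value of
`pCR ~ 1{x > c}` is recorded. Test-fold p-values are combined per candidate
with the Mudholkar–George logit method,

    T = -sum_i logit(p_i) * sqrt(3(5k+4) / (k pi^2 (5k+2))) ~ t(5k+4),

and the minimum-combined-p candidate is selected, subject to a stability
filter: it must also have been the training-fold argmin in at least 10 of
the 500 repeats, else no cutpoint is declared.

**Bayesian subgroup estimation** (`bmx.bayes`). The dichotomized biomarker
enters an 8-term logistic model,

    logit P(pCR) = b0 + b_HR*HR + b_HER2*HER2 + b_x*x + b_T*T
                   + b_{T:HR}*T*HR + b_{T:HER2}*T*HER2 + b_{T:x}*T*x,

with independent normal(0, 3) priors, sampled by adaptive random-walk
Metropolis (4 chains, split-R-hat/ESS convergence contract). Subgroup pCR
rates are posterior predictive means over each subgroup's observed
covariate rows, reported with 95% credible intervals.

**Supporting stages**: stratified-resample RPPA batch standardization
(per-array z-scoring against resampled means/SDs at a fixed receptor-subtype
balance), a 2-of-3 variant-caller consensus filter, mean-expression
signature scores, hypergeometric over-representation analysis with
Benjamini–Hochberg correction, and a synthetic cohort generator
(`bmx.synthetic_data`) with known ground truth for every inference stage.

## Worked example

Simulate a 300-patient trial whose protein endpoint carries a treated-arm
step effect at threshold θ = e^8 ≈ 2981 (true treated-arm pCR 0.85 above,
0.30 below), then run the cutpoint → Bayes chain:

```python
import numpy as np
from scipy.special import logit
from bmx import pipeline
from bmx.synthetic_data import BiomarkerSpec, SimConfig, generate_cohort

spec = BiomarkerSpec(name="pFOXO1", effect_mode="step",
                     theta=float(np.exp(8.0)),
                     delta_bm_trt=float(logit(0.85) - logit(0.30)))
cfg = SimConfig(n_per_arm=150, beta0=float(logit(0.30)), beta_hr=0.0,
                beta_her2=0.0, beta_trt=0.0, biomarkers=[spec], seed=20260923)
cohort, truth = generate_cohort(cfg)

report = pipeline.run_cutpoint_bayes(
    cohort, "pFOXO1",
    config=pipeline.RunConfig(master_seed=20260923, cutpoint_repeats=500))
```

Output:

```
status:            ok
selected cutpoint: 2992.3  (true threshold 2981.0)
stability count:   135 / 500 training selections
fraction high:     0.493
pCR, biomarker-high (treated): 0.862 95% CrI [0.779, 0.927]
pCR, biomarker-low  (treated): 0.363 95% CrI [0.259, 0.469]
max split R-hat:   1.004
```

The search recovers the generating threshold (2992 vs 2981 — the same pair
of flanking observations), easily clears the 10/500 stability filter, and
the posterior subgroup means (0.862 / 0.363) track the simulated cohort's
realized subgroup pCR rates. A biomarker-positive rule classifying ~49% of
patients with an 86% vs 36% estimated pCR split is exactly the kind of
candidate this analysis is meant to surface for external validation.

The same stages are exposed on the command line:

```bash
bmx simulate --config sim.yaml --out cohort/ --seed 3
bmx standardize-rppa --rppa cohort/rppa.tsv --clinical cohort/clinical.tsv \
    --batches cohort/batches.tsv --out rppa_std.tsv --seed 3
bmx screen --matrix rppa_std.tsv --clinical cohort/clinical.tsv \
    --kind rppa --population interaction_adjusted --out screen.tsv
bmx cutpoint --matrix rppa_std.tsv --endpoint pFOXO1 \
    --clinical cohort/clinical.tsv --repeats 500 --seed 3 --out cp.json
```

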