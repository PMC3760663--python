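# Methods

## Model

Eye colour is modelled as a three-level categorical trait — blue,
intermediate, brown — with a baseline-category (multinomial) logistic
model on the effect-allele dosages of the six IrisPlex SNPs.  For
non-reference category *k*,

    η_k = α_k + Σⱼ β_kj xⱼ,    η_ref = 0,    p_k = softmax(η)_k .

The model assumes additive allele effects on the log-odds scale, no
marker–marker interactions, and fully observed dosages.  Probabilities are
computed with a log-sum-exp normalisation, so linear predictors of
magnitude up to several hundred are handled without overflow.

The parameter container records its reference category explicitly and all
I/O is in fixed (blue, intermediate, brown) order, making parameter files
self-describing and coding-agnostic: `ParameterSet.with_reference`
re-expresses the same model under any reference, and predictions are
invariant to that transformation (property-tested).

Two parameter sources exist:

* `data/published_params.yaml` — the published IrisPlex coefficients,
  transcribed from the model's source publications and clearly marked
  externally sourced.  No test depends on these values.
* Coefficients fitted by the package itself (below); all tests run on
  fitted or hand-written parameter sets.

The effect-allele orientation of each marker (rs12913832 **T**, rs1800407
**A**, rs16891982 **C**, rs1393350 **A**, rs12896399 **G**, rs12203592
**T** — the minor alleles counted by the published model) lives in the
panel data file, not in code.

## Calling and its tunables

A colour call is made when the largest probability reaches the threshold
(default **0.7**, the level recommended for this model family), compared
**inclusively** — max(p) = 0.700 is a call.  Anything lower is
*inconclusive*.  An exact tie at or above threshold (possible only with
degenerate coefficients) is returned as inconclusive: a tie is not a
supported single-colour prediction, and this choice is deterministic and
conservative.  Thresholds ≤ 1/3 are rejected because the arg-max would
always pass.  Probabilities are thresholded unrounded.

Missing-data policy defaults to **strict** (error naming the SNP) because
the evaluation conventions assume complete profiles; **mean-impute**
replaces a missing dosage with 2 × effect-allele frequency (the
Hardy–Weinberg expectation) and flags the record as imputed.

## Fitting

`EyeColorModel.fit()` maximises the multinomial log-likelihood by
Newton–Raphson with backtracking line search: initialisation at zero
(deterministic, seedless), analytic score and Hessian, convergence when
the gradient ∞-norm falls below 1e-8 or the log-likelihood improves by
less than 1e-10, at most 200 iterations.  Standard errors come from the
inverse observed information.  Separated data are detected (diverging
coefficients or singular Hessian) and raise a typed error; an optional
ridge penalty stabilises such fits and stamps the result's provenance.
The fit is cross-checked in the test suite against statsmodels' MNLogit
(independent implementation) and against a nested grid search of the
likelihood in a single-SNP case.

Evaluation conventions: inconclusive calls are negative for every
category, feeding false negatives of the true category and true negatives
elsewhere.  Sensitivity/specificity/PPV/NPV therefore depend on the
threshold; ROC/AUC deliberately does not — each category's raw predicted
probability is the score in a one-vs-rest comparison, because the
probabilistic outputs, not the thresholded calls, carry the ranking
information.  AUC is the Mann–Whitney U probability with ties counting ½
(computed from midranks); the ROC curve steps through distinct score
values, tied samples entering as one (possibly diagonal) segment, which
makes the trapezoidal integral of the curve equal the U-based AUC to
machine precision.  Zero-denominator metrics (e.g. PPV of a category with
no positive calls) return an explicit undefined marker rendered `x` in
report tables, never NaN or an exception.  Display rounding is one decimal
for percentages, three for AUC; internal arithmetic is unrounded.

## Synthetic cohorts

The generator emulates a 105-sample Slovenian study population.  Sampling
scheme: phenotype from the category prevalences (47/105 blue, 27/105
intermediate, 31/105 brown); rs12913832 genotype from the
phenotype-conditional table implied by the joint counts

|        | blue | intermediate | brown |
|--------|-----:|-------------:|------:|
| **CC** | 45   | 4            | 0     |
| **CT** | 2    | 20           | 19    |
| **TT** | 0    | 3            | 12    |

and the five remaining SNPs independently as Binomial(2, effect-allele
frequency), i.e. Hardy–Weinberg within category.  This joint table is the
unique one consistent with every reported composition figure (91.8%
CC→blue, 46.3% CT→brown, 80% TT→brown, 55.4% of T-carriers brown, 87.5%
of T-carriers dark-eyed, marginals 47/27/31); it places the two
blue-with-brown-peripupillary-ring CT carriers in the blue category, the
only assignment that preserves the printed marginals.  The hazel share of
intermediate CT carriers (18/20) is carried in the configuration for
dark-iris expectations only; the generator does not sub-classify
intermediate irises.

Only rs12913832 is conditioned on phenotype, because joint counts are
reported for no other marker.  rs1800407's allele-A frequency is the
reported 0.119; the other four frequencies (rs16891982 C 0.05, rs1393350 A
0.26, rs12896399 G 0.45, rs12203592 T 0.14) are plausible European values
explicitly flagged `assumed` in the config, and no test asserts on them.

What the generator deliberately does **not** emulate: linkage
disequilibrium between markers, population structure or admixture,
genotyping error, and any real phenotype signal in the five minor SNPs.
Consequently, passing tests demonstrate that the pipeline's logic and the
model's statistical machinery behave correctly under the study's reported
structure — not that the five minor SNPs would show their real-data effect
sizes, nor that real-cohort AUCs would be reproduced numerically.

`generate_training_cohort` draws genotypes under Hardy–Weinberg and
phenotypes from a supplied parameter set's own predicted probabilities,
giving model-consistent training data at the scale of the n=3804 reference
panel the published model was calibrated on; it backs the
parameter-recovery and self-consistency tests.

## Problem sizes and seeds

The package derives all child seeds from one master seed via
`numpy.random.SeedSequence`, so every pipeline stage is reproducible.
Default analysis scales, chosen as comfortable desk-scale sizes with
sampling error well below the effects being checked: 20,000 samples for
structure-calibrated fits (3,804 in the one-command `reproduce`, matching
the published training-panel scale), 10,000-sample evaluation cohorts,
100,000-sample simulations for checking generator calibration (binomial
standard errors ≈ 0.15 percentage points), and 50,000 samples for the
parameter-recovery check (all coefficients within 3 standard errors of
truth).

## Known limitations

* The published per-individual probabilities are not public, so the
  published AUC values (0.966 blue / 0.913 brown / 0.796 intermediate)
  cannot be recomputed; the package instead verifies the AUC machinery
  exactly against an O(n²) pairwise oracle and reproduces the qualitative
  ordering blue > brown > intermediate on simulated cohorts.
* Because only rs12913832 carries genotype–phenotype signal in the default
  generator, simulated AUCs understate what a six-SNP signal would give.
* Intermediate eye colour is genuinely hard for this model class: under
  the study structure it is essentially never called at the 0.7 threshold
  (sensitivity 0, PPV undefined), and the package reproduces that
  behaviour rather than masking it.
* No confidence intervals on AUC; no light/dark two-category collapsing;
  no hair- or skin-colour models; VCF handling is rs-id-based with no
  liftover or multi-build support.
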