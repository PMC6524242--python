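# Methods

`mcgnet` implements a multicellular gene-network analysis for paired
tumor-cell (TC) / tumor-associated-macrophage (TAM) expression profiles,
and the survival-signature machinery built on top of it.  This note
documents the models, the tunable parameters, the synthetic study
conditions the test suite runs under, and the numerical choices made
where the design was genuinely open.

## The pipeline

1. **Vehicle normalization and differential expression.**  Each gene's
   values are divided by its mean over the Vehicle (untreated) animals,
   per compartment; genes with a zero Vehicle mean in a compartment are
   dropped there.  Rebound (drug-resistant) vs Endpoint (drug-sensitive)
   fold changes are ratios of group means of the normalized values;
   p-values come from a Welch t-test on log2(normalized + ε), ε = 0.01,
   adjusted by Benjamini–Hochberg within each compartment.  A DEG
   requires |FC| > 1.5 (strict, symmetric: FC > 1.5 or FC < 1/1.5) and
   adjusted p < 0.05 (strict).  The log-scale Welch variant is the
   robust default for skewed FPKM-like data; ε guards exact zeros.

2. **Multicellular networks.**  Nodes are (gene, compartment) pairs
   drawn from the top-k DEGs per compartment (k = 50 by default).  The
   observation unit is the paired animal, so intercellular (TC–TAM) and
   intracellular correlations are computed over the same aligned
   columns.  An edge requires |Pearson r| > 0.95 and two-sided p < 0.05
   (both strict); p comes from the exact t transform
   r·√((n−2)/(1−r²)) on n−2 df.  Node counts include edge-incident
   nodes only.  Topology: diameter of the largest connected component,
   Freeman degree centralization Σ(d_max − d_i)/((n−1)(n−2)), and mean
   degree 2E/N.

3. **Single-sample perturbation and the differential network.**  The
   sensitive network uses the Endpoint animals only (n = 6 in the
   default conditions); each perturbation network adds exactly one
   Rebound animal (n = 7).  For every candidate pair, ΔPCC_i =
   r(perturbation i) − r(sensitive) is recomputed from the raw sample
   vectors, never from the thresholded edge sets.  A pair is a robust
   differential edge when |ΔPCC| > 0.05 in at least 3 perturbations in
   a consistent direction; it is classed *gained* (ΔPCC > 0) or *lost*
   (ΔPCC < 0).  The candidate-pair universe defaults to the edge union
   (pairs that form a supra-threshold edge in the sensitive network or
   in at least one perturbation network); an all-pairs mode exists for
   oracle comparisons.

   *Sign consistency.*  `n_exceed` counts the dominant sign direction
   among the exceeding perturbations.  An evenly mixed pair can never
   reach the robustness minimum (3 of 4 is more than half), so
   contradictory pairs are not robust; counting the dominant direction
   (rather than vetoing on any opposite-sign exceedance) keeps the
   robust-edge set monotone in the ΔPCC threshold, which a hard veto
   does not (a vetoing minority exceedance can fall below a raised
   threshold and thereby *create* a robust edge).

4. **Signature learning.**  Candidate genes (the unique symbols of the
   differential network, passed through an optional ortholog symbol
   map) feed an L1-penalized Cox proportional-hazards fit
   (scikit-survival's coxnet, glmnet-style): 100 λ values log-spaced
   down to 10⁻³·λ_max, covariates standardized internally, coefficients
   reported on the original scale.  Tenfold cross-validation uses
   event-stratified folds and the Verweij–van Houwelingen partial-
   likelihood deviance −2·(ll_all(β_k) − ll_train(β_k)).  Two penalty
   rules are exposed:

   * `lambda_rule="min"` (default): λ at the minimum mean CV deviance,
     ties resolved toward the larger λ.  This maximizes predictive
     deviance and is the rule used for the risk score itself.
   * `lambda_rule="1se"`: the largest λ within one standard error of
     the minimum.  Under strong signal the minimum rule deliberately
     trades support sparsity for deviance and admits noise covariates
     (verified against R glmnet's `lambda.min` on identical exported
     data); the 1-SE rule is the appropriate choice when the goal is
     recovering the true support, and the sparse-recovery tests use it
     explicitly.

   Nonzero coefficients at the chosen λ are the risk coefficients —
   no post-selection refit.  The risk score is the linear predictor
   RS = Σ_g β_g·x_g on untransformed expression (a log2 flag exists).
   Published comparison signatures that exist only as gene lists (EGFR;
   the Cheng et al. immune signature; the IGF1/IGF1R pathway list) are
   refit by unpenalized multivariate Cox on the learning cohort.  The
   combined score CS = 0.008974621·Age + 1.617859481·Grade +
   0.940077644·RS₁ + 0.006408624·RS₃ uses grade coded 1 (lower grade)
   or 2 (high grade).

5. **Evaluation.**  Time-dependent ROC uses the cumulative-cases /
   dynamic-controls estimator with Kaplan–Meier inverse-censoring
   weights: cases (event by horizon t) weighted 1/Ĝ(T⁻), controls
   (at risk beyond t) weighted 1/Ĝ(t); AUC is the weighted probability
   that a case outscores a control (ties half).  With no censoring this
   reduces exactly to the Mann–Whitney statistic of status at the
   horizon.  "Overall survival" AUCs use the 75th percentile of
   observed follow-up as the horizon (configurable).  Optimal cutoffs
   maximize the Youden index on the relevant horizon's ROC.  High/low
   risk groups are compared by product-limit curves and the two-sided
   log-rank test (lifelines).  The random-signature null refits an
   unpenalized Cox model per draw of k genes (k = 12, B = 1000 by
   default) and reports both p = #{AUC_b ≥ AUC_obs}/B and the add-one
   version (1+#)/(B+1).  Robustness subsampling draws B = 100 paired
   50% subsamples (a 60% preset is also provided) and compares AUC
   distributions by one-tailed Wilcoxon rank-sum tests.  Drug-response
   surrogate analysis restricts to targeted-therapy patients, labels
   survival status at the 3- or 5-year horizon as sensitive (alive) or
   resistant (dead), excludes patients censored before the horizon, and
   classifies by the Youden cutoff (low RS → predicted sensitive).

## Synthetic study conditions

The generators define the conditions every stochastic test runs under;
they are fixed, not tuning knobs.

**Mouse experiment** (`mouse_truth_preset`): 1000 genes per compartment,
5/6/4 Vehicle/Endpoint/Rebound animals, log-normal abundances with
baseline log-mean N(3, 1) and within-group log-noise σ = 0.2.  Planted
DEGs get a Rebound log-mean shift of log(FC) with FC log-uniform in
[1.8, 4] (random direction), 20 per compartment.  Planted gained pairs
share a latent factor whose Rebound loading is amplified to 5.0 log
units at within-pair correlation 0.998 (Endpoint correlation 0 by
default): each single Rebound animal becomes a high-leverage point on
the pair's own diagonal, the mechanism by which adding one resistant
sample to the six-sample reference set raises the pair's correlation
past the edge threshold.  The amplitude and correlation were chosen
once so that a planted pair's perturbed correlation reliably clears the
0.95 edge gate at n = 7 (an on-diagonal point ~11σ out is required for
r > 0.95 next to a 6-point cluster).

Two facts about this mechanism worth knowing before interpreting
recovery numbers:

* *Cross-pair gains are real.*  Any two genes that are both extreme in
  the same added sample gain sample correlation — single-sample
  perturbation cannot distinguish a truly co-varying pair from two
  independently extreme genes.  In the recovery conditions the
  false-gained *rate* (false positives per non-planted candidate pair)
  is ~0.004, but because there are ~4900 candidate pairs and only 10
  planted ones, such calls still outnumber true ones; the differential
  network should be read as a set of co-perturbed genes, not of
  verified pairwise interactions.
* In the full-pipeline preset the planted pair genes carry a Rebound
  mean shift (so they are differentially expressed) *and* the amplified
  variance; the variance inflates the Welch denominator, so
  correlation-perturbed genes are not necessarily significant DEGs.
  Mean-shifted DEGs, co-shifted deterministically, dominate the
  resulting differential network — all-gained, mirroring how strongly
  resistant samples co-displace many genes at once.

**Patient cohorts** (`cohort_truth_preset`): 2000-gene universe
containing the 12 signature genes and the comparison gene lists;
expression log-normal LN(0, 0.5) i.i.d.; hazard h(t) = 0.25·exp(η) per
year with η = Σβ_g x_g + log(1.9)·1[age ≥ 60] + 0.8·(grade−1), so a Cox
fit on stored expression recovers the planted coefficients; independent
exponential censoring with its rate solved by bisection to a 30%
censoring fraction.  The planted signature uses the published 12-gene
coefficient *signs* with a uniform magnitude of 0.9: the published
magnitudes span three orders of magnitude, so genes with near-zero
coefficients carry no recoverable signal and no selection method could
find them; uniform magnitudes give every planted gene the same
signal-to-noise, calibrated once to a validation 5-year AUC ≈ 0.9.
Mutation/subtype annotations are cut from a noisy copy of η, giving
risk-score differences between annotation groups without a separate
mechanism.  Learning/validation sizes default to 310 and 690.

What the generators do *not* emulate: batch effects, tumor purity,
count noise/overdispersion at low expression, gene–gene correlation
outside planted pairs, informative censoring, and competing risks.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under clean conditions, not performance on real cohorts.

## Numerical choices and degenerate inputs

* Correlations are snapped to ±1 (p = 0) within 1e-12 of exact
  collinearity; zero-variance vectors are an error at the primitive
  level and are skipped with a log entry by network builders.
* Degenerate t-tests (all values identical in both groups) report
  p = 1; zero variance with different means reports p = 0.
* Top-k DEG ties break by smaller adjusted p, then lexicographic
  symbol; node-strength ties break lexicographically.
* The Cox partial likelihood uses Breslow tie handling throughout the
  CV deviance; `lifelines` (Efron) is used for inference tables, where
  the tie method does not affect the reported checks.
* Cox non-convergence: per-gene univariate fits return a flagged
  non-estimable record; random-signature draws are resampled (capped at
  2B attempts); gene-list refits retry once with a small ridge penalty.
* Survival time units are declared per cohort (years by default);
  "3-year"/"5-year" horizons are converted internally.

## Problem sizes

The test suite and the acceptance script run the study at the
generators' default sizes: 50 seeds for the differential-network
operating characteristics, 10 learning/validation seed pairs (n = 310 /
690) for signature recovery, 50 seeds at B = 40 (n = 150 cohorts,
300-gene universe) for null-calibration uniformity, and B = 200 for the
planted-signal null.  These sizes give stable medians while keeping a
full run in the low minutes on one core.

## Known limitations

* The ΔPCC statistic is intentionally leverage-driven; with n_Ep = 6 it
  is sensitive to any single extreme sample, and robustness across ≥ 3
  of 4 perturbations is the only guard.  It does not control a formal
  error rate.
* The edge-union pair universe makes the differential network depend on
  the 0.95 edge gate; pairs whose correlation changes without ever
  crossing it are invisible in the default mode (use all-pairs to see
  them).
* Unpenalized Cox refits of fixed gene lists can be unstable for lists
  approaching the event count; the ridge fallback changes coefficients
  slightly in that regime.
* GraphML export carries edge attributes only (no layout).
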