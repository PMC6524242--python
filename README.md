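# mcgnet

Multicellular gene-network perturbation analysis and
differential-network-constrained survival signatures.

## The problem

Resistance to molecularly targeted therapy is often shaped by the tumor
microenvironment rather than by tumor cells alone.  Given paired
expression profiles of tumor cells (TC) and tumor-associated
macrophages (TAM) from the same animals — grouped into Vehicle
(untreated), Endpoint (responding, drug-sensitive) and Rebound (regrown
under treatment, drug-resistant) arms — `mcgnet` asks which gene–gene
associations *within and between* the two cell compartments rewire as
resistance emerges, and whether the genes at those rewired edges carry
prognostic information in patient cohorts.

The package is for computational biologists who want the full chain as
a tested, scriptable library: differential expression → multicellular
co-expression networks → single-sample network perturbation → robust
differential network → penalized Cox signature → survival and
drug-response evaluation — plus synthetic data generators with known
ground truth so every stage is testable without controlled-access data.

## The method

Nodes are (gene, compartment) pairs from the top-50 DEGs per
compartment (|FC| > 1.5 and BH-adjusted p < 0.05, Rebound vs Endpoint,
vehicle-normalized).  An edge requires |Pearson r| > 0.95 and p < 0.05
across paired animals.  A *sensitive* network is built from the
Endpoint animals alone; adding each single Rebound animal to the
reference set yields one *perturbation* network per resistant animal.
For every candidate pair,

ΔPCC_i = r(Ep ∪ {Reb_i}) − r(Ep),

and a pair is a **robust differential edge** when |ΔPCC| > 0.05 with a
consistent sign in at least 3 of the 4 perturbations; edges are classed
*gained* (ΔPCC > 0) or *lost* (ΔPCC < 0).  The differential network's
genes are candidates for an L1-penalized Cox proportional-hazards fit
with tenfold cross-validated λ; the nonzero coefficients define a risk
score RS = Σ_g β_g·x_g.  Evaluation covers time-dependent ROC
(cumulative/dynamic with Kaplan–Meier censoring weights), Youden-cutoff
Kaplan–Meier/log-rank splits, a random-gene-signature bootstrap null,
50% subsample robustness, bootstrap AUC comparisons, multivariate
adjustment for clinicopathologic factors, stratified cohorts, and a
survival-status surrogate for targeted-therapy response.  See
`docs/methods.md` for assumptions, parameters and numerical choices.

## Worked example

Learn a signature on a synthetic learning cohort (n = 310, 12 planted
genes among 29 candidates) and validate it on an independent synthetic
cohort (n = 690):

```python
from mcgnet import simulate, signature, evaluate
from mcgnet.datatypes import AnalysisConfig

truth = simulate.cohort_truth_preset()
learn, _ = simulate.simulate_cohort(truth, 310, seed=11, name="learning")
valid, _ = simulate.simulate_cohort(truth, 690, seed=12, name="validation")

cfg = AnalysisConfig(rng_seed=1)
fit, sig = signature.fit_lasso_cox(learn, truth.candidate_genes, cfg)
print(f"selected {len(sig)} genes at lambda = {fit.best_alpha:.6f} "
      f"(ln lambda = {fit.log_best_alpha:.4f})")

rs = signature.apply_signature(sig, valid).scores
for h in (3.0, 5.0):
    roc = evaluate.time_dependent_roc(rs, valid.time, valid.event, h)
    print(f"{h:.0f}-year AUC = {roc.auc:.3f}  (Youden cutoff {roc.cutoff:.3f})")

roc5 = evaluate.time_dependent_roc(rs, valid.time, valid.event, 5.0)
groups = evaluate.split_by_cutoff(rs, roc5.cutoff)
km = evaluate.km_logrank(valid.time, valid.event, groups)
print(f"log-rank chi2 = {km['chi2']:.1f}, p = {km['p']:.3g}, "
      f"groups = {km['group_sizes']}")
```

Output:

```
selected 18 genes at lambda = 0.001989 (ln lambda = -6.2202)
3-year AUC = 0.890  (Youden cutoff 5.486)
5-year AUC = 0.907  (Youden cutoff 5.238)
log-rank chi2 = 315.9, p = 1.16e-70, groups = {'high': 414, 'low': 276}
```

The fit selects all 12 planted genes (plus several weakly weighted
extras — the CV-minimum penalty favors predictive deviance over
sparsity; pass `lambda_rule="1se"` in `AnalysisConfig` for the sparse
variant).  The 3- and 5-year AUCs near 0.9 and the strongly separated
risk groups reflect the planted signal strength; on null cohorts the
same pipeline returns AUC ≈ 0.5 and uniform null p-values.

The mouse-side pipeline is analogous
(`simulate.simulate_mouse_experiment` → `diffexpr.vehicle_normalize` →
`diffexpr.select_degs` → `network.build_sensitive_and_perturbation_networks`
→ `diffnet.build_differential_network`), and everything is also exposed
as a CLI:

```sh
mcgnet simulate-mouse --seed 3 --out sim/
mcgnet deg --expr sim/expression.tsv --samples sim/samples.tsv --out degs.tsv
mcgnet diffnet --expr sim/expression.tsv --samples sim/samples.tsv \
    --degs degs.tsv --out diffnet/
mcgnet train --expr learn/expression.tsv --clinical learn/clinical.tsv \
    --candidates diffnet/diffnet_genes.txt --seed 1 --out signature.json
mcgnet evaluate --expr valid/expression.tsv --clinical valid/clinical.tsv \
    --signature signature.json --out report.json
```

Users with their own extracted expression/clinical tables (TSV/CSV, gene
symbols in the first column) can skip the `simulate-*` steps.

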