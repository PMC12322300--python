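# cnfprot

Differential-abundance analysis for matched tumor/normal DIA proteomics,
built around the paired design of cutaneous neurofibromas (cNF) and their
overlying skin in neurofibromatosis 1. Starting from a normalized
protein × sample quantity matrix, the pipeline applies identification
confidence filters, classifies missing values into informative (below the
limit of detection) and random, imputes the informative ones with the
dataset-minimum quantity, rolls proteins up into Gene Ontology (GO) terms,
estimates tumor/skin abundance ratios with linear mixed-effects models,
correlates per-sample GO indices between biological processes, and
clusters samples hierarchically. A generative simulator of the paired
design, with ground truth, makes every stage testable end to end.

It is intended for proteomics analysts working with small matched-pair
cohorts (a handful of donors, each contributing several lesion/control
pairs) where donor and excision structure must be modeled, not averaged
away.

## Model

For protein *p* annotated to GO term *g*, measured in sample *s* of
excision (lesion pair) *l* from patient *i*, the log quantity is modeled
as

```
log q_ps = mu + beta_g · 1[tissue(s) = cNF] + u_p + a_i + b_l + eps_ps
```

with random intercepts `u_p` (protein), `a_i` (patient) and `b_l`
(excision nested in patient), fitted by REML. The reported effect is
`exp(beta_g)`, the cNF/skin abundance ratio, with Wald 95% CIs; a ratio of
0.41 means a 59% lower level in the tumor. On non-convergence the model is
simplified by dropping first the patient intercept, then the excision
intercept. Single-protein contrasts use the same cascade without `u_p`.
P values are Bonferroni-corrected over the family of tested terms.

Missingness handling follows an 80/20 reliability rule: if a protein is
quantified in ≥80% of the samples of one tissue and missing in more than
20% of the other tissue's samples, those missing values are attributed to
expression below the limit of detection and imputed with the minimum
quantity observed in the dataset; proteins detected in <80% of samples in
both tissues are never imputed, and all other missing values are treated
as missing at random and dropped from model likelihoods.

The per-sample GO index of a term is the mean over its proteins of
`q_ps / mean_s'(q_ps')`; indices of two processes are related within one
tissue by regressing log index on log index with a patient random
intercept.

## Worked example

```python
import cnfprot as cp
from cnfprot.io import format_ratio_ci

cfg = cp.SimulationConfig(seed=2)          # 4 patients, 15 matched pairs,
matrix, samples, annotations, truth = cp.simulate_study(cfg)  # 20 terms x 10 proteins

filtered = cp.filter_low_confidence(matrix)           # P < 0.05, >= 2 peptides
imputer  = cp.LodMinimumImputer().fit(filtered, samples)
imputed  = imputer.transform(filtered)
print("imputed:", imputer.report_.n_imputed_total,
      "remaining missing:", imputer.report_.n_remaining_missing)

terms = cp.eligible_terms(annotations)                # > 4 proteins per term
for e in cp.go_differential_abundance(imputed, samples, annotations,
                                      term_ids=terms[:3], family_size=len(terms)):
    print(e.target_id, f"true={truth.term_true_ratio[e.target_id]:.2f}",
          "est=" + format_ratio_ci(e.ratio, e.ci_low, e.ci_high),
          f"p_corr={e.p_corrected:.3f}", e.model_structure_used)

print("tissue purity:", cp.SampleClustering().fit(imputed, samples).purity_)
```

prints

```
imputed: 20 remaining missing: 282
GO:SIM0000 true=0.40 est=0.39 (0.36 to 0.42) p_corr=0.000 full
GO:SIM0001 true=0.44 est=0.43 (0.40 to 0.47) p_corr=0.000 full
GO:SIM0002 true=0.48 est=0.46 (0.43 to 0.50) p_corr=0.000 full
tissue purity: 0.7
```

The first line reports how many missing cells the 80/20 rule imputed and
how many remain as missing-at-random. Each term line compares the true
simulated cNF/skin ratio against the mixed-model estimate with its 95% CI
("full" = no fallback was needed). The final purity is the fraction of
samples whose two-cluster assignment matches their tissue; 0.7 reflects
the realistic default noise level, under which tumors and skin overlap
substantially.

The same stages are available as a CLI (`cnfprot simulate | filter |
impute | go-test | protein-test | correlate | cluster | all`) driven by a
single YAML config; `cnfprot all` writes result tables, a Newick
dendrogram, and a JSON run report recording every threshold and fallback
actually used.

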