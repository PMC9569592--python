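# fusionlab

Clinical–molecular data fusion for binary cancer classification, built
around the thyroid-nodule diagnosis setting: can adding a single feature
extracted from routine clinical data (sex, age, tumor size, Bethesda
cytology category) to a gene-expression classifier keep — or improve —
accuracy while cutting the number of molecular markers, and hence the
cost of the assay?

The package implements the full comparison pipeline:

1. **Malignancy risk extraction** (`fusionlab.clinical_bn`).  Raw
   clinical variables are discretized into expert bands, a discrete
   Bayesian network over {Sex, Age, Size, Bethesda, Risk} is learned by
   Tabu search under the AIC score, CPTs are estimated as Dirichlet
   posterior means, and each sample's *malignancy risk*
   P(Risk = malignant | Markov-blanket evidence) is computed by
   likelihood weighting.  Risks are cross-fitted (stratified k-fold,
   k = 10) so no sample is scored by a network trained on it.
2. **Fusion strategies** (`fusionlab.fusion`).  *Early fusion* appends
   the risk to the gene matrix before feature selection (it competes in
   the ranking); *late fusion* selects N genes first and then appends
   the risk (N + 1 model inputs); *no fusion* and *clinical-only* are
   the references.  Everything — fusion, selection, train-fitted z-score
   normalization, linear-kernel SVM — runs inside a bootstrap loop
   (out-of-bag test sets, in-bag draws shared across strategies for
   paired comparison) and strategies are compared with a two-sided
   Mann–Whitney test on the per-iteration accuracies.
3. **Feature selection** (`fusionlab.feature_selection`).  Wilcoxon
   rank-sum with Benjamini–Hochberg correction, and ReliefF (k nearest
   hits/misses, Manhattan distance on min–max-scaled features).
4. **Selection stability** (`fusionlab.stability`).  The Kuncheva index

   κ(S) = 2/(K(K−1)) · Σ_{i<j} (|S_i ∩ S_j| − k²/n) / (k − k²/n),

   the chance-corrected mean pairwise overlap of the K selected sets,
   with the late-fusion adaptation that gathers *all* features entering
   each classifier (selected genes + risk) on a shared universe.
5. **Dependency metrics** (`fusionlab.dependency`).  Pairwise Spearman
   correlation and Kraskov kNN mutual information between genes and
   between genes and the risk.
6. **Synthetic cohorts** (`fusionlab.synthetic`).  A generator producing
   labelled clinical tables and expression panels with controllable
   class prevalence, correlation regime (unimodal vs bimodal pairwise
   correlations), per-gene effect size and — crucially — a
   *complementarity* dial that controls how much of the class signal is
   visible only to the clinical channel.

## Worked example

```python
from fusionlab import (GeneratorConfig, generate_clinical, generate_expression,
                       discretize_clinical, extract_malignancy_risk,
                       run_experiment, compare_models)
from sklearn.metrics import roc_auc_score

cfg = GeneratorConfig(seed=1)            # 200 samples, 163-gene panel
clin = generate_clinical(cfg)
expr = generate_expression(cfg, clin["label"])
y = (clin["label"] == "malignant").astype(int).to_numpy()

risk = extract_malignancy_risk(discretize_clinical(clin), k=10, seed=1)
print(round(roc_auc_score(y, risk), 3))  # 0.867 — clinical channel alone

grid = run_experiment(expr, risk.to_numpy(), y,
                      strategies=("early", "late", "none"),
                      methods=("wilcoxon",), n_features_range=(3, 8, 15),
                      B=100, seed=1)
print(grid.summary()[["strategy", "n_features", "median_acc", "kuncheva"]])
```

On this cohort the gene-only reference peaks around a median out-of-bag
accuracy of 0.75 at 15 features, while early fusion reaches 0.85 with
just 8 molecular features plus the risk (Mann–Whitney p ≈ 1e−27 on the
paired bootstrap accuracies): the clinical feature replaces roughly half
of the molecular panel.  Early fusion is also the more stable selector
at low feature counts (mean Kuncheva ≈ 0.68 vs 0.60 for late fusion
over 1–5 features), because the risk feature sits at the top of the
ranking in nearly every bootstrap iteration.

A command-line interface mirrors the pipeline stages
(`fusionlab simulate / extract-risk / deps / rank / evaluate /
stability`); see `fusionlab --help`.

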