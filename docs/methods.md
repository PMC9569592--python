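# Methods

## The problem

A thyroid-nodule cohort carries two views of each sample: a normalized
log-scale gene-expression panel and a handful of routine clinical
variables (sex, age, tumor size, Bethesda cytology grade II–VI), with a
binary histopathology label (malignant / benign).  The package asks how
to combine the two views for classification — and in particular whether
one clinical summary feature can substitute for part of the molecular
panel.  All development and testing runs on synthetic cohorts; the
generator is a first-class, tested module.

## Clinical feature extraction

**Discretization.**  Age bands <20, (20,45], (45,60], >60 years; size
bands at 0.5, 1, 1.5, 2.5 and 4 cm (XS–XXL).  The band definitions
leave the exact boundary values unassigned, so the implementation uses
left-open right-closed intervals with the lowest bin closed at 0 (age
20 → "<20", size 0.5 cm → XS); the choice is arbitrary but fixed for
determinism.

**Structure learning.**  Tabu search over single-edge add / delete /
reverse moves, scored by AIC = log-likelihood − (number of free CPT
parameters), i.e. Σ_i (r_i − 1)·q_i with r_i the node's domain size and
q_i its parent-configuration count.  The score decomposes over node
families and family scores are cached.  Unstated search parameters were
fixed as: tabu list length 10 (storing inverses of applied moves, with
aspiration), 200 iterations, no restarts, deterministic lexicographic
tie-breaking — the search is then fully deterministic given the data.
On ≤3-node problems the result is verified against exhaustive DAG
enumeration; on a 5-node benchmark with clearly detectable edges the
learned skeleton is within structural Hamming distance 1 of the truth
in ≥90% of seeds at n = 2000.  Note AIC's penalty is scale-free in n,
so spurious-edge acceptance has a fixed small chi-square probability
per candidate edge; the SHD ≤ 1 tolerance absorbs this.

**Parameters.**  CPT entries are Dirichlet posterior means,
(n_ijk + iss/(r·q)) / (n_ij + iss/q), with imaginary sample size
iss = 1 by default — minimal smoothing that keeps every entry strictly
positive so likelihood weighting can never produce zero total weight.

**Inference.**  The risk query P(Risk = malignant | evidence) uses
likelihood weighting (evidence nodes clamped, others sampled in
topological order, draws weighted by evidence likelihood), with
evidence restricted to the Markov blanket of Risk; variables outside
the blanket carry no additional information and are ignored with a
warning.  Default 10⁴ draws per distinct evidence pattern (patterns are
cached); exact joint enumeration is available (`method="exact"`) and
serves as the oracle in tests, where the two agree to <0.01 at 10⁵
draws.

**Cross-fitting.**  Stratified 10-fold splits; structure and parameters
are learned per fold on the other nine folds with the label included as
the Risk node, and held-out samples are scored by the fold's network.
Permuting labels before extraction drives the risk–label AUC to 0.5,
confirming no leakage.

## Fusion and evaluation

Bootstrap with out-of-bag testing: each iteration draws n samples with
replacement; the unused ≈36.8% form the test set.  Fusion, ranking,
z-score normalization (per-column mean/SD fitted on the training part,
SD with the n−1 denominator, zero-SD columns mapped to zero) and the
linear SVM (C = 1, no class weighting) all sit inside the loop.  An
alternative reading of the protocol normalizes the whole dataset before
splitting; that leaks test statistics into training and is available
only behind an explicit `leaky_normalization` flag for sensitivity
analysis.  In-bag draws are shared across all grid cells at equal
iteration index so strategy comparisons are paired; rankings are
computed once per (iteration, method, candidate pool) and re-sliced per
nFeatures, which is exactly equivalent to independent cells because the
rankers are deterministic.

Early-fusion nFeatures counts the risk feature when it is selected (it
competes with the genes, so the candidate pool has p + 1 entries and
nFeatures may go up to p + 1); a late-fusion cell at nFeatures = N
always trains on N + 1 inputs.  When both strategies train on the
complete panel plus risk they produce bit-identical accuracies under
shared draws: the final design matrix is assembled in a canonical
column order before fitting, and a linear kernel is invariant to column
permutation.

Accuracy summaries are the median and the 2.5/97.5 percentiles of the
per-iteration accuracies; strategies are compared with a two-sided
Mann–Whitney U test (tie-corrected normal approximation without
continuity correction — so identical inputs give p = 1 — and the exact
distribution for small tie-free samples).  B defaults to 500; the test
suite and the acceptance script use B = 100, which is sufficient to
resolve the strategy contrasts they assert.

## Feature selection

**Wilcoxon ranker.**  Two-sided rank-sum p-value per feature — exact
when the combined sample is ≤25 without ties (verified against full
enumeration), otherwise the tie-corrected normal approximation —
followed by Benjamini–Hochberg adjustment across features; ranking
ascends by adjusted p, ties broken by raw p then feature index.
Zero-variance features get p = 1 and rank last.

**ReliefF.**  For each training instance, the k = 10 nearest hits and
k nearest misses (Manhattan distance on min–max-scaled features) update
the weights; miss contributions are weighted by prior odds
P(miss class)/(1 − P(own class)).  By default every instance is used
once (m = "all"), making the ranker deterministic; subsampling (m < n)
is available behind a flag.  Weights match an independent double-loop
implementation to 1e-12.

## Stability

Kuncheva index as defined above; k must be constant across the K sets,
so records with deviant cardinality are excluded with a warning rather
than padded, and the degenerate k = n point (undefined denominator) is
omitted from curves.  The late-fusion universe includes the risk
identifier (n = genes + 1) so early and late indices share a scale.

## Dependency metrics

Spearman rho with average ranks on ties for all C(p,2) pairs (plus each
feature against the risk); constant columns are reported missing.
Mutual information uses the Kraskov–Stoegbauer–Grassberger estimator,
algorithm 1 (max-norm neighborhoods, ψ(k) + ψ(N) − ⟨ψ(n_x+1) +
ψ(n_y+1)⟩), k = 3 by default, reported in nats; exact ties receive a
deterministic sub-resolution jitter.  The estimator reproduces the
Gaussian closed form −½·ln(1−ρ²) to within 0.05 nats at n = 5000 and is
invariant under monotone marginal transforms to the same tolerance.

## The synthetic generator

There is no public dataset, so the generator defines the study
conditions: n = 200 samples at prevalence 77/200, a 163-gene panel by
default, and these mechanisms:

* **Label** ~ Bernoulli(prevalence).
* **Clinical channel.**  Bethesda follows a proportional-odds model:
  fixed cutpoints give a benign marginal of roughly
  II .25/III .30/IV .25/V .15/VI .05 (mostly III–V, as in FNAB series)
  and the malignant latent is shifted by `clinical_signal` log-odds.
  The default 3.5 yields a theoretical Bethesda-vs-label AUC of 0.904
  (computed analytically from the cutpoints), i.e. a clinical channel
  worth AUC ≈ 0.9 on its own.  Age uses the same model at one tenth the
  log-odds strength; sex (82% F) and log-normal tumor size are
  independent of the label.
* **Molecular channel.**  Class-conditional Gaussian genes on a
  log2-microarray-like scale (baselines U(4,12), unit noise).
  Informative genes shift by `effect_size` (alternating sign) between
  molecular states, where the molecular state is the label flipped per
  sample with probability `clinical_complementarity`/2.  At
  complementarity c the genes can therefore recover the label with
  accuracy at most 1 − c/2 regardless of panel size, while the clinical
  channel is unaffected — this is what makes fusion genuinely
  beneficial at c > 0.  At c = 0 the molecular channel carries the full
  signal, and with a saturated gene panel the risk feature adds nothing
  beyond test-set noise.
* **Correlation regimes.**  `bimodal`: one shared factor with loadings
  ±√block_rho over two half-panels, giving pairwise correlations
  +block_rho within and −block_rho between blocks (almost no mass near
  zero).  `unimodal`: many weak random factor loadings, correlations
  concentrated in (−0.2, 0.2).
* Defaults `n_informative = 15` and `effect_size = 0.7` put the
  gene-only optimum near 15 selected features with accuracy clearly
  below the fusion models, reproducing the qualitative
  dimensionality-reduction pattern the pipeline is designed to detect.

What the generator does **not** emulate: probe-level microarray noise,
batch effects, missing clinical values, heavy-tailed expression, and
gene–gene regulatory structure beyond block covariance.  Passing tests
therefore demonstrate correctness of the machinery and recoverability
of the designed signal structure, not performance claims about real
cohorts.

## Problem sizes used in the checks

Structure recovery uses n = 2000 observations and 20 seeds; MI checks
n = 5000; the pipeline-level checks use the default cohort (n = 200,
163 genes) with B = 100 bootstrap iterations over nFeatures 1–8 and 15.
These sizes resolve every asserted contrast with comfortable margins.

## Known limitations

* The Bayesian network handles discrete nodes only; continuous clinical
  covariates must be banded first.
* A single network is learned per fold; bootstrap-consensus structures
  (averaging edges over resamples) are not implemented.
* AIC with penalty coefficient 1 admits a fixed small false-positive
  edge rate; for larger variable sets a BIC-type penalty would be the
  natural extension.
* The Kuncheva index requires equal-size sets; rank-aware stability
  measures are out of scope.
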