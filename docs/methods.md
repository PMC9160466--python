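# Methods

## Model

Binary symptom indicators `x ∈ {0,1}^p` are modelled as a pairwise Markov
random field (Ising model),

P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} w_{ij} xᵢ xⱼ ),

with node thresholds τ (endorsement propensities) and symmetric edge
weights w (conditional log-odds interactions: w_{ij} is the change in the
log-odds of item i given item j, holding all other items fixed).  The
0/1 state coding — not ±1 — is used throughout, matching the
logistic-regression pseudo-likelihood on which estimation is based; all
fixtures and formulas assume it.

### Estimation (eLasso)

Each node is regressed on the remaining p−1 items by ℓ1-penalized
logistic regression,

min_{β₀,β} −(1/n) Σᵢ [ yᵢηᵢ − log(1+e^{ηᵢ}) ] + λ‖β‖₁,  η = β₀ + Xβ,

with an unpenalized intercept, over a grid of `n_lambda = 100` penalties.
The per-node λ is selected by the Extended Bayesian Information Criterion

EBIC(λ) = −2ℓ̂(λ) + k log n + 2γ k log(p−1),

where k is the number of nonzero neighbor coefficients, the model-space
term uses log(p−1) (the candidate-predictor count per node — EBIC
variants differ, so this is stated explicitly), and γ defaults to 0.25,
the standard recommendation for Ising networks; γ = 0 reduces to BIC
exactly.  Directed coefficient pairs are combined with the AND rule (edge
present only when both directions are nonzero; weight is their mean),
the recommendation of the eLasso literature; OR is available in
`RegularizationConfig`.

Grid spacing is logarithmic from each node's own λ_max (the null-model
KKT boundary max_j |x_jᵀ(y−ȳ)|/n) down to `λ_max·lambda_min_ratio`
(default 0.01); linear spacing is exposed as an option since "evenly
spaced" grids are convention-dependent.  Predictors enter on their
natural 0/1 scale without standardization — binary items share a scale
and raw coefficients read directly as log-odds effects; a standardize
flag exists for sensitivity analysis.  Intercepts are never penalized.
EBIC ties are broken toward the larger penalty (the sparser model).
Edge presence is judged by exact zeros of the soft-threshold solution,
not by an epsilon.

### Contrast statistic and bootstrap

For probe `WL`, Σw_RLH sums its edges to {SB, HL, GU}, Σw_RPA its edges
to {LS, LE, NI}, and Δ = Σw_RLH − Σw_RPA.  Inference is by nonparametric
case bootstrap: subjects are resampled with replacement `n_boot` times
(default 10,000) and the entire estimation — penalty grid, EBIC
selection, AND combination — is repeated per resample.  Confidence
limits are percentile intervals (default width 0.975, i.e. the 0.0125
and 0.9875 empirical quantiles with linear interpolation between order
statistics; quantile conventions differ, so this is pinned down).  BCa
or normal intervals are deliberately not used.  The nine pairwise
edge-difference tests (each RLH edge vs each RPA edge) reuse the same
bootstrap ensemble at level 1 − 0.05/18; the divisor 18 Bonferroni-counts
9 pairs × 2 study samples and is kept as the single-dataset default for
comparability (overridable via `BootstrapConfig.alpha_pairwise`).

Resamples that leave an item constant are kept — the node is isolated in
that resample (redrawing would bias the bootstrap distribution) and the
event count is reported on the ensemble.  Per-resample random streams
are spawned from the master seed, so enlarging `n_boot` extends the
ensemble without reshuffling earlier draws.

### Permutation network comparison

Two samples are compared by pooling subjects and permuting group labels
(sizes preserved exactly), re-running the full network estimation for
both groups at every permutation.  Statistics: M = max |w₁ − w₂| over
edges (structure invariance), S = |strength₁ − strength₂| where strength
is the sum of absolute edge weights (the absolute-value convention of the
standard comparison test; a signed sum is exposed), and all p(p−1)/2
individual |edge differences| — including pairs zero in both observed
networks.  P-values use the add-one estimator (1 + #{perm ≥ obs})/(1 + B),
so the smallest attainable p is 1/(B+1).  Per-edge p-values are
Holm–Bonferroni adjusted (step-down with cumulative-max monotonicity,
capped at 1; delegated to statsmodels).

### Ordinal GGM replication

As a robustness companion, the raw 1–5 scores feed a Gaussian graphical
model: an item correlation matrix (Pearson on raw scores by default —
the field's common shortcut; Spearman and two-step polychoric available,
and the method used is recorded in the output metadata) is passed to the
graphical lasso over 100 log-spaced penalties from max|off-diagonal
correlation| downward, selected by EBIC = −2L + E log n + 4Eγ log p with
E the nonzero upper-triangle precision entries and γ = 0.5 (the
convention of the EBIC-glasso literature; the Ising-side γ = 0.25 is not
carried over).  Edges are partial correlations −θ_ij/√(θ_iiθ_jj).
Indefinite polychoric matrices are repaired by eigenvalue clipping and
diagonal renormalization.

## Synthetic data generator

The generator defines the study conditions for all tests.
`make_paper_like_network()` plants a 14-item network over the standard
item codes with: a worthlessness hub whose strongest edge is to
hopelessness (2.2), plus self-blame (0.9) and guilt (0.8); weak probe
edges to the positive-affect items (0.3–0.45, one absent); a
positive-affect triangle LS–LE–NI; a bridge NI–HL; and weakly attached
remaining items (0.3–0.6).  Magnitudes span 0.3–2.2 so recovery tests
exercise weak and strong edges alike.  Thresholds are calibrated by a
fixed-point iteration against the enumerated marginals so endorsement
frequencies span ≈0.05–0.5, the realistic range for these items.  The
planted contrast is Σw_RLH = 3.9, Σw_RPA = 0.75, Δ = 3.15.

Sampling is exact for p ≤ 16 (enumeration of all 2^p states) and by
vectorized Gibbs otherwise: independent chains per subject, 1,000
burn-in sweeps by default, thinning 10 when chains are shared
(`GibbsConfig`).  The ordinal generator thresholds a latent multivariate
normal whose correlation is built from the planted edge pattern (scaled
to max 0.45, eigenvalue-clipped to positive definite); each item's
category-2/3 cutpoint is placed at its target endorsement.

What the generator does **not** emulate: item-level measurement error
beyond the model, acquiescence/response styles, longitudinal or cohort
drift, demographic covariates, and missingness (absent by design — the
data model assumes complete responses, and missing values are a hard
error, not imputed).  Passing tests therefore certify the estimator and
inference machinery under the assumed data model, not robustness to
violations of it.

## Numerical choices

- Node-wise solver: glmnet-style coordinate descent on the IRLS
  surrogate, numba-compiled, warm-started along the descending path;
  step tolerance 1e−6 (configurable), IRLS weights floored at 1e−5,
  probabilities clipped at 1e−9.  On small instances the solution
  matches an independent L-BFGS-B solver (positive/negative-part
  splitting) to < 1e−5 in objective.
- Rows are compressed to unique 0/1 patterns with frequency counts
  before solving (bit-packing into 64-bit keys), making fit cost depend
  on the pattern count, not n; results are identical to fitting raw rows.
- The grid top is λ_max·(1+1e−6): the exact boundary is a KKT knife-edge
  where round-off can admit a ~1e−16 coefficient, which would deny EBIC
  a true null candidate.
- Bootstrap resampling draws per-subject multiplicities
  ~ Multinomial(n, 1/n) — exactly n draws with replacement, aggregated —
  then re-weights the compressed patterns.
- Degenerate (constant) response columns yield the null fit with the
  intercept capped at ±30 and a `DegenerateNodeWarning`; inside
  bootstrap/permutation loops the node is silently isolated and counted.
- Graphical-lasso fits use scikit-learn (tol 1e−6, 500 iterations);
  solutions satisfy the penalized log-det KKT conditions within 1e−4.
  Penalties where the solver fails are skipped on the EBIC path.
- Spring layouts use Fruchterman–Reingold with |weight| attraction on
  the element-wise mean weight matrix of the networks being compared,
  with a fixed seed, so paired plots share coordinates.

## Test-suite problem sizes

Simulations are sized to keep the suite quick while leaving the
acceptance thresholds untouched: parameter recovery runs 10 seeds at
n = 20,000; the planted-direction bootstrap uses n = 20,000 with
n_boot = 500; CI coverage uses 100 replicates of the 7-item planted
subnetwork at n = 2,000 with n_boot = 200 against the enumerated-truth
Δ; permutation-null calibration uses 100 replicates (600 + 600 split,
60 permutations) and the single-edge power check 20 replicates
(n = 1,500 per group, 500 permutations — with 21 edges under Holm
correction, at least 420 permutations are needed for p < 0.05 to be
attainable at all).

## Limitations

- The AND/OR combination choice can flip borderline edges; only the
  default (AND) is exercised by the recovery tests.  Concretely, the
  planted ST–HL edge (0.5, attached to the rarest item, with a collinear
  stronger neighbor) is dropped by per-node EBIC in roughly one seed in
  ten at n = 20,000, so perfect recall of threshold-strength edges on
  rare items is not guaranteed and the corresponding recovery test can
  fail for such seeds.
- EBIC selection is per node; no joint pseudo-likelihood estimation and
  no cross-validated penalty selection are provided.
- The polychoric estimator is two-step (thresholds then pairwise ρ), not
  full ML, and is quadratic in item count with a numerical bivariate-CDF
  inner loop — fine for tens of items, slow beyond.
- Percentile intervals may exclude the point estimate in pathological
  bootstrap distributions; both the observed value and the interval are
  always reported.
- Centrality indices and their stability analyses are out of scope.
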