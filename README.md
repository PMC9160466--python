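# symptomnet

Regularized symptom-network analysis for item-level questionnaire data,
built around one concrete psychopathology question: is a probe symptom
(feelings of **worthlessness**, `WL`) more strongly tied to the
*revised-learned-helplessness* symptoms — self-blame (`SB`), hopelessness
(`HL`), guilt (`GU`) — or to the *reduced-positive-affect* symptoms — loss
of sexual interest (`LS`), low energy (`LE`), loss of interest (`NI`)?

The package is aimed at researchers analysing 5-point symptom-checklist
data (the 13 depression-subscale items plus guilt), but every stage is
generic: any binary/ordinal item set and any probe/cluster specification
can be plugged in.

## What it computes

1. **Ising network estimation (eLasso).** Likert scores are binarized at
   the moderate-distress boundary (1–2 → 0, 3–5 → 1) and a sparse pairwise
   Ising network is estimated by node-wise ℓ1-regularized logistic
   regression: each item is regressed on all others over a grid of 100
   penalties, the per-node penalty is chosen by the Extended Bayesian
   Information Criterion

   EBIC(λ) = −2·ℓ(β̂λ) + k·log n + 2γ·k·log(p−1),  γ = 0.25,

   and directed coefficients are symmetrized with the AND rule (mean of
   the two coefficients when both are nonzero).

2. **Contrast statistic with percentile bootstrap.** The primary quantity

   Σw_RLH = w_WL−SB + w_WL−HL + w_WL−GU,
   Σw_RPA = w_WL−LS + w_WL−LE + w_WL−NI,
   Δ_RLH−RPA = Σw_RLH − Σw_RPA,

   with 97.5%-width percentile bootstrap confidence limits obtained by
   re-estimating the whole network on case resamples, plus
   Bonferroni-corrected (α = 0.05/18) pairwise edge-difference tests for
   the nine RLH/RPA edge pairs.

3. **Permutation network comparison.** For two samples: group labels are
   permuted, both networks re-estimated each time, and p-values computed
   for structure invariance (max absolute edge difference M), global
   strength (sum of absolute edge weights S), and every individual edge
   (Holm–Bonferroni corrected).

4. **Ordinal GGM replication.** The same contrast on the raw 1–5 scores
   via EBIC graphical lasso partial-correlation networks (Pearson,
   Spearman or polychoric input correlations).

5. **Synthetic data.** A planted 14-item network with a worthlessness hub
   (exact and Gibbs Ising samplers, plus a thresholded latent-Gaussian
   ordinal generator) so the entire pipeline runs and is testable without
   any external data.

## Worked example

```python
import symptomnet as sn
from symptomnet.inference import BootstrapConfig, run_primary_hypothesis

net = sn.make_paper_like_network()          # planted 14-item fixture
data = sn.sample_ising(net, 5000, seed=42)  # binary symptom indicators
result = run_primary_hypothesis(data, boot=BootstrapConfig(n_boot=1000, seed=42))
print(result.to_frame().head(9).round(2).to_string(index=False))
```

prints

```text
quantity  description  observed  ci_lower  ci_upper  significant
   delta    RLH - RPA      2.93      2.40      3.40         True
 sum_rlh Edge Sum RLH      3.53      3.02      3.81         True
 sum_rpa Edge Sum RPA      0.60      0.25      0.80         True
 w_WL-SB      RLH: SB      0.82      0.56      0.99         True
 w_WL-HL      RLH: HL      2.07      1.84      2.23         True
 w_WL-GU      RLH: GU      0.64      0.33      0.82         True
 w_WL-LS      RPA: LS      0.00      0.00      0.00        False
 w_WL-LE      RPA: LE      0.27      0.00      0.43        False
 w_WL-NI      RPA: NI      0.34      0.02      0.51         True
```

The fixture plants Σw_RLH = 3.9 and Σw_RPA = 0.75 (Δ = 3.15); at
n = 5,000 the pipeline estimates Δ = 2.93 with a bootstrap interval
(2.40, 3.40) that excludes zero — the planted helplessness-dominant
direction is recovered, with the mild downward pull of ℓ1 shrinkage.
The nine remaining rows of `result.to_frame()` hold the pairwise
edge-difference tests.

A command-line layer wraps the same stages:

```sh
symptomnet simulate -n 2000 --seed 7 -o data.csv
symptomnet estimate data.csv -o network.json
symptomnet contrast data.csv --n-boot 10000 -o table.csv
symptomnet compare data1.csv data2.csv -o nct.json
symptomnet report config.yaml       # full pipeline from YAML
```

## Layout

```text
src/symptomnet/
  synthetic.py      planted networks, Ising + latent-Gaussian samplers
  preprocessing.py  item catalog, selection, binarization, endorsement
  elasso.py         node-wise L1 logistic paths, EBIC, edge combination
  _solver.py        numba coordinate-descent path solver
  inference.py      contrast statistic, bootstrap, percentile CIs
  nct.py            permutation comparison, Holm adjustment
  ggm.py            correlations, EBIC graphical lasso, ordinal contrast
  reporting.py      pipeline, spring layout, plots, provenance stamps
  cli.py            command-line verbs
docs/methods.md     model, assumptions, defaults, numerical choices
```
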