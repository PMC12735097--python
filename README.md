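# echinomet

Chemometric discrimination of sea-urchin gonadal metabolomes from 1D ¹H
HR-MAS NMR spectra.

Two Mediterranean sea urchins, *Arbacia lixula* and *Paracentrotus lividus*,
carry distinct gonadal metabolic fingerprints: osmolytes and methylated
amines (betaine, taurine, sarcosine, TMA, TMAO), organic acids
(malonate, methylmalonate) and nucleoside derivatives in *A. lixula* versus
amino acids (lysine, glycine, glutamine) and methylotrophy-linked compounds
(formaldehyde, methanol, 3-CPTMA) in *P. lividus*.  `echinomet` is a tested,
reusable implementation of the complete discrimination workflow for studies
of this kind, exercised end-to-end on a synthetic spectrum generator with
known ground truth:

1. **Synthetic cohorts** — two-class 1D NMR-like spectra with Lorentzian
   lines, biological variability, noise, baseline and chemical-shift jitter,
   with species effects injected as symmetric log2 fold-changes.
2. **Preprocessing** — uniform ppm binning (trapezoidal integrals over
   half-open `[hi, lo)` buckets), water/TSP exclusion, total-area
   normalization, mean centering / Pareto / auto scaling.
3. **PLS-LDA** — NIPALS PLS1 on the +1/−1 class vector, `X = T·P′`,
   `y = T·r′`, with a pooled-covariance LDA rule in score space
   (`c₁·LV1 + c₂·LV2 + c₀ = 0` boundary), Wold VIP scores
   (`Σⱼ VIPⱼ² = p`), target-projection loadings, stratified repeated
   cross-validation (error, sensitivity, specificity, midrank ROC AUC),
   label-permutation testing and 95% χ² score ellipses.
4. **Subwindow Permutation Analysis (SPA)** — N Monte-Carlo PLS-LDA
   sub-models on random sample/variable subsets (Q = 15, K = 3,
   ratio = 0.7, N = 1000, Pareto scaling); per-variable normal vs permuted
   prediction errors; DMEAN/DSD; one-sided rank-sum p-values and
   `COSS = −log₁₀ p` with selection at COSS > 2 (p < 0.01).
5. **Targeted univariate analysis** — metabolite-window integration, Tukey
   boxplot statistics, two-sided Mann–Whitney tests with BH adjustment.
6. **Pathway over-representation** — KEGG-style name mapping, hypergeometric
   tails with Holm/FDR adjustment, relative-betweenness pathway impact, and
   bubble-plot exports, against a packaged synthetic pathway library.

## Worked example

```sh
echinomet run-all --seed 1 --outdir demo_run
echinomet report --outdir demo_run
```

prints (output of the code, seed 1):

```
PLS-LDA (A=3): R2X=0.915 R2Y=0.995 | CV error=0.000 sens=1.00 spec=1.00 AUC=1.00 | perm p=0.0050
```

meaning the three latent variables capture 91.5% of the spectral variance
and 99.5% of the class variance, stratified 5-fold cross-validation
(repeated 20×) classifies every held-out sample correctly (error 0,
sensitivity and specificity 1.00, AUC 1.00), and no label permutation out of
199 reached the observed AUC (p = 1/200).  The run directory contains
plain-text exports sufficient to redraw all standard figures: `scores.csv`
(LV scores with the discriminant boundary coefficients c₀, c₁, c₂),
`model.json` (R², CV metrics, 95% ellipses), `vip_tploadings.csv`,
`spa_coss.csv` / `spa_selected.csv` (56/965 bins selected at COSS > 2 on
this run, headed by the injected discriminant resonances at their
Monte-Carlo ceiling COSS ≈ 3.0004), `metabolite_stats.csv` (all 17 injected
metabolites at raw p < 0.01, e.g. betaine median 0.135 vs 0.043,
p = 3.7 × 10⁻⁵, direction A_lixula↑), and `ora_*.csv` / `bubble_*.csv`
(for the *A. lixula* panel the top bubble is glycine/serine–threonine
metabolism with 3 of 34 compounds hit — betaine, sarcosine, glycine).

The same functionality is available as a library:

```python
from echinomet import (CohortConfig, simulate_cohort, bin_spectra,
                       normalize_total_area, cross_validate)

spectra, truth = simulate_cohort(CohortConfig(seed=1))
fm = normalize_total_area(bin_spectra(spectra, 0.01, labels=truth.labels))
cv = cross_validate(fm, A=3, folds=5, repeats=20, seed=1)
print(cv.error, cv.auc)   # 0.0 1.0
```

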