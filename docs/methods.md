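# Methods

## The discrimination problem

Given 1D ¹H NMR spectra of gonadal tissue from two sea-urchin species, the
workflow asks three questions: (i) can the species be separated from the
spectral fingerprint alone, and how reliably (PLS-LDA with cross-validation
and permutation testing); (ii) which spectral variables drive the
separation (VIP, target-projection loadings, Subwindow Permutation
Analysis); and (iii) what biochemical context do the discriminant
metabolites map onto (univariate confirmation and pathway
over-representation with topology impact).  Because raw spectra from such
studies are rarely deposited, the package ships a synthetic-spectrum
generator with known ground truth; every claim the test suite makes is a
claim about this generator's cohorts, not about any measured dataset.

## Synthetic cohorts

Each metabolite is a template of 1–3 Lorentzian lines (center ppm, relative
area summing to 1, FWHM; default width 0.003 ppm, broad fatty-acid envelope
0.03–0.045 ppm).  The packaged chemical-shift table
(`data/chemical_shifts.tsv`) holds 22 metabolites: 11 biased toward
*A. lixula*, 6 toward *P. lividus*, 5 shared.  Shift values are
literature-style reference positions (e.g. betaine N(CH₃)₃ near 3.26 ppm)
chosen so that, at 0.05-ppm bucketing, no bucket mixes peaks of opposite
species bias; they are configuration data, not measured values.

A cohort of `2·n_per_class` spectra (default 12 + 12) is rendered on a
descending 0–10 ppm axis (16384 points).  Per sample and metabolite the
concentration is `2^(±log2_effect/2) · LogNormal(cv)`: biased metabolites
are scaled symmetrically in log space so the class geometric means straddle
the shared baseline of 1 and total-area normalization does not trivially
leak the class.  Defaults: `log2_effect = 2` (4-fold between classes — a
strong, clearly resolvable species difference), biological CV 0.15, additive
Gaussian noise sd 0.3 (sharp-line SNR of order 10²–10³, typical of CPMG
spectra), Chebyshev baseline of amplitude 0.5 shifted non-negative, and a
per-spectrum global shift jitter of sd 0.002 ppm.  Each rendered line is
renormalized by its trapezoidal area on the finite axis, so at zero
noise/baseline the spectrum's trapezoidal area equals the summed
concentrations exactly (the conservation invariant); the closed-form
Lorentzian interval integral is then accurate to the quadrature tolerance
rather than bit-exact.  Randomness uses one root seed with per-spectrum
substreams `default_rng([seed, i])`, making cohorts bit-reproducible.

What the generator does *not* emulate: multiplet fine structure and
J-coupling, peak-shape distortions, water/macromolecule residuals,
pH-dependent shift drift of individual metabolites, and correlated
(pathway-level) concentration changes.  Passing tests therefore demonstrate
correctness and calibration of the algorithms under idealized but
NMR-shaped data, not performance on real tissue spectra.

## Preprocessing

Bins are half-open intervals `[hi, lo)` descending from the axis maximum
(default width 0.01 ppm — the community-standard bucket — configurable);
a bin's value is the trapezoidal integral over the interval, computed from
the cumulative integral with edge interpolation, which makes binning linear
in the spectrum and exact for piecewise-linear signals.  Bins overlapping
the exclusion windows (4.7–5.0 ppm water, ±0.05 ppm TSP) are dropped whole.
Rows are normalized to unit total area (probabilistic quotient offered as an
option).  Column pretreatments: `centre` (x − mean), `pareto`
((x − mean)/√sd), `auto` ((x − mean)/sd), with sample (ddof = 1) standard
deviations; zero-variance columns get scale 1 and are flagged.  Stored
means/scales make every transform invertible and applicable to held-out
samples.

## PLS-LDA

NIPALS PLS1 with the class vector encoded +1/−1 and centered internally.
Per component: `w ∝ X′u`, `t = Xw`, loadings `p = X′t/(t′t)`,
y-loading `r = y′t/(t′t)`, deflation `X ← X − t p′`, `y ← y − t r`
(PLS1 convention).  Cumulative R²X/R²Y are residual-norm ratios and are
non-decreasing; scores are mutually orthogonal (asserted in tests).  The
regression vector `b = W(P′W)⁻¹ r` reproduces `ŷ = T r` and projects new
samples to scores.  The default model uses A = 3 latent variables and mean
centering.

The classifier is a two-class LDA with pooled covariance on the scores;
the decision value `c′t + c₀` is affine in the latent variables and its
zero set restricted to (LV1, LV2) is the plotted boundary.  A singular
pooled covariance is ridge-regularized by `1e-8 · trace/A` on the diagonal.
The intercept includes the empirical log-prior ratio (zero for balanced
cohorts).

Diagnostics: Wold VIP,
`VIPⱼ = √(p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ)` with `SSYₐ = rₐ²·tₐ′tₐ`,
so `Σ VIP² = p`; and Kvalheim-style target projection: `t_tp = X·b/‖b‖`,
`tpLoadings = X′t_tp/(t_tp′t_tp)`.

Validation: stratified K-fold cross-validation (default 5 folds, 20
repeats) with pretreatment re-estimated inside every training fold;
held-out decision values are pooled across repeats; error/sensitivity/
specificity use the sign rule (ties assigned to the negative class), and
AUC is the midrank (tie-aware trapezoidal) statistic.  The permutation test
recomputes the same single-repeat CV AUC for label permutations and reports
the add-one estimator `p = (1 + #{AUC_perm ≥ AUC_obs})/(n_perm + 1)`
(default n_perm = 199).  Confidence ellipses scale the score covariance by
the χ²₂ quantile (0.95 by default).

## Subwindow Permutation Analysis

Each of N Monte-Carlo iterations draws a stratified calibration set
(⌈ratio·n⌉ per class, without replacement, default ratio 0.7) and Q = 15
distinct variables, Pareto-scales on calibration statistics, picks the
latent-variable count in 1…min(Q, n_cal − K) by internal stratified K-fold
CV (K = 3, smallest-A tie-break; NIPALS truncates gracefully at vanishing
residuals), and records the held-out misclassification rate as the *normal*
error of each sampled variable.  Each variable's values are then permuted
across the held-out block only — the trained sub-model stays fixed — giving
its *permuted* error.  Per variable: DMEAN and DSD are the differences of
means and sds (permuted − normal); the p-value is a one-sided Mann–Whitney
test (permuted stochastically greater), exact by enumeration when both
error samples have ≤ 8 values and tie-corrected normal approximation with
continuity correction otherwise; `COSS = −log₁₀ p` with p floored at
1/(N+1) so the score is finite at the Monte-Carlo resolution.  Variables
never sampled into any sub-model are reported with p = 1, COSS = 0 and
flagged.  Selection takes COSS strictly greater than the threshold
(default 2, i.e. p < 0.01), sorted by descending COSS.

### Scaled study sizes

The full-scale design (N = 1000 iterations over ~965 bins of 0.01 ppm)
runs in ~10 s and selects all seven headline metabolites — betaine,
sarcosine, glycine, malonate, taurine, formaldehyde, lysine — at the COSS
ceiling.  The repeated calibration/power experiments in the test suite use
a scaled design chosen to preserve the two quantities that govern SPA
behaviour rather than naively shrinking N: the expected number of error
samples per variable (N·Q/bins ≈ 15) and the density of informative
variables (≈ 3%).  Density matters because SPA is conditional: when a
sub-model contains two or more variables that each separate the classes
alone, permuting one leaves predictions intact, so informative variables
mask each other and COSS collapses at high density.  The scaled design is
therefore N = 200 with 0.05-ppm bins (~192 of them) on a reduced-panel
cohort (`spa_benchmark_library()`) in which exactly the seven headline
metabolites are biased, one line each, at the default effect size.  Under
that design all injected bins clear COSS > 2 in ≥ 90% of seeded runs and
the shuffled-label false-positive rate stays within the nominal 1% plus
Monte-Carlo slack.

## Targeted univariate analysis

Metabolite windows (main resonance ± 0.02 ppm) are integrated on
total-area-normalized spectra.  Group summaries follow the Tukey boxplot
convention with linear-interpolation quartiles; whiskers sit on the most
extreme points within 1.5·IQR.  Between-species tests are two-sided
Mann–Whitney (exact for groups ≤ 8), with Benjamini–Hochberg adjusted
p-values reported alongside the raw ones — the headline calls on strong
effects are unchanged, but the adjusted column is the honest default for
larger panels.  The direction label follows the sign of the median
difference.

## Pathway over-representation

Compound names map to KEGG-style identifiers through a packaged,
case-insensitive synonym table; unmapped names are returned, never silently
dropped.  The universe is all compounds of the loaded library (an external
reference universe would not be reproducible offline), the query is
restricted to it with a logged discard count, and each pathway's raw p is
the hypergeometric tail `P(X ≥ k)`; Holm and BH-FDR are computed across
tested pathways; zero-hit pathways report p = 1.  Impact is
relative-betweenness: node betweenness normalized by the pathway maximum,
hit share of the total; graphs with no positive betweenness give 0.

The packaged library (`data/pathways.json`) is a synthetic KEGG-modelled
fixture: 14 pathways with study-typical names and sizes (glycine/serine/
threonine 34, one-carbon pool by folate 26, taurine/hypotaurine 8,
glyoxylate/dicarboxylate 32, nitrogen 6, …), real KEGG identifiers for the
core members that anchor the expected hit patterns, synthetic filler
compounds for the remainder, and deterministic chain-plus-hub graphs.
Because the universe and graphs are fixture-defined, p-values, FDR and
impact magnitudes are internally consistent but not comparable to any
specific KEGG release; hit counts and hit identities are the meaningful
outputs.  The curated species panels include glycine in both lists — it
separates the species univariately (higher in *P. lividus*) yet belongs to
the discriminant context of both panels' pathway queries.

## Pipeline and reproducibility

`run_pipeline` chains simulate → preprocess → fit → SPA → integrate →
pathway; every stage writes plain-text CSV/JSON exports sufficient to
regenerate the standard figures without recomputation, plus a manifest with
the verbatim configuration, package version, seed and per-file SHA-256
checksums (no timestamps, so identical configurations give byte-identical
manifests).  Stages toggled off consume cached outputs or fail with a
stage-tagged missing-input error.  A `--threads` flag is accepted for
interface stability; all stages are single-threaded.

## Numerical choices and limitations

- Sample standard deviations (ddof = 1) everywhere; linear-interpolation
  quantiles; midrank tie handling in every rank statistic.
- Sign-rule class assignment sends a zero decision value to the −1 class;
  `select_variables` uses strict inequality, so COSS exactly at the
  threshold is excluded.
- The NIPALS inner iteration converges in one pass for a single y but is
  kept as a loop with a tolerance for clarity and future multi-y use.
- LDA regularization, the COSS floor and the `strict=False` NIPALS
  truncation are the three deliberate degenerate-input escapes; all are
  exercised in tests.
- Known limitations: no peak alignment beyond an optional global
  cross-correlation shift; no multiplet simulation; the pathway fixture is
  not a KEGG snapshot; SPA results at small N depend on the
  informative-density regime documented above.
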