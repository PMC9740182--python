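# Methods

`hairdyn` implements an end-to-end analysis of elemental dynamics in single
hair strands: a synthetic cohort generator emulating laser-ablation ICP-MS
strand profiles, recurrence-based feature engineering, a feature-wide
association scan against diagnosis, and a gradient-boosted diagnostic
classifier. This note records the models, the defaults and why they were
chosen, and what the synthetic data can and cannot establish.

## The measurement model the generator emulates

A strand is scanned along ~10 mm of growth (about one month), producing 660
sampling points per channel — one point per ≈1.1 h of growth — across 15
element channels plus sulfur. Each element channel is generated as

    I_e(t) = B_e · [1 + a_slow sin(2π t / P_slow + φ_slow) + δ_e (t/N − ½)]
                 · [1 + A_e sin(2π t / P_e + φ_e + W(t))
                      + 0.3 A_e sin(2π t / P'_e + φ'_e + W(t))]_+
                 · exp(σ ε_t) · b_{site,e}

with

* `B_e` — baseline level (element-specific scale × lognormal subject factor);
* a slow sinusoidal modulation (`a_slow = 0.1`, period 200–400 samples) and a
  monotone drift `δ_e` (|δ| ∈ [0.1, 0.3], random sign) representing gradual
  dietary/seasonal level shifts across the month;
* one or two circadian-like components with per-sample periods `P_e, P'_e ~
  U(18, 26)` — a 24 h cycle at the ≈1.1 h/sample grid — amplitudes `A_e ~
  U(0.3, 0.5)`, and a shared phase random walk `W(t)` with diffusion 0.05
  rad/√sample (circadian phase jitter);
* multiplicative lognormal measurement noise with `σ = noise_sd` (default
  0.008) and a per-site, per-element batch factor `b_{site,e} =
  exp(N(0, batch_shift_sd))`, default scale 0.15.

Sulfur is generated similarly but without a fast periodic component and with
half the noise scale; it is strictly positive. The **case effect** multiplies
the periodic amplitudes of the perturbed elements (default Zn, Cu, Li) by
`1 − effect_size`; mean levels are untouched, so any downstream separation
reflects dynamics, not concentration.

Two defaults deserve explanation. First, the circadian period is expressed
on the sampling grid (18–26 samples) because only per-sample periods matter
downstream; the grid itself (≈1.1 h/point) is fixed by 10 mm ≈ 1 month ≈ 660
points. Second, `noise_sd = 0.008` was calibrated once against the
replicate-strand QA contract: duplicate strands from one subject share the
entire latent process (baselines, periods, phases, phase walk, drift, batch
factors) and differ only in redrawn noise, and the default noise scale is
the level at which ≥90% of RQA/CRQA features reproduce within ±10% between
duplicates — the reproducibility level this kind of assay is expected to
reach. The line-based extreme-value statistics (`l_max`, `div`, `trend`) are
the binding constraint: they respond discontinuously to single recurrence
cells flipping, so their replicate agreement decays quickly with noise no
matter how much of the process is latent-shared.

Sex and age are generated independently of diagnosis (ages follow three
site profiles emulating an infant cohort, an adolescent twin cohort, and a
mixed-age clinic sample); `age_case_shift` can introduce confounding to
exercise the covariate adjustment.

### What the generator does not emulate

No laser-ablation physics, washout/contamination, spike artifacts, or
isotope interference; no twin-pair dependence; no heavy-tailed count noise.
Passing tests on this synthetic cohort show that the *pipeline* recovers
the kind of signal the analysis posits (attenuated periodicity) at
realistic sampling geometry — not that real hair data contain that signal.

## Preprocessing

Each element trace is divided point-wise by sulfur, cancelling ablated-mass
variation; the ratio is invariant under common rescaling of the raw counts.
Points with non-positive sulfur or non-finite channels are deleted listwise
on a common per-subject index (recurrence analysis needs one even grid for
all channels of a subject; interpolation would fabricate dynamics). Strands
losing more than 10% of points are rejected as unusable. No smoothing or
detrending is applied before embedding: recurrence quantification tolerates
non-stationarity, and the trend metric deliberately measures it.

## Delay embedding

State vectors are `(x_t, x_{t+τ}, …, x_{t+(m−1)τ})`.

**Delay τ** is the first local minimum of the average mutual information
AMI(τ), falling back to the scanned argmin when no interior minimum exists.
The AMI estimator is a Gaussian-copula estimate: the series is transformed
to normal scores once and AMI(τ) = −½·log(1 − ρ²(τ)) with ρ the correlation
of the scored series against its lag. This estimator was chosen over the
classic equal-width 2-D histogram because the histogram estimate fluctuates
with τ-parity on near-periodic signals (the joint support is a closed curve
whose cell occupancy beats against the bin grid), which corrupts the
first-minimum rule: on a noiseless sine of period 40 the histogram AMI has
spurious minima at τ = 6–8 for any bin count between 8 and 24, while the
copula estimate attains its first minimum exactly at the quarter period
(τ = 10), the canonical delay for an oscillatory signal. The copula AMI is
also exactly invariant under monotone transforms of the series. The
histogram estimator remains available (`estimator="histogram"`,
⌈√(n/5)⌉ bins capped at 64).

**Dimension m** uses Kennel's false-nearest-neighbor criterion with the
canonical thresholds rtol = 10, atol = 2, acceptance fraction 0.05, and
max_m = 10 (returned with a warning flag when the fraction never falls
below threshold — typical for pure noise). Pairs whose m-dimensional
nearest-neighbor distance is below ~machine precision (10⁻⁸ of the series
SD) are judged by the absolute criterion alone: periodic signals revisit
states exactly, and the stretch ratio 0/0 is meaningless there.

Parameters are estimated independently per series (each element of each
subject), and recorded in the provenance table.

## Recurrence matrices at a fixed recurrence rate

Distances are Euclidean. The threshold ε is not free: per matrix, it is set
to the 10% quantile of the included pairwise distances, so every matrix has
recurrence rate 0.10 (±0.005 discreteness) and recurrence structure is
comparable across subjects and elements. For auto-recurrence a Theiler
window of 1 removes exactly the line of identity from both the calibration
and the matrix (cells with |i−j| < w are excluded); cross-recurrence uses
no exclusion, since no diagonal is privileged, which also makes
`cross(x, x)` identical to the window-0 auto matrix. For a pair of series,
each keeps its own delay and both are re-embedded at m = max(m_a, m_b), the
minimal common phase space.

## The 12 features

From exhaustive diagonal/vertical line-length histograms (lmin = vmin = 2):
RR, DET, L (mean diagonal length), Lmax, DIV = 1/Lmax, ENTR (Shannon
entropy of diagonal lengths, nats), LAM, TT, Vmax, VENTR, DET/RR, and
TREND — the least-squares slope of diagonal-wise recurrence density over
displacement, computed over diagonals with ≥10 cells to stabilize the fit.
Degenerate matrices yield defined zeros, not errors. A 15-element panel
yields 15 auto + 105 cross matrices per subject — 1,440 features, each
tagged with its pathway (element or element pair) and metric.

## Association scan

Features are batch-corrected by within-batch location–scale standardization
followed by global re-z-scoring (a transparent estimator adequate at
synthetic scale; an empirical-Bayes variant could be slotted in), with
features constant within a batch set missing rather than infinite. Each
feature is tested in a logistic regression of diagnosis on feature + sex +
age (Wald test), the natural reading of a "discrete" generalized linear
model for a binary diagnosis. Benjamini–Hochberg FDR is applied across all
cleanly fitted features; separated fits are flagged and excluded from the
FDR family. Subjects are treated as independent (no twin-pair random
effects). Significance means q < 0.05.

## Diagnostic classifier

Subjects are split 80/20 by simple (non-stratified) random assignment with
round-half-up training size — splitting 486 subjects gives 389/97. Feature
screening is a transparent rule: top-k (default 64) features by
training-set-only association q-value; the holdout is hashed before
training and verified untouched at evaluation. XGBoost hyperparameters
(learning rate, depth, subsample, column subsample, min child weight,
boosting rounds) are tuned by maximizing 5-fold cross-validated AUC under a
surrogate-guided search: an initial random design, then iterative
expected-improvement proposals from a random-forest surrogate over a
candidate pool — a desk-scale model-based-optimization loop, default budget
50 evaluations (1000 with `--paper-budget`). The best configuration is
refit on the full training set.

Holdout evaluation sweeps all score thresholds; the operating point
maximizes Youden's J = sensitivity + specificity − 1, ties resolved to the
lowest qualifying threshold (favoring sensitivity, the right bias for a
screening aid). Sensitivity, specificity and accuracy carry Clopper–Pearson
95% intervals. Stratified performance (e.g., by sex) reports per-stratum
AUC and a two-sided p-value for stratum-vs-overall equality using a
delete-one-subject jackknife variance of the AUC difference on the shared
scores (an influence-function estimate of the DeLong type; it degenerates
correctly to p = 1 when the stratum is the whole sample).

As a documented illustration only: if a positive call required three
concordant positive strands analyzed in tandem, the positive predictive
value at prevalence π would be PPV₃ = π·sens³ / (π·sens³ + (1−π)(1−spec)³)
— with 96.4% sensitivity and 75.4% specificity at 28% prevalence this is
≈94%. The package does not implement multi-strand ensembling.

## Numerical and scale choices

* Line lengths are extracted by shearing the matrix so diagonals become
  columns, then one vectorized run-length pass; verified exactly against a
  cell-walking enumerator on random matrices.
* ε is the k-th smallest included distance, k = ⌊target·N⌋, so the achieved
  rate equals the target up to ties.
* Desk-scale problem sizes used by the test-suite checks: null calibration
  on 200 subjects × 540 features (9-element panel); signal recovery on 400
  subjects × 180 features (5-element panel, screening k = 48, tuning budget
  8); effect-size monotonicity on 10 replicate cohorts of 40 subjects ×
  3 elements per effect size. These sizes keep every check honest (fresh
  cohorts, full pipeline) while remaining runnable on a laptop.
* All randomness flows from explicit integer seeds; the pipeline fans a
  master seed out per stage through `SeedSequence(master, spawn_key)` so
  stages are independently reproducible.

## Known limitations

Histogram-free AMI assumes a monotone dependence structure is informative
for delay choice; strongly bimodal joint dependence could favor the
histogram estimator. The batch correction is location–scale only. The FNN
warning path (pure noise) silently embeds at max_m, which is conservative
but slow. Twin dependence, missing-at-random dropouts beyond listwise
deletion, and count-valued noise are not modeled. The classifier's feature
screening uses marginal association only; interactions enter only through
the trees.
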