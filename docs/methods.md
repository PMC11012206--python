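# Methods

## Generative model of the synthetic cohort

Each spectrum of a block (UV-Vis on 190–700 nm at 1 nm, 511 points; mid-IR
on 400–4000 cm⁻¹ at 10 cm⁻¹, 361 points) is

x_ij = a_i + c_i·t̃_j + b_i·Σ_k (A_k + δ_{k,c(i)} + η_{ik})·G_k(t_j) + ε_ij

with Gaussian peak shapes G_k(t) = exp(−(t − μ_k)²/2w_k²), axis t̃ rescaled
to [0, 1], and per-sample artefacts: multiplicative gain
b_i = exp(N(0, scatter_sigma²)) (log-normal, so gains are positive),
additive offset a_i ~ N(0, offset_sigma²), linear baseline slope
c_i ~ N(0, slope_sigma²); per-sample-per-peak amplitude jitter
η ~ N(0, amp_jitter_sigma²) and white noise ε ~ N(0, noise_sigma²). This is
deliberately the minimal model under which SNV and MSC are exactly the
right corrections — an affine distortion of a common shape — so
preprocessing behaviour is analytically checkable: with all sigmas zero,
between-class differences equal the offset-weighted peak shapes in closed
form, and the test suite asserts exactly that.

Defaults (absorbance units unless noted): scatter_sigma 0.10 (log-gain sd,
i.e. gains typically ±10%), offset_sigma 0.08, slope_sigma 0.02,
amp_jitter_sigma 0.02, noise_sigma 0.01 — artefact levels of a careful
laboratory acquisition, large enough that raw spectra overlap visibly
between classes yet small enough that scatter correction restores a
separable geometry. Peak centres sit in the regions
where garlic spectra show origin-dependent bands: UV 215/250/280 nm, MIR
1080/1260/1450/2900/3400 cm⁻¹, with widths of roughly the visual width of
such bands (10–14 nm; 50–150 cm⁻¹). The cohort is 225 samples over five
origin classes sized 45/46/48/44/42.

### Split-signal class coding

Class effects are one-hot at the group level: the UV block separates the
coarse grouping {shandong, yunnan} | {anhui, henan} | {jiangsu} (peaks at
250 and 280 nm elevated by 0.5 for their own group), the MIR block the
complementary grouping {shandong, anhui, jiangsu} | {yunnan, henan} (1080
vs 2900 cm⁻¹). Each class has a unique (UV group, MIR group) pair, so the
fused blocks separate all five classes while either block alone has a hard
accuracy ceiling (≈ 60% for UV, ≈ 42% for MIR given class shares) — the
property the fusion experiment is designed to demonstrate. One-hot coding
(each group elevates its own peak) was chosen over graded amplitudes of a
shared peak: it mimics region-specific compounds being abundant at
distinct bands and gives every classifier family, including axis-aligned
tree ensembles, a clean decision geometry. The effect size of 0.5
absorbance on ~1.0 peaks makes the default cohort comfortably separable
after SNV; `zero_effect_config()` removes all class effects for
chance-level controls.

Randomness is organised as one seed per config; each block and each random
component (gain, offset, slope, jitter, noise) draws from its own spawned
sub-stream in a fixed order, so a block generated alone is bit-identical
to the same block from `generate_paired` and any component can be
regenerated independently.

### What the simulator does not emulate

Real garlic spectra have correlated, non-Gaussian band structure,
water-vapour and CO₂ artefacts, instrument line shapes, detector
nonlinearity, and between-batch drift; none are modelled. Passing tests
therefore show that the workflow recovers the signal structure it assumes
(affine scatter over class-coded peaks), not that it would reach the same
accuracies on real spectra.

## Preprocessing

- SNV uses the sample standard deviation (divisor p − 1), giving the exact
  [1,2,3] → [−1,0,1] identity; a `ddof` switch restores the population
  convention.
- MSC regresses each spectrum on a reference by OLS and corrects to
  (x − a)/b. The reference defaults to the column mean of the TRAINING
  partition and is then frozen for test-set correction — computing it from
  all samples would leak test information into a fitted statistic.
- SG smoothing is scipy's polynomial filter (derivative order 0) with
  mirror padding (reflection without repeating the edge point), window 11
  and order 2 by default — common chemometric practice; the interpolating
  case (order = window − 1) is the identity and order-1/window-3 equals a
  3-point moving mean, both asserted in tests.
- Preprocessing is applied per block before fusion; SNV places every
  spectrum of every block on a common per-row scale, so no extra block
  weighting is applied at fusion (an autoscale flag exists for non-SNV
  workflows).

## GA wavelength selection

Individuals are binary masks; fitness is mean stratified k-fold CV
accuracy of a base classifier on the masked training columns minus
λ·(selected fraction). Training data only: selecting wavelengths on
held-out data would inflate test accuracy. Defaults: population 50, 100
generations, uniform crossover 0.8, per-bit mutation 1/p, tournament 3,
elitism 1, init density 0.3, λ = 0.01, 5-fold CV with a 100-tree random
forest, patience 20. Ties break toward smaller masks, then lexicographic
bit order, making runs exactly reproducible from the seed. All-zero masks
are repaired by setting one uniformly random bit. For end-to-end runs a
reduced budget (population 30, ≤ 40 generations, 3-fold CV, 50-tree
forest) gives the same selections at a few minutes per run on one CPU;
fitness values are cached per mask. The recovery diagnostics use sparse
initialisation (init density 0.05): when masks carry few columns, fitness
is sensitive to how many informative columns each mask holds, which is the
per-column signal a selection-frequency enrichment check measures.

## Classifiers

Hyperparameter defaults, all configurable: SVC with RBF kernel, C = 10,
γ = 1/(p·Var(X)); random forest with 500 trees and √p candidate features
per split; one-hidden-layer (100 ReLU units) network trained up to 1000
iterations without early stopping; gradient-boosted trees with 300 rounds,
depth 6, learning rate 0.1, row subsampling 0.8 and column subsampling 0.5
per tree. The boosting subsampling is deliberate: on row-normalised (SNV)
spectra, any residual per-sample scale distortion (e.g. from the baseline
slope, which SNV does not remove) shifts a whole row across the fixed
thresholds a deterministic boosted ensemble learns; stochastic boosting
decorrelates the trees and removes this failure mode, which we observed as
isolated, hyperparameter-insensitive test misclassifications. The
gradient-boosted family is an engine contract (any XGBoost-compatible
implementation); the split is stratified 70/30 with exact floor allocation
and remainders to the largest fractional parts.

## Pipeline and leakage discipline

One stratified split, derived from the global seed, is shared by all cells
of a comparison so models are judged on common footing. The split is
computed before any stateful preprocessing; MSC references, GA fitness and
classifier fitting see training rows only. A tainting test corrupts test
rows and asserts that every fitted artefact (mask, preprocessing state,
train-set predictions) is byte-identical. All sub-seeds (split, GA,
classifiers) derive from the global seed through CRC-tagged seed
sequences, so identical configs produce byte-identical result files.

## Evaluation conventions

Confusion rows are predicted classes and columns true classes — the
transpose of the common convention, kept because the workflow's reports
follow that layout; `evaluate` exposes the underlying matrix so either
orientation is one transpose away. Accuracy is 100·trace/n_test to two
decimals. Undefined precision/recall (a class never predicted or never
present) is NaN, never a silent 0 or 1.

## Problem sizes used in checks

End-to-end checks run the full 225-sample cohort. The fused-pipeline
headline check uses the reduced GA budget above; fusion-dominance
comparisons average 10 generator seeds without GA; GA-optimality checks
use p = 8 with exhaustive enumeration (255 masks) as the oracle; recovery
checks average 5 generator seeds. Contract tests (alignment, determinism,
validation) use a 40-sample cohort on coarse grids.

## Known limitations

- The GA's fitness is a noisy, expensive black box; with many redundant
  informative variables the per-variable selection signal is weak and
  selection frequencies approach the initialisation density unless masks
  are kept sparse.
- CV-fitness wavelength selection carries a selection bias: with hundreds
  of candidate variables and ~150 training spectra, variables whose chance
  correlation with the training labels improves the CV score survive in
  the mask, and the parsimony penalty (a small constant per variable)
  cannot outweigh them. Classifiers that average many decorrelated
  learners (forests, kernels over all variables) are insensitive to these
  survivors; greedy boosted trees occasionally follow them and lose a
  borderline test sample.
- The generator's artefact model is affine per spectrum; preprocessing
  comparisons on it cannot distinguish SNV from MSC (both are exact there).
- Single-block accuracy ceilings are by construction; they quantify the
  designed signal split, not any property of real UV/MIR garlic spectra.
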