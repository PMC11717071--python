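# Methods

`hypercal` implements a hyperspectral calibration pipeline for predicting
milk-powder protein content (g/100 g) from 400–1000 nm reflectance spectra:
reference correction, spectral preprocessing, wavelength selection by a
CARS→UVE cascade scored against PLS1, a whale-optimized BiLSTM-Attention
regressor, and the standard chemometric evaluation metrics. Because the
measured spectra behind the method are not public, the package ships a
synthetic generator that reproduces the study design and gives every
statistical claim in the test suite a known ground truth.

## Data model and synthetic spectra

A `SpectralDataset` holds an `n × p` reflectance matrix on a strictly
increasing wavelength grid, a reference analyte value per row, a brand label
and a unique id. The default synthetic design matches the study: 5 brands ×
20 samples × 8 regions of interest = 800 rows, 125 bands from 400 to 1000 nm,
brand protein values (19.0, 23.8, 28.0, 25.4, 20.2) g/100 g.

Each clean spectrum is

    scale_s · (base(λ) − Σ_j depth_j(a_s) · G_j(λ)) + drift_s(λ) + ε

* `base(λ)`: smooth sigmoidal reflectance rising from ≈0.58 to ≈0.90;
* `G_j`: Gaussian absorption profiles — broad pigment bands at 450/670 nm
  and four narrow overtone-like bands at 905/935/962/988 nm;
* `depth_j(a) = amp_j · (k_j · a/25 + (1 − k_j) · m_sj)`: only the NIR
  overtone bands couple to the analyte (`k_j = 1`), affinely, which is the
  physically expected location of protein N–H/C–H overtones; the visible
  pigment bands fluctuate per sample (`m_sj ~ 1 + N(0, 0.1)`) independently
  of protein, so a realistic fraction of the spectrum is genuinely
  uninformative and wavelength selection has something to discard;
* per-sample analyte jitter sd 0.1 g/100 g (within-brand variability around
  the single per-brand reference value), quadratic baseline drift with
  coefficient sd 0.01, multiplicative amplitude jitter sd 0.01, and i.i.d.
  per-ROI noise sd 0.005 — magnitudes chosen once as plausible for a
  push-broom system measuring a flattened powder surface.

What the generator does *not* emulate: scattering nonlinearity (multiplicative
effects enter only as a global scale), wavelength-dependent detector noise,
inter-brand matrix effects beyond protein, or acquisition replicates. The
analyte→spectrum map is affine, so passing tests demonstrate that the pipeline
recovers a recoverable signal under realistic nuisance structure — not that it
would master scattering-dominated real spectra. A separate sparse generator
(`generate_sparse_regression`, i.i.d. normal bands, unit-weight signal on a
known subset, SNR defined as a variance ratio) provides exact ground truth for
selection-recovery tests.

The 7:3 train/test split is stratified by brand by default (configurable),
with per-brand sizes rounded half-up: 112/48 per brand, 560/240 overall.

## Preprocessing

Reference correction is `(raw − dark)/(white − dark)` elementwise, with an
error (never silent clipping) if the denominator vanishes anywhere. The six
operators — mean centering (MC), standardization (SS), min–max scaling (MMS),
Savitzky–Golay smoothing (SG) and SG first/second derivatives (D1/D2) — act
per wavelength column (the chemometric convention) and compose into ordered
chains. Column statistics are learned from the calibration matrix only and
reused on test spectra. SG defaults to window 11, polynomial order 2 (common
near-infrared practice; the source settings are unstated) and derivatives use
the SG machinery by default so the band count is preserved; a finite-difference
mode (which shrinks the band axis) is available.

## PLS1 and RMSECV

PLS1 is fitted by NIPALS with deflation, retaining the whole coefficient path
`B_1..B_A`. Cross-validated RMSECV over component counts 1..A_max therefore
costs one fit per fold: each held-out block is predicted at every component
count from a single path. Folds are contiguous blocks of a seeded shuffle;
the RMSECV is a single RMSE over all n held-out predictions. Component counts
infeasible inside a small fold are reduced to the fold's maximum and logged.
A_max defaults to 10; the latent dimension is treated as a tuned nuisance
parameter (minimized over inside selection) since no value is given for it.

## Wavelength selection

**CARS.** N runs (default 50). Retention ratios follow the exponentially
decreasing schedule `r_i = (p/2)^((1−i)/(N−1))`, fixed so the first run keeps
all p bands and the last keeps 2. Per run: PLS is fitted on a Monte-Carlo row
subsample (ratio 0.8) restricted to the currently retained bands; the set is
truncated to the forced count by |coefficient| and then resampled by adaptive
reweighted sampling (weighted draw with replacement, unique survivors,
clamped at 2). When the forced count does not require shrinking, the
retention step is the identity — this makes the run-1 set exactly the full
spectrum. The 10-fold RMSECV of each run's retained set is recorded
(minimized over the component path) and the final selection is the
minimum-RMSECV run's set.

**UVE.** As many tiny-amplitude (1e-10 of the data scale) standard-normal
noise bands as real bands are appended. Coefficient *stability* — mean
divided by standard deviation across refits — is scale-invariant, so the tiny
amplitude leaves predictions untouched while the noise bands sample
chance-level stability. Refits use leave-one-out when n ≤ 200 and 10×
repeated 5-fold splits otherwise; the component count is fixed beforehand by
RMSECV on the real bands. The cutoff is `cutoff_factor` (default 1.0) times
the largest |noise stability|; real bands above it survive. A zero coefficient
spread across splits maps to signed-infinite stability (band retained, with a
warning).

**CU cascade.** UVE runs on the CARS-selected columns only; the result is
reported in original band coordinates and is a subset of the CARS set by
construction. On the synthetic defaults the cascade keeps ≈40–50 of 125
bands, concentrated in the analyte-coupled NIR region.

## BiLSTM-Attention regressor

The spectrum is treated as a sequence over wavelength (increasing order, one
reflectance value per step). Two stacked bidirectional LSTM layers
(per-direction hidden sizes `hidden1`, `hidden2`) produce per-step states; at
every step the two directions merge through `O_t = tanh(W_f h→_t + W_b h←_t +
b)`. Additive attention scores each merged state through a tanh projection of
width `attn_dim` and a scalar scoring vector; the softmax-normalized weights
pool the states into a context vector (a dot-product scoring variant sits
behind a config switch; attention consumes the post-merge states). A tanh
dense layer of width `dense` and a linear unit produce the scalar output.
Unidirectional and attention-free variants (the attention-free models use the
last merged step) support the model-comparison studies.

The implementation is NumPy with hand-written backpropagation; the recurrent
step loops are JIT-compiled with numba, and a vectorized NumPy reference path
remains in the module with a unit test pinning their equivalence. Finite
central differences validate the analytic gradients to better than 1e-4
relative. Optimization is Adam (default moments) on mean squared error over
seeded mini-batches; the forget-gate bias initializes at 1, other weights
Glorot-uniform from the config seed.

Two scalers are learned from the training data only and stored with the
model: targets are standardized to zero mean/unit sd (reported RMSEs on the
raw g/100 g scale unless tagged otherwise; the loss history is on the
standardized scale), and inputs are divided by one *global* scalar (the
training matrix's overall sd). The global factor conditions the optimization
— mean-centered reflectance has sd ≈0.02, small enough to stall training for
some initializations — while deliberately *not* equalizing columns, so the
differences between preprocessing variants feeding the network are preserved.
A NaN/inf training loss aborts with a diagnostic rather than continuing.

## Whale optimization

`woa_minimize` is a faithful whale-optimization loop over a bounded box:
convergence factor `a` linear from 2 to 0; per whale and iteration, random
`p ∈ [0,1]`, `l ∈ [−1,1]`, coefficient vectors `A = 2a·r₁ − a`, `C = 2r₂`;
encircling toward the best position when `p < 0.5, |A| < 1` (the vector norm
of A), random search toward a random whale when `|A| ≥ 1`, and the
logarithmic spiral `|X* − X|·e^{bl}·cos(2πl) + X*` otherwise. Positions clamp
to the box; the best-so-far is elitist, so the best-fitness curve is
non-increasing by construction. NaN fitness becomes +inf with a warning.

The hyperparameter harness searches lr (log10 scale, [1e-3, 1e-1] — the
linear published box excludes learning rates below 0.01 although smaller
values are routinely optimal, including the one ultimately reported),
num_epochs [10, 100], batch_size [16, 128], hidden1/hidden2 [1, 20], dense
[1, 100], and attention width [1, 50] (no published bound; removable).
Integer dimensions decode by round-half-up then clamp while whale motion
stays continuous. Every candidate trains from the same derived parameter
seed so fitness differences reflect hyperparameters rather than
initialization luck, and one whale warm-starts at the untuned default
configuration — the search can then only improve on the reference it is
compared against. The fitness is the validation MSE (standardized scale) on
a 20% holdout carved from the training set; the final model retrains on the
full training set with the best configuration.

## Evaluation

RC²/RMSEC (calibration) and RP²/RMSEP (prediction) follow the standard
definitions; RPD is computed as `1/√(1−RP²)`, which is algebraically
identical to `sd(y_test)/RMSEP` at full precision (recomputing it from
*rounded* printed R² values differs in the third decimal — reports therefore
carry the full-precision value, four significant figures, and a scale tag).
Percent-change comparisons between models use
`(value − reference)/reference × 100` (or its decrease form). Classical
baselines delegate to scikit-learn: PLSR with 3 components, PCA to 2 scores
feeding a PLSR, and RBF-kernel SVR.

## Problem sizes and reproducibility

All randomness flows from one master seed through named per-stage seeds; the
CLI writes a MANIFEST with the config hash and every seed, and deterministic
stages reproduce bit-for-bit. The end-to-end study used by the tests and the
acceptance script runs the full 800 × 125 design with a 6-whale × 5-iteration
search (36 trained candidates) — a deliberately small search that still
improves clearly on the untuned reference; the selection-recovery study uses
20 seeds of a 250 × 100 design with 5 informative bands at variance-SNR 20;
the optimizer benchmark uses 20 seeds of the 2-D sphere against an
equal-budget random-search oracle.

## Known limitations

* The synthetic analyte map is affine; nonlinear-regime advantages of the
  recurrent model over PLSR/SVR are not demonstrated here.
* CARS rarely improves RMSECV before UVE on the synthetic defaults (n ≫ p and
  smooth collinear bands make the full PLS model hard to beat), so the
  cascade's pruning is mostly UVE's; on the sparse recovery design CARS does
  the heavy lifting.
* The whale search is stochastic; only seeded runs are reproducible, and the
  36-candidate budget explores a 7-dimensional box coarsely.
* Absolute metric values depend on the synthetic noise scales and are not
  comparable to values measured on the non-public spectra.
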