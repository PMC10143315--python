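# Methods

## Scope and data model

The package implements a complete LIBS calibration workflow for Cd, Cu
and Pb in a powdered plant matrix. Its currency is the `SpectraSet`: an
n_samples × n_channels intensity matrix on a strictly ascending
wavelength axis (default 1024 channels, 210–231 nm) with per-sample
metadata — brand (1–8), concentration-gradient group (1–8), replicate
(1–3), and reference concentrations in mg/kg. Train/test partitioning is
replicate-aware: within every (brand, group) cell, 2 of the 3 replicate
pellets are drawn uniformly at random into the calibration set and the
third goes to prediction, giving the 128/64 split of the emulated
experiment. Randomization is per cell (not one global replicate index),
from a dedicated generator seeded per call.

## Synthetic spectrum generator

The generator stands in for the unavailable instrument data, reproducing
the experiment's design and the spiking arithmetic exactly.

**Spiking arithmetic.** A gradient level c (mg/kg) in m grams of powder
requires V = c·m/(M·C) µL of a C mol/L nitrate solution with molar mass
M. With the protocol's values (m = 5 g, C = 0.01 mol/L, M = 112.4 / 64 /
207.2 g/mol for Cd / Cu / Pb — the roundings that make the printed
volumes exact; IUPAC masses available by flag) this reproduces every
published pipette volume, e.g. 22.24 µL for Cd at 5 mg/kg and 2343.75 µL
for Cu at 300 mg/kg. The Pb gradient contains 7 nonzero levels; volumes
are always computed from levels.

**Spectrum model.** Each spectrum is

    I(λ) = m · [ B(λ) + Σ_lines s_el · r_line · g(c_el) · G(λ; λ0, σ) + Σ_matrix a_j · G(λ; λ_j, σ) ] + o + ε

- `B(λ)`: quadratic continuum (coefficients (250, 120, −80) in the
  normalized wavelength u ∈ [0,1]), with per-sample coefficient jitter
  (fractional sd 0.06);
- analyte lines at the NIST wavelengths (Cd II 214.44/226.50, Cd I
  228.80; Cu II 217.94/222.89/224.26; Pb I 217.00, Pb II 220.35 nm) with
  Gaussian profile σ = 0.06 nm (≈3 channels FWHM) and height
  proportional to concentration, `g(c) = c`, or saturating
  `c/(1 + c/K)` when a self-absorption constant K is set;
- sensitivities 8.0 / 4.0 / 5.5 intensity units per mg/kg (Cd/Cu/Pb), so
  top-gradient peaks reach ~800–1200 units — the scale of the matrix
  lines, as trace lines ride on, not dominate, the plant emission;
- six fixed decoy matrix lines away from the analyte wavelengths, each
  with per-sample lognormal intensity jitter (σ = 0.12) emulating
  correlated plasma/matrix fluctuation;
- per-sample multiplicative scatter `m = exp N(0, 0.1)` and additive
  offset `o ~ N(0, 2% of median intensity)` — the artefacts MSC/SNV
  exist to remove; a per-brand multiplicative factor (lognormal σ 0.05);
- white noise ε with sd 5 (the residual noise of an 18-shot-averaged
  spectrum), clipped at zero.

**Concentrations.** Group g of every brand is spiked to the g-th
gradient level; a brand-level unspiked background is drawn once per
brand (lognormal around medians Cd 0.4, Cu 3, Pb 0.3 mg/kg, σ = 0.5),
and each pellet's realized content jitters lognormally (σ = 0.04) around
the target, emulating the spread of reference ICP-MS measurements. The
recorded reference value is the realized content the spectrum was
generated from — i.e. the reference method is treated as exact.

**Variance structure.** The jitter parameters were set so that the
spectral covariance looks like real averaged LIBS data: a few correlated
directions (scatter, baseline, matrix lines) dominate, and ~4–6
principal components reach 95% cumulative variance, matching the
magnitude reported for the instrument data this design emulates. A
white-noise-dominated generator would instead need ~70+ components at
95% and would misrepresent the dimensionality of the problem.

**What the generator does not model:** Saha–Boltzmann plasma physics,
self-absorption beyond the optional saturation term, line-shape changes
(Stark broadening), wavelength drift, detector nonlinearity, and
reference-method error. Passing tests therefore demonstrate that the
algorithms behave correctly on data with the study's design, SNR scale
and covariance shape — not that the real instrument would achieve the
same figures.

## Preprocessing

All four pretreatments are row-wise. MSC regresses each spectrum on a
reference (the mean calibration spectrum, frozen at fit time and reused
on test data — never recomputed from held-out rows) and inverts the
affine distortion; rows with |slope| < 1e-12 pass through with a logged
warning. SNV centers and scales each row with the sample standard
deviation (ddof = 1; the package uses ddof = 1 everywhere a standard
deviation appears, including RPD). SG smoothing uses window 9,
polyorder 3, boundary handling by polynomial extrapolation; WT uses
Daubechies-4, level 3, soft universal threshold
t = σ̂·sqrt(2 ln n), σ̂ = median(|finest detail|)/0.6745 — common
chemometric defaults where no others are given.

Method selection fits the reference PLSR inside each of 5
concentration-group-stratified CV folds, with all fitted state learned
from the fold's training rows only, and picks the minimum-RMSECV method;
exact ties resolve toward the simpler method
(none < SNV < SG < WT < MSC).

## Variable selection

**PCA** is a mean-centered SVD; the pipeline keeps the smallest k whose
cumulative explained variance reaches 95%. **SPA** grows a chain from
every candidate start channel by repeatedly projecting the remaining
columns onto the orthogonal complement of the chosen span and taking the
maximum-norm projection; every (start, chain-length) prefix with
k ∈ [1, 10] is scored by the 5-fold RMSECV of an ordinary multiple
linear regression, and ties resolve toward smaller k then lower start
index. **CARS** runs N = 50 Monte Carlo iterations: each draws 80% of
the calibration rows, fits a PLSR on the currently retained channels,
shrinks the retained count to round(r_i·p) with the exponential
decreasing function r_i = a·e^(−k·i), a = (p/2)^(1/(N−1)),
k = ln(p/2)/(N−1) (all p channels at run 1, exactly 2 at run N), and
resamples channel identities by a weighted draw without replacement with
weights |PLS regression coefficient|. The retained set of the
minimum-RMSECV run is returned with per-run diagnostics. The PLS
component count is chosen once on the full spectrum by CV and held
fixed, capped when the retained set shrinks below it.

Both selectors score by cross-validation on calibration rows only —
the prediction partition is never consumed during selection.

## Regression models

**PLSR** is PLS1 by NIPALS: weights from X'y, scores t = Xw, loadings
p = X't/t't, q = y't/t't, deflation of X per component; the regression
vector B = W(P'W)⁻¹q reproduces the latent model exactly. Component
count for pipeline models is the 5-fold RMSECV argmin, capped at 20,
ties toward fewer.

**BPNN** is a single-hidden-layer feed-forward network: tanh hidden
units, linear output, inputs and targets min–max scaled to [−1, 1] on
calibration data only. Hidden size defaults to round(sqrt(n_in + n_out))
+ 4 — the conventional sizing heuristic (7 units for 6 inputs). Training
is full-batch gradient descent on MSE in scaled space, learning rate
0.01, 2000 epochs, stopping early below MSE 1e-4; a momentum term is
available but off by default. Plain gradient descent is a deliberate
choice: the hybrid models' raison d'être is that gradient training from
random [−1, 1] initial weights is sensitive to its starting point, and
a quasi-Newton trainer would erase exactly the instability the
metaheuristics are meant to repair. 2000 epochs lets a well-initialized
network converge while leaving random initializations visibly apart.

## Metaheuristic optimizers

**PSO** is the canonical global-best variant: inertia linearly decayed
0.9 → 0.4, c1 = c2 = 1.49445, velocities clipped to 20% of the bound
span, positions clipped to bounds, swarm 30.

**SSA** classifies the population into discoverers (best 20%), joiners,
and a random 20% of scouts per iteration, safety threshold 0.8:
discoverers shrink exponentially toward exploration while the alarm is
quiet and take Gaussian jumps otherwise; joiners follow the best
discoverer with a random ±1 binary-weighted displacement, the worse half
making long escape jumps; scouts move toward the global best, or — if
already best — step away by a uniform [−1, 1] factor scaled by the
distance to the worst individual (one concrete reading of the scout
rule, documented as such). Both optimizers are deterministic given
(seed, config, fitness), record a best-so-far history of length
iterations + 1, and abort on non-finite fitness.

**Hybrid training (PSO-BP / SSA-BP).** The optimizer searches the
network's full flattened parameter vector (weights *and* thresholds);
fitness is the calibration RMSE of the decoded network in scaled space,
with no gradient steps inside the fitness. The best vector initializes
the network and back-propagation fine-tunes it. Defaults for the weight
search: bounds [−1, 1] and 150 iterations. Wider bounds (e.g. ±3) were
rejected because box-constrained swarm search tends to return
boundary-pinned weight vectors that saturate the tanh layer, leaving
gradient fine-tuning unable to recover — the hybrid then underperforms
the plain network it is supposed to improve. With [−1, 1] (the same
range as random initialization) the optimizer explores exactly the
space the network samples from, and 150 iterations suffice for the
~60–90-dimensional weight spaces of the PCA-score models. With zero
optimizer iterations the hybrid reduces exactly to plain seeded BPNN
training.

Optimizer fitness uses calibration RMSE (no internal validation split)
by default, matching common hybrid-network practice; wall-clock duration
is recorded in every report but never asserted, since it is
hardware-dependent.

## Evaluation

R² is the coefficient of determination 1 − SS_res/SS_tot (the squared
Pearson correlation is available as an option, but determination is the
default because it is the reading consistent with RMSE). RPD is
sd(y_test, ddof = 1)/RMSEP, with the customary labels: > 1.5 good,
2.0–2.5 satisfactory, > 3.0 valid. Cross-validation concatenates
out-of-fold predictions and computes metrics once on the full vector;
folds are near-equal and stratified by concentration group. The
performance report carries all seven figures (R²c, R²cv, R²p, RMSEC,
RMSECV, RMSEP, RPD) plus variable count, duration and seed; a guard
aborts if any sample id appears in both partitions. Reports are rounded
to 3 decimals for display and kept at full precision in machine output.

## Pipeline

`run_pipeline` executes, per element: split → preprocessing (fixed or
RMSECV-selected per element) → each selector on calibration data → each
model on each selector's features → reports and per-sample
relative-error tables (|ŷ−y|/y for y > 0, absolute error flagged where
the reference is 0, with a low/high stratum label cut at the median by
default; the threshold is a config key). Stochastic models are rerun
`repeats` times (default 10) with derived seeds; the median-RMSEP run is
the headline and all RMSEPs are retained. All randomness flows through
declared seeds, so a rerun with the same config is byte-identical up to
recorded durations. Diagnostic PNG plots (spectra overview, PCA
explained variance) are written only when requested.

## Problem sizes used in validation

The validation suite runs the full 192 × 1024 design for the paired-seed
model comparison (10 seeds × 3 elements × {BP, PSO-BP, SSA-BP} on PCA
scores, plus CARS/SPA vs full-spectrum PLSR on one element per seed,
~2 minutes total), and reduced designs (2 brands × 8 groups × 3
replicates) for tests where the full design adds nothing. Oracle
equivalence checks (MSC vs per-row least squares, SG vs windowed
polynomial fits, PCA vs covariance eigendecomposition, full-rank PLSR vs
OLS, SPA vs exhaustive chain search) run on small random instances at
1e-8 tolerance.

## Known limitations

- The generator's linear concentration–intensity response makes the
  problem nearly linear after scatter correction; neural models
  therefore beat PLSR by modest margins, and absolute metrics on
  synthetic data can exceed what a real instrument would deliver.
- SPA's exhaustive start-channel loop is O(p²·n) per call; at 1024
  channels a call takes a few seconds, which is fine for this design but
  would warrant a restricted start set for much larger axes.
- CARS diagnostics expose per-run retained counts and RMSECV, but the
  best-run selection considers RMSECV alone (no parsimony penalty), so
  returned subsets can be large when the error curve is flat.
- The SSA scout rule follows one concrete reading of the published
  update equations; other implementations differ in how the "step away"
  magnitude is scaled.
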