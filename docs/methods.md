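# Methods

This note records the models implemented in `gingerspec`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Problem

The response is the 6-gingerol : 6-shogaol concentration ratio of a dried
ginger-powder sample — a unitless quality index. The predictors are the
sample's averaged Vis-NIR reflectance spectrum (204 wavebands, ≈ 397–1004
nm) extracted from a hyperspectral image. The task is multivariate
calibration: learn ratio = f(spectrum) from reference samples whose ratio
is known from chromatography, then predict it non-destructively. The
response is always the ratio; the individual concentrations are never used
as a modelling target (they exist only inside the simulator as ground
truth).

## From cube to spectrum

Raw frames are digital numbers. Flat-fielding converts them to relative
reflectance per pixel and band:

    I_c = (I_raw − I_dark) / (I_white − I_dark)

The white tile's nominal 99% reflectance is *not* divided out — the
constant is absorbed by the regression, and the correction is applied
exactly as written. Pixels with |denominator| < ε (default 1e-10) are set
to NaN, counted in the cube's metadata, and excluded band-wise from the
ROI mean; more than 1% of them triggers a warning, as does a frame pair
with white ≤ dark on over 1% of pixels. The ROI is a user-supplied
rectangle (0-based, half-open); all pixel spectra inside it are averaged
into the sample's one spectrum. There is no automatic segmentation and no
illumination-field model beyond the equation above.

## Pre-treatments

Eight variants form the canonical grid: `raw`, `snv`, `msc`, `mf5`, `mf9`,
`mf11`, `sg1`, `sg2`. All are pure functions of the N × K spectra matrix,
applied after ROI averaging; the moving averages therefore run along the
band axis. (A per-band spatial mean filter on the cube is available
separately for the alternative reading of an n × n window, but is not part
of the canonical grid.) Choices that needed fixing:

- **SNV** uses the unbiased K−1 standard deviation, so `[1, 2, 3]` maps to
  `[−1, 0, 1]` exactly.
- **MSC** regresses each spectrum on a reference by OLS and inverts the
  fitted line. The reference is the *training-set* column mean, fitted once
  and applied frozen to test spectra — the test split never influences the
  correction. Slopes below 1e-8 in magnitude are an error.
- **Savitzky–Golay** derivative windows and polynomial orders are not
  dictated by the study design; the defaults are the common chemometric
  choice of window 11 with polyorder 2 (1st derivative) and 3 (2nd
  derivative), both configurable. Derivatives are expressed per nanometre
  by dividing by the band spacing; edges use the local polynomial fit
  (`mode="interp"`), which keeps the derivative exact on polynomials up to
  the polyorder.
- **Mean filters** truncate the window at the edges (average over in-range
  bands only), so constant spectra are fixed points. Widths 5, 9 and 11
  are all first-class; the set of three covers the window sizes in common
  chemometric use for ~3 nm band spacing.

## Regression models

**PLSR.** Classical single-response NIPALS: per component the weight
`w ∝ Xᵀy` (unit norm), score `t = Xw`, loadings `p = Xᵀt/tᵀt`,
`q = yᵀt/tᵀt`, then rank-one deflation of both blocks. The coefficient
vector is `β = W(PᵀW)⁻¹q` on centred data, which makes prediction via β
identical to the sequential scores pathway (asserted in tests to 1e-10).
Scores are mutually orthogonal; with J = rank(X) the fit reproduces OLS.
X and y are centred, not autoscaled (an opt-in flag exists): the
pre-treatments already normalise scale where that is intended, and the two
model families are treated symmetrically. J is selected by leave-one-out
cross-validation over 1..20 (configurable), minimising RMSECV, ties to the
smaller J; each fold's NIPALS run is performed once with nested predictions
collected at every J.

**LASSO.** The objective is kept on its plain scale,
`RSS + αΣ|β|`, with no 1/(2N) factor; grids from libraries using the
`1/(2N)·RSS + α‖β‖₁` convention translate as `α_here = 2N·α_there`. The
solver is cyclic coordinate descent on the Gram matrix with
soft-thresholding at α/2, compiled with numba; `α = 0` falls back to
(minimum-norm) least squares. α is selected by the same leave-one-out
criterion over a 50-point descending log grid from
`α_max = 2·max_j |X_jᵀy|` (the smallest fully-sparsifying penalty, from the
stationarity conditions) down to `10⁻⁴·α_max`, warm-starting along the path
within each fold; ties take the larger α (the sparser model). Leave-one-out
is used for α deliberately, to keep hyperparameter selection identical
across the two model families, although k-fold is more common for LASSO.

**Convergence.** Treated spectra are heavily collinear (204 bands, ~70
training samples), so the Gram matrix is nearly rank-deficient and
coefficient changes along its near-null directions decay too slowly for a
purely absolute stopping rule at the small end of the α grid. The solver
therefore stops on whichever fires first: the strict rule (max per-sweep
coefficient change < 1e-8), certified stationarity (max KKT violation
< 1e-7, computable exactly from the maintained gradient), or a
scale-invariant progress rule in the glmnet style (max single-coordinate
objective decrease < 1e-9·‖y_c‖²). Final fits add a bounded polish phase
(≤ 2000 sweeps, progress rule disabled): on well-conditioned problems it
reaches certified stationarity, on near-singular ones it spends its budget
and keeps the iterate. The CV path uses the progress rule alone — the CV
curve is a fold average and does not benefit from the last digit. The
stationarity conditions (`X_jᵀ(y − Xβ) = (α/2)·sign(β_j)` on the active
set, `|X_jᵀ(y − Xβ)| ≤ α/2` off it) are exercised in the tests.

**Split.** One seeded uniform-random 80/20 partition
(`|test| = round(0.2·N)`, seed 20 by default) is shared by every model in a
grid, so all 32 rows are comparable. The seed fixes this package's own
permutation; splits from other toolchains with the same seed will differ,
since permutation algorithms are not portable across RNG implementations.

## Wavelength selection

Applied to PLSR only (the LASSO penalty already zeroes coefficients):

- **β-coefficient rule**: retain bands with `|β_j| ≥ SD(β)`. The SD is the
  population (1/K) value by default — the discard rule references the
  coefficient vector itself, and the choice (vs K−1) is configurable and
  only shifts the threshold by ~0.25% at K = 204. Equality retains the
  band. The rule is invariant under global rescaling or sign flip of β.
- **VIP rule**: `VIP_j = sqrt(K·Σ_a SSY_a(w_ja/‖w_a‖)² / Σ_a SSY_a)` with
  `SSY_a = q_a²·t_aᵀt_a`, the standard single-response form; its
  mean-square normalisation `(1/K)ΣVIP² = 1` is what makes 1 the natural
  threshold (and guarantees at least one retained band).

Selection uses the training fit only; the retained columns are then taken
from both splits and the PLSR refitted with J re-selected by leave-one-out
on the reduced matrix.

## Evaluation

Per split: R² `= 1 − Σ(y_p−y_m)²/Σ(y_m−ȳ_m)²` (the standard form; a
variant with the predicted values in the denominator circulates in parts of
the applied literature but can exceed 1 and contradicts its own usual
legend — it is available behind `printed_denominator=True`, never default).
RMSE uses denominator m. RPD divides the SD (K−1) of the *predicted*
values by the split RMSE — as specified for this pipeline; the conventional
SD(measured) numerator is a flag away. RPD ≥ 1.4 flags a usable
calibration. LOD `= 3·RMSE_cal/slope_cal` uses the training-split RMSE and
the OLS slope of predicted-on-measured in training — the conventional
reading of "slope of the calibration" in multivariate work. A perfect fit
reports RMSE 0, LOD 0 and an infinite RPD rather than erroring, so
degenerate grid cells still produce complete rows.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* the analysis assumes,
not ginger's actual spectra:

- **Pure spectra.** `r(λ) = baseline(λ) − Σ_i c_i Σ_k w_k·gauss(λ; μ_k, σ_k)`,
  clipped to [0.02, 0.98]: Beer–Lambert-like additive absorption on a
  smooth powder baseline. The two constituents' Gaussian band sets are
  disjoint in centre (gingerol 670/915 nm, shogaol 560/985 nm by default),
  making the concentration pair — and hence the ratio — linearly
  identifiable: a noise-free 2-LV PLSR recovers either concentration with
  R² > 0.999 (tested).
- **Acquisition.** Per pixel: `DN = gain(λ)·(a·r + b) + dark(λ) + ε·gain`,
  with `a ~ N(1, 0.05)` and `b ~ N(0, 0.02)` drawn once per *sample*
  (packing and surface geometry vary between powder beds, not between
  neighbouring pixels) and `ε ~ N(0, 0.01)` per pixel and band. The white
  frame is `gain + dark`, the dark frame `dark`; flat-fielding recovers
  `a·r + b` up to pixel noise — by construction, the artifact classes the
  pre-treatments remove (multiplicative scatter, offset, random noise) and
  nothing else.
- **Concentrations.** Published numeric ranges are unavailable, so the law
  is an acknowledged invention chosen once: shogaol ~ LogNormal(ln 1.8
  mg/g, σ = 0.12), ratio ~ LogNormal(ln 1.5, σ = 0.45), gingerol = ratio ×
  shogaol. The correlation mirrors the chemistry (shogaol derives from
  gingerol during drying), the ratio spans ≈ 0.5–4, and limits of detection
  in the 0.6–1.0 range fall inside the data. Everything is configuration,
  including the band sets and all noise scales.
- **Study conditions.** Defaults: 89 samples, 204 uniformly spaced bands
  397.32–1003.58 nm, 64 × 64-pixel cubes, seed-deterministic to the byte.

What passing tests on this substrate show: the pipeline's algebra, its
selection and evaluation logic, and its end-to-end behaviour under exactly
the distortions it claims to handle. What they do not show: performance on
real ginger, whose spectra carry water/starch features, nonlinear
scattering, and constituent collinearity this forward model does not
attempt. Synthetic metrics are accordingly optimistic (test R² ≈ 0.98,
RPD ≈ 8 at the default noise levels — far beyond what real powder
calibrations achieve); they validate the machinery, not the instrument.

## Grid and reproducibility

The canonical grid is 8 treatments × {PLSR, LASSO} plus 8 × {β, VIP}
refits = 32 rows, one shared split, each cell's failure recorded without
stopping the grid (the CLI exits non-zero if any cell failed). Outputs:
`grid_results.csv`, `best_models.json` (per-family argmax by test RPD,
ties to canonical order), per-winner measured-vs-predicted scatter CSVs,
and a `manifest.json` with the config hash, seeds, sizes and library
versions. Identical config and seed reproduce every output byte.
`scripts/acceptance.py` runs this end to end at the full default scale
(a few minutes on one CPU); the test suite exercises the same path both at
a reduced scale (30 samples, 60 bands, 8 × 8 cubes) for speed and at the
full scale in the acceptance tests.

## Known limitations

- ENVI I/O covers uncompressed BIL/BIP/BSQ rasters with a wavelength
  block; no tiled/compressed variants, no vendor metadata interpretation
  (unknown header keys are preserved verbatim but not parsed).
- No elastic net, sparse PLS, or nonlinear models; no CARS/SPA-style
  selection; no per-pixel prediction maps; no plotting (CSV outputs feed
  external tools).
- Leave-one-out α selection targets prediction, not support recovery: at
  the CV-minimum penalty the LASSO keeps some spurious small coefficients
  (the familiar over-selection of CV-optimal L1 models). The true support
  dominates by magnitude; users wanting sparser sets should threshold or
  use a 1-SE-style rule on the returned CV curve.
- The β-SD and VIP thresholds are the field's conventions, not optimised
  quantities; both are parameters.
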