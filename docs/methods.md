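# Methods

## Scope and model

`hsiquant` implements a spectral–spatial calibration pipeline for
quantifying plant metabolites (total flavonoids, total chlorogenic
acids; mg/g) from hyperspectral imaging: reflectance correction, ROI
mean-spectrum extraction, Savitzky–Golay + MSC preprocessing,
wavelength selection by a variable-similarity-regularized binary PSO
(with SPA and UVE baselines), GLCM/color spatial features, feature
fusion and gradient-boosted-tree / PLSR / SVR regression with R², RMSE,
MAE and RPD evaluation.

## The regularized fitness

The selector minimizes, over binary band masks `X_k` with `l` of `L`
bands on,

```
f(X_k) = RMSE_cv(X_k) + λ · (l/L) · S̄(X_k),      0 ≤ λ < 1
```

Decisions behind this form, all configurable:

- **Inner model.** The RMSE term is 5-fold cross-validated PLS1
  (10 latent variables, capped by subset and fold size) with folds
  frozen per run, so every subset is scored on identical splits and
  the search is deterministic given its seed. A minimal NIPALS PLS1 is
  used here for speed (thousands of fits per run); its predictions are
  asserted against `sklearn.cross_decomposition.PLSRegression(scale=False)`
  in the test suite.
- **Unit-free error term.** `RMSE_cv` is computed on the
  SD-standardized target (`normalize_rmse=True`). RMSE in mg/g makes
  the balance between the two terms depend on the component's
  concentration scale (≈3 mg/g error for flavonoids vs ≈0.2 mg/g for
  chlorogenic acids), so no single λ in (0, 1) could serve both
  components; standardizing the target makes λ transferable. At λ = 0
  the fitness is exactly the inner model's CV RMSE of the standardized
  target.
- **Similarity kernel.** `S̄` is the mean over unordered pairs of
  `exp(−‖w_a − w_b‖² / (2 s² n))` computed on z-scored selected
  columns, with the squared distance normalized by the calibration
  size `n` (two columns with correlation ρ are at distance
  `2n(1−ρ)`, so the kernel sees `exp(−(1−ρ)/s²)` regardless of `n`).
  A similarity that *grows* with distance would reward, not penalize,
  redundancy; the Gaussian form is the reading consistent with the
  selector's purpose. The literal growing-exponent variant is kept
  behind `similarity="literal_exp"` for audit. A zero-variance column
  is assigned similarity 1 to every partner (a constant band is
  maximally redundant).
- **Aggregation and length scale.** Summing similarities over all
  pairs makes the penalty grow quadratically in `l` and overwhelm the
  error term (the swarm collapses to < 15 bands at any λ > 0 and loses
  informative regions); the mean over pairs with `s = 2.5` was fixed
  by requiring the selector to reproduce the published behaviour of
  the method on its λ sweep — roughly half as many bands at
  λ = 0.2–0.4 as at λ = 0, declining monotonically — and is not a
  tuned quantity thereafter.

## Swarm dynamics

Canonical velocity update (`ω` linearly decayed 0.9 → 0.4, `c₁ = c₂ = 2`,
`v_max = 4`, 30 particles, 200 iterations by default), positions
re-binarized each step through the sigmoid transfer. Two transfer
variants are provided:

- `threshold_half` (default): bit on iff `sigmoid(v) > 0.5`. Positions
  are deterministic functions of velocity, so personal/global bests
  accumulate and the swarm converges within ~100 iterations on
  288 bands. Velocities are initialized with signs matching the
  initial bits so the deterministic transfer does not erase consensus
  bits on the first step.
- `sigmoid_stochastic`: bit on with probability `sigmoid(v)`. This is
  the textbook binary-PSO transfer, but with ~300 dimensions it
  re-randomizes tens of bits per particle per iteration and the global
  best stagnates long before the penalty can shrink the subset; it is
  kept for reference and small problems.

Empty positions are repaired by switching on one uniformly random
band; personal/global bests update on strict improvement only, making
the best-ever fitness trajectory non-increasing by construction.
Fitness values are cached per position (folds are frozen, so the
fitness is a pure function of the mask).

## Baseline selectors

- **SPA** grows, from every starting band, a chain that repeatedly adds
  the column with the largest residual norm against the orthonormal
  basis of the chain (classic successive projections); chains stop
  early at rank deficiency, and the subset size is chosen by
  cross-validated OLS RMSE.
- **UVE** augments the spectra with as many artificial noise columns as
  real bands, computes PLS1 coefficients under leave-one-out, and keeps
  bands whose stability `|mean(b)/std(b)|` exceeds the maximum among
  the noise columns. The noise amplitude defaults to the data's median
  column SD: with a near-zero amplitude the noise-column stabilities
  are numerical artifacts and the filter degenerates (it retained
  essentially nothing at n = 200 in our experiments), whereas
  noise at the data's own floor gives a meaningful null reference.
  On spectra where only a quarter of bands carry (strongly collinear)
  signal, UVE's per-coefficient stability is diluted and its retained
  set can be small; its characteristic behaviour — retaining many
  stable, mutually redundant variables where a projections chain keeps
  a parsimonious subset — is asserted on a redundant-design matrix in
  the tests.

## Spatial features

GLCM statistics use 64 gray levels (per-image min–max binning), step
length 1, and the average over 0°/45°/90°/135°. Pair counting is
mask-aware: a pair contributes only when both pixels are inside the
ROI, so background texture cannot contaminate features; matrices are
symmetrized and normalized to sum 1. The gray image defaults to the
Rec.601 luminance of the false-color composite. Color features are
per-pixel conversions (sRGB companding, D65 white point for L\*a\*b\*)
averaged over ROI pixels — converting before averaging matters because
both L\*a\*b\* and HSV are nonlinear. Identities asserted in tests:
constant images give ASM = energy = homogeneity = 1 and
contrast = dissimilarity = 0; four-angle averaging is invariant to 90°
rotation; min–max binning absorbs any constant offset.

## Regression and metrics

Features are fused by concatenation with per-column z-scores fitted on
calibration rows only (prediction rows are scaled with the calibration
statistics — asserted by a leakage-guard test). Grid search minimizes
5-fold CV RMSE with shuffled, seeded folds and refits the winner on all
calibration rows. Default grids stay inside the method's stated search
spaces (SVR C ∈ [0, 10], γ ∈ [5, 5000]; PLSR latent variables 1–60;
boosted trees of depth 3 with learning rate, rounds and L1/L2 around
the reported optimum). R² is the coefficient of determination (can be
negative), RPD uses the sample (n−1) SD of the evaluated references,
and a zero RMSE flags RPD as infinite rather than raising.

## Synthetic data: what it emulates and what it does not

Each spectrum is a smooth polynomial continuum plus
concentration-weighted Gaussian absorption features at
1200/1460/1730/1930 nm on the 948–2513 nm, 288-band grid, then
per-sample affine scatter `(1+slope)·x + offset` and i.i.d. Gaussian
noise. Concentrations are truncated-normal with the study's reference
statistics (TF 126.77 ± 9.97, TCA 19.57 ± 0.52 mg/g). Bands within two
peak widths of a center are recorded as planted ground truth; "planted
region recall" is the fraction of the four peak windows containing at
least one selected band — the meaningful recall for a
redundancy-penalized selector, which deliberately keeps only a few
bands per collinear window. Images are HSV fields whose mean hue and
value-noise amplitude are linear in a weighted z-score of the
concentrations (color and texture coupling), rendered to RGB.

Not emulated: instrument physics (PSF, smile/keystone, line timing),
wavelength-dependent scatter, correlated (pink) noise, and any real
biochemical relation between morphology and metabolite content — the
image coupling is a linear stand-in whose strength is a free
parameter. Passing tests therefore demonstrate correctness of the
algorithms and the qualitative orderings (preprocessing helps; fused
features ≥ spectra alone; spatial-only is worst; larger λ → fewer
bands), not field performance on real chrysanthemum data.

## Numerical choices and degenerate inputs

- Reflectance correction flags pixels with a zero white–dark gap as
  NaN and excludes them from ROIs rather than imputing.
- MSC raises on |slope| < 1e-12 (flat or inverted spectrum) and on a
  constant reference.
- Savitzky–Golay edges are handled by evaluating the edge-window
  polynomial fit (`mode="interp"`), preserving band count and passing
  polynomial rows through exactly.
- PLS1 truncates its deflation loop when the weight vector collapses
  (rank exhaustion / perfect fit) instead of dividing by ~0.
- Ties in the swarm keep the incumbent best (strict improvement only)
  for reproducibility; k-fold splits come from a seeded permutation.
- The calibration/prediction split is by explicit sample lists in the
  CLI config, with a seeded random-fraction fallback for synthetic
  runs.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the selector studies at
n = 200 samples × 288 bands with 30 particles and 100 iterations
(5–10 repeats), and the ablation at 200 samples with a reduced
selection budget (20 particles, 40 iterations) and a fixed
LightGBM configuration — sizes chosen so the full suite completes in a
few minutes on one CPU while preserving the regime the method targets
(more bands than samples, collinear informative regions).

## Known limitations

- The exact inner model and CV scheme behind the published fitness are
  not specified anywhere; matching the method's printed band counts
  (e.g., 40/37 selected) exactly is therefore out of reach, and only
  behaviour — shrinkage ratios, monotone λ response, region coverage —
  is asserted.
- Band-level recall of all planted bands is intentionally not a goal:
  the similarity penalty exists to discard collinear in-window bands.
- UVE's leave-one-out stability is a √n-scaled t-statistic; on data
  where few bands carry diluted signal its retained set is small, and
  the strict max-over-noise cutoff is conservative.
- The CLI's `extract` assumes one cube (or one image) per sample;
  grouping several specimens into one sample is left to configuration.
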