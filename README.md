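# hsiquant

Hyperspectral-imaging chemometrics for estimating bioactive component
contents — total flavonoids (TF) and total chlorogenic acids (TCA), in
mg/g — of dried plant material (chrysanthemum tea) from SWIR reflectance
spectra and VNIR color/texture information.

The package is aimed at chemometricians and food-quality researchers who
want a fully testable implementation of a spectral–spatial calibration
pipeline, including a wavelength selector that explicitly penalizes
redundant (collinear) bands.

## The method

1. **Reflectance correction.** Raw cubes are normalized against white
   (Teflon) and dark references, `R = (I_raw − I_dark)/(I_white − I_dark)`;
   the sample surface is segmented (Otsu or fixed threshold, largest
   connected component) and ROI pixels are averaged into one spectrum
   per sample (948–2513 nm, 288 bands).
2. **Preprocessing.** Savitzky–Golay convolution smoothing (window 11,
   order 2) followed by multiplicative scatter correction against the
   calibration mean spectrum.
3. **Variable-similarity PSO (VSPSO) wavelength selection.** A binary
   particle swarm searches band subsets `X_k` minimizing

   ```
   f(X_k) = RMSE_cv(X_k) + λ · (l/L) · S̄(X_k)
   ```

   where `RMSE_cv` is the 5-fold cross-validated error of an inner PLS
   model on the SD-standardized target, `l` of `L` bands are selected,
   and `S̄` is the mean pairwise Gaussian similarity
   `exp(−‖w_a − w_b‖²/(2·s²·n))` of the standardized selected columns.
   Velocities follow the canonical update
   `v ← ωv + c₁r₁(pbest − x) + c₂r₂(gbest − x)` with a sigmoid transfer
   to bits. `λ = 0` reduces to standard binary PSO; larger `λ` removes
   collinear bands more aggressively. SPA (successive projections) and
   UVE (uninformative variable elimination) are included as baselines.
4. **Spatial features.** 9 color means (RGB, CIE L\*a\*b\*, HSV) and 5
   GLCM texture statistics (ASM, contrast, dissimilarity, energy,
   homogeneity; 64 gray levels, step 1, averaged over 0°/45°/90°/135°).
5. **Fusion and regression.** Selected bands and the 14 spatial
   features are concatenated, z-standardized on calibration rows only,
   and fitted with LightGBM (or PLSR/SVR) via grid search; evaluation
   reports R², RMSE, MAE and RPD = SD/RMSE.

Because no public dataset accompanies the method, a first-class
synthetic generator produces spectra with planted absorption regions
(near 1200/1460/1730/1930 nm), realistic concentration statistics
(TF ≈ 127 ± 10 mg/g, TCA ≈ 19.6 ± 0.5 mg/g), per-sample scatter, noise,
and images whose hue/texture couple to the concentrations — so recall
of the informative bands and every pipeline contract can be verified
exactly.

## Worked example

```python
import numpy as np
import hsiquant as hq
from hsiquant.spatial_features import SPATIAL_FEATURE_NAMES, spatial_feature_vector

cfg = hq.SyntheticConfig(n_samples=200, seed=42)
ds = hq.generate_dataset(cfg)
y = ds.references["TF_mg_g"].to_numpy()

rng = np.random.default_rng(0)
perm = rng.permutation(200)
cal, pred = np.sort(perm[:140]), np.sort(perm[140:])

pp_cfg = hq.PreprocessConfig()
cal_ss = hq.SpectrumSet(ds.spectra.X[cal], ds.spectra.wavelengths,
                        [ds.spectra.sample_ids[i] for i in cal])
pred_ss = hq.SpectrumSet(ds.spectra.X[pred], ds.spectra.wavelengths,
                         [ds.spectra.sample_ids[i] for i in pred])
cal_pp, state = hq.apply_pipeline(cal_ss, pp_cfg)
pred_pp, _ = hq.apply_pipeline(pred_ss, pp_cfg, state, fit=False)

res = hq.run_vspso(cal_pp.X, y[cal],
                   hq.SwarmConfig(n_particles=30, max_iter=100, seed=7),
                   hq.FitnessConfig(lam=0.2))
print(f"selected {res.n_selected} of 288 bands ...")

mask = np.ones(ds.images.shape[1:3], bool)
spatial = np.array([spatial_feature_vector(img, mask) for img in ds.images])
idx = res.selected_indices
labels = [f"{ds.spectra.wavelengths[i]:.1f}nm" for i in idx]
train = hq.fuse(cal_pp.X[:, idx], spatial[cal], y[cal], labels,
                list(SPATIAL_FEATURE_NAMES))
test = hq.fuse(pred_pp.X[:, idx], spatial[pred], y[pred], labels,
               list(SPATIAL_FEATURE_NAMES))
model = hq.fit(train, hq.ModelSpec(family="gbt",
                                   grid={"n_estimators": [300],
                                         "learning_rate": [0.08],
                                         "max_depth": [3]}))
m = hq.evaluate(model, test)
print(f"total flavonoids: R2={m.r2:.4f} RMSE={m.rmse:.3f} mg/g ...")
```

which prints:

```
selected 73 of 288 bands (fitness 0.2420 = rmse 0.1988 + penalty 0.0432)
total flavonoids: R2=0.9112 RMSE=2.716 mg/g MAE=2.072 mg/g RPD=3.38 (n=60)
```

The swarm keeps 73 of 288 bands (the regularization term is what holds
the count down — at `λ = 0` the same search keeps ~100), the fused
spectral+spatial model explains 91% of the held-out concentration
variance, and RPD > 3 indicates a calibration strong enough for
quantitative use.

## Command line

A config-driven CLI wraps the same library:

```bash
hsiquant simulate -c run.yaml      # synthetic dataset -> CSV/PNG
hsiquant extract  -c run.yaml      # cubes/images -> spectra + 14 features
hsiquant select   -c run.yaml      # VSPSO / PSO / SPA / UVE band selection
hsiquant train    -c run.yaml      # fused-feature model + metrics JSON
hsiquant ablate   -c run.yaml      # stage-toggling comparison table
hsiquant sweep-lambda -c run.yaml  # band count / accuracy vs lambda
```

Every output embeds the config hash, and all randomness derives from
the single `seed` key, so re-running any command reproduces its outputs
byte-for-byte.

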