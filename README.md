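# fvcinv

Fractional vegetation cover (FVC) estimation for alpine grassland.

FVC — the fraction of ground covered by green vegetation, in [0, 1] —
is the basic state variable for monitoring grassland ecosystems such as
those of the Qinghai–Tibet Plateau. The modern workflow calibrates
satellite inversion models against ground truth extracted from
centimetre-scale aerial photographs: segment each photo into vegetation
and background with the Excess Green Index (EGI = 2G − R − B), pair the
resulting per-site FVC with Landsat-8 surface reflectance and
topography, and invert FVC over the whole region.

`fvcinv` implements that workflow end to end for researchers in
vegetation remote sensing who want a tested, seeded, fully reproducible
reference implementation:

* **imagery** — EGI computation and threshold segmentation, with the
  threshold chosen automatically by a range-restricted Otsu criterion
  inside the empirical 40–160 window (or fixed manually);
* **features** — the multi-dimensional feature table: 7 OLI bands, 22
  vegetation indices (NDVI, EVI, SAVI, MSAVI, SR, ARVI, DVI, GEMI,
  GARI, GDVI, GNDVI, GRVI, GVI, IPVI, LAI, MNLI, MSR, NLI, OSAVI,
  RDVI, TDVI, VARI) and DEM/slope/aspect, with train-fitted min–max
  normalisation;
* **classic** — the two non-ML baselines: empirical VI regression
  (FVC = a·VI + b, or quadratic) and the pixel dichotomy model
  FVC = (NDVI − NDVI_s)/(NDVI_v − NDVI_s) with literature
  (0.837/0.164) and 95%-interval (0.882/0.067) endmember presets;
* **selection** — three feature-selection algorithms implemented from
  scratch: Boruta (shadow features + binomial tests), sequential
  forward selection, and PI-RFE — recursive feature elimination whose
  per-step ranking is *permutation importance* (held-out RMSE increase
  under column shuffling) instead of built-in model weights;
* **models** — MLR, a BPNN (tanh layers, linear output, weight decay
  0.01), epsilon-SVR (RBF) and random forest, with exhaustive
  grid-search tuning under k-fold cross-validation;
* **evaluation** — R², RMSE (fraction and percent), training-sample-size
  sensitivity sweeps (30…270 in steps of 30), and a four-arm experiment
  runner with byte-reproducible outputs;
* **synthetic** — generators for UAV-like scenes (exact vegetation
  pixel counts, guaranteed EGI class margins) and site tables (linear
  spectral mixing of vegetation/soil endmembers with NDVI ≈ 0.88/0.07,
  topography-driven cover with elevation the dominant driver), so the
  whole pipeline is testable without any field data.

See `docs/methods.md` for the model details, parameter defaults, and
the limits of what the synthetic benchmarks demonstrate.

## Worked example

Generate a 120-site synthetic campaign, run the classic baselines and
the machine-learning arms, and compare accuracy on the 30% holdout:

```python
from fvcinv import evaluation
from fvcinv.synthetic import SiteSimConfig

cfg = evaluation.ExperimentConfig(
    arms=("classic", "ml_4vi", "ml_full"),
    sim=SiteSimConfig(n_sites=120, band_noise_sd=0.05, seed=7),
    rf_trees=200, seed=7,
)
results, _ = evaluation.run_experiment(cfg)
print(results.drop(columns="params").to_string(index=False))
```

```
    arm algorithm       r2  rmse_percent  n_features
classic vi_linear 0.716010     17.739798           1
classic   vi_poly 0.712935     17.835566           1
classic dichotomy 0.712232     17.857391           1
 ml_4vi       mlr 0.631849     20.198072           4
 ml_4vi      bpnn 0.775603     15.769049           4
 ml_4vi       svr 0.730185     17.291408           4
 ml_4vi        rf 0.690455     18.520754           4
ml_full       mlr 0.788340     15.314982          32
ml_full      bpnn 0.785526     15.416460          32
ml_full       svr 0.835415     13.504920          32
ml_full        rf 0.801889     14.816695          32
```

Each row is one inversion method evaluated on the same held-out 36
sites: `r2` is the coefficient of determination between measured and
predicted FVC and `rmse_percent` the root mean square error in cover
percentage points. The pattern the package is built to study is visible
directly: the single-index classic methods sit near R² ≈ 0.71, and
moving the machine-learning models from the four classic indices to the
full 32-column feature set (bands + indices + topography) lifts every
algorithm — here by 0.05–0.16 R², because elevation and its
interaction with canopy spectra carry real information about cover.

Image-based extraction works the same way from Python or the shell:

```python
from fvcinv.synthetic import SceneConfig, make_scene
from fvcinv.imagery import image_fvc

img, mask, true_fvc = make_scene(SceneConfig(target_fvc=0.25, seed=1))
res = image_fvc(img)            # auto threshold in [40, 160]
print(res.threshold, res.fvc)   # -> 65 0.25
```

```bash
fvc extract --image scene.png --out fvc.csv
fvc classic --method dichotomy --endmembers ci95 --sites sites.csv --out pred.csv
fvc select --algo pirfe --features feats.csv --target fvc --out selection.json
fvc run --seed 1 --out results/
```

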