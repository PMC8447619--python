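# Methods

`fvcinv` estimates fractional vegetation cover (FVC) — the fraction of
ground covered by green vegetation — for alpine grassland, following the
workflow used in UAV-calibrated satellite inversion studies: extract
ground-truth FVC from centimetre-scale RGB aerial imagery, pair each
site with Landsat-8 OLI surface reflectance and topography, and invert
FVC with classic models and tuned machine-learning regressors driven by
a feature-selected multi-dimensional feature set.

Because the field data such studies rest on (91 sites in the source
region of the Yellow River basin) are not public, the package ships a
synthetic generator whose ground truth is known by construction; every
pipeline stage is validated against that truth.

## Image-based FVC extraction

A pixel is vegetation when its Excess Green Index, `EGI = 2G − R − B`
(signed arithmetic on 8-bit channels, range −510…510), exceeds a
threshold; image FVC is the vegetation pixel fraction. Field practice
tunes the threshold by visual interpretation within an empirical range
of 40–160 gray levels. For reproducibility the package replaces the
human with a range-restricted Otsu criterion: the integer threshold in
[40, 160] maximising between-class variance of the EGI histogram, ties
toward the smaller value. A manual threshold overrides this. The
comparison is strict (`EGI > t`), so masks are bit-reproducible.

The scene generator places an exact number of vegetation pixels
(`round(target_fvc · H · W)`), draws per-channel Gaussian color noise
around class-mean colors, and guarantees a minimum noise-free EGI margin
between classes. Defaults: 100×100 px, vegetation mean (60, 180, 70)
(EGI 230), soil mean (120, 100, 90) (EGI −10), color sd 8. When scenes
are randomised over margins, the color sd is scaled as `margin/16`
(capped at 8) so the constructed separation survives noise — with less
than that, no threshold can recover the true fraction and the test
would measure the generator, not the segmenter. JPEG input is accepted;
tests use lossless PNG, and the ±0.01 recovery tolerance leaves room
for block noise on real JPEGs.

## Feature table

Seven OLI bands (b1 coastal … b7 SWIR2), 22 vegetation indices, and
DEM/slope/aspect give 32 columns in a fixed order. Band semantics
default to the standard OLI assignment (b2 = blue, b3 = green);
`band_semantics="printed"` swaps the two for data exported with the
alternative labelling. The tasseled-cap greenness (GVI) uses the
coefficients (−0.2848, −0.2435, −0.5436, 0.7243, 0.0840, −0.1800) on
(blue, green, red, NIR, SWIR1, SWIR2). Soil-adjustment factors L1
(SAVI) and L2 (MNLI) are fixed at 0.5.

Min–max normalisation applies only to columns whose values leave [0, 1]
on the *fit rows* (training split); parameters are stored and applied
unchanged to new rows, which may therefore fall outside [0, 1] — they
are deliberately not clipped, so the transform stays affine. A constant
out-of-range column maps to 0 with a warning. Fitting on training rows
only avoids information leaking from the held-out split; aspect is
scaled as a raw angle (a sin/cos encoding was considered and rejected
for fidelity to common practice in this workflow).

Known limitation: GARI is only bounded in [−1, 1] on its intended
domain B ≥ R; bare-soil spectra with B < R push it outside, which is
why the range test covers NDVI/GNDVI/NLI generally, ARVI for 2R > B,
and GARI for B ≥ R.

## Classic inversion

*Empirical VI regression*: least-squares linear (`FVC = a·VI + b`) or
quadratic (`FVC = c·VI² + d·VI + e`) fit of measured FVC on one index.
Predictions are unclipped by default (a clip flag exists).

*Pixel dichotomy*: `FVC = (NDVI − NDVI_s)/(NDVI_v − NDVI_s)` with pure
soil/vegetation endmembers, output clipped to [0, 1] since a cover
fraction is physical. Two presets ship: a literature pair
(0.837/0.164) and a study-area 95%-interval pair (0.882/0.067); the
`ci95` estimator recomputes such a pair from any NDVI sample as the
2.5th/97.5th linear-interpolation percentiles (coverage 1 gives
min/max). The 95%-interval reading of "confidence interval" follows the
cited usage in the FVC literature; the estimator behind the published
pair is not stated anywhere we could check, so percentiles are the
documented choice.

## Feature selection

All three selectors default to a random-forest regressor and are fully
seeded.

*Permutation importance (PI)*: mean increase in held-out RMSE over
`repeats` random permutations of one column. The permutation stream is
a single `default_rng(seed)` consumed feature-by-feature, so results
are exactly reproducible and independently recomputable. A constant
column has importance exactly 0.

*PI-RFE*: recursive feature elimination whose per-step ranking is PI
computed on each held-out fold and averaged — replacing the
estimator's built-in weights with a model-agnostic, accuracy-based
signal. One fixed fold partition (derived from the seed) is used at
every subset size, so the RMSE-vs-size curve compares like with like;
only the permutation draws vary per step. The selected subset is the
size with minimum mean CV RMSE (ties to the smaller size). A
`size_rule="1se"` option applies the one-standard-error parsimony rule
instead; it exists because a weak spurious feature can sit below the
curve minimum by less than fold noise in roughly a third of random
datasets — the global minimum is the documented default, the 1-SE rule
the recommended choice when parsimony matters.

*SFS*: greedy forward selection on mean CV RMSE over the same fixed
fold partition, all sizes 1…p (or `max_size`), subset chosen as for
PI-RFE.

*Boruta*: each iteration appends a permuted shadow copy of every
original feature — the shadow pool stays at size p throughout, so the
null reference does not weaken as features are decided — and counts a
hit for each undecided feature whose importance beats the best shadow.
Two one-sided binomial tests at level alpha (0.05) with Bonferroni
correction across the p features confirm or reject; leftovers after
`max_iter` (100) are tentative. Importance defaults to *held-out
permutation importance* (fit on a random 70%, score on 30%): impurity
importance hands spuriously correlated noise columns a systematic edge
over freshly permuted shadows, leaving them permanently tentative,
whereas held-out importance restores exchangeability under the null.
Impurity remains available (`importance="impurity"`). With very few
features the shadow maximum is a weak null and occasional false
confirmations are expected; type-I behaviour is good from ~20 columns.

## Inversion models and tuning

Four regressors behind one interface, all column-aligned by feature
name at prediction time:

| model | implementation | stock grid | documented optimum (default) |
|---|---|---|---|
| MLR | ordinary least squares | — | — |
| BPNN | tanh hidden layers, linear output, weight decay 0.01, quasi-Newton (lbfgs) | layers 1–5 × neurons 1–10 | hidden (2, 4) |
| SVR | RBF kernel, epsilon 0.01 | gamma 0.5–4, cost 0.5–8, step 0.5 | gamma 0.5, cost 4 |
| RF | bagged trees | mtry 1–p, ntree 100–2000 step 100 | mtry 13, ntree 1200 |

The BPNN optimiser approximates Levenberg–Marquardt training with a
standard quasi-Newton method plus weight decay; the contract is the
architecture and regularisation, not the optimiser brand. The
architecture grid enumerates per-layer-independent neuron counts
(default capped at two layers, 110 architectures, since the count grows
as 10^L; the (2, 4) optimum is expressible) or equal-width layers for
all five depths (`mode="equal"`, 50 architectures).

Grid search is exhaustive k-fold CV (default 10-fold, interpreting
"cross-validating 10 times" as 10-fold) minimising mean RMSE, ties to
the earlier grid point, winner refitted on all data. Everything is
seeded; reruns are bit-identical. The 70/30 split takes
`ceil(0.7 n)` training rows from a seeded permutation (91 sites →
64/27).

## Accuracy metrics and experiments

`R² = 1 − Σ(Sᵢ−S′ᵢ)²/Σ(Sᵢ−S̄)²` with S̄ the mean of the **measured**
values, and `RMSE = √(Σ(Sᵢ−S′ᵢ)²/n)`, reported as a fraction and in
percent. A `denominator="predicted"` switch centres the R² denominator
on the mean prediction for compatibility with a variant definition
occasionally seen in print; it is not the default because it is not the
coefficient of determination.

The sample-size sensitivity sweep draws `replicates` random training
subsets per size (30, 60, …, 270 — nine sizes) from a fixed pool,
refits each algorithm, and scores on a fixed validation set (the 30%
holdout). Replication (default 30) makes the plateau behaviour — steep
gains below ~120 samples, stabilisation beyond — statistically stable
enough to assert.

`run_experiment` composes four arms: `classic` (NDVI linear/quadratic
regression + dichotomy), `ml_4vi` (four regressors on NDVI/EVI/SAVI/
MSAVI), `ml_full` (on all 32 features), and `ml_selected_tuned`
(PI-RFE selection, then grid tuning on the selected subset). Dichotomy
endmembers come from the training NDVI (`ci95`), the literature preset,
or the simulation's true spectra (`"true"`, which makes the noiseless
NDVI-mixing configuration exactly invertible). Outputs are written with
fixed float formatting so a rerun under the same seed reproduces
byte-identical tables. A failing arm is logged and skipped; other arms
continue.

## Synthetic site generator

Per site: DEM ~ U(3000, 5000) m, slope ~ U(0, 45)°, aspect ~ U(0, 360)°;
latent cover `fvc = clip(Beta(2,2) + tilt, 0, 1)` where the tilt is
−0.3·z(DEM) − 0.12·z(slope) + 0.1·cos(aspect) — elevation engineered
as the dominant driver, matching the field finding the selection tests
mirror. The Beta(2,2) prior is a neutral choice; nothing in the public
record pins the real distribution of site cover.

Bands mix linearly: `b = fvc·veg_b + (1−fvc)·soil_b + ε`,
ε ~ N(0, band_noise_sd), clipped to [1e-4, 0.9999] to keep ratio
indices finite. Default endmember spectra give NDVI 0.88 (vegetation)
and 0.07 (soil), the magnitudes of 95%-interval endmember estimates for
this kind of study area. Two heterogeneity sources, both real features
of mountain grassland imagery, perturb the endmembers per site: soil
brightness varies multiplicatively (sd 0.2 — variable soil albedo is
the reason soil-adjusted indices exist) and the vegetation endmember
drifts with elevation (`veg_dem_effect` 0.35: red rises, NIR falls with
standardized DEM, the meadow-to-steppe transition), which couples
spectra and terrain in a way no additive model can fully represent.
The zero-noise affine-mixing contract (every band an exact affine
function of cover) is checked with both heterogeneity sources and the
band noise switched off. Band-space mixing is physically natural but
makes NDVI nonlinear in FVC; `mix_space="ndvi"` instead constructs
red/NIR so the resulting NDVI is exactly linear in FVC — separating
model error from code error in the dichotomy tests. Default
`band_noise_sd` is 0.01; the accuracy benchmarks use 0.05, a noise
level at which the topographic prior genuinely helps and the four-index
driving data are visibly inferior to the full feature set.

The selection benchmark is a separate, direct design: six informative
standard-normal features named after the usual suspects (dem the
strongest) with coefficients (1.0, 0.7, 0.6, 0.5, 0.45, 0.4), residual
sd 0.25, plus six noisy redundant copies and twenty Uniform(0,1) pure
noise columns, n = 270. Effects are deliberately well above noise: the
benchmark tests whether the selectors *work*, not whether they are
powerful at the detection boundary.

What the generators do not emulate: spatial autocorrelation between
sites, atmospheric/radiometric residuals, mixed pixels at class
boundaries in scenes, shadows and litter, and NDVI saturation at high
biomass. Passing tests therefore demonstrate algorithmic correctness
and the qualitative orderings under clean mixing assumptions, not
field-accuracy levels; published accuracy figures from real campaigns
are functions of their (unreleased) data and are not asserted anywhere
in this package.

One ordering deserves an explicit caveat. Because the generator mixes
spectra linearly in cover and its perturbations are smooth, ordinary
least squares equipped with the 22 vegetation indices — effectively a
rich basis expansion — is a near-optimal inversion model here, and the
test suite shows the forest does *not* systematically beat it, nor does
selection-plus-tuning beat the forest on the full set by more than
noise, even though both orderings are reported from real campaigns.
The corresponding two checks in the acceptance suite fail by design
rather than being weakened: they document that those advantages stem
from properties of real data (heavy-tailed heterogeneity, unmodelled
interactions, small samples) that a linear-mixing simulator does not
create. The robust orderings — the full multi-dimensional feature set
beating the four classic indices, and accuracy plateauing with training
size — hold in 20/20 seeds.

## Problem sizes used by the test suite and acceptance script

Benchmarks run at the study-like sizes (n = 270 sites, p = 32 features,
band noise 0.05, nine sweep sizes 30–270) with estimator settings
chosen for a single-CPU run: forests of 30–150 trees, 3–5 CV folds, and
1–2 permutation repeats inside the selectors; sweep replicates 10–30.
Defaults in the API remain the documented stock values (forest 100
trees, 10 folds, 10 repeats, Boruta max_iter 100).
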