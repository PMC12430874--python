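# Methods

## Scope and data model

`osiscan` estimates leaf nitrogen concentration (LNC, mg N g⁻¹ dry mass)
from canopy hyperspectral reflectance sampled at 1 nm over 350–1830 nm.
The core objects are a `SpectrumSet` (n samples × m bands of unitless
reflectance on a validated, strictly increasing wavelength grid), a
`TraitVector` of positive LNC values aligned by sample id, a
`ScreeningResult` (best band tuple, signed Pearson r, two-sided p, top-k
list) per index form, and a `MetricSet` (R², RMSE in mg g⁻¹, MRE in %).

## Preprocessing

**Replicate-scan reduction.** Field protocols collect ~9 consecutive scans
per quadrat and average them after discarding outliers "beyond ±3 SD".
Taken literally per band, that rule can never fire: with s scans the
largest attainable standardized deviation is (s−1)/√s (2.67 at s = 9), so a
plain z-score test at 3 SD is vacuous. The package therefore applies the
deviation test leave-one-out: each scan's value at each band is compared
with the mean and SD of the *other* scans, and a scan flagged at more than
5% of bands is dropped wholesale (downstream index evaluation needs
complete spectra, so exclusion is per scan, not per band). If the other
scans agree exactly (SD = 0), any real deviation flags the scan; a 1e-12
absolute tolerance absorbs floating-point noise so identical scans are
never flagged. All scans excluded is a degenerate-input error.

**Savitzky–Golay smoothing.** Window 9, polynomial order 2 by default
(configurable; window must be odd and exceed the order). Interior bands use
the standard least-squares convolution kernel; the first and last four
bands are fitted on the shrunken one-sided window with no padding, matching
common spectroscopy practice. Consequences tested: any quadratic spectrum
is reproduced to ≤ 1e-10 (edges included), the filter is linear, and grid
length/sample count never change. Output is clipped to the physical
[0, 1.2] ingestion range (1.2 tolerates calibration overshoot).

## Index families

Three registries hold the formulas; each entry is overridable at runtime so
an alternative literature reading is a one-line change.

- Empirical (fixed bands): DDI = (R749−R720)−(R701−R672);
  MNDSI = (R800−R680)/(R800+R680−2R445); DDn = 2R710−R660−R760 (the
  canonical double-difference definition with λ₁ = 710 nm, Δλ = 50 nm);
  RDVI = (R800−R670)/√(R800+R670); CI = (R675·R690)/R683²;
  MTCI = (R754−R709)/(R709−R681); Gitelson2 = (R687−R500)/R750.
- Two-band forms in free wavelengths i, j: SASI = 1.16(Rᵢ−Rⱼ)/(Rᵢ+Rⱼ+0.16);
  NDSI; TSI = 0.5[120(Rᵢ−R550) − 200(Rⱼ−R550)]; mSR = (Rᵢ−R455)/(Rⱼ−R455);
  mNDI = (Rᵢ−Rⱼ)/(Rᵢ+Rⱼ−2R455); RSI = Rᵢ/Rⱼ; DSI = Rᵢ−Rⱼ. The TSI
  constants assume reflectance as fractions, not percent.
- Three-band forms: RTSI = Rᵢ/Rⱼ/R_k parsed left-associatively as
  Rᵢ/(Rⱼ·R_k); DTSI = Rᵢ−Rⱼ−R_k; RDTSI = 1/Rᵢ−1/Rⱼ−1/R_k;
  RATSI = 1/Rᵢ+1/Rⱼ+1/R_k.

Divisions whose denominator magnitude falls below 1e-12 (and reciprocals of
reflectance below 1e-12) yield NaN for that sample — an undefined flag.
Flags propagate to screening, where the affected samples are dropped per
band combination rather than poisoning the whole search.

## Exhaustive correlation screening

For a form and a stride (a multiple of the grid step), every wavelength
combination on the strided grid — optionally restricted to a sub-range,
e.g. the red-edge/NIR window — is evaluated against the trait and its
Pearson r recorded. The optimum maximizes |r|; the signed r is reported, so
both positively and negatively correlated optima are found. p-values use
the t transform with n−2 degrees of freedom, two-sided, and no
multiple-testing correction is applied (the significance filter acts on the
selected winners only; this mirrors the screening tradition in this
literature and is a known caveat).

**Symmetry canonicalization.** Several forms are invariant (DTSI, RTSI,
RDTSI under j↔k; RATSI under any permutation) or sign-invariant (NDSI, DSI,
SASI, mNDI under i↔j) across band permutations, so permuted tuples have
mathematically identical |r| while their floating-point values differ by
ulps depending on evaluation order. A naive "largest |r|" rule would pick
an arbitrary permutation. The argmax and top-k therefore consider only the
lexicographically smallest representative of each symmetry orbit (i ≤ j,
k ≥ j, or i ≤ j ≤ k as appropriate), which makes the documented
lexicographic tie-break exact and the result platform-independent. The
dense pair r-matrix and the triad per-slice maxima are still computed over
all ordered tuples for visualization.

**Streaming triad search.** The full m³ cube is never materialized. All
four triple forms are separable per sample: additive
(X = s₁f(Rᵢ)+s₂f(Rⱼ)+s₃f(R_k) with f identity or reciprocal) or
multiplicative (X = Rᵢ·(1/Rⱼ)·(1/R_k)). For additive forms the correlation
over every triad reduces to column means, trait covariances and three m′×m′
Gram matrices of centered factors, assembled by broadcasting; for RTSI the
three required moment tensors (ΣX, ΣXy, ΣX²) are BLAS contractions of an
n×m′ factor matrix with an n×m′² outer-product block. Both routes agree
with a materializing "direct" route and with naive enumeration to ≤ 1e-12;
the direct route (NaN-aware, two-pass centered correlation) is used
automatically whenever a factor is undefined somewhere. Results are
invariant to the streaming chunk size. Combinations with fewer than 3
defined samples or (numerically) zero index variance are undefined and
skipped; if every combination is undefined the search raises a screening
failure. A `refine_triples` pass re-searches a ±5 nm stride-1 box around a
coarse optimum.

Default strides: 1 nm for pairs (2.2M combinations, seconds), 5 nm for
triads (~13M canonical combinations over 297 bands, seconds via the moment
routes). The
enumeration resolution of published searches is usually unstated; both
strides are configurable and a search sub-range can emulate a restricted
3D search.

## Dataset preparation

**Grubbs filter** (iterative, two-sided, α = 0.05): at each step
G = max|yᵢ−ȳ|/s is compared with
G_crit = (n−1)/√n · √(t²/(n−2+t²)), t = t₁₋α/(2n), n−2; the most extreme
sample is removed while G > G_crit. The iterative two-sided variant is the
one consistent with removing a small number of gross trait outliers before
splitting.

**Stratified split**: samples are binned into LNC quantile strata (tertiles
by default), a seeded shuffle within each bin allocates samples to the
modeling set, and per-bin quotas are rounded by the largest-remainder
method so the modeling count is exactly ⌊n·2/3⌋ — 44/22 at n = 66. Bins
collapse gracefully under tied quantile edges; one stratum reduces to a
simple random split.

**Combines**: 1 = significant empirical indices, 2 = significant 2D-OSIs,
3 = significant 3D-OSIs, 4 = 1∪2, 5 = 1∪3, 6 = 2∪3, 7 = 1∪2∪3, with column
order empirical → pair → triple in registry order. A `CombineSpec`
serializes to JSON and rebuilding the feature matrix from it is exact.
Screening runs on the modeling set by default (`screen_on="all"` screens
before splitting instead; which a given study used is often ambiguous).

## Estimators

Features are z-scored on the modeling set (transform reused on validation)
for the two networks; the forest takes raw features.

- **ELM**: hidden weights and biases ~ U[−1, 1] under a restart-specific
  child seed, sigmoid hidden layer (1000 units by default), output weights
  by least squares on the hidden matrix augmented with an intercept
  column (so constant targets are fitted exactly); 50 restarts, keeping the
  lowest training RMSE. With n_hidden ≥ n the model interpolates noiseless
  targets (training RMSE < 1e-6).
- **BPNN**: one tanh hidden layer (15 units), linear output, trained by
  L-BFGS (scikit-learn `MLPRegressor`); a quasi-Newton stand-in for the
  damped second-order schemes used in MATLAB-era studies, with seeded
  initialization and a 2000-iteration budget. Non-finite training
  predictions raise a training-failure error.
- **RF**: 100 bootstrap regression trees, variance-reduction splitting (the
  regression analogue of the impurity criterion named in the
  classification literature), OOB RMSE reported from the out-of-bag
  predictions.

Metrics: R² = 1 − SSres/SStot per subset (not squared Pearson),
RMSE = √(mean squared error), MRE = 100·mean(|y−ŷ|/y). Perfect predictions
give exactly (1, 0, 0); the mean predictor gives R² = 0; zero trait
variance or a zero observation make R²/MRE undefined errors in evaluation
(training-set summaries report NaN instead so degenerate fits remain
inspectable).

## Synthetic canopy generator

The generator is a smooth parametric curve, not a radiative-transfer code.
With u = LNC/50:

- visible baseline 0.16 + 0.10·exp(−((λ−560)/50)²), darkened by a pigment
  absorption profile (Gaussians at 670 and 450 nm) scaled by 0.55·u;
- logistic red edge with inflection 700 + 25u nm and 12 nm width;
- NIR plateau 0.40 + 0.10u, multiplied by water-absorption Gaussians at
  1450, 1200 and 970 nm;
- i.i.d. Gaussian band noise (default sd 0.005, the order of a
  well-calibrated field spectroradiometer's band-to-band scatter), clipped
  to [1e-4, 1] so reciprocal indices stay defined.

LNC is uniform over 15–50 mg g⁻¹ by default, a realistic jointing-stage
leaf range that keeps RMSE/MRE magnitudes comparable to field studies. At
zero noise the three nitrogen couplings are exactly monotone (680 nm
reflectance strictly falls, the continuum-removed 680 nm well depth
strictly grows, the red-edge inflection never moves left, the 760–900 nm
mean strictly grows with LNC); these are contract-tested pairwise.

`plant_index_signal` evaluates one chosen form/band tuple per sample and
maps it affinely (positive slope) onto the 15–50 mg g⁻¹ scale — Pearson r
is affine-invariant, so at zero trait noise the planted index correlates
exactly 1 — then adds Gaussian trait noise.

**What passing tests do and do not show.** The generator produces one
smooth spectrum family driven by a single latent variable, with independent
band noise. Real canopies add structural variation, soil and illumination
effects, water-status confounds, and spectrally correlated sensor noise;
near-perfect synthetic correlations (|r| ≈ 0.999) and validation R² ≈ 0.99
therefore demonstrate that the machinery is correct and self-consistent,
not that field accuracy of that magnitude is attainable (field studies of
this design report r ≈ 0.7 and validation R² ≈ 0.8). Recovery experiments
plant bands inside the red-edge/NIR window and screen at 1 nm: with
band-limited noise, an index even one band off the planted tuple
decorrelates sharply, so a coarser candidate grid that misses the planted
bands has no near-miss to find — recovery "within one stride" is only
meaningful when the planted bands lie on the candidate grid.

## Pipeline and reproducibility

`run_pipeline(RunConfig)` chains simulate/load → smooth → Grubbs → split →
screen (modeling set) → significance filter → Combines → 7×3 model grid,
writing every artifact plus a manifest (config hash, package and numpy
versions, per-stage wall time). All randomness — simulation, split, model
seeds — derives from the single config seed, and re-running a config
reproduces the metric grid exactly. The acceptance script runs this
pipeline at 1 nm pair / 5 nm triad strides on n = 66 and reports the best
|r| per family, the 44/22 subset sizes, and the validation metrics of the
RF × Combine 5 cell alongside the best validation R².

## Known limitations

- The generator's single latent variable makes all index families highly
  informative; it cannot probe which family *should* win on real data.
- No multiple-testing correction across the millions of screened
  combinations; screening p-values are descriptive.
- ELM with 1000 hidden units interpolates 44 training samples; its
  validation scores are the honest signal, and the restart selection uses
  training RMSE only.
- The BPNN optimizer is L-BFGS, not Levenberg–Marquardt; on these problem
  sizes both reach the stated capacity benchmarks, but iteration-for-
  iteration trajectories differ from MATLAB implementations.
- ASD binary parsing, detector-splice correction and radiometric
  calibration are out of scope; inputs are assumed calibrated reflectance.
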