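# Methods

`littersim` implements a multigaussian geostatistical analysis of two
correlated beach-litter variables — cigarette-butt and sharp-item densities
(items/m²) — on a 50 m × 150 m beach strip discretised into 1 m² cells.
This note records the model, the numerical choices, what the synthetic
generator does and does not emulate, and the known limitations.

## Coordinate and direction conventions

`x` is cross-shore (50 m), `y` along-shore (150 m); nodes sit at cell
centres in x-fastest (GSLIB) scan order. Azimuths are degrees clockwise
from "grid north" (+y), so azimuth 0° is the along-shore axis. The long
variogram range (84 m) lies along-shore, consistent with the along-shore
continuity visible in litter deposition on a linear beach.

## Normal-scores transform

Each variable is mapped to standard-normal scores by ranking with plotting
position `(r − ½)/n` (the GSLIB convention; the source analysis does not
state one). Count-derived densities tie frequently; ties are ordered by a
seeded shuffle and the table's raw column receives a jitter of order
`1e−9 × data range` so both table columns are strictly increasing and the
map is invertible. Back-transform is piecewise-linear inside the table.
Tails: below the table, linear decay clamped at 0 (densities are
non-negative); above it, hyperbolic extrapolation in probability,
`v = v_max ((1 − p_max)/(1 − p))^{1/ω}` with ω = 1.5, capped at
1.5 × the sample maximum. The cap bounds a physical quantity the data
cannot constrain; it nudges simulated grid means less than ~1% above the
survey mean in practice.

## Variography and the coregionalization model

Directional experimental (cross-)variograms use the classical
half-mean-squared-increment estimator over pairs within a lag tolerance
(default half the 1 m lag spacing) and an angular cone (default ±22.5°).
Empty bins are reported as missing, never imputed. Each bin also records
its pairs' mean absolute lag components along/perpendicular to the azimuth:
with strong anisotropy, a bin's pairs are not uniformly spread over the
cone (grid geometry concentrates them near the axis at long lags), and the
fit evaluates the model at this representative lag vector. Without the
correction, refits of the 84 m/27 m model from simulated fields were biased
high by ~10%; with it, bias is under 2%. A fast exact path
(`grid_variogram_set`) enumerates integer cell offsets for complete grids.

The model is a linear model of coregionalization: nugget plus one
anisotropic spherical structure, `Γ(h) = B₀ n(h) + B₁ Sph(r(h))`, with
geometric anisotropy `r = √((h_∥/a_max)² + (h_⊥/a_min)²)`. Fitting
minimises the pair-count-weighted squared misfit; for fixed ranges the
sills are a per-pair linear least-squares solve followed by projection of
each sill matrix onto the PSD cone (eigenvalue clipping), so the fitted
model is always mathematically valid; free ranges are optimised by
multi-start Nelder–Mead on log-ranges over that inner solve. The
reference model (`beach_litter_lmc`) carries the published sills
(nugget [[0.075, 0.02], [0.02, 0.115]], spherical
[[0.925, 0.77], [0.77, 0.885]]) and ranges 84 m/27 m; both matrices are
PSD.

## Turning-bands cosimulation

Each structure is simulated as independent scalar Gaussian fields combined
through a factorization `A Aᵀ = B` (eigendecomposition; eigenvalues in
[−1e−8, 0) are clamped to zero). Spherical fields use the spectral
(randomization) form of turning bands: `Σ_k w_k cos(⟨ω_k, x⟩ + φ_k)` with
L = 1000 lines by default. Frequencies are drawn from the spherical
covariance's 3-D radial spectral density — known in closed form because the
spherical model is the self-convolution of a ball indicator,
`f(u) ∝ (sin u − u cos u)²/u⁴`, `u = |ω| range/2` — via a tabulated inverse
CDF truncated at u = 400 (≈0.25% tail mass, i.e. a ≤0.0025 absolute
covariance error at sub-cell scales), then projected onto the simulation
plane, which yields exactly the planar spectral measure. Line amplitudes
are Rayleigh (`|N + iN|/√L`): conditional on the frequency draw the field
is then exactly Gaussian, and realization-level statistics (e.g. the
spread of the per-realization spatial variance) match a true Gaussian
random field, which equal deterministic amplitudes understate by half.
Anisotropy is handled by rotating/scaling coordinates to the unit-range
isotropic frame.

Conditioning uses the standard construction: conditional field =
unconditional field + simple cokriging of (data score − unconditional at
the data node), solved in a unique neighbourhood (all ≤ 530×2 data at
once; the Cholesky-factorised system and the weight matrix are built once
per survey and reused across realizations). Samples are snapped to their
grid node (the survey grid equals the simulation grid); duplicated nodes
are averaged with a logged warning. Because simple cokriging is an exact
interpolator and the data node's unconditional value is the grid value
itself, every realization honors the data to the back-transform round-trip
tolerance (~1e−9 relative). Ordinary cokriging (per-variable unbiasedness
constraints) is available for non-centred uses. A master seed spawns
per-realization streams, so any single realization is independently
reproducible.

## Risk products

Counts are densities × cell area (numerically equal on the 1 m grid). Per
realization, `CCI = total/area × K` and
`HII = (hazardous / log₁₀ total)/area × K`, K = 20, hazardous = sharp
items, total = both variables; the reported index is the mean over
realizations, with the across-realization SD as spread. The HII reading
follows the adopted grouping of the ambiguous published formula; the
alternative grouping (`hazard × log₁₀ total`) is selectable by flag.
Categories use the published bins (CCI: ≤2 Very Clean … >20 Extremely
Dirty; HII: 0 → I … >8 → V, with the printed one-decimal gaps closed as
half-open intervals). Node classification defaults to the E-type mean
surface; butts bins [0,1,2,6), sharp bins [0,1,3), all left-closed as
printed. The injury-risk exceedance map counts realizations **at or
above** 3 items/m² (the worked-example rule). Sector indices apply the
same formulas to sector totals; the area-weighted mean of sector CCIs
equals the global CCI exactly.

## Split-sample validation

200 of 530 samples (uniform random) condition a simulation at the 330
held-out locations. Reported per variable: the OLS regression of true on
estimated (realization-mean) values, and the accuracy plot — for nominal
p, the symmetric interval between the (1∓p)/2 ensemble quantiles (linear
interpolation of order statistics) and the fraction of locations whose
true value it covers.

Calibration of the intervals depends on which model conditions the
simulation. Normal-scoring studentizes the survey window, while any single
window of a long-range field realizes less than the ensemble variance; a
model with the generator's unit sills therefore over-disperses the
ensembles (observed over-coverage up to ~0.15). Refitting the sill
matrices to the training scores — the field workflow, where the variogram
is always fitted to the data — restores coverage to within ~0.05 of
nominal. The pipeline's `model_source="fit"` option does this; the risk
indices are insensitive to the choice.

## The synthetic generator

No raw survey exists, so a generator emulates the study conditions:
530 samples drawn uniformly without replacement from the 7500 cell
centres of a simulated truth. Marginals are lognormal — the published
quartiles/maxima are strongly right-skewed on positive support; the family
itself is this package's choice — calibrated by method of moments to means
3.57/2.39 and SDs 4.0/2.4 (σ² = ln(1+(sd/mean)²), μ = ln mean − σ²/2).
The truth is an unconditional Gaussian cofield with the reference spatial
structure mapped through the lognormal quantile transform. Because the
back-transform attenuates correlation, the raw-scale target 0.87 requires
Gaussian-scale correlation ≈0.907 (closed-form inversion of the bivariate
lognormal correlation); by default the generator rescales the model's
cross-sills to that total (both rescaled matrices remain PSD), with the
published 0.79 cross-sill available by flag. An optional multiplicative
cross-shore trend on the mean (cleaner toward the ocean) is off by
default. The generator does not emulate: the real survey's spatial layout
(shown only graphically in the source), zero-inflation or discreteness of
counts, within-cell sampling error, or seasonal dynamics — so passing
tests demonstrate correctness of the machinery under the stated model, not
robustness to those real-data features.

## Monte-Carlo design of the reproduction experiments

The spatial ranges are comparable to the domain (84 m vs 150 m), so
single-realization statistics are far from ergodic: the domain-mean
density has relative SD ≈ 0.31–0.35 across generator seeds, and a single
field's fitted ranges scatter with relative SD > 0.5. The self-checks in
`littersim.experiments` therefore average:

* **Range recovery** pools directional variograms of 192 independent
  cofields before one fit (Monte-Carlo SD ≈ 3% per range). Along-shore
  lags run to 90 m — an 84 m range is not identifiable from the default
  50 m window — cross-shore to 45 m.
* **Survey correlation** averages 20 independent surveys.
* **Pipeline indices** average 24 antithetic pairs of full-pipeline
  replicates (fresh truth + 530-point survey + 100 conditional
  realizations each). Pairing each truth with its negated-Gaussian twin is
  unbiased — each member is a valid generator draw — and roughly quarters
  the replicate variance, leaving Monte-Carlo SEs of ≈0.2 (HII) and ≈2.4
  (CCI). Measured over replicates the estimators centre near HII ≈ 9.7 and
  CCI ≈ 111.

The pytest suite runs the same experiments at reduced sizes (16 pooled
fields, 5 antithetic pairs × 30 realizations) chosen to keep the default
run within minutes while retaining ≥2.5σ margins at the asserted
tolerances.

## Numerical choices and degenerate inputs

* Cokriging systems get no jitter; duplicated locations raise a
  `SingularSystemError` naming the offenders. Estimation variances are
  clamped at 0 against roundoff. In conditional simulation the residual
  krige is computed per realization as `kᵀ K⁻¹ r` through the factorised
  system (the covariance block `k` is built once per survey), rather than
  via a precomputed weight matrix.
* The turning-bands harmonic sum is evaluated in single precision (phase
  error ~1e−3 rad at the highest tabulated frequency — far below Monte-Carlo
  noise); all draws, kriging solves and transforms are double precision, and
  conditioning exactness cancels algebraically regardless.
* `fit_lmc` reports under-determined templates (`FittingError`) instead of
  silently regularising; empty variograms warn and carry NaN bins.
* All-equal value vectors cannot be normal-scored (`DegenerateInputError`);
  a zero-sill model yields a constant field at the marginal median.
* Seeds: every public stochastic entry point takes an integer seed;
  derived streams use `SeedSequence` spawning, and pipeline outputs are
  byte-identical across reruns of the same config.

## Known limitations

* The multigaussian assumption cannot represent, e.g., destructuring of
  extremes or asymmetric spatial connectivity of high/low litter zones.
* The spectral turning-bands field is Gaussian only conditionally on its
  L frequency draws; with the default L = 1000 the residual
  non-Gaussianity is far below Monte-Carlo noise in all checks, but exact
  multivariate Gaussianity (as from dense factorization) is not claimed.
* Unique-neighbourhood cokriging scales as O((2n)³) in the sample count —
  ample for 530 points, unsuitable for surveys orders of magnitude larger.
* Indices computed on the synthetic stand-in inherit its ~30% single-run
  fluctuation; only replicate averages are comparable to the published
  point values.
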