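# Methods

`nirdry` calibrates the moisture (and thereby the aging time) of drying
dairy residues from near-infrared absorbance spectra. Because the
measured datasets such studies produce are rarely archived, the package
pairs every estimator with a synthetic-study generator that reproduces the
statistical structure the estimators assume, so the whole pipeline can be
exercised, tested and benchmarked end to end.

## The synthetic drying study

### Drying kinetics

Moisture follows first-order thin-layer drying,

    M(t) = M_eq + (M_0 − M_eq) · exp(−k t),

with `M` expressed as remaining water in **% of the fresh mass**. With the
default rate constants (`k ≤ 0.08 / h`) the curve is nearly linear over the
first 4 h (a least-squares line explains ≥ 99 % of its variance), which is
what makes aging time recoverable from moisture in the fresh regime.

Per food type the defaults are chosen to match the gravimetric reference
values of the emulated campaign (mean initial moisture and its
across-sample spread) and the qualitative drying behaviour (yoghurt loses
water fastest late in the run):

| food type         | M₀ mean (%) | spread (%) | k (1/h) | M_eq (%) |
|-------------------|------------:|-----------:|--------:|---------:|
| chocolate pudding |        71.4 |        5.6 |   0.040 |      5.0 |
| vanilla pudding   |        74.6 |        4.4 |   0.045 |      5.0 |
| yoghurt           |       86.97 |        1.7 |   0.080 |      4.0 |

Compositions are the per-food means of the nine declared samples bundled in
`nirdry.fixtures`.

### Study design

The default design mirrors the emulated campaign's accounting: 9 sample IDs
(3 per food type), 3 physical dishes per sample tracked through 17 time
steps of 0.5 h (so the series spans 8 h), and 5 NIR measurement points per
dish and time step. That yields 255 raw spectra per sample ID (2295 in
total) and, after averaging the points of each dish, 51 per ID, 153 per
food type and 459 overall. Dishes are *persistent*: each draws one initial
moisture and one fresh mass, so its moisture declines strictly
monotonically across time steps.

Each dish-time-step record carries masses that are exactly consistent with
the gravimetric formulas: `m2 = m0 (1 − M₀/100)` and
`m1 = m2 + m0 · M(t)/100`, hence `(m0 − m2)/m0·100` recovers the initial
moisture and `(m0 − m1)/m0·100` the weight loss `M₀ − M(t)`.

### Spectra

A spectrum is a sum of Gaussian absorption bands on the 256-point grid
(1100 nm start, 4.27 nm step; the grid is defined by `(start, step, n)` and
ends at 2188.85 nm), plus a cubic baseline drift and noise. Water
dominates through bands at 1300 nm and 1700 nm whose amplitudes are
proportional to the moisture fraction; fat, sugar and protein contribute
smaller bands at 1210, 1440 and 2050 nm proportional to their declared
mass fractions. Point noise is Gaussian and heteroscedastic with SD
`0.002 + 0.02 · moisture/100` absorbance units — fresher (wetter) samples
are noisier — and each dish measurement adds a flat offset shared by its
five points, drawn with the same SD (a 1:1 dish-to-point variance ratio),
which is what makes per-dish averaging meaningful.

Randomness splits deterministically from one master seed:
`SeedSequence(master_seed, spawn_key=(sample, dish))` for dish-level draws
and `spawn_key=(sample, dish, timestep)` for measurement-level draws, so
any dish can be regenerated in isolation.

### What the generator does *not* emulate

No skin formation or diffusion-limited drying (the thin-layer closed form
only), no instrument line-shape or wavelength-registration error, no
scattering/particle-size effects beyond the additive baseline, and band
amplitudes that are exactly linear in composition. Real spectra are less
linear and more collinear; passing tests on this generator demonstrate the
correctness and self-consistency of the estimators, not their field
accuracy on a physical spectrometer.

## Preprocessing

The PLS pipeline applies, in order: Savitzky-Golay smoothing (window 7,
polynomial order 3), iterative polynomial baseline correction (order 3),
and SNV. SNV runs last so every spectrum enters the regression with mean 0
and SD 1; the stage order is configurable and recorded in the dataset
provenance. Design details:

* **SNV** uses the population (1/N) standard deviation; constant spectra
  are rejected as degenerate.
* **Savitzky-Golay** interior points use the classical fixed convolution
  (weights `(−2, 3, 6, 7, 6, 3, −2)/21` for 7/3); edge points are fitted on
  the truncated one-sided window with the polynomial degree capped at the
  window size minus one — no padding, so the filter remains linear and
  exactly reproduces cubics at interior points.
* **Baseline correction** is the modified-polyfit scheme: fit, clip the
  working spectrum to the elementwise minimum of itself and the fit,
  repeat. Convergence is declared when the relative L2 change of the
  coefficient vector drops below `tol` (default 1e-4, measured against the
  previous iteration's coefficients, initialized at zero — so a huge
  tolerance stops after one plain least-squares fit). Non-convergence
  within `max_iter` returns the partial result flagged `converged=False`.
  The min-clipping scheme carries a small downward bias under broad peaks
  (a few percent of the baseline RMS when peak widths approach a tenth of
  the spectral span); for narrow peaks it recovers a known cubic baseline
  to better than 2 % RMS off-peak.
* **Min-max scaling** for the neural networks uses one global (min, max)
  pair per dataset, stored for the inverse transform. Targets are scaled
  the same way, so all reported RMSE values are on the [0, 1] normalized
  moisture scale (the scale on which error magnitudes of ~0.1 are
  meaningful); physical-scale errors follow by multiplying with the
  moisture range.

## PLS1 calibration

The calibration model is `y = X b + e` fitted with Helland's PLS1: the
weight vector of each component is the covariance direction `Xᵀy`
(normalized), the score its projection, and X and y are deflated by the
score before the next component. Predictors are column-centered and the
response centered; no unit-variance scaling is applied because SNV already
standardizes each spectrum. The regression vector is
`b = W (PᵀW)⁻¹ q`, and prediction is affine,
`ŷ = (x − x̄)·b + ȳ`. The implementation is validated against an
independent NIPALS implementation and, at full rank, against the ordinary
least-squares normal equations.

Data are split once into 75 % calibration / 25 % validation with a seeded
permutation. The latent-variable sweep performs a single Helland pass at
the maximum count (components are nested) and reports RMSEC, RMSEV, R² and
adjusted R² (`1 − (N−1)/(N−p−1)(1−R²)`) per count; the sweep's default
upper bound is `min(100, rank)`.

## Neural regressors

Three architectures map the 256-point spectrum to one output:

* **ANN** 256 → H → 1 (one hidden layer);
* **DNN** 256 → H → H → H → 1 (three equal hidden layers);
* **CNN** 256 → conv1d (F filters, kernel 5, valid mode, stride 1) →
  flatten → D → 1.

Hidden activations are ReLU (slope 1 by default, configurable); the output
node is linear. Weights are He-initialized (`σ = √(2/fan_in)`; the conv
kernel uses its kernel size as fan-in) and biases — included although a
minimal formulation can omit them — start at zero. Training minimizes the
batch mean-squared error with exact reverse-mode gradients, mini-batches of
32, and Adam (η = 1e-3, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) by default; plain
SGD is available. Epochs default to 200, satisfying the at-least-100
training protocol. Everything is deterministic for fixed seeds, and a
non-finite loss raises an error carrying the epoch index. A learning rate
of zero is accepted as the degenerate no-op configuration (useful as a
training-loop contract check).

Size sweeps default to 100–1000 hidden nodes in steps of 100 for the dense
networks and 2–18 filters in steps of 2 (nine configurations) for the CNN.

## Cross-method comparison

The bundled comparison evaluates PLS, ANN, DNN and CNN per food type on
the dish-averaged dataset with the min-max-normalized moisture target.
Every method enters at its sweep-optimal configuration per food type: PLS
re-sweeps latent variables per seed (it costs one decomposition), while
each network's size is selected once per food type by a selection sweep at
100 epochs over a coarse five-point subsample of its standard grid
({100, 200, 400, 700, 1000} nodes; {2, 6, 10, 14, 18} filters) — the
package's tractability choice for the bundled experiment; the full grids
remain available through `architecture_sweep` and the `sweep-nn` command.
The selected size is then trained per seed at the full epoch count.

Per-method metrics are averaged over seeds within each food type, then
aggregated across the (three) food types as arithmetic mean and population
SD, and methods are ranked by mean validation RMSE. Aggregation is a pure
function of the recorded per-food metrics; re-reporting never re-trains.
Calibration and validation statistics are kept separate throughout.

## Problem sizes and numerical choices

The bundled experiments run on the default synthetic study: 2295 raw
spectra, 459 after dish averaging, 153 per food type (~115 calibration /
38 validation per split). The comparison uses 5 seeds at the default
200-epoch training protocol; the standalone PLS analyses sweep 30 latent
variables. Ties in the
latent-variable and size selections resolve to the smaller model (first
minimum). Degenerate inputs (constant spectra for SNV, zero-variance
responses, rank-exceeding component counts, constant datasets for min-max)
raise explicit `ValueError`s rather than returning NaNs.

## Known limitations

* The generator's band model is linear in composition; it cannot produce
  the nonlinear matrix effects that motivate neural models on real data,
  so relative method rankings on synthetic data are indicative, not
  conclusive.
* The modified-polyfit baseline has the broad-peak bias noted above.
* Networks train on a single CPU in numpy; the implementation favours
  clarity and exactness (loop-oracle-verified forward passes, finite-
  difference-verified gradients) over large-scale performance.
* The moisture-vs-weight-loss bookkeeping assumes no solids are lost
  during drying; `residual_other` can legitimately be negative and is
  returned unclamped to flag declaration/measurement inconsistencies.
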