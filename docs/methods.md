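# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the `enose` package.

## The measurement model

Each channel of the instrument is a metal-oxide-semiconductor (MOS) gas
sensor read through a load-resistor voltage divider. With supply `v_cc`
(default 5 V, a config value — the divider supply is an assumption of this
package, not an instrument fact) and load `R_L = 10 kΩ` on every channel,

    v_out = v_cc · R_L / (R_L + Rs),        Rs = R_L · (v_cc − v_out) / v_out.

`Rs` falls as the reducing-gas (here: ethanol headspace) concentration rises,
so `v_out` rises with concentration. `Rs` also drifts with ambient
temperature `x0` (°C) and relative humidity `x1` (%). Each sensor carries a
quadratic ambient polynomial fitted (upstream of this package) to its
datasheet characteristic curves:

    D(x0, x1) = α0·x0 + α1·x0² + β0·x1 + β1·x1² + δ·x0·x1 + ξ,

and the compensated feature is `y = Rs / D(x0, x1)`. The 13 channels and
their constants ship as a versioned CSV (`enose/data/sensor_registry.csv`)
asserted bit-exactly by the tests; the registry's `fit_r2` column is
metadata only — no datasheet refitting happens here. The full six-term
polynomial is always evaluated even where `β1` and `δ` are zero. `D` is
strictly positive over the operating box 20–35 °C × 20–60 %RH for every
bundled sensor (asserted by grid scan); outside it `D ≤ 0` is possible
(e.g. TGS2603 near 100 °C) and compensation raises rather than returning a
negative resistance.

## Signal preprocessing

1. **Warm-up trim** (`trim_warmup`, default 0 s): drops records with
   `t < warmup_s`. The simulator already excludes the preheating interval
   (see below), so the default pipeline trims nothing; the knob exists for
   real recordings that include the transient.
2. **σ-gated moving average** (`gated_moving_average`, window 50, gate 3σ):
   a causal (trailing) window of up to 50 raw samples; the mean μ and
   population σ are computed on the full raw window, then only samples with
   `|p − μ| ≤ 3σ` enter the unweighted average. A single gating pass is
   used (no re-iteration). The window is causal because the instrument
   filters in real time; centered filtering would be equally defensible
   offline. Filtering is applied to voltages, before the divider inversion.
   An exactly constant window returns the constant itself (a floating-point
   mean of identical values can differ in the last ulp).
3. **Compensation**: divider inversion then division by `D` with each
   record's own (T, RH).
4. **Min–max normalization** per channel, `p ↦ (p − min)/(max − min)`, with
   the state frozen on the **entire calibration set**. Test features are
   never clipped and may fall outside [0, 1]; a constant channel raises
   `DegenerateFeatureError` naming the channel rather than silently
   emitting zeros. Freezing the calibration state is required for
   test-time prediction to be well-defined; normalizing calibration and
   test jointly would leak test information into the transform.

## The four regressors

All four consume the same pruned, normalized feature matrix and predict the
ethanol volume fraction (% v/v) per record.

* **MLR** — OLS with intercept (statsmodels). Reports R² and
  R²adj = 1 − (1−R²)(n−1)/(n−p−1).
* **MNLR** — OLS after `x ↦ log(x + c)` on every predictor. The sensor
  response saturates at high alcohol content, which the log linearizes;
  transforming the response instead is a config switch
  (`mnlr_transform="response"`). The offset defaults to `c = 0.1`: small
  enough to retain curvature on the normalized [0, 1] range, large enough
  that test features slightly below the training minimum (they are not
  clipped) cannot cross the log-domain boundary at realistic noise levels.
* **ELM** — single hidden layer, input weights and biases drawn once from
  Uniform(−1, 1) with a fixed seed and frozen; 15 hidden units; identity
  ("purelin") activation by default (sigmoid/tanh available); output
  weights are the minimum-norm least-squares solution `pinv(H)·y` with a
  relative singular-value cut of 1e−10. Minimum-norm matches the ELM
  literature's preference for small output weights. With identity
  activation and a hidden matrix of full affine rank, the ELM is exactly
  the least-squares affine predictor, i.e. prediction-equivalent to MLR —
  a cross-model oracle the tests exercise on every simulated dataset.
* **RF** — scikit-learn `RandomForestRegressor`: 500 trees, 4 candidate
  predictors per split, bootstrap resamples of size n, leaf minimum 5, no
  depth cap and no pruning. Leaf minimum and bootstrap size are common
  defaults, not instrument facts. A single deterministic tree (1 tree, all
  features, no bootstrap) is checked against a brute-force exhaustive-split
  CART oracle.

**Significance pruning** fits OLS of the target on all 13 channels plus
intercept and removes channels whose coefficient t-test p-value (equivalent
to the 1-df partial F-test, 95 % confidence) exceeds α = 0.05. The pruned
set is computed once on calibration features and shared by all four models.
Applying the same rule to the bundled reference p-value table from the
physical prototype (`enose/data/reference_sensor_pvalues.csv`) removes
MQ-135 and TGS822, leaving 11 channels. On simulated data the retained set
varies with the noise realization — every simulated channel genuinely
responds to ethanol, but the channels are strongly collinear, so individual
coefficients can lose significance jointly; that is the same mechanism by
which the physical instrument's redundant channels were pruned.

## Evaluation

* **10-fold cross-validation**, record-level, seeded shuffle; the pooled CV
  RMSE is the RMSE over the concatenated held-out predictions, not the mean
  of per-fold RMSEs. Record-level folding leaks within-measurement
  autocorrelation: adjacent seconds of the same measurement land in
  different folds, so flexible models (RF especially) show optimistic
  validation RMSE. A grouped, measurement-level CV (`CVConfig(grouped=True)`)
  is provided; the default stays record-level because each 1-second record
  is treated as one example throughout.
* **Per-beverage aggregation** is the arithmetic mean of record-level
  predictions pooled over both bottles (the aggregation rule is this
  package's choice).
* **Percent error** `|pred − labeled| / labeled × 100`; the per-model
  summary is the unweighted mean over the seven beers.
* **Tolerance flag**: `|pred − labeled| ≤ 0.5 % v/v`, the normative
  labeling tolerance for beer; the boundary is inclusive.

## The synthetic-data generator

The generator emulates the calibration/test protocol so that every claim
the pipeline makes is falsifiable without laboratory recordings: 15
ethanol/water standards (1, 1.5, 2, 2.5, 3, 3.5, 3.7, 3.9, 4.1, 4.3, 4.5,
5, 5.5, 6, 8 % v/v), six experiments (two each at 25 °C/33 %, 25 °C/27 %,
27 °C/31 %RH — both same-day experiments share the day's conditions), 8 min
per measurement at 1 Hz (480 records per measurement, 2 880 per
concentration, 43 200 total), and a test campaign of 7 beers × 2 bottles at
30 °C/41 %RH (14 measurements, 6 720 records).

The per-channel forward model is

    R_obs(t) = r0 · (1 + k·c)^(−γ) · D(T, RH) · (1 + e^(−(t+warmup)/τ)) · ε_t,

converted to voltage through the divider.

* **Power-law concentration response** `(1 + k·c)^(−γ)` is standard MOS
  behavior. Per-channel `(r0, k, γ)` defaults were chosen once for realism:
  MQ-3 is the most sensitive channel and its steady-state voltage walks
  from ≈0.76 V at 1 % to ≈2.0, 2.7 and 3.2 V at 3.9, 6 and 8 % — the
  qualitative progression a bench operator sees on the physical sensor.
  MQ-135 and TGS822, the channels the physical instrument found
  uninformative, get the weakest response; MQ-9, whose target-gas list
  omits ethanol, responds weakly through cross-sensitivity. These defaults
  are config, not instrument facts.
* **Ambient confounding** enters multiplicatively as the sensor's own
  compensation polynomial `D(T, RH)`, which makes the compensation stage
  exactly invertible: at zero noise, compensated features from runs at
  different conditions agree to ≲1e−8 relative, and that invariance is an
  acceptance check. This is a deliberate idealization — real ambient drift
  is only approximately multiplicative and only approximately matches a
  datasheet fit.
* **Warm-up** is first-order with τ = 120 s. The protocol's ~10-minute
  preheating (`warmup_s = 600`) elapses *before* recording starts: the
  transient is evaluated at `t + warmup_s`, so emitted measurements carry
  only its residual tail and the per-measurement record count stays 480.
* **Noise** is multiplicative log-normal on resistance (resistances are
  positive); additive Gaussian on voltage is an option. The default
  `noise_sd = 0.06` (6 % per reading, log scale) was calibrated so that
  record-level prediction scatter after window-50 smoothing is of the same
  order as the physical instrument's reported test errors, while per-beer
  aggregate errors stay inside the ±0.5 % v/v norm.
* **Beverages**: non-ethanol volatiles are lumped into a single
  `voc_multiplier ≥ 1` on the concentration the sensors see. The default
  panel gives the dark malt beer C4M a multiplier of 1.15, so it reads high
  on every model — the same signature the physical instrument showed —
  while all other beers carry multiplier 1. No chemical speciation of
  esters/aldehydes, no chamber-diffusion or airflow physics, and no sensor
  aging or poisoning are modeled. Pressure is recorded as a covariate but
  ignored by the analysis.
* **Determinism**: each measurement draws from `default_rng([seed, stage,
  index])`, so equal (seed, design, config) reproduce byte-identical
  datasets.

Because the generator satisfies the pipeline's assumptions by construction,
passing tests demonstrate the *internal correctness* of every stage (the
compensation inverts the confounding it was designed to remove; the models
recover the true contents), not field performance on real beer headspace.

## Numerical choices and degenerate inputs

* Rank decisions use a relative singular-value cut of 1e−10 (shared with
  the ELM output solve). At zero noise the 13 smooth power-law channels are
  *numerically* collinear (smallest relative singular value ~1e−17, the
  same order as an exactly duplicated column), so `fit_mlr` defaults to
  raising `CollinearityError` but accepts `rank_check=False` to solve by
  minimum-norm pseudoinverse; zero-noise recovery checks use that path.
  Significance testing has no such escape: t-tests are undefined at zero
  residual variance, and noisy (full-rank) data is required.
* The gated filter guards the (only possible for gate < 1σ) empty-gate case
  by falling back to the plain window mean.
* Voltage readings at or beyond the supply rails raise
  `InvalidReadingError`; ambient conditions where `D ≤ 0` raise
  `AmbientEnvelopeError`; schema violations name the offending column or
  measurement.
* `percent_error` requires a positive labeled content.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full study scale — one
complete 43 200-record calibration campaign and 6 720-record test campaign
with all four models and 10-fold CV — once each; stage-level oracles run on
reduced designs (fewer standards, shorter measurements) or small Gaussian
instances, and the ten-seed recovery check uses MLR and ELM only, whose
fits are closed-form. The permutation oracle uses 10 000 draws at n = 30;
the type-I calibration uses 200 replicates of a 100 × 13 null design.

## Known limitations

* The generator's idealizations above: anything they exclude (drift,
  cross-sensitivity chemistry, airflow) is untested here.
* Record-level CV leakage (see Evaluation) makes validation RMSEs
  optimistic for flexible models; compare with `grouped=True` for honest
  generalization-across-measurements numbers.
* MNLR's log transform acts on normalized features, so its curvature
  depends on the normalization state; the `log_offset` default is tied to
  the [0, 1] feature scale.
* The ELM hidden layer is useful exactly insofar as its activation is
  nonlinear; with the default identity activation it is a (deliberately
  redundant) re-parameterization of MLR, kept because it mirrors the
  instrument's configuration and provides a cross-model oracle.
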