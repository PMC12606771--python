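# Methods

This note documents the models, the synthetic data process, the numerical
choices, and the limitations of `hutchcast`. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute themselves.

## Problem setting

Enclosed rabbit houses are regulated through ventilation, evaporative
cooling and heating, all of which act with delay (thermal inertia,
residual evaporation). Forecasting indoor temperature, relative humidity
and CO₂ concentration over a horizon of one to a few hours turns reactive
control into anticipatory control. The forecasting problem is multivariate
and multi-step: from N past 10-minute steps of six channels — indoor
temperature (°C), indoor RH (%), indoor CO₂ (ppm), indoor wind speed
(m/s), outdoor temperature (°C), outdoor RH (%) — predict the next H steps
of the first three (the targets). Wind speed and the outdoor channels are
auxiliary drivers: predictively useful, never predicted.

## Preprocessing chain

Raw loggers sample once per minute and exhibit two artifact kinds:
transient spikes (sensor faults) and missing spans (power/network loss).
The chain is:

1. **Outlier masking.** Centred sliding window (default 61 points ≈ 1 h),
   robust z-score |x − median| / (1.4826·MAD), threshold 3.0; flagged
   points become missing. The window median tracks the diurnal trend, so
   genuine slow variation is not flagged; MAD makes the scale estimate
   immune to the spike itself. The defaults are exposed on the CLI. Edge
   points reuse the nearest full window rather than a truncated one.
2. **Gap imputation.** Missing runs of n points with valid neighbours y₁,
   y₂ and duration ≤ 60 min are filled linearly,
   y_k = y₁ + k/(n+1)·(y₂−y₁). Longer runs — and runs touching either end
   of the series — are not imputable and become *segment breaks*; no
   training window may span one. The 60-minute bound is the longest span
   over which linear interpolation of a diurnal signal stays defensible.
3. **Down-sampling.** Non-overlapping 10-point block means reduce the
   interval to 10 min (block-start timestamps, trailing remainders
   dropped, segments preserved). Block means — rather than a stride-1
   sliding mean, which would not change the interval — both smooth local
   fluctuation and deliver the coarser grid that control decisions use.
4. **Normalization.** Per-channel min–max scaling
   x′ = (x − xmin)/(xmax − xmin + 10⁻⁷), fitted on the training portion
   only (no leakage). The 10⁻⁷ guard makes constant channels map to 0
   instead of dividing by zero; the transform is inverted exactly before
   any metric is computed (round-trip error ≤ 10⁻⁹ relative, tested).
5. **Split and windows.** Contiguous chronological 6:1:3
   train/validation/test split; train and validation sizes round half-up,
   the test set takes the remainder (7548 rows → 4529/755/2264). Stride-1
   windows of N inputs and H following targets, each wholly inside one
   segment.

## Network

See the README for the architecture summary. Design points that were
genuinely open, and how they were resolved:

- **Patch length L.** Default 12 (= 2 h of 10-min steps, the operational
  forecast horizon). When N < L, L falls back to N (single patch); L must
  divide N otherwise, and the error lists the valid lengths.
- **Aggregator scoring.** The additive-attention score is a scalar per
  token: e_tj = tanh(w_e·[h_{t−1}; p_j]) with a single learned row vector
  w_e, since the softmax runs over tokens and therefore needs scalar
  logits. The readout is the weighted sum Σ_j α_tj p_j, the standard
  additive-attention readout.
- **Recurrence length.** One GRU step per token (k+1 steps), patches in
  temporal order with the global token last, h₀ = 0. With the aggregator
  ablated, step t consumes token t directly.
- **Layer stacking.** "Encoder layer" means the full block
  (aggregator+GRU → cross-attention → add&norm → FFN → add&norm), stacked
  `n_layers` times; layer l+1 consumes layer l's k+1 output vectors as its
  token set. All three target channels share the temporal-encoder weights
  (bounded parameter count; per-channel token sets keep channels
  separate), and are folded into the batch axis for efficiency.
- **Cross-attention details.** Scaled dot-product with √d_k scaling,
  single head by default (configurable), learned Q/K/V/O projections,
  post-norm residual placement. With the flag off, the queries are
  layer-normalized and the auxiliary path is skipped entirely (its
  parameters are never created — every ablation strictly reduces the
  parameter count, which the tests assert).
- **Initialization and loss.** Uniform fan-in scaling U(±1/√fan_in),
  seeded; biases and layer-norm offsets start at 0, gains at 1. The loss
  is the sum over the three targets of per-target MSE on the normalized
  scale.

Defaults follow the published training configuration: feature dimension
256, 3 encoder layers, Adam at 10⁻³, batch 128, 100 epochs. The weights
retained after training are those of the best-validation epoch (the
selection rule was unstated; best-validation is the conventional choice).
A reduced `SMOKE_PROFILE` (d = 32, 1 layer, 5 epochs, FFN 64) is the
problem size used by the heavy tests and the acceptance script; it is
small enough for a desktop CPU yet large enough for the architecture
ordering effects (full ≥ each ablation) to be visible on the synthetic
data.

### Autodiff engine

No deep-learning framework is a dependency; the models run on a ~300-line
reverse-mode autodiff core over NumPy (`hutchcast._autodiff`) providing
broadcasted arithmetic, batched matmul, tanh/sigmoid/relu/exp, reductions,
slicing, concatenation, softmax, layer-norm and Adam. Every operator is
gradient-checked against central finite differences in
`tests/test_autodiff.py`. Float64 throughout: the matrices are small, so
the numerical headroom costs little.

## Metrics

MAE and RMSE are the usual means over all forecast points of a target,
computed after inverting the normalization (a unit-range guard raises if
the targets still look normalized). R² is implemented in two forms:
the **standard** form 1 − Σ(y−y′)²/Σ(y−ȳ)² (default everywhere, can be
negative), and the **printed** explained-variance ratio
Σ(y′−ȳ)²/Σ(y−ȳ)² (selectable as `r2_form="printed"`), which can exceed 1
and is kept because published values may have used it; which form
produced the published R² values cannot be determined without the
original data. `improvement_pct` reproduces the two quoting conventions
used around the published tables: percentage decrease
100·(baseline−proposed)/baseline rounded to one decimal, and percentage
increase 100·(ablated−full)/full rounded to the nearest integer, both
round-half-up.

## Synthetic data generator

The generator is a first-class module, not a fixture: it defines the
study conditions under which the pipeline is validated.

- **Outdoor drivers.** Temperature is mesor + amplitude·sin(phase) with a
  15:00 peak plus stationary AR(1) noise (φ = 0.9 at 1-min steps); mesor
  and amplitude derive from the published seven-day-mean daily max/min of
  each region, so in the noise-free limit the seven-day pointwise mean
  attains those extremes exactly (the sine peak falls on the sampling
  grid for every step that divides 60 min). Outdoor RH runs in
  anti-phase. Regional presets: Fujian 30.15/23.51 °C and 98.09/74.25 %RH;
  Gansu 23.15/15.73 °C and 95.03/59.93 %RH; Henan 29.97/20.45 °C and
  97.15/67.26 %RH.
- **Indoor response.** Indoor temperature is a first-order lag filter
  (τ = 60 min) of outdoor temperature plus an offset, wind-speed coupling
  and AR(1) noise. Indoor RH couples negatively to the indoor-temperature
  anomaly (warmer air, lower RH) plus lagged outdoor-moisture ingress.
  CO₂ has a night-peaking cycle (ventilation scales with daytime heat)
  plus negative coupling to temperature and wind speed. Indoor levels are
  free preset parameters — the published indoor curves are figures, not
  tables — chosen once to respect the documented qualitative ordering:
  Fujian hottest, most humid, most tightly coupled; Gansu coolest, largest
  swings, highest CO₂, weakest coupling; Henan intermediate. Coupling
  signs force r(Tin, Tout) > 0 and r(Tin, RHin) < 0, which the tests
  check on generated data.
- **Artifacts.** Spikes displace ⌊rate·n_rows⌋ points by 6–8 *local*
  robust SDs (61-point window median/MAD at the injection site, with a
  floor for near-constant neighbourhoods), so a detector thresholding at
  3 robust SDs must recover them — making detector recall a sharp,
  testable quantity. Gaps mask every channel over the specified spans
  (power loss), and may not overlap the table end. Every artifact is
  logged exactly.

What the generator does **not** emulate: weather fronts and rain events
(non-sinusoidal outdoor excursions), management interventions (feeding,
cleaning, stocking changes), sensor drift and recalibration jumps, and
inter-sensor placement differences within a house. Passing tests
therefore demonstrate that the pipeline and architecture behave correctly
on data with the documented correlation and periodicity structure — not
that the published accuracy figures transfer to any real house.

## Experiment harnesses

All harnesses are deterministic functions of (config, seed).

- **Length sweep.** The published grid: N ∈ {6,12,24,48,72,96,144},
  H ∈ {6,12,24} — 21 experiments, reported as a tidy table with one row
  per (N, H, target). Cells whose split is too short for N+H are recorded
  with a skip reason rather than aborting.
- **Ablations.** Full model plus the three single-flag-off variants on
  identical windows and seeds; the table carries parameter counts.
- **Transfer.** Initializations: random, each single pretrain source,
  and the combined sources. Each is evaluated zero-shot on the target
  test set, then fine-tuned (all weights, same learning rate; freezing is
  a config option) on nested chronological prefixes of 10–60% (step 10%)
  of the target training windows — 4 × (1 + 6) = 28 evaluations per
  target. Fine-tuning restarts from the pretrained weights for every
  subset, so curves are comparable across fractions.

Acceptance-scale study conditions, fixed up front: 14-day Fujian-preset
series (1-min, then 10-min after down-sampling, ≈ 2016 rows), N = 48,
H = 12, smoke profile, 3 seeds with mean reporting for the
model-vs-persistence comparison and per-seed majority for the ablation
ordering. The 7-day variants used for harness-shape checks trade size for
speed; the 14-day set is required for the full sweep grid (the validation
split must hold at least one N=144, H=24 window).

## Degenerate inputs and tie-breaks

- Constant channel: normalizes to all-zeros (guard denominator); its
  Pearson correlations are NaN and flagged with a warning, never
  silently 0.
- Constant detector window (MAD = 0): nothing deviates robustly; the
  scale is treated as infinite and no point is flagged.
- Aggregator with a single token: α = [1], readout is the token itself.
- `epochs=0`: the model is returned unchanged; non-finite loss aborts
  with a diagnostic rather than continuing.
- Splits of fewer than 10 rows are refused.

## Known limitations

- The published absolute metric values were obtained on private
  multi-month farm records and cannot be reproduced here; the synthetic
  study validates orderings and behaviours, not absolute accuracy.
- The NumPy engine is single-device and eager; at the full published
  width (d = 256, 3 layers, 100 epochs) training is possible but slow —
  the defaults are faithful, the smoke profile is practical.
- Whether replicate indoor sensor groups should be averaged before
  modelling is unstated in the source protocol; the pipeline accepts one
  series per channel and a mean-of-replicates pre-step is left to the
  caller.
- The auxiliary-channel count is configurable (the source text is
  ambiguous between three and four); three is the default, matching the
  enumerated channels.
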