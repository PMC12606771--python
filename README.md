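# hutchcast

Multi-step forecasting of the microclimate inside enclosed rabbit houses.

Intensive rabbit farming regulates temperature, relative humidity and CO₂
concentration with fans, cooling pads and heaters, but thermal inertia and
residual evaporation delay the effect of every control action. Purely
reactive control therefore chases the environment instead of anticipating
it. `hutchcast` forecasts the three indoor targets — temperature (°C),
relative humidity (%), CO₂ (ppm) — several hours ahead from recent indoor
and outdoor sensor history, so control strategies can act on predicted
trends. It is aimed at agricultural-informatics researchers and engineers
building predictive environmental controllers for livestock housing.

## The model

Given N past steps of six 10-minute-resolution channels — the three
targets x₁..x₃ (indoor T, RH, CO₂) and three auxiliary drivers s₁..s₃
(indoor wind speed, outdoor T, outdoor RH) — the **PatchCrossFormer**
network predicts the next H steps of each target:

- **Patch + global embedding.** Each target series is cut into k = N/L
  non-overlapping patches of length L; each patch and the whole sequence
  are linearly projected to d-vectors, giving a token set
  {p₁, …, p_k, p_G} per channel with sinusoidal positional encodings
  (local trends + global context). Auxiliary channels are embedded along
  the channel axis, one token per channel.
- **Patch-Global Aggregator + GRU.** At each recurrence step t the
  aggregator scores every token against the previous hidden state,
  e_tj = tanh(w_e·[h_{t−1}; p_j]), softmax-normalizes the scores to α_t,
  and feeds the weighted readout p̃_t = Σ_j α_tj p_j into a GRU:
  z_t = σ(W_z[h_{t−1}; p̃_t]), r_t = σ(W_r[h_{t−1}; p̃_t]),
  h̃_t = tanh(W[r_t⊙h_{t−1}; p̃_t]), h_t = (1−z_t)⊙h_{t−1} + z_t⊙h̃_t.
- **Cross-attention fusion.** The temporal encodings query the auxiliary
  tokens (keys/values) through scaled dot-product attention,
  softmax(QKᵀ/√d_k)V, with residual connection, layer-norm, and a
  position-wise feed-forward block; this stack is the encoder layer,
  repeated `n_layers` times.
- **Per-target heads.** Three parallel linear layers map each target
  channel's flattened (k+1)·d encoding to its H-step forecast.

Every module has an ablation switch (`use_patch_encoding`,
`use_aggregator`, `use_cross_attention`). Three recurrent baselines (RNN,
GRU, LSTM; 3 layers × 256 tanh units) share the forward contract, and a
persistence predictor (repeat the last observation) is the naive
reference. Evaluation reports per-target MAE, RMSE and R² after inverting
the min-max scaling; training minimizes MSE with Adam
(lr 10⁻³, batch 128).

Since real multi-site rabbit-house records are not redistributable, the
package ships a synthetic generator whose regional presets reproduce the
published seven-day outdoor statistics of three climatically distinct
sites (Nanping/Fujian, Qingyang/Gansu, Jiyuan/Henan) together with
diurnal cycles, AR(1) sensor noise, cross-channel coupling, spike
outliers and missing spans — enough structure to exercise every stage of
the pipeline end to end.

The network runs on a small reverse-mode autodiff engine over NumPy that
is part of the package (`hutchcast._autodiff`), gradient-checked against
finite differences in the test suite.

## Worked example

```python
import hutchcast as hc
from hutchcast.experiments import prepare_windows, PersistencePredictor

# 14 days of synthetic 1-min Fujian-preset data
preset = hc.make_region_preset("fujian")
raw = hc.simulate_house(preset, hc.SimulationConfig(n_days=14, seed=1))

# clean -> impute -> 10-min down-sample -> 6:1:3 split -> windows
table = hc.downsample_mean(hc.fill_gaps(hc.detect_outliers(raw)), 10)
prep = prepare_windows(table, N=48, H=12)   # 8 h history -> 2 h forecast

cfg = hc.ModelConfig(N=48, H=12, seed=0, **hc.SMOKE_PROFILE)
model = hc.PatchCrossFormer(cfg)
hc.train_model(model, prep.train, prep.val, hc.TrainConfig(epochs=5, seed=0))

print(hc.evaluate(model, prep.test, prep.norm_state).to_frame())
print(hc.evaluate(PersistencePredictor(cfg), prep.test, prep.norm_state).to_frame())
```

Output (reduced `SMOKE_PROFILE` width, 5 epochs):

```
  target        MAE       RMSE        R2
0    Tin   0.252134   0.320276  0.976999
1   RHin   0.915555   1.131187  0.957060
2    CO2  37.597542  47.513605  0.950728
  target        MAE       RMSE        R2
0    Tin   0.553465   0.701934  0.889518
1   RHin   1.549914   1.964437  0.870501
2    CO2  60.469981  75.700892  0.874926
```

The trained model roughly halves the persistence baseline's 2-hour
temperature RMSE (0.32 °C vs 0.70 °C) and clearly beats it on humidity
and CO₂; R² ≈ 0.98 for temperature means the forecast explains almost all
of the diurnal variance in the synthetic house.

The same workflow is available from the shell:

```bash
hutchcast simulate --region fujian --days 14 --seed 7 --out sim.csv
hutchcast preprocess --in sim.csv --out clean.csv --norm-state norm.json
hutchcast train --data sim.csv --out-dir run/ --profile smoke --seed 0
hutchcast evaluate --data sim.csv --checkpoint run/model.npz \
    --norm-state run/norm_state.json --out-dir eval/
```

plus `sweep` (N×H grid), `ablate` (module ablations) and `transfer`
(cross-region pretrain/fine-tune). Every command writes a JSON manifest
sufficient to re-execute the run.

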