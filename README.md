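# incepspect

Quantitative near-infrared calibration pipeline for adulterated plant
powders: spectral I/O and reflectance/absorbance conversion, SPXY
calibration/prediction partitioning, MSC/SNV scatter correction, CARS/SPA
wavelength selection, PLSR/SVR baselines, and a family of 1-D convolutional
regressors — a multi-scale (Inception-style) network with channel/spatial
attention (CBAM) and a residual shortcut, plus two simpler deep baselines.
A built-in simulator generates mixture spectra with the same design
(4 adulterant series x 21 mass-fraction levels x 5 replicates = 420 samples
on a 213-point grid over 1000-2400 nm), so the whole pipeline is exercisable
without proprietary data.

The neural networks run on a small numpy reverse-mode autodiff engine that
ships inside the package (`incepspect.nets.autograd`) — no GPU framework is
required. Training is CPU-only, float32, and bit-reproducible for a fixed
seed.

## CLI

```bash
# synthetic dataset (CSV: sample_id, adulterant, target, <wavelengths...>)
incepspect simulate --out data.csv --seed 7 --noise-preset default

# SPXY partition (per adulterant, 8:2), sample_ids per subset as JSON
incepspect split --in data.csv --fraction 0.8 --per-adulterant --out split.json

# CARS or SPA wavelength selection
incepspect select --method cars --in data.csv --seed 1 --out vars.json

# train a network on the calibration subset
incepspect train --arch incepspect_cbam --variant full --in data.csv \
    --split split.json --seed 1 --out model_dir/

# full experiment matrix from YAML (models x strategies x scopes)
incepspect run --config experiment.yaml --out results/
```

Example `experiment.yaml`:

```yaml
simulator_seed: 0
models: [plsr, svr, incepspect_cbam]
variants: [full, no_cbam]
strategies: [raw, snv+cars]
scopes: [combined]
seed: 0
compute_rmsecv: false
net_config:
  max_epochs: 100
  patience: 25
```

## Library sketch

```python
from incepspect.simulate import simulate_dataset, NoiseModel
from incepspect.preprocess import split_multi, minmax_fit, minmax_apply
from incepspect.nets import NetConfig, fit_net, predict_net
from incepspect.evaluate import r2, rmse, rpd

data = simulate_dataset(noise=NoiseModel(seed=0))      # 420 x 213
split = split_multi(data, 0.8)                         # 336 / 84
cal, pred = data.subset(split.calibration_idx), data.subset(split.prediction_idx)
norm = minmax_fit(cal)
model = fit_net(minmax_apply(norm, cal), NetConfig(seed=1, max_epochs=150))
yhat = predict_net(model, minmax_apply(norm, pred))
print(r2(pred.target, yhat), rmse(pred.target, yhat), rpd(pred.target, yhat))
```

## Layout

- `src/incepspect/spectra_core.py` — domain types, CSV I/O, reflectance ->
  absorbance, wavelength truncation
- `src/incepspect/simulate.py` — Gaussian-band endmembers, linear mixing,
  scatter/noise model
- `src/incepspect/preprocess.py` — SNV, MSC, min-max normalization, SPXY
- `src/incepspect/select.py` — CARS and SPA
- `src/incepspect/baselines.py` — PLSR (CV over latent variables), SVR
  (two-step grid search)
- `src/incepspect/nets/` — autodiff engine, layers, architectures, training
- `src/incepspect/evaluate.py` — R2 / RMSE / RPD, leak-free RMSECV,
  experiment harness
- `src/incepspect/cli.py` — `incepspect` entry point
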