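# asthmacast

Forecasting weekly national asthma outpatient and emergency-room (ER) visit
counts from environmental exposures — and asking *which* exposures drive
them — with small recurrent neural networks benchmarked against classical
count models, under leak-free time-series validation.

## The problem

Asthma exacerbation tracks air pollution (CO, NO₂, O₃, PM₁₀, PM₂.₅, SO₂),
weather (temperature and its diurnal range, humidity, precipitation, solar
radiation, wind), airborne pollen (oak, pine, grass) and influenza activity,
with effects that are nonlinear, lagged by days to weeks, and entangled with
seasonality, holiday clinic closures (outpatient visits dip while ER visits
spike — the "balloon effect") and epidemic shocks that keep people away from
hospitals. Classical tools — quasi-Poisson GLM/GAM, random forests, gradient
boosting — struggle to capture lagged interactions jointly. This package
implements the full analysis pipeline for that problem:

- **Recurrent regressors** (simple RNN, LSTM, GRU; implemented in numpy with
  exact hand-derived backpropagation through time) reading 5-week windows of
  22 weekly inputs: 18 environmental factors plus 4 confounders
  (week-of-year, epoch date, holidays per week, epidemic-outbreak patient
  counts). Topology: one recurrent input layer (final state only), two dense
  ReLU layers, a linear output; dropout at all four layers; Adam at learning
  rate 0.004; early stopping after 50 epochs without improvement, restoring
  the best weights.
- **Walk-forward expanding-window cross-validation**: train on 2015–16,
  2015–17, 2015–18; test on 2017, 2018, 2019 respectively. Scalers and
  models are fitted per fold on training rows only; performance is the
  unclipped R² = 1 − SSE/SST on counts, pooled over fold test sets.
- **Hyperparameter search**: 216 configurations per architecture (648 models
  total); the final model is the best mean test R² over both targets within
  the top decile for each target.
- **Permutation feature importance**: ΔMSE when a feature's weekly series is
  temporally shuffled before window construction, plus the pairwise
  interaction statistic `I = FI_AB − FI_A − FI_B`, where `FI_AB` shuffles
  both features jointly. `I > 0` flags synergy (the model exploits the
  pair's joint structure); `I < 0` flags redundancy.
- **Classical baselines** on the identical information (22 features × lags
  0–4, flattened): quasi-Poisson GLM and GAM, random forest and gradient
  boosting with grid-searched hyperparameters.
- **A synthetic-data generator** with declared ground truth (which features
  drive the counts, at which lags, with what effect sizes), standing in for
  the restricted national health-insurance data, so every stage is testable
  end to end.

Weeks follow the epidemiological first-Wednesday convention: week 1 of a
year is the Sunday–Saturday block containing the year's first Wednesday;
indices run 1–52.

## Worked example

```python
from asthmacast import (
    HyperConfig, TrainSpec, WalkForwardPredictor, evaluate_network,
    make_folds, make_weekly_table, permutation_importance, importance_report,
)
from asthmacast.columns import INPUT_COLUMNS

table, truth = make_weekly_table(range(2015, 2020), seed=42)
plan = make_folds(sorted(table["year"].unique()))
metrics = evaluate_network(
    table, "outpatient", HyperConfig("lstm", 16, 32, 16),
    plan, train_spec=TrainSpec(max_epochs=400, seed=42), seed=42,
)
print("pooled test R^2:", round(metrics.pooled["test_r2"], 3))
print(metrics.per_fold[["train_years", "test_year", "test_r2"]].round(3))

predict_fn = WalkForwardPredictor(metrics, table)
records = [permutation_importance(predict_fn, table, f, n_repeats=20, seed=42)
           for f in INPUT_COLUMNS]
print(importance_report(records)["importance"].head(5))
```

Output:

```
pooled test R^2: 0.906
train_years  test_year  test_r2
  2015-2016       2017    0.931
  2015-2017       2018    0.870
  2015-2018       2019    0.928
          feature  delta_mse  significant
        influenza  7949562.0         True
         temp_min  3302292.0         True
         temp_max  2027405.0         True
  solar_radiation  1585037.0         True
holidays_per_week  1507358.0         True
```

The LSTM explains ~91% of out-of-sample variance in weekly outpatient
counts, and the importance ranking recovers the generator's true drivers:
influenza (lag 0) and minimum temperature (lag 1) lead, holiday closures
make the top five, and `temp_max`/`solar_radiation` appear as the expected
correlated proxies of the cold-season signal.

There is also a CLI for end-to-end runs:

```bash
asthmacast simulate --config config.yaml   # weekly_table.csv + truth.json
asthmacast run --config config.yaml        # grid search -> selection -> importance
asthmacast evaluate --model glm --target er --config config.yaml
```

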