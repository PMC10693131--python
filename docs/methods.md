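# Methods

## Scope and data model

The pipeline consumes one weekly national table: 18 environmental inputs
(six air-pollutant concentrations; eight weather variables; three pollen
hazard indices; weekly influenza patient counts), 4 confounders
(week-of-year, days since 1970-01-01, holidays per week, weekly
epidemic-outbreak patient counts) and 2 targets (outpatient and ER asthma
visit counts). The real outcome series is restricted national
health-insurance data, so the package ships a generator that produces a
statistically analogous table with a declared ground truth; all empirical
claims made by the test suite and the acceptance script are claims about
that synthetic system, at the problem sizes stated below.

## Calendar conventions

Week 1 of a year is the 7-day block containing the year's first Wednesday;
blocks run Sunday through Saturday (the MMWR epidemiological-week
convention, which shares the first-Wednesday rule). Indices are capped at
52: a 53rd block is merged into index 52, and days preceding week 1 of
their own calendar year belong to week 52 of the previous year (so
1970-01-01, a Thursday, falls in week 52 of 1969). These two conventions —
the week's starting day and 53-block handling — are choices the
first-Wednesday rule alone does not determine; both are covered by a
brute-force calendar oracle in the tests over 1970–2030.

## Synthetic data generator

**Environment.** Each of the 14 pollutant/weather variables is generated
daily per station as annual sinusoid + nationwide weekly AR(1) anomaly
(φ = 0.6) + station offset + daily noise, with readings deleted completely
at random at a configurable rate (default 5%, 10 stations). The synoptic
anomaly matters: without it, averaging stations and days leaves weekly
national series that are almost purely seasonal and therefore mutually
interchangeable. The three temperature variables share part of their
anomaly; the nightly minimum carries the largest specific component
(cold spells depress minima most). Pollen indices are bounded seasonal
pulses on [0, 4] (oak/pine spring, grass late summer). Influenza surges
each winter (weeks 48–52/1–4) with lognormal season-to-season amplitude;
outbreak counts are a single triangular pulse in the outbreak year
(default weeks 21–29 of 2015).

**Counts.** Outcomes are negative binomial with log link — the generative
analogue of the quasi-Poisson assumption the classical baselines make:

    mu = base_rate * exp(seasonal + sum_j beta_j * g(z_j, lag_j)
                         + beta_hol * holidays + outbreak)

where `z_j` is the driver's z-scored series clipped at ±3 (a saturating
dose-response; epidemic-scale influenza peaks sit 5+ sd out and would
otherwise dominate the error surface), `g` is linear, thresholded or
quadratic, lags are 0–4 weeks, the holiday effect is per holiday day
(negative for outpatients, positive for ER), and the outbreak term
suppresses the ER mean during the outbreak window, decaying linearly over a
4-week recovery lag. Defaults: seasonal amplitude 0.25 (winter peak);
drivers influenza (lag 0, +0.30) and minimum temperature (lag 1, −0.35);
holiday effects −0.20/+0.15 per day; outbreak suppression −0.5; dispersion
k = 200 (≈7% extra-Poisson CV, plausible for national aggregates of
thousands of weekly visits); base rates 5000 (outpatient) and 300 (ER).
Lagged drivers are edge-padded at the start of the simulated period so the
table has no gaps. Everything is a pure function of (parameters, seed).

What the generator does *not* emulate: true Korean pollutant/pollen
magnitudes and holiday dates, spatial station structure, reporting
artefacts, demographic composition, and long-term secular trends. Passing
tests therefore demonstrate that the pipeline recovers structure it is
pointed at under realistic noise — not that the real data contain that
structure.

## Preprocessing

Stations are averaged per (day, variable) with missing readings excluded
(a fully missing pair is an error); days are averaged into epidemiological
weeks. Min–max scalers are fitted on each fold's training rows only and
applied unchanged to its test rows (no clamping; a constant column maps
to 0). Networks regress on the min-max-scaled target and predictions are
inverted to counts before any metric is computed, so R² is comparable
across model families. Windows are 5 weeks with stride 1; the target is
the count at the window's final week (lags 0–4 — nowcasting from
concurrent plus lagged exposures). Test windows may draw their 4-week
history from the training tail: history is covariates only, never future
information.

## Recurrent models

Four layers: a recurrent input layer (simple RNN, LSTM, or GRU cell,
classic formulations; LSTM forget bias initialised to 1) that emits only
its final-step state, two dense ReLU layers, one linear output. Inverted
dropout is applied to the input tensor and to each layer's activations
(four rates, uniform by default). Forward and backward passes are written
directly in numpy; the backward pass is exact and checked against central
finite differences for all three cell types in the test suite (ReLU-kink
coordinates excluded).

Training is minibatch Adam (β₁ = 0.9, β₂ = 0.999, batch 32, shuffled each
epoch) at learning rate 0.004, minimising MSE of the scaled target. After
each epoch the monitored MSE is computed with dropout off; training stops
when it has not strictly improved for 50 consecutive epochs (no minimum
delta) or at `max_epochs` (default 1000; the experiments use 400, which
the early stopper rarely reaches), and the best-epoch weights are
restored. The default monitor is the fold's test windows — faithful to the
protocol being replicated but a form of selection leakage — with
`monitor="validation_tail"` (last 20% of training windows) as the
leak-free alternative. The null-calibration experiment must use the
leak-free monitor: stopping at the epoch that minimises test MSE means any
perturbation of the inputs raises it, which masquerades as importance on
data with none. One integer seed drives initialisation, dropout masks and
shuffling; runs are bit-reproducible.

## Validation, search, selection

`make_folds` builds the expanding plan (train years[0..k+1], test
years[k+2]); a leakage audit asserts that no (year, week) identifier
appears in both roles within a fold. R² is unclipped (1 − SSE/SST about
the evaluated set's mean; negative when a model underperforms that mean).
Pooled metrics concatenate fold test predictions; per-fold values are also
reported, since either convention is defensible. The default grid is
6 recurrent sizes × 6 hidden layouts × 6 dropout rates = 216 per
architecture (648 over three architectures); an 8-point smoke grid serves
fast runs. Final selection restricts to models in the inclusive top decile
of test R² for *both* targets, then maximises the mean of the two, with
ties broken by fewer parameters then lexicographic order; an empty
intersection falls back to the global best mean with a warning.

## Baselines

The flattened design gives every classical model the same information as a
window: 22 features × lags 0–4 = 110 columns aligned to the same target
weeks. GLM is Poisson ML (= quasi-Poisson point estimates) with a Pearson
dispersion estimate; linearly dependent columns are dropped by pivoted QR
with a logged warning. The GAM places penalized cubic B-spline smooths
(df 5) on the lag-0 columns only and linear terms on lagged copies —
smoothing all 110 columns at 100–250 weekly samples is statistically
untenable; spline bases are evaluated with test values clamped to the
fitted range. RF and GBM hyperparameters are selected by time-ordered
inner cross-validation on training rows only, then refit. At these sample
sizes the 110-column GLM overfits badly out of fold (large negative test
R² is expected and honest); the penalized GAM and the ensembles degrade
more gracefully.

## Permutation importance and interaction

Importance of feature A is ΔMSE = mean shuffled MSE − baseline MSE, where
each repeat permutes A's weekly series over the whole evaluation period
*before* window construction (so all five lag copies are disrupted
coherently) and the evaluation surface is the pooled walk-forward test
rows re-predicted by each fold's model. Permutations are keyed by
(seed, feature, repeat), so the single-feature terms inside an interaction
are bit-identical to the standalone records. Default 30 repeats. A feature
is flagged significant when its mean shuffled MSE exceeds the baseline.

The interaction is I = FI_AB − FI_A − FI_B with FI_AB shuffling both
features in the same repeat under independent permutations. Analytic
facts, verified in the tests against brute-force recomputation sharing the
permutation draws: an additive model of independent features gives I = 0;
a pure product of centered independent unit-variance features gives
I = −2 (a single shuffle already destroys a product, so joint destruction
is subadditive — a redundancy signature); a model leaning on positively
correlated features gives I = 2·Cov > 0 — the synergy signature, which is
the regime real pollutant pairs occupy.

Null calibration uses the exchangeability scale: under the null the
observed alignment is one more permutation, so ΔMSE fluctuates at the sd
of the permutation distribution of the MSE — not that sd over √repeats,
and not the cross-feature SE (per-feature ΔMSE values share one trained
model and one test draw and are strongly dependent). The mean ΔMSE over
all 22 features stays within ±1.3 of that scale on every seed probed.

## Experiment problem sizes

The pre-registered experiments in `asthmacast.experiments` use five
simulated years (260 weeks, three folds), the 8-point LSTM smoke grid,
400-epoch training, and 15–20 permutation repeats; driver recovery and
architecture ordering each aggregate five derived seeds. These sizes keep
a complete acceptance run to a few minutes on one CPU while exercising
every pipeline stage; the paper-scale 648-model grid is available via
`default_hyper_grid()` / `--grid paper`.

## Known limitations

- Test-monitored early stopping (the faithful default) inflates test R²
  relative to a strictly held-out protocol; the validation-tail monitor
  quantifies the difference.
- Permutation importance on correlated inputs spreads credit across
  proxies (here: the temperature family); rankings are stable for the
  declared drivers but proxy features legitimately appear significant.
- The quasi-Poisson baselines receive no regularisation, so the GLM is
  honest but weak at p ≈ n; a ridge-penalised variant is out of scope.
- The generator's marginal distributions are pragmatic choices, not fits
  to the restricted data.
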