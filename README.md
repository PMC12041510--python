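# vitalcast

Joint multi-horizon quantile forecasting of ICU vital-sign trajectories.

## The problem

Vital signs in the intensive care unit — mean arterial blood pressure,
pulse, SpO2, respiratory rate, temperature — are recorded continuously but
irregularly, with very different sampling rates per channel. Most
trajectory forecasters are *local*: one model per signal, each blind to
the others. That is both wasteful and statistically weak, because vitals
are correlated; a sparsely observed channel (SpO2 is ~70% missing after
15-minute binning in our reference conditions) carries far less
information on its own than together with the channels that drive it.

`vitalcast` implements a *global* forecaster: one temporal fusion
transformer (TFT) whose output head emits, in a single pass, the 10th,
50th and 90th quantile of every target channel at every future step. It
is aimed at researchers working with clinical time series who need
multi-horizon forecasts with usable prediction bounds, plus the
surrounding machinery: irregular-series preparation with explicit
imputation masks, masked evaluation, interval-coverage and Bland–Altman
calibration, attention/selection interpretability, and counterfactual
medication-scenario forecasting.

## The model and its loss

Observations are resampled to 15-minute bins (mean for numeric, median
for categorical variables) and forward-filled; each encounter's first 100
bins form a window of 75 past and 25 future steps. A per-bin indicator
records whether the bin held a real observation (1) or was imputed (0).

The network is a standard TFT — per-variable projections, variable
selection networks, a static covariate encoder, an LSTM
sequence-to-sequence pair, static enrichment, interpretable multi-head
attention with a causal mask, and a position-wise feed-forward block —
with the output head widened to emit |V|·|Q| values per future step for
the target set V (five vitals) and quantile set Q = {0.1, 0.5, 0.9}.

Training minimises a masked multivariate pinball loss. With y the truth,
ŷ(q) the q-quantile forecast, and 𝕀 the real-value indicator:

    L = mean over windows of  Σ_{v∈V} Σ_{q∈Q}
        [ Σ_t QL(y_t^v, ŷ_t^v(q), q) · 𝕀_t^v ] / [ Σ_t 𝕀_t^v ]

    QL(y, ŷ, q) = q·max(0, y−ŷ) + (1−q)·max(0, ŷ−y)

Imputed steps contribute nothing: the model learns dependencies across
real values only, which is what lets a jointly trained model keep its
accuracy on channels with heavy missingness. The same rule governs every
metric (masked MAE/MAPE, coverage, agreement).

The network, its gradients and the Adam optimiser are implemented on a
small self-contained reverse-mode autodiff core over NumPy
(`vitalcast.nn`), float64 and single-threaded, so runs are exactly
reproducible under a fixed seed with no framework dependency.

Because the clinical cohorts this kind of model is developed on are
credential-gated, the package ships a first-class synthetic cohort
generator with fully known structure — AR(1) channels, a pulse→SpO2
coupling, MCAR missingness at per-channel rates, and a pressor channel
with a known +5 mmHg effect on mean BP — so every pipeline stage is
testable end to end, including exact conditional-mean oracles.

## Worked example

`examples/03_train_and_evaluate.py` simulates the reference cohort
(375 subjects), trains a fixture-size model (state 16, 30 epochs, a few
minutes on one CPU) and evaluates it on held-out subjects:

```
trained 30 epochs; validation loss 5.047 -> 3.702

masked MAE on held-out windows (clinical units), model vs persistence:
   meanbp:   6.68  vs    8.30
    pulse:   7.97  vs    9.45
     spo2:   1.70  vs    2.27
     resp:   3.08  vs    3.78
     temp:   0.34  vs    0.40

pooled coverage of the 10-90 band (nominal 80%):
   meanbp:  79.3%
    pulse:  80.5%
     spo2:  80.8%
     resp:  84.6%
     temp:  74.0%
```

Masked MAE is in clinical units (mmHg for mean BP, % for SpO2, ...),
computed over genuinely observed future points only; the persistence
column is a last-observation-carried-forward baseline. The joint model
beats it on every channel, most relevantly on SpO2, where it borrows
strength from the coupled, better-observed pulse channel. Coverage close
to the nominal 80% says the 10–90 band is a usable prediction interval.

The other examples cover cohort simulation (`01`), window preparation
(`02`), feature importance (`04`), and counterfactual medication
scenarios (`05`). The same pipeline is scriptable from the shell:

```sh
vitalcast simulate --out cohort/ --seed 1
vitalcast prepare --long cohort/long_table.csv --static cohort/static_table.csv --out windows/ --seed 1
vitalcast train --windows windows/ --out ckpt/ --seed 1
vitalcast predict --checkpoint ckpt/ --windows windows/ --out forecasts/
vitalcast evaluate --forecasts forecasts/ --windows windows/ --out report.json
```

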