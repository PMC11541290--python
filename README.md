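# riverwq

Water-quality assessment and pollution source apportionment for river
monitoring data: weighted arithmetic Water Quality Index (WQI) computation
and classification, seasonal ARIMA model selection / validation /
forecasting, positive matrix factorization (PMF) with detection-limit
uncertainty weighting, and Pearson correlation screening — together with a
synthetic-data generator that makes every stage verifiable against known
ground truth.

The package is aimed at environmental scientists working with long-running
multi-station monitoring programmes (the motivating system is an urban
estuarine river with a cleaner upstream and a more polluted downstream
reach, monitored monthly for 12 physicochemical and microbiological
parameters over 16 years), where three questions recur: *how good is the
water*, *where is it heading*, and *where is the pollution coming from*.

## Methods at a glance

**Index.** For parameter *i* with measured value *V_i*, ideal value *V_o*
(0 except pH: 7.0, DO: 14.6 mg/L) and guideline value *S_i*:

    Q_i = 100 |V_i − V_o| / |S_i − V_o|,   W_i = K / S_i,   K = 1 / Σ(1/S_i)

    WQI = Σ Q_i W_i / Σ W_i

with classes [0,25] excellent, (25,50] good, (50,75] poor, (75,100] very
poor, >100 unfit for use.  Guideline values are a required user input.

**Forecasting.** SARIMA (p,d,q)(P,D,Q)_m models

    φ_p(B) Φ_P(B^m) (1−B^m)^D (1−B)^d y_t = θ_q(B) Θ_Q(B^m) ε_t

fitted by Gaussian maximum likelihood, selected by exhaustive order search
(AIC/BIC) and rolling-window cross-validation (RMSE, MAE, MAPE, MASE,
Theil U1), validated by Ljung–Box residual tests, compared against ETS
exponential smoothing.

**Source apportionment.** PMF decomposes a sample × species matrix A into
nonnegative contributions C and profiles B by minimising
Q = ΣΣ (e_ij/s_ij)² with per-cell uncertainties
s = Cs/10 + limit/3 above the detection limit (or SD), else 5·limit/6;
multi-start alternating minimisation keeps the run with the least robust Q.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on the
synthetic dataset (each takes an optional seed argument):

```
python analysis/01_simulate_monitoring.py
python analysis/02_wqi.py
python analysis/03_forecast.py
python analysis/04_pmf.py
python analysis/05_correlate.py
```

Typical output of `analysis/04_pmf.py`:

```
4-factor solution: Q_true=1.49e-12, Q_robust=1.49e-12
dominant species per factor: ['tss', 'nitrate', 'orthophosphate', 'fecal_coliform']
contribution rates [36.2, 31.8, 21.7, 10.3] vs programmed [40.0, 30.0, 20.0, 10.0] (max abs error 3.8 points)
species R^2: [1.0, 1.0, 1.0, 1.0]; bootstrap mapped [100.0, 100.0, 100.0, 100.0] % per factor
```

Each factor is dominated by one indicator species (the sediment-like,
fertilizer-like, industrial-like and sewage-like programmed sources); the
recovered factor contribution rates sit within a few points of the
programmed 40/30/20/10 mass shares, the per-species R² of 1.0 reflects the
saturated 4-species/4-factor fit, and the bootstrap maps every resampled
factor back to its base factor — a stable solution.

`analysis/02_wqi.py` prints, for the synthetic reaches:

```
synthetic annual WQI: ULPR 37-46, DLPR 49-58 (downstream consistently worse, mean gap 15 points)
published-table arithmetic: ULPR range 34-64, DLPR max 95; recomputed % difference for 2007 = 80
```

A thin CLI mirrors the same stages for CSV-in/CSV-out use:
`riverwq simulate|wqi|forecast|pmf|correlate --help`.

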