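# Methods

This note documents the models implemented in `riverwq`, the choices made
where conventions genuinely diverge, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Weighted arithmetic water quality index

The index follows the Brown-family weighted arithmetic form: per-parameter
quality ratings `Qi = 100·|Vi − Vo| / |Si − Vo|` are combined with unit
weights `Wi = K/Si`, `K = 1/Σ(1/Si)`, into `WQI = ΣQiWi / ΣWi`.  Design
points:

- **Absolute-value rating.** Dissolved oxygen below its ideal 14.6 mg/L and
  pH below 7 must degrade the index, so the rating uses `|Vi − Vo|`.
  Ratings are continuous (no flooring); a floored rating would contradict
  the smooth behaviour of reported annual index series.
- **Ideal values.** `Vo = 0` for all parameters except pH (7.0) and DO
  (14.6 mg/L, the freshwater saturation anchor).
- **Guideline values are user input.** Regulatory criteria differ by
  jurisdiction and parameter use-class; the package refuses to guess.
  The test-suite and analysis scripts use plausible aquatic-life-style
  magnitudes, declared as fixtures.
- **Aggregation order.** An area-period index is computed by averaging
  concentrations over the area's stations and the period's months first,
  then indexing once (`mode="mean_concentration"`).  The alternative —
  index every station-month, then average the indices — is available as
  `mode="mean_wqi"`.  The two differ whenever a parameter crosses its ideal
  value within the period (the rating is piecewise linear).  Averaging
  concentrations first matches the common agency convention for
  area-aggregated reporting and is the default.
- **Missing parameters.** Weights are renormalised over the parameters
  present; `n_parameters` is recorded so sparse periods can be filtered.
- **Units.** Because `Wi ∝ 1/Si`, a parameter reported on a large native
  scale (fecal coliform in CFU/100 mL) is automatically down-weighted by
  its large guideline value; no ad-hoc rescaling is applied.  Rescaling a
  parameter's (Vi, Vo, Si) jointly leaves its rating unchanged but shifts
  all weights — mixed-unit configurations are therefore a documented
  hazard, not an error.
- **Seasons.** Meteorological: Dec–Feb winter, Mar–May spring, Jun–Aug
  summer, Sep–Nov fall; December is attributed to the winter labelled by
  the following January's year.
- Reported index values are rounded to integers only at the reporting
  layer; internal values keep full precision.

A note on the shipped reference table (`riverwq.datasets.lpr_annual_wqi`):
a few of the originally printed percent-difference entries do not equal
`round(100·(D−U)/U)` of the printed integer index pairs (e.g. 2012 prints
88 where the integers give 86), consistent with the original column having
been computed from unrounded index values.  The package recomputes the
column from the printed integers; the rows used as arithmetic anchors
(2004, 2007, 2010) agree exactly.

## Seasonal ARIMA protocol

Estimation (Gaussian state-space maximum likelihood), ETS smoothing, ACF /
PACF, the ADF unit-root test and seasonal decomposition are delegated to
statsmodels; the module owns the protocol around them.

- **Seasonality screen.** The combined-test idea is reproduced with a
  documented criterion: seasonal strength
  `1 − Var(remainder)/Var(remainder + seasonal)` from a moving-average
  decomposition (flag at > 0.4 by default) reported jointly with a
  Kruskal–Wallis test on month-of-cycle groups.  The decision (seasonal
  yes/no) is the contract, not any particular proprietary test composition.
- **Intercepts.** An intercept is estimated only for undifferenced
  specifications; differencing absorbs the level, which also makes AIC
  ranking invariant to adding a constant to the series when d ≥ 1 (tested).
- **Order search.** Exhaustive over the (p,q,P,Q) lattice with d, D fixed
  beforehand (or enumerated on request); ties broken by fewer parameters,
  then lexicographically.  On pure white noise an ARMA(1,1) pair with
  near-cancelling roots occasionally wins even by BIC — a known likelihood
  ridge artifact; the white-noise spec reliably stays in the top three, and
  that is the property the tests assert.
- **Cross-validation.** Fixed-size rolling training window (default in the
  analysis: 120 months) advanced by a step (12 months), refitting and
  forecasting the next window each time; per-fold metrics are pooled by
  mean, and the fold table is returned for inspection.
- **Metrics.** RMSE, MAE, MAPE (%); MASE scaled by the in-sample
  seasonal-naive MAE at lag m = 12; Theil U1 = RMSE/(rms(obs)+rms(pred)),
  bounded in [0,1] (U2 is not implemented).  MAPE refuses zero
  observations, listing the offending indices.
- **Ljung–Box** is computed from its defining formula
  `Q = n(n+2)·Σ r_k²/(n−k)` with df = lags − fitted ARMA orders, and is
  cross-checked against statsmodels in the tests.  Outliers (comparison
  tables) are residuals with |standardized residual| > 3.
- **Forecasting.** Central prediction intervals default to 95%.  The
  year × season summary trims a trailing December (whose winter belongs to
  the following year) so a whole-year horizon yields the fixed
  years × 4 shape; the leading winter is partial (Jan–Feb) by the same
  convention.
- **Missing months** are linearly interpolated up to 2 consecutive gaps in
  the analysis drivers; longer gaps are left to the state-space filter.

## Positive matrix factorization

The solver is written from scratch: per-cell weights `1/s²` define a
weighted Frobenius objective (`Q_true`), minimised by multiplicative
updates (weighted Lee–Seung) followed by exact alternating weighted-NNLS
polish sweeps — each block solve is an exact minimiser, so the Q path is
monotone non-increasing (asserted in tests) and degenerate optima are
reached to machine precision instead of the multiplicative updates' crawl.
Multi-start (seeded child generators spawned from the master seed) with
the winner chosen by least `Q_robust`, mirroring the repeated
random-seed-run practice of receptor modelling.

- **Robust Q.** Cells with |e/s| > 4 contribute `4·|e/s|` instead of
  `(e/s)²` (the EPA-style down-weighting of extreme scaled residuals).
  The robust objective is used only for run selection, not inside the
  update steps.
- **Orientation.** A (n samples × m species) ≈ C (n × k) · Bᵀ (k × m);
  profiles B are species × factors everywhere.
- **Uncertainty equations.** `s = Cs/10 + limit/3` strictly above the
  limit, `s = 5·limit/6` at or below it (equality falls to the
  below-limit branch); the limit is the MDL, or the species SD where no
  MDL exists — the arithmetic is identical and a provenance flag records
  which.  Concentrations below the limit are used as reported; only the
  uncertainty branch switches.
- **Missing cells** are imputed to the species median with uncertainty set
  to 4× the median uncertainty, flagged (EPA-style convention).
- **Factor count.** `select_n_factors` reports Q_robust, Q_true, their
  ratio and per-species R² per k; no automatic choice is made — the
  analyst selects, as is standard.  With 4 species, k = 4 is saturated:
  exact fits (Q ≈ 0, R² ≈ 1) are expected and are a property of the model
  dimension, not evidence of a good source model.
- **Reporting.** Species-profile percentages normalise each species row of
  B to 100; contribution rates are mass-weighted
  (`rate_k ∝ Σ_i c_ik · Σ_j b_jk`, the factor's share of total
  reconstructed concentration), with a mean-normalised alternative behind
  a flag.  R² is the squared Pearson correlation of observed vs
  reconstructed concentrations per species.
- **Bootstrap.** Moving-block bootstrap over samples (default block 6
  months, preserving short-range temporal correlation); each refit factor
  maps to the base factor of highest absolute profile correlation if it
  exceeds 0.6, else counts as unmapped.  Mapped fractions near 100%
  indicate a reproducible solution; a pure-noise negative control sits
  visibly lower (tested).
- **Alignment.** All recovery comparisons align factors by greedy maximum
  cosine similarity first; the alignment itself is tested on hand-permuted
  cases.  Factor scale is not identified (only the product C·Bᵀ is); all
  reported quantities are scale-invariant.

## Synthetic-data generator

Every generator is a pure function of (config, seed).

- **Monitoring tables** emulate the structure of a 5-station, 12-parameter,
  16-year monthly export: per-parameter baseline, annual cosine seasonality
  (warm-season peaks for nutrients, TSS, fecal coliform and chlorophyll;
  winter peak for DO), mild linear trend, lognormal multiplicative noise
  for concentrations (right-skewed, strictly positive) and additive
  truncated noise for temperature and pH, plus a programmed 1.35–1.45×
  downstream enrichment of pollutant parameters.  Default dispersions are
  moderate (σ ≈ 0.2–0.6 on the log scale, largest for fecal coliform,
  whose counts are the most variable in practice).
- **SARIMA realizations** are simulated from the state-space form with a
  burn-in of ten seasonal cycles discarded.
- **Source mixtures** mix four programmed sources over the four
  apportionment species with mass shares rescaled to hit 40/30/20/10
  exactly before noise (5% multiplicative lognormal by default).  Two
  deliberate design choices make recovery a well-posed question:
  concentrations are expressed in species-normalised units (each species
  relative to its typical level) so no single species dominates the mass
  balance, and the truth lies on the boundary — profiles contain exact
  zeros and contributions are highly dispersed (lognormal σ = 1.5,
  episodic storm-driven sources), yielding near-pure samples.  With a
  saturated 4×4 model, a strictly positive interior truth would admit a
  continuum of exact nonnegative factorizations and *no* Q-minimising
  solver could recover contribution rates; the boundary structure is what
  real receptor-model datasets rely on too.
- **Correlated blocks** are Gaussian with a user-supplied joint correlation
  matrix (Cholesky construction; PSD checked).

What passing tests on these data do **not** show: robustness to real
monitoring pathologies — censored values at detection limits, irregular
sampling, instrument changes, non-lognormal outliers, or genuinely dense
source profiles (for which rotational ambiguity would need Fpeak-style
exploration, out of scope here).

## Problem sizes and tolerances

Recovery studies use 10 seeds × 60 samples (factorization) and 20 seeds at
n = 192/360 (SARIMA estimation / order search) — sizes at which the sampling
error of the checked statistics is comfortably below the asserted margins.
Numerical tolerances: weight normalisation 1e−12; oracle equivalence 1e−9
(index) and 1e−10 (Q value); solver stop at relative ΔQ < 1e−8 or 5000
multiplicative iterations + 30 polish sweeps.  Identical seeds reproduce
identical outputs bit-for-bit, including the multi-start Q table.

## Known limitations

- Guideline values (hence the absolute scale of any index series) are user
  input; results are only comparable across studies sharing criteria.
- The ETS comparison uses additive components only.
- PMF error estimation is bootstrap-only: no rotational (Fpeak) or
  displacement (DISP/BS-DISP) analysis, and no source labelling — naming a
  factor "sewage" is interpretation, not computation.
- Correlation screening reports raw p-values (with a Benjamini–Hochberg
  flag as a convenience); temporal/spatial alignment of the two variable
  blocks is the user's responsibility via shared sample ids.
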