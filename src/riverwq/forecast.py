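"""Seasonal ARIMA / exponential-smoothing forecasting protocol.

Implements the model-selection and validation workflow used for monthly
water-quality index series: stationarity and seasonality screening, SARIMA
(p,d,q)(P,D,Q)_m and ETS fitting, exhaustive order search, rolling-window
cross-validation with a fixed metric set (RMSE, MAE, MAPE, MASE, Theil U),
Ljung-Box residual diagnostics and multi-year monthly forecasting with a
year-by-season summary table.

Estimation is delegated to statsmodels' state-space machinery; this module
owns the protocol: order lattices, fold bookkeeping, metric definitions and
the reporting schema.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.exponential_smoothing.ets import ETSModel
from statsmodels.tsa.seasonal import seasonal_decompose
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import adfuller
from statsmodels.tsa.stattools import pacf as sm_pacf

from .wqi import SEASONS, assign_season, season_year

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class SarimaSpec:
    """Order specification (p,d,q)(P,D,Q)_m."""

    p: int
    d: int
    q: int
    P: int = 0
    D: int = 0
    Q: int = 0
    m: int = 12

    def __post_init__(self) -> None:
        for name in ("p", "d", "q", "P", "D", "Q"):
            if getattr(self, name) < 0:
                raise ValueError(f"order {name} must be >= 0")
        if self.m < 1:
            raise ValueError("season length m must be >= 1")
        if self.d + self.D > 3:
            raise ValueError("total differencing d + D > 3 is not supported")

    @property
    def n_params(self) -> int:
        """Estimated parameters: ARMA coefficients + innovation variance
        (+ intercept when no differencing is applied)."""
        k = self.p + self.q + self.P + self.Q + 1
        return k + (1 if self.d + self.D == 0 else 0)

    def __str__(self) -> str:
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q})_{self.m}"


@dataclass
class SarimaFit:
    """Fitted SARIMA model: coefficients, residuals and fit statistics."""

    spec: SarimaSpec
    coefficients: dict[str, float]
    residuals: pd.Series
    loglik: float
    aic: float
    bic: float
    nobs: int
    converged: bool
    _results: object = field(repr=False, default=None)

    @property
    def fitted_df(self) -> int:
        """ARMA degrees of freedom consumed, for portmanteau tests."""
        return self.spec.p + self.spec.q + self.spec.P + self.spec.Q


@dataclass
class EtsFit:
    """Fitted error-trend-seasonal smoothing model (same metric surface as
    :class:`SarimaFit`)."""

    trend: str | None
    seasonal: str | None
    coefficients: dict[str, float]
    residuals: pd.Series
    loglik: float
    aic: float
    bic: float
    nobs: int
    converged: bool
    _results: object = field(repr=False, default=None)

    @property
    def fitted_df(self) -> int:
        smoothing = 1 + (self.trend is not None) + (self.seasonal is not None)
        return smoothing


@dataclass(frozen=True)
class AccuracyMetrics:
    rmse: float
    mae: float
    mape: float
    mase: float | None
    theil_u: float

    def as_dict(self) -> dict[str, float | None]:
        return {"rmse": self.rmse, "mae": self.mae, "mape": self.mape,
                "mase": self.mase, "theil_u": self.theil_u}


@dataclass
class ForecastResult:
    point: pd.Series
    lower: pd.Series
    upper: pd.Series
    level: float
    seasonal_summary: pd.DataFrame | None


def compute_acf_pacf(series, max_lag: int) -> pd.DataFrame:
    """Sample ACF and PACF (Durbin-Levinson) up to ``max_lag``.

    Returns a frame indexed by lag 0..max_lag with columns acf, pacf
    (pacf at lag 0 is 1 by convention).
    """
    y = np.asarray(series, float)
    if len(y) <= max_lag + 1:
        raise ValueError(f"series length {len(y)} too short for max_lag={max_lag}")
    if np.ptp(y) == 0:
        raise ValueError("constant series: autocorrelation undefined beyond lag 0")
    acf_vals = sm_acf(y, nlags=max_lag, fft=True)
    pacf_vals = sm_pacf(y, nlags=max_lag, method="ld")
    return pd.DataFrame({"acf": acf_vals, "pacf": pacf_vals},
                        index=pd.RangeIndex(max_lag + 1, name="lag"))


def stationarity_seasonality_tests(
    series, m: int = 12, strength_threshold: float = 0.4
) -> dict:
    """Augmented Dickey-Fuller unit-root test plus a combined seasonality
    screen.

    Seasonal strength is 1 − Var(remainder)/Var(remainder + seasonal) from
    a moving-average decomposition; the series is flagged seasonal when the
    strength exceeds ``strength_threshold`` (default 0.4).  A Kruskal-Wallis
    test across month-of-cycle groups is reported alongside as a second,
    distribution-free reading of the same question.
    """
    y = np.asarray(series, float)
    n = len(y)
    if n < 3 * m:
        raise ValueError(f"need at least 3 seasonal cycles ({3 * m}), got {n}")
    adf_stat, adf_p, *_ = adfuller(y, autolag="AIC")
    decomp = seasonal_decompose(y, period=m, model="additive",
                                extrapolate_trend="freq")
    resid = decomp.resid
    seasonal = decomp.seasonal
    denom = np.var(resid + seasonal)
    strength = 0.0 if denom == 0 else max(0.0, 1.0 - np.var(resid) / denom)
    groups = [y[k::m] for k in range(m)]
    kw_stat, kw_p = stats.kruskal(*groups)
    return {
        "adf_stat": float(adf_stat),
        "adf_p": float(adf_p),
        "seasonal_strength": float(strength),
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
        "seasonality_flag": bool(strength > strength_threshold),
    }


def difference(series, d: int = 0, D: int = 0, m: int = 12) -> np.ndarray:
    """Apply (1−B)^d (1−B^m)^D; output length n − d − D·m."""
    y = np.asarray(series, float)
    if len(y) <= d + D * m:
        raise ValueError(f"series length {len(y)} insufficient for d={d}, D={D}, m={m}")
    for _ in range(D):
        y = y[m:] - y[:-m]
    for _ in range(d):
        y = np.diff(y)
    return y


def _as_series(series) -> pd.Series:
    s = pd.Series(np.asarray(series, float)) if not isinstance(series, pd.Series) \
        else series.astype(float)
    return s


def fit_sarima(series, spec: SarimaSpec) -> SarimaFit:
    """Gaussian maximum-likelihood SARIMA fit.

    An intercept is estimated only for undifferenced specs (differencing
    absorbs a constant level).  The fit is deterministic given series and
    spec.  Non-invertible or boundary optima produce a warning from the
    optimizer and are returned with ``converged=False``.
    """
    y = _as_series(series)
    min_n = 4 * (spec.p + spec.q + spec.P + spec.Q + 1) + spec.d + spec.D * spec.m
    if len(y) < min_n:
        raise ValueError(f"series length {len(y)} < required {min_n} for {spec}")
    trend = "c" if spec.d + spec.D == 0 else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(y, order=(spec.p, spec.d, spec.q),
                        seasonal_order=(spec.P, spec.D, spec.Q, spec.m),
                        trend=trend)
        try:
            res = model.fit(disp=0)
        except Exception as exc:  # optimizer failure carries the spec
            raise RuntimeError(f"SARIMA fit failed for {spec}: {exc}") from exc
    converged = bool(getattr(res.mle_retvals, "get", lambda *a: True)("converged", True))
    resid = pd.Series(np.asarray(res.resid), index=y.index)
    return SarimaFit(spec=spec, coefficients=dict(res.params),
                     residuals=resid, loglik=float(res.llf),
                     aic=float(res.aic), bic=float(res.bic),
                     nobs=int(res.nobs), converged=converged, _results=res)


def fit_ets(series, m: int = 12, seasonal_allowed: bool = True) -> EtsFit:
    """Additive exponential smoothing with automatic component selection.

    Candidates span trend in {none, additive} and seasonal in {none,
    additive (period m)}; the AIC-minimal candidate is returned.
    """
    y = _as_series(series)
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be finite")
    candidates: list[tuple[str | None, str | None]] = [(None, None), ("add", None)]
    if seasonal_allowed and len(y) >= 2 * m:
        candidates += [(None, "add"), ("add", "add")]
    best = None
    for trend, seasonal in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = ETSModel(y, error="add", trend=trend, seasonal=seasonal,
                               seasonal_periods=m if seasonal else None).fit(disp=0)
            except Exception:
                continue
        if best is None or res.aic < best[0].aic:
            best = (res, trend, seasonal)
    if best is None:
        raise RuntimeError("all ETS candidates failed to fit")
    res, trend, seasonal = best
    return EtsFit(trend=trend, seasonal=seasonal, coefficients=dict(res.params_formatted["param"])
                  if hasattr(res, "params_formatted") else {},
                  residuals=pd.Series(np.asarray(res.resid), index=y.index),
                  loglik=float(res.llf), aic=float(res.aic), bic=float(res.bic),
                  nobs=int(res.nobs), converged=True, _results=res)


def order_lattice(
    max_orders: tuple[int, int, int, int],
    d: int | tuple[int, ...] = 1,
    D: int | tuple[int, ...] = 1,
    m: int = 12,
) -> list[SarimaSpec]:
    """All candidate specs with p,q,P,Q up to ``max_orders`` and d, D
    either fixed (int) or enumerated (iterable of ints)."""
    max_p, max_q, max_P, max_Q = max_orders
    ds = (d,) if isinstance(d, int) else tuple(d)
    Ds = (D,) if isinstance(D, int) else tuple(D)
    return [SarimaSpec(p, dd, q, P, DD, Q, m)
            for p, dd, q, P, DD, Q in itertools.product(
                range(max_p + 1), ds, range(max_q + 1),
                range(max_P + 1), Ds, range(max_Q + 1))]


def grid_search_sarima(
    series,
    max_orders: tuple[int, int, int, int] = (3, 3, 3, 3),
    d: int | tuple[int, ...] = 1,
    D: int | tuple[int, ...] = 1,
    m: int = 12,
    criterion: str = "aic",
) -> pd.DataFrame:
    """Exhaustive fit over the order lattice.

    Differencing orders d, D are usually fixed beforehand from unit-root /
    seasonality screening but may be enumerated by passing iterables.
    Ranked by the requested information criterion; ties broken by fewer
    parameters, then lexicographically on (p,q,P,Q).  Returns a frame with
    one row per successfully fitted spec (failures are logged) sorted best
    first.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    rows = []
    failures = []
    for spec in order_lattice(max_orders, d, D, m):
        try:
            fit = fit_sarima(series, spec)
        except Exception as exc:
            failures.append((spec, str(exc)))
            continue
        rows.append({"spec": spec, "p": spec.p, "d": spec.d, "q": spec.q,
                     "P": spec.P, "D": spec.D, "Q": spec.Q, "m": spec.m,
                     "aic": fit.aic, "bic": fit.bic,
                     "loglik": fit.loglik, "n_params": spec.n_params})
    if not rows:
        raise RuntimeError(f"all {len(failures)} candidate fits failed: {failures[:5]}")
    if failures:
        logger.warning("grid_search_sarima: %d/%d specs failed", len(failures),
                       len(failures) + len(rows))
    out = pd.DataFrame(rows)
    out = out.sort_values([criterion, "n_params", "p", "q", "P", "Q"],
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def accuracy_metrics(observed, predicted, training_series=None, m: int = 12) -> AccuracyMetrics:
    """Forecast accuracy: RMSE, MAE, MAPE (%), MASE, Theil U1.

    MASE scales MAE by the in-sample MAE of the seasonal-naive forecast
    (lag m) on the training series; Theil U1 = RMSE / (rms(obs) +
    rms(pred)), bounded in [0, 1].
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    err = obs - pred
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    zero_idx = np.flatnonzero(obs == 0)
    if zero_idx.size:
        raise ValueError(f"MAPE undefined: observed values are zero at indices {zero_idx.tolist()}")
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(obs)))
    mase = None
    if training_series is not None:
        train = np.asarray(training_series, float)
        if len(train) <= m:
            raise ValueError("training series shorter than one seasonal cycle")
        scale = np.mean(np.abs(train[m:] - train[:-m]))
        mase = float(mae / scale) if scale > 0 else (0.0 if mae == 0 else np.inf)
    denom = np.sqrt(np.mean(obs ** 2)) + np.sqrt(np.mean(pred ** 2))
    theil = float(rmse / denom) if denom > 0 else 0.0
    return AccuracyMetrics(rmse=rmse, mae=mae, mape=mape, mase=mase, theil_u=theil)


def ljung_box(residuals, lags: int, fitted_df: int = 0) -> dict:
    """Ljung-Box portmanteau test for residual autocorrelation.

    Q = n(n+2) Σ_{k=1..lags} r_k²/(n−k), referred to a chi-square with
    ``lags − fitted_df`` degrees of freedom.
    """
    if lags <= fitted_df:
        raise ValueError(f"lags ({lags}) must exceed fitted_df ({fitted_df})")
    e = np.asarray(residuals, float)
    n = len(e)
    if n <= lags:
        raise ValueError(f"need more residuals ({n}) than lags ({lags})")
    r = sm_acf(e, nlags=lags, fft=True)[1:]
    q = n * (n + 2) * np.sum(r ** 2 / (n - np.arange(1, lags + 1)))
    df = lags - fitted_df
    p = float(stats.chi2.sf(q, df))
    return {"statistic": float(q), "df": int(df), "p": p}


def _forecast_sarima(fit: SarimaFit, horizon: int, level: float):
    fc = fit._results.get_forecast(steps=horizon)
    ci = fc.conf_int(alpha=1 - level / 100.0)
    ci = np.asarray(ci)
    return (pd.Series(np.asarray(fc.predicted_mean)),
            pd.Series(ci[:, 0]), pd.Series(ci[:, 1]))


def _forecast_ets(fit: EtsFit, horizon: int, level: float):
    res = fit._results
    pred = res.get_prediction(start=fit.nobs, end=fit.nobs + horizon - 1)
    frame = pred.summary_frame(alpha=1 - level / 100.0)
    return (pd.Series(np.asarray(frame["mean"])),
            pd.Series(np.asarray(frame["pi_lower"])),
            pd.Series(np.asarray(frame["pi_upper"])))


def forecast(fit: SarimaFit | EtsFit, horizon: int, level: float = 95.0,
             start: pd.Timestamp | None = None) -> ForecastResult:
    """Monthly point forecasts with central prediction intervals and a
    (year x season) summary of mean monthly forecasts.

    ``start`` is the calendar month of the first forecast step; if omitted
    it is inferred from the fitted series' DatetimeIndex, and the seasonal
    summary is skipped when no dates are available.  For a whole-year
    horizon the summary is trimmed to the forecast's own years (a trailing
    December whose winter is attributed to the following year is dropped),
    giving the fixed years x 4 shape.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    m = fit.spec.m if isinstance(fit, SarimaFit) else 12
    if horizon > 10 * m:
        warnings.warn(f"horizon {horizon} far beyond the seasonal cycle; "
                      "forecasts are extrapolative", stacklevel=2)
    if isinstance(fit, SarimaFit):
        point, lower, upper = _forecast_sarima(fit, horizon, level)
    else:
        point, lower, upper = _forecast_ets(fit, horizon, level)

    index = None
    if start is not None:
        index = pd.date_range(start, periods=horizon, freq="MS")
    else:
        fitted_index = fit.residuals.index
        if isinstance(fitted_index, pd.DatetimeIndex) and len(fitted_index):
            nxt = fitted_index[-1] + pd.offsets.MonthBegin(1)
            index = pd.date_range(nxt, periods=horizon, freq="MS")
    if index is not None:
        point.index = lower.index = upper.index = index

    summary = None
    if index is not None:
        frame = pd.DataFrame({"date": index, "forecast": point.to_numpy()})
        frame["season"] = [assign_season(d.month) for d in frame["date"]]
        frame["season_year"] = [season_year(d) for d in frame["date"]]
        if horizon % 12 == 0:
            first = index[0].year
            years = range(first, first + horizon // 12)
            frame = frame[frame["season_year"].isin(years)]
        summary = (frame.groupby(["season_year", "season"])["forecast"].mean()
                   .unstack("season").reindex(columns=SEASONS))
        summary.index.name = "year"
    return ForecastResult(point=point, lower=lower, upper=upper, level=level,
                          seasonal_summary=summary)


def rolling_cv(
    series,
    train_months: int,
    test_months: int,
    step_months: int,
    models: dict[str, "SarimaSpec | str | object"],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rolling-window cross-validation.

    A fixed-size training window advances by ``step_months``; at each
    position every model is refit on the window and forecasts the next
    ``test_months``.  ``models`` maps a name to a :class:`SarimaSpec`, the
    string ``"ets"``, or a callable ``(train_series, horizon) -> ndarray``.

    Returns ``(pooled, folds)``: per-model metrics averaged over folds, and
    the full per-fold table.  Folds where a fit fails are skipped and
    counted.
    """
    y = _as_series(series)
    n = len(y)
    if n < train_months + test_months:
        raise ValueError("series shorter than one train+test window")
    starts = range(0, n - train_months - test_months + 1, step_months)
    fold_rows = []
    for name, model in models.items():
        for fold, s in enumerate(starts):
            train = y.iloc[s:s + train_months]
            test = y.iloc[s + train_months:s + train_months + test_months]
            try:
                if isinstance(model, SarimaSpec):
                    fit = fit_sarima(train, model)
                    pred = _forecast_sarima(fit, test_months, 95.0)[0].to_numpy()
                elif model == "ets":
                    fit = fit_ets(train)
                    pred = _forecast_ets(fit, test_months, 95.0)[0].to_numpy()
                else:
                    pred = np.asarray(model(train, test_months), float)
            except Exception as exc:
                logger.warning("rolling_cv: model %s fold %d failed: %s",
                               name, fold, exc)
                fold_rows.append({"model": name, "fold": fold, "failed": True})
                continue
            metrics = accuracy_metrics(test.to_numpy(), pred,
                                       training_series=train.to_numpy())
            fold_rows.append({"model": name, "fold": fold, "failed": False,
                              **metrics.as_dict()})
    folds = pd.DataFrame(fold_rows)
    ok = folds[~folds["failed"]]
    pooled = (ok.groupby("model")[["rmse", "mae", "mape", "mase", "theil_u"]]
              .mean().reset_index())
    counts = folds.groupby("model")["failed"].agg(n_folds="size", n_failed="sum")
    pooled = pooled.merge(counts.reset_index(), on="model")
    return pooled, folds


def model_report(
    name: str,
    fit: SarimaFit | EtsFit,
    cv_metrics: AccuracyMetrics | dict | None = None,
    lb_lags: int = 24,
) -> dict:
    """One comparison-table row: fit statistics, accuracy metrics,
    Ljung-Box diagnostics and outlier count (|standardized residual| > 3)."""
    resid = fit.residuals.to_numpy()
    sd = np.std(resid)
    outliers = int(np.sum(np.abs(resid) > 3 * sd)) if sd > 0 else 0
    lags = min(lb_lags, len(resid) - 1)
    lb = ljung_box(resid, lags=lags, fitted_df=min(fit.fitted_df, lags - 1))
    row = {"model": name,
           "order": str(fit.spec) if isinstance(fit, SarimaFit)
           else f"ETS(trend={fit.trend}, seasonal={fit.seasonal})",
           "aic": fit.aic, "bic": fit.bic,
           "lb_statistic": lb["statistic"], "lb_df": lb["df"], "lb_p": lb["p"],
           "n_outliers": outliers}
    if cv_metrics is not None:
        d = cv_metrics.as_dict() if isinstance(cv_metrics, AccuracyMetrics) else dict(cv_metrics)
        row.update({k: d.get(k) for k in ("rmse", "mae", "mase", "mape", "theil_u")})
    return row
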