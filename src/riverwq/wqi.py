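"""Weighted arithmetic water quality index (Brown-type WQI).

The index aggregates per-parameter quality ratings

    Qi = 100 * |Vi - Vo| / |Si - Vo|

(Vi measured, Vo ideal, Si guideline) using unit weights inversely
proportional to the guideline value,

    Wi = K / Si,   K = 1 / sum(1/Si),

into WQI = sum(Qi*Wi) / sum(Wi).  Lower WQI means cleaner water; the class
bands are [0,25] excellent, (25,50] good, (50,75] poor, (75,100] very poor
and above 100 unfit for use.

The absolute-value form of Qi keeps ratings positive when a parameter sits
below its ideal value (dissolved oxygen under saturation, pH under 7),
which is the standard reading of this index family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import AreaMap, GuidelineSet, MonitoringTable

CLASS_LABELS = ["Excellent", "Good", "Poor", "Very poor", "Unfit"]
#: Upper edges of the first four class bands; above the last edge is Unfit.
CLASS_EDGES = [25.0, 50.0, 75.0, 100.0]

SEASONS = ["Winter", "Spring", "Summer", "Fall"]
_MONTH_SEASON = {12: "Winter", 1: "Winter", 2: "Winter",
                 3: "Spring", 4: "Spring", 5: "Spring",
                 6: "Summer", 7: "Summer", 8: "Summer",
                 9: "Fall", 10: "Fall", 11: "Fall"}


@dataclass(frozen=True)
class WeightSet:
    """Unit weights Wi = K/Si for a parameter subset; sums to one."""

    weights: dict[str, float]
    k: float


@dataclass(frozen=True)
class WqiRecord:
    """One computed index value with its components."""

    area: str
    period: str
    wqi: float
    wqi_class: str
    ratings: dict[str, float]
    weights: WeightSet
    n_parameters: int


def quality_rating(vi: float, vo: float, si: float) -> float:
    """Quality rating Qi = 100|Vi−Vo|/|Si−Vo|; 0 at the ideal value, 100 at
    the guideline."""
    if si == vo:
        raise ValueError(f"Si equals Vo ({si}); rating undefined")
    if not np.isfinite(vi):
        raise ValueError(f"non-finite measurement {vi}")
    return 100.0 * abs(vi - vo) / abs(si - vo)


def unit_weights(guidelines: GuidelineSet, parameters=None) -> WeightSet:
    """Unit weights over a parameter subset, renormalised to sum to one."""
    params = list(parameters) if parameters is not None else guidelines.parameters
    if not params:
        raise ValueError("empty parameter subset")
    inv = {p: 1.0 / guidelines.si[p] for p in params}
    k = 1.0 / sum(inv.values())
    return WeightSet(weights={p: k * inv[p] for p in params}, k=k)


def compute_wqi(
    sample: dict[str, float],
    guidelines: GuidelineSet,
    area: str = "",
    period: str = "",
) -> WqiRecord:
    """Index one area-period from a parameter -> concentration map.

    Only parameters present in both the sample and the guideline set enter;
    weights are renormalised over that subset, so a partially observed month
    still yields a well-defined index (``n_parameters`` records the
    coverage).
    """
    params = [p for p in sample if p in guidelines.si and np.isfinite(sample[p])]
    if not params:
        raise ValueError("no overlap between sample parameters and guidelines")
    ws = unit_weights(guidelines, params)
    ratings = {p: quality_rating(sample[p], guidelines.vo[p], guidelines.si[p])
               for p in params}
    total_w = sum(ws.weights.values())
    wqi = sum(ratings[p] * ws.weights[p] for p in params) / total_w
    return WqiRecord(area=area, period=period, wqi=wqi,
                     wqi_class=classify_wqi(wqi), ratings=ratings,
                     weights=ws, n_parameters=len(params))


def classify_wqi(wqi: float) -> str:
    """Class label for an index value; bands partition [0, inf)."""
    if not np.isfinite(wqi) or wqi < 0:
        raise ValueError(f"WQI must be a nonnegative real, got {wqi}")
    for edge, label in zip(CLASS_EDGES, CLASS_LABELS):
        if wqi <= edge:
            return label
    return "Unfit"


def assign_season(month: int) -> str:
    """Meteorological season of a calendar month (Dec-Feb winter, etc.)."""
    if month not in range(1, 13):
        raise ValueError(f"month must be 1-12, got {month}")
    return _MONTH_SEASON[month]


def season_year(date: pd.Timestamp) -> int:
    """Year a month's season is attributed to; December belongs to the
    winter labelled by the following January."""
    return date.year + 1 if date.month == 12 else date.year


def percent_difference(baseline: float, other: float) -> float:
    """Relative difference 100*(other−baseline)/baseline (unrounded)."""
    if not baseline > 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return 100.0 * (other - baseline) / baseline


def _period_keys(dates: pd.Series, period: str) -> pd.Series:
    if period == "monthly":
        return dates.dt.strftime("%Y-%m")
    if period == "annual":
        return dates.dt.year.astype(str)
    if period == "seasonal":
        years = [season_year(d) for d in dates]
        seasons = [assign_season(d.month) for d in dates]
        return pd.Series([f"{y}-{s}" for y, s in zip(years, seasons)],
                         index=dates.index)
    raise ValueError(f"period must be monthly/seasonal/annual, got {period!r}")


def aggregate_wqi(
    table: MonitoringTable,
    areas: AreaMap,
    guidelines: GuidelineSet,
    period: str = "annual",
    mode: str = "mean_concentration",
) -> pd.DataFrame:
    """Area-period WQI table.

    Default mode averages concentrations across the area's stations and the
    period's months first, then computes one index from the averaged
    concentrations.  ``mode="mean_wqi"`` instead indexes each station-month
    and averages the monthly indices — both conventions appear in the
    applied WQI literature.

    Returns a frame with columns (area, period, wqi, wqi_class,
    n_parameters, n_months, n_stations).
    """
    if mode not in ("mean_concentration", "mean_wqi"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    records = []
    df = table.data
    for area in areas.labels:
        sub = df[df["station"].isin(areas[area])]
        if sub.empty:
            continue
        keys = _period_keys(sub["date"], period)
        for key, grp in sub.groupby(keys, sort=True):
            try:
                if mode == "mean_concentration":
                    sample = grp.groupby("parameter")["value"].mean().to_dict()
                    rec = compute_wqi(sample, guidelines, area=area, period=key)
                    wqi = rec.wqi
                    n_params = rec.n_parameters
                else:
                    vals = []
                    n_params = 0
                    for (_, _d), mgrp in grp.groupby(["station", "date"]):
                        sample = mgrp.set_index("parameter")["value"].to_dict()
                        r = compute_wqi(sample, guidelines)
                        vals.append(r.wqi)
                        n_params = max(n_params, r.n_parameters)
                    wqi = float(np.mean(vals))
            except ValueError:
                continue  # period with no indexable parameters: omitted
            records.append({
                "area": area, "period": key, "wqi": wqi,
                "wqi_class": classify_wqi(wqi), "n_parameters": n_params,
                "n_months": grp["date"].nunique(),
                "n_stations": grp["station"].nunique(),
            })
    return pd.DataFrame.from_records(
        records, columns=["area", "period", "wqi", "wqi_class",
                          "n_parameters", "n_months", "n_stations"])


def percent_difference_table(
    wqi_table: pd.DataFrame, baseline_area: str, other_area: str
) -> pd.DataFrame:
    """Per-period percent difference of ``other_area`` relative to
    ``baseline_area``, reported rounded to the nearest integer alongside the
    unrounded value."""
    base = wqi_table[wqi_table["area"] == baseline_area].set_index("period")["wqi"]
    other = wqi_table[wqi_table["area"] == other_area].set_index("period")["wqi"]
    shared = base.index.intersection(other.index)
    rows = []
    for key in shared:
        pct = percent_difference(base[key], other[key])
        rows.append({"period": key, f"wqi_{baseline_area}": base[key],
                     f"wqi_{other_area}": other[key],
                     "pct_difference": pct,
                     "pct_difference_rounded": int(round(pct))})
    return pd.DataFrame(rows)
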