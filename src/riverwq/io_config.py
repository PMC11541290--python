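"""Tabular I/O and configuration: monitoring tables, guideline sets, areas.

No science lives here.  The canonical interchange format is a long (tidy)
CSV with one row per (station, month, parameter) observation; a wide reader
is provided as a convenience that melts to long form.  Dates are normalised
to the first of the month and sub-monthly observations are averaged to
monthly means before any analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import PARAMETERS, resolve_parameter

logger = logging.getLogger(__name__)

#: Ideal ("pristine") values Vo; zero for every parameter except pH and
#: dissolved oxygen, whose quality scales are anchored at 7.0 and the
#: freshwater saturation value 14.6 mg/L respectively.
DEFAULT_IDEAL_VALUES: dict[str, float] = {"ph": 7.0, "do": 14.6}


class ValidationError(ValueError):
    """Raised when an input table or config violates its contract."""


@dataclass(frozen=True)
class MonitoringTable:
    """Validated long-format monitoring data.

    ``data`` has columns (station, date, parameter, value, unit) with dates
    normalised to month starts, canonical parameter names, and one row per
    (station, date, parameter).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        validate_monitoring_frame(self.data)

    @property
    def stations(self) -> list[str]:
        return sorted(self.data["station"].unique())

    @property
    def parameters(self) -> list[str]:
        return sorted(self.data["parameter"].unique())

    def series(self, station: str, parameter: str) -> pd.Series:
        """Monthly series for one station/parameter, indexed by date."""
        sub = self.data[(self.data["station"] == station)
                        & (self.data["parameter"] == parameter)]
        return sub.set_index("date")["value"].sort_index()


@dataclass(frozen=True)
class GuidelineSet:
    """Per-parameter guideline values Si and ideal values Vo.

    Si is the recommended criterion concentration for each parameter (user
    supplied — regulatory criteria vary by jurisdiction and are not baked
    in); Vo defaults to zero except pH (7.0) and DO (14.6 mg/L).
    """

    si: dict[str, float]
    vo: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vo_full = {p: DEFAULT_IDEAL_VALUES.get(p, 0.0) for p in self.si}
        vo_full.update(self.vo)
        object.__setattr__(self, "vo", vo_full)
        for p, s in self.si.items():
            if not np.isfinite(s) or s <= 0:
                raise ValidationError(f"guideline Si for {p!r} must be > 0, got {s}")
            if s == self.vo[p]:
                raise ValidationError(
                    f"Si equals Vo ({s}) for {p!r}; quality rating undefined")

    @property
    def parameters(self) -> list[str]:
        return sorted(self.si)


@dataclass(frozen=True)
class AreaMap:
    """Mapping of area labels to disjoint, non-empty station lists."""

    areas: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, stations in self.areas.items():
            if len(stations) == 0:
                raise ValidationError(f"area {label!r} has no stations")
            overlap = seen & set(stations)
            if overlap:
                raise ValidationError(f"stations {sorted(overlap)} appear in multiple areas")
            seen |= set(stations)

    def __getitem__(self, label: str) -> tuple[str, ...]:
        return self.areas[label]

    @property
    def labels(self) -> list[str]:
        return list(self.areas)


def validate_monitoring_frame(df: pd.DataFrame) -> None:
    required = {"station", "date", "parameter", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"monitoring table missing columns {sorted(missing)}")
    if df.empty:
        return
    values = df["value"].to_numpy(float)
    if not np.all(np.isfinite(values)):
        bad = df.index[~np.isfinite(values)].tolist()
        raise ValidationError(f"non-finite values at rows {bad[:10]}")
    problems = []
    for idx, (param, v) in enumerate(zip(df["parameter"], values)):
        if param == "ph":
            if not (0.0 <= v <= 14.0):
                problems.append((df.index[idx], param, v, "pH outside [0, 14]"))
        elif param != "temperature" and v < 0:
            problems.append((df.index[idx], param, v, "negative concentration"))
    if problems:
        lines = "; ".join(f"row {r}: {p}={v} ({msg})" for r, p, v, msg in problems[:10])
        raise ValidationError(f"invalid observations: {lines}")
    dup = df.duplicated(["station", "date", "parameter"])
    if dup.any():
        raise ValidationError(
            f"duplicate (station, date, parameter) rows at {df.index[dup].tolist()[:10]}")


def read_monitoring_csv(
    path: str | Path,
    schema: dict[str, str] | None = None,
    on_unknown_parameter: str = "warn",
) -> MonitoringTable:
    """Read a long-format monitoring CSV into a validated table.

    Parameters
    ----------
    path
        CSV with header; columns station, date, parameter, value, unit
        (or as remapped by ``schema``: canonical -> actual column name).
    schema
        Optional column-name mapping, e.g. ``{"station": "Site ID"}``.
    on_unknown_parameter
        ``"warn"`` (default) drops rows whose parameter cannot be resolved
        to the twelve-name vocabulary with a logged warning; ``"error"``
        raises instead.

    Duplicate (station, month, parameter) rows — including sub-monthly
    observations falling in the same month — are averaged with a log entry.
    Every input row is accepted, averaged-with-log, or reported; none are
    silently dropped.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {actual: canon for canon, actual in schema.items()}
    raw = raw.rename(columns=rename)
    required = ["station", "date", "parameter", "value"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if "unit" not in raw.columns:
        raw["unit"] = [PARAMETERS.get(resolve_parameter(p) or "", "")
                       for p in raw["parameter"]]

    canon = raw["parameter"].map(lambda p: resolve_parameter(p))
    unknown = raw.loc[canon.isna(), "parameter"].unique().tolist()
    if unknown:
        msg = f"{path}: unknown parameter names {unknown} (rows dropped)"
        if on_unknown_parameter == "error":
            raise ValidationError(msg)
        logger.warning(msg)
    raw = raw.assign(parameter=canon).dropna(subset=["parameter"])

    dates = pd.to_datetime(raw["date"], format="mixed")
    raw = raw.assign(date=dates.dt.to_period("M").dt.to_timestamp())

    dup_mask = raw.duplicated(["station", "date", "parameter"], keep=False)
    if dup_mask.any():
        n_groups = raw[dup_mask].groupby(["station", "date", "parameter"]).ngroups
        logger.warning("%s: %d (station, month, parameter) groups had multiple "
                       "observations; averaged to monthly means", path, n_groups)
    out = (raw.groupby(["station", "date", "parameter"], as_index=False)
              .agg(value=("value", "mean"), unit=("unit", "first"))
              .loc[:, ["station", "date", "parameter", "value", "unit"]])
    return MonitoringTable(out.reset_index(drop=True))


def read_monitoring_wide_csv(path: str | Path, **kwargs) -> MonitoringTable:
    """Convenience reader for wide CSVs (station, date, one column per
    parameter); melts to long form and delegates to the long-format path."""
    wide = pd.read_csv(path)
    long = wide.melt(id_vars=["station", "date"], var_name="parameter",
                     value_name="value").dropna(subset=["value"])
    tmp = Path(path).with_suffix(".long.tmp.csv")
    try:
        long.to_csv(tmp, index=False)
        return read_monitoring_csv(tmp, **kwargs)
    finally:
        tmp.unlink(missing_ok=True)


def load_guidelines(path: str | Path) -> GuidelineSet:
    """Load a YAML guideline config.

    Expected shape::

        guidelines:
          tss: {si: 30}
          ph:  {si: 8.5, vo: 7.0}   # vo optional, defaults applied

    A bare ``param: si_value`` mapping is also accepted.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    section = cfg.get("guidelines", cfg) if isinstance(cfg, dict) else None
    if not isinstance(section, dict) or not section:
        raise ValidationError(f"{path}: no guideline entries found")
    si: dict[str, float] = {}
    vo: dict[str, float] = {}
    for name, entry in section.items():
        canon = resolve_parameter(name)
        if canon is None:
            raise ValidationError(f"{path}: unknown parameter {name!r}")
        if isinstance(entry, dict):
            if "si" not in entry:
                raise ValidationError(f"{path}: missing Si for {name!r}")
            si[canon] = float(entry["si"])
            if "vo" in entry:
                vo[canon] = float(entry["vo"])
        else:
            si[canon] = float(entry)
    return GuidelineSet(si=si, vo=vo)


def load_area_map(cfg: dict | str | Path) -> AreaMap:
    """Build an AreaMap from a YAML path or an ``{area: [stations]}`` dict."""
    if not isinstance(cfg, dict):
        with open(cfg) as fh:
            cfg = yaml.safe_load(fh)
        cfg = cfg.get("areas", cfg)
    return AreaMap({label: tuple(st) for label, st in cfg.items()})


def write_monitoring_csv(table: MonitoringTable, path: str | Path) -> None:
    df = table.data.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m")
    df.to_csv(path, index=False, float_format="%.12g")


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: dict | None = None,
) -> dict[str, str]:
    """Write named result tables as CSV plus a JSON run-metadata sidecar.

    Column order is preserved as given (deterministic); metadata records the
    seed/config the caller passes plus a content hash per table, so two runs
    with identical inputs produce byte-identical artifacts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    hashes: dict[str, str] = {}
    for name, df in tables.items():
        dest = out_dir / f"{name}.csv"
        df.to_csv(dest, index=False, float_format="%.12g")
        manifest[name] = str(dest)
        hashes[name] = hashlib.sha256(dest.read_bytes()).hexdigest()[:16]
    meta = {"tables": hashes}
    if metadata:
        meta.update(metadata)
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    manifest["run_metadata"] = str(meta_path)
    return manifest
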