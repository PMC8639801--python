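"""Regional daily weather/air series and the per-visit W-score.

Station records (long format: station, date, element, value) are harmonized to
one value per region/day/element by taking the median across the region's
reporting stations; remaining gaps are filled with the average of that
element's regional daily medians over the study window.  Daily points per
element come from two-tier advisory/warning criteria with run-length
persistence requirements; the W-score of a visit is the element-wise sum of
daily points over the 7 consecutive days starting at the discharge date.

Elements scored: pm10 (fine dust), rainfall (heavy rain), humidity (dryness,
fall-below), tmin (cold wave, fall-below), tmax (heat wave).  Other ingested
pollutants (pm25, so2, no2, o3) are harmonized and exported but never scored:
pm2.5 is heavily missing in source data and collinear with pm10.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

ELEMENTS = ("tmax", "tmin", "humidity", "rainfall", "pm10", "pm25", "so2", "no2", "o3")
SCORED_ELEMENTS = ("pm10", "rainfall", "humidity", "tmin", "tmax")
WINDOW_DAYS = 7

W_COLUMNS = [f"w_{e}" for e in SCORED_ELEMENTS]


class ElementCriteria(BaseModel):
    """Two-tier threshold rule for one element."""

    direction: str = Field(pattern="^(above|below)$")
    advisory: float
    warning: float
    persistence_days: int = Field(ge=1, default=1)
    advisory_points: float = Field(ge=0, default=1.0)
    warning_points: float = Field(ge=0, default=2.0)

    @model_validator(mode="after")
    def _warning_stricter(self) -> "ElementCriteria":
        if self.direction == "above" and self.warning < self.advisory:
            raise ValueError("warning threshold must be >= advisory for 'above'")
        if self.direction == "below" and self.warning > self.advisory:
            raise ValueError("warning threshold must be <= advisory for 'below'")
        if self.warning_points < self.advisory_points:
            raise ValueError("warning_points must be >= advisory_points")
        return self


class WarningCriteria(BaseModel):
    elements: dict[str, ElementCriteria]

    @model_validator(mode="after")
    def _scored_only(self) -> "WarningCriteria":
        unknown = set(self.elements) - set(SCORED_ELEMENTS)
        if unknown:
            raise ValueError(f"criteria for unscorable elements: {sorted(unknown)}")
        return self


def load_criteria(path: str | Path | None = None) -> WarningCriteria:
    """Load warning criteria (the shipped daily-resolution defaults if None)."""
    if path is None:
        with resources.as_file(resources.files("readmitwx.data") / "criteria.yaml") as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return WarningCriteria(**raw)


def harmonize(
    stations: pd.DataFrame,
    station_map: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp],
    impute: bool = True,
) -> pd.DataFrame:
    """Station records -> per-region daily series.

    ``stations``: columns station_id, date, element, value (value NaN for a
    missing report).  ``station_map``: station_id -> region_id.  Returns a
    long DataFrame (region_id, date, element, value, imputed) with complete
    date coverage over ``window`` for every element observed in each region.
    """
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    mapped_regions = set(station_map["region_id"])
    unmapped = set(stations["station_id"]) - set(station_map["station_id"])
    if unmapped:
        raise ValueError(f"stations without region mapping: {sorted(unmapped)}")
    if not mapped_regions:
        raise ValueError("station map defines no regions")

    df = stations.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df[(df["date"] >= lo) & (df["date"] <= hi)]
    df = df.merge(station_map[["station_id", "region_id"]], on="station_id")
    med = (
        df.dropna(subset=["value"])
        .groupby(["region_id", "element", "date"], sort=False)["value"]
        .median()
        .reset_index()
    )

    dates = pd.date_range(lo, hi, freq="D")
    elements = sorted(df["element"].unique())
    full = pd.MultiIndex.from_product(
        [sorted(mapped_regions), elements, dates], names=["region_id", "element", "date"]
    ).to_frame(index=False)
    out = full.merge(med, on=["region_id", "element", "date"], how="left")
    out["imputed"] = out["value"].isna()
    if impute:
        out = impute_missing(out)
    return out


def impute_missing(series: pd.DataFrame) -> pd.DataFrame:
    """Fill missing region-days with the mean of that element's regional daily
    medians over the study window; sets the ``imputed`` flag.

    An element never observed in a region is a fatal error.  After filling,
    days where imputation left tmin above tmax are reconciled by clipping tmin
    to tmax (the generator and real stations never report tmin > tmax; only
    one-sided imputation can produce it).
    """
    out = series.copy()
    if "imputed" not in out.columns:
        out["imputed"] = out["value"].isna()
    grp = out.groupby(["region_id", "element"], sort=False)["value"]
    never = grp.count() == 0
    if never.any():
        missing = never[never].index.tolist()
        raise ValueError(f"element never observed in region: {missing}")
    fill = grp.transform("mean")
    out["value"] = out["value"].fillna(fill)

    wide = out.pivot_table(
        index=["region_id", "date"], columns="element", values="value", aggfunc="first"
    )
    if {"tmin", "tmax"} <= set(wide.columns):
        bad = wide["tmin"] > wide["tmax"]
        if bad.any():
            fixed = wide.loc[bad, "tmax"]
            key = out.set_index(["region_id", "date"]).index
            mask = (out["element"] == "tmin").to_numpy() & key.isin(bad[bad].index)
            out.loc[mask, "value"] = out.loc[mask].set_index(["region_id", "date"]).index.map(fixed).to_numpy()
    return out


def daily_points(
    series: pd.DataFrame, criteria: WarningCriteria
) -> pd.DataFrame:
    """Per region/date daily points for every scored element.

    Persistence is evaluated retrospectively: a tier is met at date d only if
    its threshold test passes on ``persistence_days`` consecutive series days
    ending at d (days before the series start cannot contribute, so the first
    ``persistence_days - 1`` days of a series can never satisfy a multi-day
    tier).  Returns a wide frame indexed by (region_id, date) with one column
    per scored element.
    """
    wide = series.pivot_table(
        index=["region_id", "date"], columns="element", values="value", aggfunc="first"
    ).sort_index()
    out = {}
    for elem, crit in criteria.elements.items():
        if elem not in wide.columns:
            continue
        pts = np.zeros(len(wide))
        for region, sub in wide.groupby(level="region_id", sort=False):
            vals = sub[elem].to_numpy(dtype=float)
            pos = wide.index.get_locs([region])
            pts[pos] = _element_points(vals, crit)
        out[elem] = pts
    return pd.DataFrame(out, index=wide.index)


def _element_points(values: np.ndarray, crit: ElementCriteria) -> np.ndarray:
    if crit.direction == "above":
        adv = values >= crit.advisory
        warn = values >= crit.warning
    else:
        adv = values <= crit.advisory
        warn = values <= crit.warning
    k = crit.persistence_days
    adv_run = _runlength_ok(adv, k)
    warn_run = _runlength_ok(warn, k)
    return np.where(warn_run, crit.warning_points, np.where(adv_run, crit.advisory_points, 0.0))


def _runlength_ok(flags: np.ndarray, k: int) -> np.ndarray:
    """True at i iff flags[i-k+1 .. i] all True (False where fewer than k days)."""
    if k == 1:
        return flags.copy()
    ok = np.zeros_like(flags, dtype=bool)
    if len(flags) >= k:
        csum = np.cumsum(np.concatenate([[0], flags.astype(int)]))
        ok[k - 1 :] = (csum[k:] - csum[:-k]) == k
    return ok


def wscore_events(
    events: pd.DataFrame,
    series: pd.DataFrame,
    criteria: WarningCriteria | None = None,
    window_days: int = WINDOW_DAYS,
) -> pd.DataFrame:
    """W-score for each index event: per-element daily points summed over the
    ``window_days`` consecutive days starting at the discharge date.

    ``events`` needs visit_id, region_id, discharge_date.  Raises if any
    event's exposure window is not covered by its region's series, naming the
    event and missing dates.
    """
    if criteria is None:
        criteria = load_criteria()
    pts = daily_points(series, criteria).reset_index()
    cols = [e for e in SCORED_ELEMENTS if e in pts.columns]
    out_cols = ["visit_id", *[f"w_{c}" for c in cols], "window_start", "window_end"]
    if not len(events):
        return pd.DataFrame(columns=out_cols)

    ev = events[["visit_id", "region_id", "discharge_date"]].copy()
    ev["discharge_date"] = pd.to_datetime(ev["discharge_date"])
    # expand each event into its window_days calendar days, then join points
    expanded = ev.loc[ev.index.repeat(window_days)].reset_index(drop=True)
    offsets = np.tile(np.arange(window_days), len(ev))
    expanded["date"] = expanded["discharge_date"] + pd.to_timedelta(offsets, unit="D")
    merged = expanded.merge(pts, on=["region_id", "date"], how="left", indicator=True)
    uncovered = merged["_merge"] == "left_only"
    if uncovered.any():
        bad = merged.loc[uncovered, ["visit_id", "date"]]
        first = bad["visit_id"].iloc[0]
        dates = sorted(d.date().isoformat() for d in bad.loc[bad["visit_id"] == first, "date"])
        raise ValueError(
            f"exposure window not covered for visit {first}: missing dates {dates}"
            + ("" if bad["visit_id"].nunique() == 1 else f" (+{bad['visit_id'].nunique() - 1} more events)")
        )
    sums = merged.groupby("visit_id", sort=False)[cols].sum()
    out = ev[["visit_id", "discharge_date"]].copy()
    for c in cols:
        out[f"w_{c}"] = out["visit_id"].map(sums[c]).astype(float)
    out["window_start"] = out["discharge_date"]
    out["window_end"] = out["discharge_date"] + pd.Timedelta(days=window_days - 1)
    return out[out_cols].reset_index(drop=True)


@dataclass(frozen=True)
class WScore:
    """Five-element exposure vector for one index event."""

    visit_id: object
    pm10: float
    rainfall: float
    humidity: float
    tmin: float
    tmax: float
    window_start: pd.Timestamp
    window_end: pd.Timestamp


def wscore(event, series: pd.DataFrame, criteria: WarningCriteria | None = None) -> WScore:
    """Single-event convenience wrapper around :func:`wscore_events`."""
    ev = pd.DataFrame(
        [
            {
                "visit_id": event["visit_id"],
                "region_id": event["region_id"],
                "discharge_date": event["discharge_date"],
            }
        ]
    )
    row = wscore_events(ev, series, criteria).iloc[0]
    return WScore(
        visit_id=row["visit_id"],
        pm10=row.get("w_pm10", 0.0),
        rainfall=row.get("w_rainfall", 0.0),
        humidity=row.get("w_humidity", 0.0),
        tmin=row.get("w_tmin", 0.0),
        tmax=row.get("w_tmax", 0.0),
        window_start=row["window_start"],
        window_end=row["window_end"],
    )
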