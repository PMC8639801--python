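"""Station harmonization, daily-median imputation and W-score computation,
checked against a brute-force day-by-day scoring oracle."""

import numpy as np
import pandas as pd
import pytest

from readmitwx.exposure import (
    SCORED_ELEMENTS,
    ElementCriteria,
    WarningCriteria,
    daily_points,
    harmonize,
    impute_missing,
    load_criteria,
    wscore,
    wscore_events,
)

LO, HI = pd.Timestamp("2017-07-01"), pd.Timestamp("2017-07-31")


def station_records(values_by_station, element="pm10", dates=None):
    dates = dates if dates is not None else pd.date_range(LO, periods=3)
    rows = []
    for sid, vals in values_by_station.items():
        for d, v in zip(dates, vals):
            rows.append({"station_id": sid, "date": d, "element": element, "value": v})
    return pd.DataFrame(rows)


def smap(stations, region="R1"):
    return pd.DataFrame({"station_id": list(stations), "region_id": region})


# ---------------------------------------------------------------- harmonize

def test_single_station_passthrough():
    recs = station_records({"s1": [10.0, 20.0, 30.0]})
    out = harmonize(recs, smap(["s1"]), (LO, LO + pd.Timedelta(days=2)))
    assert out["value"].tolist() == [10.0, 20.0, 30.0]
    assert not out["imputed"].any()


def test_cross_station_median():
    recs = station_records({"s1": [10.0], "s2": [20.0], "s3": [90.0]},
                           dates=[LO])
    out = harmonize(recs, smap(["s1", "s2", "s3"]), (LO, LO))
    assert out["value"].tolist() == [20.0]


def test_disjoint_missing_days_union_coverage():
    recs = station_records({"s1": [1.0, np.nan, 3.0], "s2": [np.nan, 2.0, np.nan]})
    out = harmonize(recs, smap(["s1", "s2"]), (LO, LO + pd.Timedelta(days=2)))
    assert out["value"].tolist() == [1.0, 2.0, 3.0]
    assert not out["imputed"].any()


def test_unmapped_station_fatal():
    recs = station_records({"s1": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="without region mapping"):
        harmonize(recs, smap([]), (LO, HI))


# ------------------------------------------------------------ impute_missing

def test_impute_fills_with_mean_of_daily_medians():
    # 4-day series with one missing day among observed {10, 20, 30}
    dates = pd.date_range(LO, periods=4)
    recs = station_records({"s1": [10.0, 20.0, np.nan, 30.0]}, dates=dates)
    out = harmonize(recs, smap(["s1"]), (LO, dates[-1]))
    assert out.loc[2, "value"] == pytest.approx(20.0)
    assert out.loc[2, "imputed"]
    assert out["imputed"].sum() == 1  # conservation: exactly the missing day


def test_impute_identity_when_complete():
    recs = station_records({"s1": [10.0, 20.0, 30.0]})
    series = harmonize(recs, smap(["s1"]), (LO, LO + pd.Timedelta(days=2)), impute=False)
    out = impute_missing(series)
    assert out["value"].tolist() == [10.0, 20.0, 30.0]
    assert not out["imputed"].any()


def test_never_observed_element_fatal():
    recs = station_records({"s1": [np.nan, np.nan, np.nan]})
    series = harmonize(recs, smap(["s1"]), (LO, LO + pd.Timedelta(days=2)), impute=False)
    with pytest.raises(ValueError, match="never observed"):
        impute_missing(series)


def test_imputation_preserves_tmin_le_tmax():
    dates = pd.date_range(LO, periods=4)
    recs = pd.concat(
        [
            station_records({"s1": [30.0, 2.0, 30.0, 30.0]}, element="tmax", dates=dates),
            station_records({"s1": [20.0, np.nan, 20.0, 20.0]}, element="tmin", dates=dates),
        ]
    )
    out = harmonize(recs, smap(["s1"]), (LO, dates[-1]))
    wide = out.pivot_table(index="date", columns="element", values="value")
    assert (wide["tmin"] <= wide["tmax"]).all()


# ------------------------------------------------------------- daily scoring

def make_series(region="R1", start="2017-07-01", **element_values):
    """Build a harmonized series from per-element daily value lists."""
    rows = []
    for elem, vals in element_values.items():
        for i, v in enumerate(vals):
            rows.append(
                {"region_id": region, "date": pd.Timestamp(start) + pd.Timedelta(days=i),
                 "element": elem, "value": float(v), "imputed": False}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def criteria():
    return load_criteria()


def test_unremarkable_day_scores_zero(criteria):
    series = make_series(tmax=[25.0, 25.0], tmin=[15.0, 15.0], humidity=[60.0, 60.0],
                         rainfall=[0.0, 1.0], pm10=[40.0, 50.0])
    pts = daily_points(series, criteria)
    assert (pts.to_numpy() == 0).all()


def test_heat_advisory_with_persistence(criteria):
    # advisory >= 33 on two consecutive days -> advisory points on day 2 only
    pts = daily_points(make_series(tmax=[34.0, 34.0, 20.0]), criteria)
    assert pts["tmax"].tolist() == [0.0, 1.0, 0.0]


def test_heat_warning_tier(criteria):
    pts = daily_points(make_series(tmax=[36.0, 36.0]), criteria)
    assert pts["tmax"].tolist() == [0.0, 2.0]


def test_pm10_warning_no_persistence(criteria):
    pts = daily_points(make_series(pm10=[320.0, 40.0, 160.0]), criteria)
    assert pts["pm10"].tolist() == [2.0, 0.0, 1.0]


def test_dryness_fall_below_direction(criteria):
    pts = daily_points(make_series(humidity=[30.0, 30.0, 20.0]), criteria)
    # day 2: advisory run (<=35 twice); day 3: warning needs <=25 twice -> only advisory
    assert pts["humidity"].tolist() == [0.0, 1.0, 1.0]
    pts2 = daily_points(make_series(humidity=[20.0, 20.0]), criteria)
    assert pts2["humidity"].tolist() == [0.0, 2.0]


def test_cold_wave_fall_below(criteria):
    pts = daily_points(make_series(tmin=[-16.0, -16.0, -13.0]), criteria)
    assert pts["tmin"].tolist() == [0.0, 2.0, 1.0]  # day3: advisory run continues


# ------------------------------------------------------------------- wscore

def event(visit="V1", region="R1", discharge="2017-07-01"):
    return pd.DataFrame(
        [{"visit_id": visit, "region_id": region,
          "discharge_date": pd.Timestamp(discharge)}]
    )


def test_wscore_sums_window(criteria):
    vals = [320.0, 40.0, 160.0, 40.0, 40.0, 40.0, 160.0, 320.0]
    series = make_series(pm10=vals)
    out = wscore_events(event(), series, criteria)
    # days 0..6: 2 + 0 + 1 + 0 + 0 + 0 + 1 = 4; the day-7 warning is outside
    assert out.loc[0, "w_pm10"] == 4.0
    assert out.loc[0, "window_start"] == pd.Timestamp("2017-07-01")
    assert out.loc[0, "window_end"] == pd.Timestamp("2017-07-07")


def test_zero_daily_scores_zero_wscore(criteria):
    series = make_series(pm10=[40.0] * 7)
    out = wscore_events(event(), series, criteria)
    assert out.loc[0, "w_pm10"] == 0.0


def test_uncovered_window_names_event(criteria):
    series = make_series(pm10=[40.0] * 5)  # only 5 days
    with pytest.raises(ValueError, match="V1"):
        wscore_events(event(), series, criteria)


def test_pm10_monotonicity(criteria):
    vals = [140.0] * 7
    base = wscore_events(event(), make_series(pm10=vals), criteria).loc[0, "w_pm10"]
    for day in range(7):
        bumped = list(vals)
        bumped[day] = 500.0
        up = wscore_events(event(), make_series(pm10=bumped), criteria).loc[0, "w_pm10"]
        assert up >= base


def test_window_shift_across_year_boundary(criteria):
    """Shifting discharge by k days shifts the scored window by exactly k."""
    start = "2017-12-25"
    n = 20
    rng = np.random.default_rng(7)
    vals = rng.uniform(30, 400, size=n)
    series = make_series(start=start, pm10=list(vals))
    pts = daily_points(series, criteria)["pm10"].to_numpy()
    for k in range(0, 14):
        d = pd.Timestamp(start) + pd.Timedelta(days=k)
        got = wscore_events(event(discharge=d), series, criteria).loc[0, "w_pm10"]
        assert got == pts[k : k + 7].sum()


def test_wscore_single_event_wrapper(criteria):
    series = make_series(pm10=[320.0] * 7)
    w = wscore({"visit_id": "V9", "region_id": "R1", "discharge_date": "2017-07-01"},
               series, criteria)
    assert w.pm10 == 14.0
    assert w.visit_id == "V9"


# ------------------------------------------------- brute-force oracle

def oracle_daily_score(values, i, crit):
    """Day-by-day loop: check the persistence run ending at day i per tier."""
    def run_ok(threshold):
        if i - crit.persistence_days + 1 < 0:
            return False
        for j in range(i - crit.persistence_days + 1, i + 1):
            v = values[j]
            if crit.direction == "above" and not v >= threshold:
                return False
            if crit.direction == "below" and not v <= threshold:
                return False
        return True

    if run_ok(crit.warning):
        return crit.warning_points
    if run_ok(crit.advisory):
        return crit.advisory_points
    return 0.0


def oracle_wscore(series_wide, discharge_idx, criteria):
    out = {}
    for elem, crit in criteria.elements.items():
        vals = series_wide[elem]
        out[elem] = sum(
            oracle_daily_score(vals, i, crit)
            for i in range(discharge_idx, discharge_idx + 7)
        )
    return out


def random_instance(rng, start="2017-11-20", n=30):
    tmax = rng.uniform(-20, 40, size=n)
    gap = rng.uniform(1, 12, size=n)
    return {
        "tmax": list(tmax),
        "tmin": list(tmax - gap),
        "humidity": list(rng.uniform(5, 100, size=n)),
        "rainfall": list(rng.exponential(40, size=n)),
        "pm10": list(rng.uniform(0, 400, size=n)),
    }


@pytest.mark.parametrize("seed", range(5))
def test_wscore_matches_oracle_random(seed, criteria):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        wide = random_instance(rng)
        series = make_series(start="2017-11-20", **wide)
        idx = int(rng.integers(0, 30 - 7 + 1))
        d = pd.Timestamp("2017-11-20") + pd.Timedelta(days=idx)
        got = wscore_events(event(discharge=d), series, criteria).iloc[0]
        want = oracle_wscore(wide, idx, criteria)
        for elem in SCORED_ELEMENTS:
            assert got[f"w_{elem}"] == want[elem], (elem, idx)


def test_criteria_validation():
    with pytest.raises(ValueError):
        ElementCriteria(direction="above", advisory=35.0, warning=33.0)
    with pytest.raises(ValueError):
        ElementCriteria(direction="below", advisory=-15.0, warning=-12.0)
    with pytest.raises(ValueError):
        WarningCriteria(elements={"so2": ElementCriteria(direction="above", advisory=1, warning=2)})
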