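"""Two-site synthetic EHR + weather study generator.

Emulates the study design the pipeline is built for: two hospital sites
(internal/training and external/validation) of elderly inpatients with
ICD-10-coded diagnoses concentrated in four chapter groups (F mental,
I circulatory, J respiratory, M musculoskeletal), drug exposures, residence
regions, seasonal station weather and PM10 series, and a logistic readmission
outcome whose linear predictor uses the TRUE covariates -- including the true
W-score computed from the generated series through the same exposure code the
pipeline uses, so downstream label and signal recovery can be checked exactly.

Visits of one person are spaced far enough apart (>100 days) that the only
admissions falling inside a 30-day outcome window are the readmission visits
this generator plants; cohort labelling therefore recovers the planted
outcomes exactly.  All randomness flows from one integer seed through named
`numpy` SeedSequence children (weather / clinical / outcomes, per site), so
adding persons does not perturb the weather stream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .cdm import CdmBundle, write_cdm_bundle
from .charlson import charlson_scores_bulk
from .cohort import assign_disease_groups, identify_index_admissions
from .exposure import SCORED_ELEMENTS, WarningCriteria, harmonize, load_criteria, wscore_events

# ICD-10 discharge-diagnosis pools per chapter group
DIAGNOSIS_POOLS: dict[str, tuple[str, ...]] = {
    "F": ("F03", "F05", "F10", "F20", "F31", "F32", "F41"),
    "I": ("I10", "I20", "I21", "I25", "I48", "I50", "I63", "I70"),
    "J": ("J12", "J15", "J18", "J20", "J40", "J44", "J45", "J96"),
    "M": ("M16", "M17", "M25", "M48", "M54", "M75", "M80", "M81"),
}

#: historical-condition pool (about half Charlson-mapped, elderly-typical)
HISTORY_POOL: tuple[str, ...] = (
    "E119", "E112", "I10", "I50", "I63", "I21", "J44", "F03", "N18",
    "C34", "C78", "K74", "K25", "M05", "G81", "M54", "K21", "H25",
    "E78", "J45",
)

#: drug ingredient pool (ATC-style codes)
DRUG_POOL: tuple[str, ...] = (
    "A02BC01", "A10BA02", "B01AC06", "C01DA14", "C03CA01", "C07AB03",
    "C08CA01", "C09AA05", "C10AA05", "J01CA04", "M01AE01", "N02BE01",
    "N05BA06", "N06AB03", "R03AC02", "R03BB04", "H03AA01", "A11CC05",
    "B03BA01", "N02AA05",
)

TRUTH_COLUMNS = [
    "visit_id", "person_id", "site_id", "region_id", "age_at_index",
    "length_of_stay", "charlson", "disease_group",
    *[f"w_{e}" for e in SCORED_ELEMENTS],
    "lin_pred", "prob", "outcome", "readmission_date",
]


class SeasonalParams(BaseModel):
    """Sinusoidal annual cycle: mean + amplitude*sin(2*pi*(doy - phase)/365) + noise."""

    mean: float
    amplitude: float = 0.0
    phase_day: float = 122.0  # sine peaks ~91 days after the phase day
    noise_sd: float = Field(ge=0, default=0.0)


class WeatherParams(BaseModel):
    tmax: SeasonalParams = SeasonalParams(mean=18.0, amplitude=13.0, phase_day=122.0, noise_sd=3.5)
    #: daily tmin = tmax - max(gap_min, Normal(gap_mean, gap_sd))
    diurnal_gap_mean: float = 8.0
    diurnal_gap_sd: float = Field(ge=0, default=2.0)
    diurnal_gap_min: float = 1.0
    humidity: SeasonalParams = SeasonalParams(mean=62.0, amplitude=12.0, phase_day=122.0, noise_sd=10.0)
    #: rainfall: P(dry) = zero_inflation; wet amount ~ Exp(scale seasonal)
    rain_zero_inflation: float = Field(ge=0, le=1, default=0.65)
    rain_scale_mean: float = 14.0
    rain_scale_amplitude: float = 11.0
    rain_phase_day: float = 122.0
    #: pm10: lognormal with seasonally elevated log-mean (spring peak)
    pm10_log_mean: float = 3.91  # ~= log(50 ug/m3)
    pm10_log_sd: float = Field(ge=0, default=0.5)
    pm10_seasonal_elevation: float = 0.4
    pm10_phase_day: float = 46.0  # elevation peaks mid-May


class OutcomeModel(BaseModel):
    """Logistic readmission model on the true covariates; age enters centred
    at 75 years so the intercept stays interpretable as the baseline logit."""

    intercept: float = -2.9
    beta_age: float = 0.02
    beta_los: float = 0.05
    beta_charlson: float = 0.3
    beta_w: dict[str, float] = Field(
        default_factory=lambda: {"pm10": 0.15, "rainfall": 0.1, "humidity": 0.0, "tmin": 0.0, "tmax": 0.1}
    )
    beta_condition: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.25, "I": 0.1, "J": 0.2, "M": 0.0}
    )

    @model_validator(mode="after")
    def _finite(self) -> "OutcomeModel":
        vals = [self.intercept, self.beta_age, self.beta_los, self.beta_charlson,
                *self.beta_w.values(), *self.beta_condition.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("outcome-model coefficients must be finite")
        unknown = set(self.beta_w) - set(SCORED_ELEMENTS)
        if unknown:
            raise ValueError(f"beta_w for unknown elements: {sorted(unknown)}")
        return self


class RegionParams(BaseModel):
    region_id: str
    postal_code: str = "00000"
    tmax_offset: float = 0.0
    humidity_offset: float = 0.0
    pm10_log_offset: float = 0.0


class SiteShift(BaseModel):
    """Additive offsets applied to the external site's generating parameters."""

    age_years: float = 0.0
    temp: float = 0.0
    humidity: float = 0.0
    pm10_log: float = 0.0
    intercept: float = 0.0


def _default_regions() -> list[RegionParams]:
    return [
        RegionParams(region_id="R1", postal_code="03080", pm10_log_offset=0.05),
        RegionParams(region_id="R2", postal_code="06236", tmax_offset=0.5),
        RegionParams(region_id="R3", postal_code="13605", tmax_offset=-0.5, pm10_log_offset=-0.05),
        RegionParams(region_id="R4", postal_code="16499", humidity_offset=2.0),
    ]


class SimConfig(BaseModel):
    seed: int = 0
    n_persons_per_site: int = Field(ge=0, default=2000)
    study_start: dt.date = dt.date(2017, 1, 1)
    study_end: dt.date = dt.date(2018, 12, 31)
    regions: list[RegionParams] = Field(default_factory=_default_regions)
    # internal-cohort group shares patterned on a four-chapter elderly case mix
    disease_group_mix: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.087, "I": 0.257, "J": 0.283, "M": 0.373}
    )
    mean_visits_per_person: float = Field(gt=0, default=1.3)
    los_mean_days: float = Field(gt=0, default=3.0)
    er_los_mean_days: float = Field(gt=0, default=0.4)
    emergency_fraction: float = Field(ge=0, le=1, default=0.3)
    death_rate: float = Field(ge=0, le=1, default=0.03)
    age_min: int = 60
    age_max: int = 99
    mean_history_conditions: float = 1.2
    mean_drug_exposures: float = 2.0
    n_stations_per_region: int = Field(ge=1, default=1)
    missing_weather_rate: float = Field(ge=0, le=1, default=0.02)
    weather: WeatherParams = WeatherParams()
    outcome_model: OutcomeModel = OutcomeModel()
    site_shift: SiteShift = SiteShift(age_years=1.0, temp=-0.5, pm10_log=0.08)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        total = sum(self.disease_group_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"disease_group_mix must sum to 1, got {total}")
        if set(self.disease_group_mix) - set(DIAGNOSIS_POOLS):
            raise ValueError("disease_group_mix keys must be chapters F/I/J/M")
        if self.study_end <= self.study_start:
            raise ValueError("study window empty")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return pd.Timestamp(self.study_start), pd.Timestamp(self.study_end)


# margin (days) kept between the last allowed admission and the window end so
# that index stay (<=30 d), planted readmission (<=30 d later, <=10 d stay)
# and both 7-day exposure windows stay inside the generated weather series
ADMIT_MARGIN_DAYS = 80
MAX_INDEX_LOS = 30
MAX_READMIT_LOS = 10
MIN_VISIT_SPACING = 105


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "weather_internal", "weather_external",
        "clinical_internal", "clinical_external",
        "outcomes_internal", "outcomes_external",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _seasonal(doy: np.ndarray, p: SeasonalParams, rng: np.random.Generator, offset: float = 0.0) -> np.ndarray:
    base = p.mean + offset + p.amplitude * np.sin(2 * np.pi * (doy - p.phase_day) / 365.0)
    return base + rng.normal(0.0, p.noise_sd, size=doy.shape)


def generate_weather_series(
    params: WeatherParams,
    regions: list[RegionParams],
    window: tuple[pd.Timestamp, pd.Timestamp],
    seed: int | np.random.Generator,
    n_stations_per_region: int = 1,
    missing_rate: float = 0.0,
    temp_shift: float = 0.0,
    humidity_shift: float = 0.0,
    pm10_log_shift: float = 0.0,
) -> pd.DataFrame:
    """Station-level daily records, long format (station_id, date, element, value).

    Values are NaN where a missing report was injected.  Besides the five
    scored elements, correlated pm25 and small so2/no2/o3 series are emitted
    so ingestion of unscored pollutants is exercised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dates = pd.date_range(window[0], window[1], freq="D")
    doy = dates.day_of_year.to_numpy().astype(float)
    frames = []
    for region in regions:
        for k in range(n_stations_per_region):
            station = f"{region.region_id}_s{k + 1}"
            tmax = _seasonal(doy, params.tmax, rng, region.tmax_offset + temp_shift)
            gap = np.maximum(
                params.diurnal_gap_min,
                rng.normal(params.diurnal_gap_mean, params.diurnal_gap_sd, size=len(dates)),
            )
            tmin = tmax - gap
            hum = np.clip(
                _seasonal(doy, params.humidity, rng, region.humidity_offset + humidity_shift),
                2.0, 100.0,
            )
            wet = rng.random(len(dates)) >= params.rain_zero_inflation
            scale = np.maximum(
                0.5,
                params.rain_scale_mean
                + params.rain_scale_amplitude * np.sin(2 * np.pi * (doy - params.rain_phase_day) / 365.0),
            )
            rain = np.where(wet, rng.exponential(scale), 0.0)
            logmu = (
                params.pm10_log_mean
                + region.pm10_log_offset
                + pm10_log_shift
                + params.pm10_seasonal_elevation * np.sin(2 * np.pi * (doy - params.pm10_phase_day) / 365.0)
            )
            pm10 = np.exp(rng.normal(logmu, params.pm10_log_sd))
            pm25 = pm10 * 0.55 * np.exp(rng.normal(0.0, 0.15, size=len(dates)))
            so2 = np.exp(rng.normal(1.4, 0.3, size=len(dates)))
            no2 = np.exp(rng.normal(3.2, 0.3, size=len(dates)))
            o3 = np.exp(rng.normal(3.9, 0.3, size=len(dates)))
            wide = pd.DataFrame(
                {
                    "tmax": tmax, "tmin": tmin, "humidity": hum, "rainfall": rain,
                    "pm10": pm10, "pm25": pm25, "so2": so2, "no2": no2, "o3": o3,
                },
                index=dates,
            )
            long = wide.reset_index(names="date").melt(
                id_vars="date", var_name="element", value_name="value"
            )
            long.insert(0, "station_id", station)
            if missing_rate > 0:
                drop = rng.random(len(long)) < missing_rate
                long.loc[drop, "value"] = np.nan
            frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["station_id", "element", "date"], kind="mergesort").reset_index(drop=True)


def station_region_map(config: SimConfig) -> pd.DataFrame:
    rows = [
        {
            "station_id": f"{r.region_id}_s{k + 1}",
            "region_id": r.region_id,
            "postal_code": r.postal_code,
        }
        for r in config.regions
        for k in range(config.n_stations_per_region)
    ]
    return pd.DataFrame(rows)


def generate_clinical(
    config: SimConfig,
    site_id: str,
    rng: np.random.Generator | None = None,
    age_shift: float = 0.0,
) -> CdmBundle:
    """One site's CDM bundle: persons, visits, discharge + historical
    conditions and drug exposures -- without any planted readmissions."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.window
    n = config.n_persons_per_site

    locations = pd.DataFrame(
        {
            "location_id": [f"{site_id}_L{r.region_id}" for r in config.regions],
            "postal_code": [r.postal_code for r in config.regions],
            "region_id": [r.region_id for r in config.regions],
        }
    )
    if n == 0:
        empty_persons = pd.DataFrame(columns=["person_id", "gender", "year_of_birth", "location_id"])
        empty_persons["year_of_birth"] = empty_persons.get("year_of_birth", pd.Series(dtype=int)).astype(int)
        visits = pd.DataFrame(
            columns=["visit_id", "person_id", "visit_kind", "admit_date", "discharge_date", "discharged_alive", "site_id"]
        )
        visits["admit_date"] = pd.Series(dtype="datetime64[ns]")
        visits["discharge_date"] = pd.Series(dtype="datetime64[ns]")
        visits["discharged_alive"] = pd.Series(dtype=bool)
        conds = pd.DataFrame(columns=["person_id", "icd10_code", "start_date"])
        conds["start_date"] = pd.Series(dtype="datetime64[ns]")
        drugs = pd.DataFrame(columns=["person_id", "ingredient_code", "start_date", "end_date"])
        drugs["start_date"] = pd.Series(dtype="datetime64[ns]")
        drugs["end_date"] = pd.Series(dtype="datetime64[ns]")
        return CdmBundle(empty_persons, visits, conds, drugs, locations, site_id=site_id,
                         study_window=config.window).validate()

    ages = np.clip(
        np.round(rng.uniform(config.age_min, config.age_max + 1, size=n) + age_shift).astype(int),
        config.age_min, config.age_max + 5,
    )
    persons = pd.DataFrame(
        {
            "person_id": [f"{site_id}_P{i:06d}" for i in range(n)],
            "gender": np.where(rng.random(n) < 0.5, "male", "female"),
            "year_of_birth": lo.year - ages,
            "location_id": locations["location_id"].to_numpy()[
                rng.integers(0, len(locations), size=n)
            ],
        }
    )

    max_admit_day = (hi - lo).days - ADMIT_MARGIN_DAYS
    n_visits = 1 + rng.poisson(max(config.mean_visits_per_person - 1.0, 0.0), size=n)
    groups = np.array(sorted(config.disease_group_mix))
    probs = np.array([config.disease_group_mix[g] for g in groups])

    visit_rows, cond_rows = [], []
    vseq = 0
    for i in range(n):
        pid = persons.loc[i, "person_id"]
        day = float(rng.uniform(0, max_admit_day))
        for _ in range(int(n_visits[i])):
            if day > max_admit_day:
                break
            admit = lo + pd.Timedelta(days=int(day))
            is_er = rng.random() < config.emergency_fraction
            mean_los = config.er_los_mean_days if is_er else config.los_mean_days
            los = min(int(rng.geometric(1.0 / (1.0 + mean_los)) - 1), MAX_INDEX_LOS)
            vseq += 1
            vid = f"{site_id}_V{vseq:07d}"
            visit_rows.append(
                (vid, pid, "emergency" if is_er else "inpatient", admit,
                 admit + pd.Timedelta(days=los), rng.random() >= config.death_rate, site_id)
            )
            group = str(rng.choice(groups, p=probs))
            pool = DIAGNOSIS_POOLS[group]
            cond_rows.append((pid, pool[int(rng.integers(0, len(pool)))], admit))
            day += MIN_VISIT_SPACING + float(rng.exponential(150.0))

    visits = pd.DataFrame(
        visit_rows,
        columns=["visit_id", "person_id", "visit_kind", "admit_date", "discharge_date", "discharged_alive", "site_id"],
    )

    # historical comorbidity conditions, dated strictly before the first
    # admission so they can never be mistaken for a discharge diagnosis
    first_admit = visits.groupby("person_id")["admit_date"].min()
    n_hist = rng.poisson(config.mean_history_conditions, size=n)
    for i in range(n):
        pid = persons.loc[i, "person_id"]
        span = (first_admit[pid] - lo).days
        for _ in range(int(n_hist[i])):
            if span <= 0:
                break
            d = lo + pd.Timedelta(days=int(rng.integers(0, span)))
            cond_rows.append((pid, HISTORY_POOL[int(rng.integers(0, len(HISTORY_POOL)))], d))
    conditions = pd.DataFrame(cond_rows, columns=["person_id", "icd10_code", "start_date"])

    drug_rows = []
    n_drugs = rng.poisson(config.mean_drug_exposures, size=n)
    for i in range(n):
        pid = persons.loc[i, "person_id"]
        span = (first_admit[pid] - lo).days
        for _ in range(int(n_drugs[i])):
            start = lo + pd.Timedelta(days=int(rng.integers(0, span + 1)))
            end = min(start + pd.Timedelta(days=int(rng.integers(7, 91))), hi)
            drug_rows.append((pid, DRUG_POOL[int(rng.integers(0, len(DRUG_POOL)))], start, end))
    drugs = pd.DataFrame(drug_rows, columns=["person_id", "ingredient_code", "start_date", "end_date"])
    if not len(drugs):
        drugs = pd.DataFrame(columns=["person_id", "ingredient_code", "start_date", "end_date"])

    bundle = CdmBundle(persons, visits, conditions, drugs, locations,
                       site_id=site_id, study_window=config.window)
    return bundle.validate()


def true_linear_predictor(truth: pd.DataFrame, model: OutcomeModel) -> np.ndarray:
    lp = (
        model.intercept
        + model.beta_age * (truth["age_at_index"].to_numpy(float) - 75.0)
        + model.beta_los * truth["length_of_stay"].to_numpy(float)
        + model.beta_charlson * truth["charlson"].to_numpy(float)
    )
    for e in SCORED_ELEMENTS:
        lp = lp + model.beta_w.get(e, 0.0) * truth[f"w_{e}"].to_numpy(float)
    lp = lp + truth["disease_group"].map(lambda g: model.beta_condition.get(g, 0.0)).to_numpy(float)
    return lp


def inject_outcomes(
    bundle: CdmBundle,
    series: pd.DataFrame,
    model: OutcomeModel,
    rng: np.random.Generator | int,
    criteria: WarningCriteria | None = None,
    intercept_shift: float = 0.0,
) -> tuple[CdmBundle, pd.DataFrame]:
    """Draw readmission outcomes for every prospective index event and append
    the corresponding emergency readmission visits.

    Returns the augmented bundle and the truth record (one row per prospective
    index event, with the true W-score, linear predictor, probability and the
    planted outcome).  ``series`` must be the harmonized regional daily series
    for this site's regions covering every exposure window.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if criteria is None:
        criteria = load_criteria()

    events = identify_index_admissions(bundle)
    truth = events.copy()
    truth["disease_group"] = assign_disease_groups(events, bundle.conditions)
    truth["charlson"] = charlson_scores_bulk(
        bundle.conditions,
        pd.DataFrame({"person_id": events["person_id"], "as_of": events["discharge_date"]}),
    )
    w = wscore_events(events, series, criteria)
    truth = truth.merge(w.drop(columns=["window_start", "window_end"]), on="visit_id")

    truth["lin_pred"] = true_linear_predictor(truth, model) + intercept_shift
    truth["prob"] = expit(truth["lin_pred"])
    truth["outcome"] = (rng.random(len(truth)) < truth["prob"]).astype(int)

    # principal diagnosis of each index stay, reused for the readmission visit
    principal = _principal_diagnosis(truth, bundle.conditions)

    readmit_days = rng.integers(1, 31, size=len(truth))
    readmit_los = np.minimum(rng.geometric(1.0 / 1.4, size=len(truth)) - 1, MAX_READMIT_LOS)
    hit = truth["outcome"].to_numpy(bool)
    truth["readmission_date"] = pd.NaT
    new_visits, new_conds = [], []
    for j, pos in enumerate(np.flatnonzero(hit)):
        row = truth.iloc[pos]
        r_admit = row["discharge_date"] + pd.Timedelta(days=int(readmit_days[pos]))
        r_disch = r_admit + pd.Timedelta(days=int(readmit_los[pos]))
        vid = f"{bundle.site_id}_RV{j + 1:06d}"
        new_visits.append(
            (vid, row["person_id"], "emergency", r_admit, r_disch, True, bundle.site_id)
        )
        new_conds.append((row["person_id"], principal.get(row["visit_id"], "R69"), r_admit))
        truth.iloc[pos, truth.columns.get_loc("readmission_date")] = r_admit

    visits = bundle.visits
    conditions = bundle.conditions
    if new_visits:
        visits = pd.concat(
            [visits, pd.DataFrame(new_visits, columns=visits.columns)], ignore_index=True
        )
        conditions = pd.concat(
            [conditions, pd.DataFrame(new_conds, columns=["person_id", "icd10_code", "start_date"])],
            ignore_index=True,
        )
    out = CdmBundle(
        bundle.persons, visits, conditions, bundle.drugs, bundle.locations,
        site_id=bundle.site_id, study_window=bundle.study_window,
    ).validate()
    return out, truth[TRUTH_COLUMNS]


def _principal_diagnosis(events: pd.DataFrame, conditions: pd.DataFrame) -> dict:
    cond = conditions.reset_index(drop=True).reset_index(names="_order")
    cond["start_date"] = pd.to_datetime(cond["start_date"])
    merged = events[["visit_id", "person_id", "admit_date", "discharge_date"]].merge(
        cond, on="person_id", how="inner"
    )
    in_stay = merged[
        (merged["start_date"] >= merged["admit_date"])
        & (merged["start_date"] <= merged["discharge_date"])
    ]
    return (
        in_stay.sort_values(["start_date", "_order"], kind="mergesort")
        .groupby("visit_id", sort=False)["icd10_code"]
        .first()
        .to_dict()
    )


@dataclass
class StudyData:
    """Everything one simulated study produces, keyed by site."""

    config: SimConfig
    internal: CdmBundle
    external: CdmBundle
    stations: dict[str, pd.DataFrame]        # site -> station records
    station_maps: dict[str, pd.DataFrame]    # site -> station/region map
    series: dict[str, pd.DataFrame]          # site -> harmonized regional series
    truth: pd.DataFrame                      # both sites, TRUTH_COLUMNS

    def bundle(self, site: str) -> CdmBundle:
        return {"internal": self.internal, "external": self.external}[site]


def generate_study(
    config: SimConfig, criteria: WarningCriteria | None = None
) -> StudyData:
    """Generate the full two-site study: train-site and shifted external-site
    bundles with planted outcomes, station weather files and the truth record."""
    if criteria is None:
        criteria = load_criteria()
    streams = _streams(config.seed)
    shift = config.site_shift
    stations, maps, series, bundles, truths = {}, {}, {}, {}, []
    for site, ashift, tshift, hshift, pshift, ishift in (
        ("internal", 0.0, 0.0, 0.0, 0.0, 0.0),
        ("external", shift.age_years, shift.temp, shift.humidity, shift.pm10_log, shift.intercept),
    ):
        st = generate_weather_series(
            config.weather, config.regions, config.window, streams[f"weather_{site}"],
            n_stations_per_region=config.n_stations_per_region,
            missing_rate=config.missing_weather_rate,
            temp_shift=tshift, humidity_shift=hshift, pm10_log_shift=pshift,
        )
        smap = station_region_map(config)
        ser = harmonize(st, smap, config.window)
        clin = generate_clinical(config, site, streams[f"clinical_{site}"], age_shift=ashift)
        full, truth = inject_outcomes(
            clin, ser, config.outcome_model, streams[f"outcomes_{site}"],
            criteria=criteria, intercept_shift=ishift,
        )
        stations[site], maps[site], series[site] = st, smap, ser
        bundles[site] = full
        truths.append(truth)
    return StudyData(
        config=config,
        internal=bundles["internal"],
        external=bundles["external"],
        stations=stations,
        station_maps=maps,
        series=series,
        truth=pd.concat(truths, ignore_index=True),
    )


WEATHER_ELEMENTS = ("tmax", "tmin", "humidity", "rainfall")
AIR_ELEMENTS = ("pm10", "pm25", "so2", "no2", "o3")


def write_study(study: StudyData, out_dir: str | Path) -> None:
    """Write a study to disk: cdm_internal/, cdm_external/, weather/, truth.csv."""
    out = Path(out_dir)
    write_cdm_bundle(study.internal, out / "cdm_internal")
    write_cdm_bundle(study.external, out / "cdm_external")
    for site in ("internal", "external"):
        wdir = out / "weather" / site
        wdir.mkdir(parents=True, exist_ok=True)
        st = study.stations[site].copy()
        st["date"] = pd.to_datetime(st["date"]).dt.strftime("%Y-%m-%d")
        st[st["element"].isin(WEATHER_ELEMENTS)].to_csv(wdir / "weather.csv", index=False, lineterminator="\n")
        st[st["element"].isin(AIR_ELEMENTS)].to_csv(wdir / "air.csv", index=False, lineterminator="\n")
        study.station_maps[site].to_csv(wdir / "station_map.csv", index=False, lineterminator="\n")
    truth = study.truth.copy()
    for c in ("admit_date", "discharge_date", "readmission_date"):
        if c in truth.columns:
            truth[c] = pd.to_datetime(truth[c]).dt.strftime("%Y-%m-%d")
    truth.to_csv(out / "truth.csv", index=False, lineterminator="\n")


def read_station_files(weather_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read weather.csv + air.csv + station_map.csv back into station records."""
    wdir = Path(weather_dir)
    frames = []
    for name in ("weather.csv", "air.csv"):
        p = wdir / name
        if p.exists():
            df = pd.read_csv(p)
            df["date"] = pd.to_datetime(df["date"])
            frames.append(df)
    if not frames:
        raise FileNotFoundError(f"no station files found in {wdir}")
    smap = pd.read_csv(wdir / "station_map.csv", dtype=str)
    return pd.concat(frames, ignore_index=True), smap
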