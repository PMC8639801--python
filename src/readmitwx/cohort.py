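"""Index admissions, planned/unplanned classification and the 30-day outcome.

An index event is a hospitalization (inpatient or emergency) of a person aged
>= 65 at admission, discharged alive inside the study window, whose residence
resolves to a weather-covered region.  The outcome is an unplanned
emergency-route admission with admit date in ``(discharge, discharge + 30]``
days; a visit starting on the discharge date itself is treated as a transfer.
Planned readmissions (chemotherapy, organ transplant, rehabilitation by
default) are identified by ICD-10 prefix lists and never count as outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .charlson import CharlsonMap, charlson_scores_bulk, normalize_code

logger = logging.getLogger(__name__)

MIN_AGE = 65
OUTCOME_WINDOW_DAYS = 30
DISEASE_CHAPTERS = ("F", "I", "J", "M")

COHORT_COLUMNS = [
    "visit_id",
    "person_id",
    "site_id",
    "region_id",
    "admit_date",
    "discharge_date",
    "age_at_index",
    "age_band",
    "gender",
    "season",
    "length_of_stay",
    "disease_group",
    "charlson",
    "outcome",
    "readmission_date",
]

_SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}


@dataclass(frozen=True)
class PlannedCodeLists:
    """ICD-10 prefix lists identifying planned admission categories."""

    prefixes: dict[str, tuple[str, ...]]

    def validate(self) -> "PlannedCodeLists":
        if not self.prefixes or any(not v for v in self.prefixes.values()):
            raise ValueError("planned-code lists must be non-empty")
        return self

    def all_prefixes(self) -> tuple[str, ...]:
        return tuple(p for v in self.prefixes.values() for p in v)


def load_planned_codes(path: str | Path | None = None) -> PlannedCodeLists:
    if path is None:
        with resources.as_file(
            resources.files("readmitwx.data") / "planned_codes.csv"
        ) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    prefixes = {
        cat: tuple(normalize_code(x) for x in sub["prefix"])
        for cat, sub in df.groupby("category", sort=False)
    }
    return PlannedCodeLists(prefixes).validate()


def assign_season(admit_date: pd.Timestamp | str) -> str:
    """Meteorological season of the admission date (Mar-May spring, ...)."""
    return _SEASON_OF_MONTH[pd.Timestamp(admit_date).month]


def age_band(age: int) -> str:
    # inclusion is >= 65, so the "60s" band is 65-69
    if age < 70:
        return "60s"
    if age < 80:
        return "70s"
    if age < 90:
        return "80s"
    return "90s"


def _visit_diagnoses(conditions: pd.DataFrame, person_id, admit, discharge) -> pd.DataFrame:
    sub = conditions[conditions["person_id"] == person_id]
    dates = pd.to_datetime(sub["start_date"])
    return sub[(dates >= admit) & (dates <= discharge)]


def classify_planned(visit_diagnoses, lists: PlannedCodeLists) -> bool:
    """True iff any diagnosis at the visit prefix-matches a planned category.

    A visit with no diagnoses is unplanned (everything outside the scheduled
    lists is unscheduled).
    """
    prefs = lists.all_prefixes()
    return any(
        normalize_code(c).startswith(p) for c in visit_diagnoses for p in prefs
    )


def identify_index_admissions(
    bundle, window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    inpatient_only: bool = False,
) -> pd.DataFrame:
    """Select qualifying index hospitalizations (outcome columns unset).

    Exclusion counts per criterion (age, death, window, location) are logged.
    Age at index is computed from year of birth at day resolution of the
    admission year.
    """
    visits = bundle.visits.merge(
        bundle.persons[["person_id", "gender", "year_of_birth", "location_id"]],
        on="person_id",
        how="left",
    ).merge(
        bundle.locations[["location_id", "region_id"]], on="location_id", how="left"
    )
    n0 = len(visits)
    if inpatient_only:
        visits = visits[visits["visit_kind"] == "inpatient"]
    visits = visits.copy()
    visits["age_at_index"] = visits["admit_date"].dt.year - visits["year_of_birth"]

    keep_age = visits["age_at_index"] >= MIN_AGE
    keep_alive = visits["discharged_alive"].astype(bool)
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        keep_window = (visits["discharge_date"] >= lo) & (visits["discharge_date"] <= hi)
    else:
        keep_window = pd.Series(True, index=visits.index)
    keep_loc = visits["region_id"].notna()
    logger.info(
        "index selection from %d visits: excluded age<65=%d, died=%d, "
        "outside window=%d, unresolved location=%d",
        n0,
        int((~keep_age).sum()),
        int((~keep_alive).sum()),
        int((~keep_window).sum()),
        int((~keep_loc).sum()),
    )
    idx = visits[keep_age & keep_alive & keep_window & keep_loc].copy()
    idx["length_of_stay"] = (idx["discharge_date"] - idx["admit_date"]).dt.days
    idx["age_band"] = idx["age_at_index"].map(age_band)
    idx["season"] = idx["admit_date"].dt.month.map(_SEASON_OF_MONTH)
    idx["site_id"] = bundle.site_id
    idx = idx.sort_values("visit_id", kind="mergesort").reset_index(drop=True)
    return idx[
        [
            "visit_id",
            "person_id",
            "site_id",
            "region_id",
            "admit_date",
            "discharge_date",
            "age_at_index",
            "age_band",
            "gender",
            "season",
            "length_of_stay",
        ]
    ]


def assign_disease_groups(events: pd.DataFrame, conditions: pd.DataFrame) -> pd.Series:
    """Chapter of the principal (first-listed) discharge diagnosis, else 'other'.

    The principal diagnosis is the first condition row (input order, earliest
    date first) dated within the index stay.  Events with no discharge
    diagnosis map to 'other' with a logged warning count.
    """
    cond = conditions.reset_index(drop=True).reset_index(names="_order")
    cond["start_date"] = pd.to_datetime(cond["start_date"])
    merged = events[["visit_id", "person_id", "admit_date", "discharge_date"]].merge(
        cond, on="person_id", how="left"
    )
    in_stay = merged[
        (merged["start_date"] >= merged["admit_date"])
        & (merged["start_date"] <= merged["discharge_date"])
    ]
    principal = (
        in_stay.sort_values(["start_date", "_order"], kind="mergesort")
        .groupby("visit_id", sort=False)["icd10_code"]
        .first()
    )
    chapters = principal.str[0].where(principal.str[0].isin(DISEASE_CHAPTERS), "other")
    mapped = events["visit_id"].map(chapters)
    n_missing = int(mapped.isna().sum())
    out = mapped.fillna("other")
    if n_missing:
        logger.warning("%d index events have no discharge diagnosis; assigned 'other'", n_missing)
    return out


def subgroup_membership(events: pd.DataFrame, conditions: pd.DataFrame) -> pd.DataFrame:
    """Multi-membership subgroup map: one row per (visit_id, chapter) where any
    discharge diagnosis falls in that chapter.  Mirrors running the analysis
    per disease subgroup, where a stay with both M and J diagnoses joins both
    cohorts.
    """
    cond = conditions.copy()
    cond["start_date"] = pd.to_datetime(cond["start_date"])
    merged = events[["visit_id", "person_id", "admit_date", "discharge_date"]].merge(
        cond, on="person_id", how="inner"
    )
    in_stay = merged[
        (merged["start_date"] >= merged["admit_date"])
        & (merged["start_date"] <= merged["discharge_date"])
    ].copy()
    in_stay["chapter"] = in_stay["icd10_code"].str[0]
    in_stay = in_stay[in_stay["chapter"].isin(DISEASE_CHAPTERS)]
    return (
        in_stay[["visit_id", "chapter"]]
        .drop_duplicates()
        .sort_values(["visit_id", "chapter"], kind="mergesort")
        .reset_index(drop=True)
    )


def label_outcome(
    events: pd.DataFrame,
    bundle,
    lists: PlannedCodeLists | None = None,
    window_days: int = OUTCOME_WINDOW_DAYS,
) -> pd.DataFrame:
    """Set the 30-day unplanned-readmission outcome on index events.

    outcome = 1 iff the person has a subsequent *emergency* admission with
    admit date in ``(discharge, discharge + window_days]`` that is not
    planned; the earliest such visit supplies ``readmission_date``.
    Readmissions are sought within the same site's bundle only.
    """
    if lists is None:
        lists = load_planned_codes()
    events = events.copy()
    er = bundle.visits[bundle.visits["visit_kind"] == "emergency"].copy()

    # classify each candidate ER visit as planned/unplanned once
    if len(er):
        planned_flags = {}
        prefs = lists.all_prefixes()
        cond = bundle.conditions.copy()
        cond["start_date"] = pd.to_datetime(cond["start_date"])
        cond["norm"] = cond["icd10_code"].map(normalize_code)
        cond["planned_code"] = cond["norm"].map(
            lambda c: any(c.startswith(p) for p in prefs)
        )
        m = er[["visit_id", "person_id", "admit_date", "discharge_date"]].merge(
            cond[cond["planned_code"]], on="person_id", how="inner"
        )
        m = m[(m["start_date"] >= m["admit_date"]) & (m["start_date"] <= m["discharge_date"])]
        planned_ids = set(m["visit_id"])
        er["planned"] = er["visit_id"].isin(planned_ids)
    else:
        er["planned"] = pd.Series(dtype=bool)
    candidates = er[~er["planned"]][["visit_id", "person_id", "admit_date"]]

    joined = events[["visit_id", "person_id", "discharge_date"]].merge(
        candidates.rename(columns={"visit_id": "readmit_visit_id", "admit_date": "readmit_date"}),
        on="person_id",
        how="left",
    )
    delta = (joined["readmit_date"] - joined["discharge_date"]).dt.days
    hit = joined[(delta > 0) & (delta <= window_days)]
    first = (
        hit.sort_values("readmit_date", kind="mergesort")
        .groupby("visit_id", sort=False)["readmit_date"]
        .first()
    )
    events["readmission_date"] = events["visit_id"].map(first)
    events["outcome"] = events["readmission_date"].notna().astype(int)
    return events


def build_cohort(
    bundle,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    planned: PlannedCodeLists | None = None,
    charlson_map: CharlsonMap | None = None,
    window_days: int = OUTCOME_WINDOW_DAYS,
    inpatient_only: bool = False,
    charlson_include_outcome_window: bool = False,
) -> pd.DataFrame:
    """Full cohort derivation: index events, disease group, Charlson, outcome.

    ``charlson_include_outcome_window`` reproduces the literal
    all-conditions-before-end-of-interval reading (lookback extends
    ``window_days`` past discharge); the default cutoff is the index discharge
    date, which cannot leak outcome-window information into a covariate.
    """
    events = identify_index_admissions(bundle, window, inpatient_only=inpatient_only)
    events["disease_group"] = assign_disease_groups(events, bundle.conditions)
    cutoff = events["discharge_date"]
    if charlson_include_outcome_window:
        cutoff = cutoff + pd.Timedelta(days=window_days)
    events["charlson"] = charlson_scores_bulk(
        bundle.conditions,
        pd.DataFrame({"person_id": events["person_id"], "as_of": cutoff}),
        charlson_map,
    )
    events = label_outcome(events, bundle, planned, window_days)
    return events[COHORT_COLUMNS]
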