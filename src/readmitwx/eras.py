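"""CONDITION_ERA / DRUG_ERA derivation.

Occurrences of the same concept for the same person are collapsed into
continuous eras whenever the gap between them does not exceed a persistence
window (OHDSI convention: 30 days).  A condition occurrence occupies a single
day; a drug exposure occupies ``[start_date, end_date]`` and the gap is
measured from the running latest end to the next start, so overlapping
exposures always merge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_GAP_DAYS = 30

ERA_COLUMNS = ["person_id", "concept_code", "start_date", "end_date", "occurrence_count"]


def _empty_eras() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in ERA_COLUMNS})
    df["start_date"] = pd.Series(dtype="datetime64[ns]")
    df["end_date"] = pd.Series(dtype="datetime64[ns]")
    df["occurrence_count"] = pd.Series(dtype=int)
    return df


def _build_eras(
    df: pd.DataFrame, code_col: str, start_col: str, end_col: str, gap_days: int
) -> pd.DataFrame:
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    if not len(df):
        return _empty_eras()
    work = pd.DataFrame(
        {
            "person_id": df["person_id"].to_numpy(),
            "concept_code": df[code_col].to_numpy(),
            "start": pd.to_datetime(df[start_col]).to_numpy(),
            "end": pd.to_datetime(df[end_col]).to_numpy(),
        }
    ).sort_values(["person_id", "concept_code", "start", "end"], kind="mergesort")

    grp = work.groupby(["person_id", "concept_code"], sort=False)
    gid = grp.ngroup().to_numpy()
    start = work["start"].to_numpy()
    # running max of ends within each (person, concept) group, shifted by one:
    # the era boundary test is start > prev_cummax_end + gap
    end_ord = work["end"].to_numpy().astype("datetime64[D]").astype(np.int64)
    start_ord = start.astype("datetime64[D]").astype(np.int64)
    cummax = np.empty_like(end_ord)
    new_group = np.empty(len(work), dtype=bool)
    new_group[0] = True
    new_group[1:] = gid[1:] != gid[:-1]
    run = end_ord[0]
    for i in range(len(end_ord)):  # small inputs in practice; O(n) scan
        if new_group[i]:
            run = end_ord[i]
        else:
            run = max(run, end_ord[i])
        cummax[i] = run
    prev_cummax = np.empty_like(cummax)
    prev_cummax[0] = np.iinfo(np.int64).min
    prev_cummax[1:] = cummax[:-1]
    breaks = new_group | (start_ord - prev_cummax > gap_days)
    era_id = np.cumsum(breaks)

    work = work.assign(era_id=era_id)
    out = (
        work.groupby(["era_id", "person_id", "concept_code"], sort=False)
        .agg(start_date=("start", "min"), end_date=("end", "max"), occurrence_count=("start", "size"))
        .reset_index()
        .drop(columns="era_id")
    )
    out["occurrence_count"] = out["occurrence_count"].astype(int)
    return out[ERA_COLUMNS].sort_values(
        ["person_id", "concept_code", "start_date"], kind="mergesort"
    ).reset_index(drop=True)


def build_condition_eras(
    occurrences: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS
) -> pd.DataFrame:
    """Collapse condition occurrences into eras.

    Consecutive occurrences of the same (person, ICD-10 code) whose dates are
    at most ``gap_days`` apart (inclusive) merge into one era spanning the
    first to the last date.
    """
    return _build_eras(occurrences, "icd10_code", "start_date", "start_date", gap_days)


def build_drug_eras(exposures: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS) -> pd.DataFrame:
    """Collapse drug exposure intervals into eras.

    The gap is measured between one exposure's end and the next exposure's
    start; overlapping or contained exposures always merge.
    """
    return _build_eras(exposures, "ingredient_code", "start_date", "end_date", gap_days)
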