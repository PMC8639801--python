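"""CDM-lite data model: typed tables, CSV readers/writers, integrity validation.

The five tables mirror the slice of the OMOP common data model that a
readmission study actually touches -- PERSON, VISIT_OCCURRENCE,
CONDITION_OCCURRENCE, DRUG_EXPOSURE and LOCATION -- flattened to
comma-delimited UTF-8 files with ISO-8601 calendar dates.  Visit concepts are
collapsed to the two kinds that drive index/outcome logic (``inpatient``,
``emergency``); diagnoses are raw ICD-10 code strings rather than standard
concept ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GENDERS = ("male", "female")
VISIT_KINDS = ("inpatient", "emergency")

#: canonical column order per table; also the on-disk header
TABLE_COLUMNS: dict[str, list[str]] = {
    "persons": ["person_id", "gender", "year_of_birth", "location_id"],
    "visits": [
        "visit_id",
        "person_id",
        "visit_kind",
        "admit_date",
        "discharge_date",
        "discharged_alive",
        "site_id",
    ],
    "conditions": ["person_id", "icd10_code", "start_date"],
    "drugs": ["person_id", "ingredient_code", "start_date", "end_date"],
    "locations": ["location_id", "postal_code", "region_id"],
}

TABLE_FILES = {name: f"{name}.csv" for name in TABLE_COLUMNS}

DATE_COLUMNS: dict[str, list[str]] = {
    "persons": [],
    "visits": ["admit_date", "discharge_date"],
    "conditions": ["start_date"],
    "drugs": ["start_date", "end_date"],
    "locations": [],
}

_SORT_KEYS: dict[str, list[str]] = {
    "persons": ["person_id"],
    "visits": ["visit_id"],
    "conditions": ["person_id", "icd10_code", "start_date"],
    "drugs": ["person_id", "ingredient_code", "start_date", "end_date"],
    "locations": ["location_id"],
}

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


class CdmValidationError(ValueError):
    """A bundle violates a schema or referential-integrity invariant."""


@dataclass
class CdmBundle:
    """One site's CDM-lite tables held as pandas DataFrames.

    Dates are ``datetime64[ns]`` at day resolution.  ``validate()`` checks
    schema, enum domains, date ordering and foreign-key resolution and raises
    :class:`CdmValidationError` naming the offending table and row.
    """

    persons: pd.DataFrame
    visits: pd.DataFrame
    conditions: pd.DataFrame
    drugs: pd.DataFrame
    locations: pd.DataFrame
    site_id: str = "site"
    study_window: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self) -> "CdmBundle":
        for name, cols in TABLE_COLUMNS.items():
            df = self.table(name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise CdmValidationError(f"{name}: missing columns {missing}")
        self._check_unique("persons", "person_id")
        self._check_unique("visits", "visit_id")
        self._check_unique("locations", "location_id")
        self._check_enum("persons", "gender", GENDERS)
        self._check_enum("visits", "visit_kind", VISIT_KINDS)

        bad = self.visits["admit_date"] > self.visits["discharge_date"]
        if bad.any():
            row = int(bad.idxmax())
            raise CdmValidationError(
                f"visits row {row}: admit_date after discharge_date "
                f"(visit_id={self.visits.loc[row, 'visit_id']})"
            )
        bad = self.drugs["start_date"] > self.drugs["end_date"]
        if bad.any():
            row = int(bad.idxmax())
            raise CdmValidationError(f"drugs row {row}: start_date after end_date")

        ok = self.conditions["icd10_code"].astype(str).str.match(ICD10_PATTERN)
        if not ok.all():
            row = int((~ok).idxmax())
            raise CdmValidationError(
                f"conditions row {row}: malformed ICD-10 code "
                f"{self.conditions.loc[row, 'icd10_code']!r}"
            )

        self._check_fk("persons", "location_id", "locations", "location_id")
        self._check_fk("visits", "person_id", "persons", "person_id")
        self._check_fk("conditions", "person_id", "persons", "person_id")
        self._check_fk("drugs", "person_id", "persons", "person_id")

        # age must be non-negative at every visit
        if len(self.visits):
            v = self.visits.merge(
                self.persons[["person_id", "year_of_birth"]], on="person_id"
            )
            neg = v["admit_date"].dt.year < v["year_of_birth"]
            if neg.any():
                raise CdmValidationError(
                    f"visits: visit before birth year for person_id="
                    f"{v.loc[neg.idxmax(), 'person_id']}"
                )

        if self.study_window is not None:
            lo, hi = self.study_window
            for name, cols in DATE_COLUMNS.items():
                df = self.table(name)
                for c in cols:
                    if len(df) and ((df[c] < lo) | (df[c] > hi)).any():
                        raise CdmValidationError(
                            f"{name}.{c}: dates outside study window [{lo.date()}, {hi.date()}]"
                        )
        return self

    # -- helpers ----------------------------------------------------------
    def _check_unique(self, table: str, col: str) -> None:
        df = self.table(table)
        dup = df[col].duplicated()
        if dup.any():
            raise CdmValidationError(
                f"{table} row {int(dup.idxmax())}: duplicate {col}={df.loc[dup.idxmax(), col]}"
            )

    def _check_enum(self, table: str, col: str, allowed: tuple[str, ...]) -> None:
        df = self.table(table)
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(bad.idxmax())
            raise CdmValidationError(
                f"{table} row {row}: unknown {col} value {df.loc[row, col]!r} "
                f"(allowed: {allowed})"
            )

    def _check_fk(self, table: str, col: str, ref_table: str, ref_col: str) -> None:
        df = self.table(table)
        if not len(df):
            return
        known = set(self.table(ref_table)[ref_col])
        bad = ~df[col].isin(known)
        if bad.any():
            row = int(bad.idxmax())
            raise CdmValidationError(
                f"{table} row {row}: {col}={df.loc[row, col]!r} "
                f"not found in {ref_table}.{ref_col}"
            )


def _parse_dates(df: pd.DataFrame, table: str, path: Path) -> pd.DataFrame:
    for col in DATE_COLUMNS[table]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise CdmValidationError(
                f"{path.name} row {row + 2}: unparseable date {df.loc[row, col]!r} in {col}"
            )
        if parsed.isna().any():
            row = int(parsed.isna().idxmax())
            raise CdmValidationError(f"{path.name} row {row + 2}: missing date in {col}")
        df[col] = parsed
    return df


def read_cdm_bundle(
    directory: str | Path,
    site_id: str = "site",
    study_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> CdmBundle:
    """Read and validate one site's CDM-lite tables from ``directory``.

    Raises ``FileNotFoundError`` if a table file is absent and
    :class:`CdmValidationError` (with file and row number) on malformed
    content.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"required CDM table file missing: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise CdmValidationError(f"{path.name}: missing columns {missing}")
        df = df[TABLE_COLUMNS[name]]
        if name == "persons" and len(df):
            df["year_of_birth"] = df["year_of_birth"].astype(int)
        if name == "visits" and len(df):
            df["discharged_alive"] = df["discharged_alive"].map(
                {"True": True, "False": False, "true": True, "false": False}
            )
            if df["discharged_alive"].isna().any():
                row = int(df["discharged_alive"].isna().idxmax())
                raise CdmValidationError(
                    f"{path.name} row {row + 2}: discharged_alive must be True/False"
                )
        elif name == "visits":
            df["discharged_alive"] = df["discharged_alive"].astype(bool)
        if name == "persons" and not len(df):
            df["year_of_birth"] = df["year_of_birth"].astype(int)
        df = _parse_dates(df, name, path)
        tables[name] = df
    bundle = CdmBundle(site_id=site_id, study_window=study_window, **tables)
    return bundle.validate()


def write_cdm_bundle(bundle: CdmBundle, directory: str | Path) -> dict[str, Path]:
    """Write a validated bundle as one CSV per table.

    Rows are sorted by primary key and dates serialized as ISO-8601, so two
    writes of the same bundle are byte-identical.
    """
    bundle.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, fname in TABLE_FILES.items():
        df = bundle.table(name).copy()
        df = df[TABLE_COLUMNS[name]]
        if len(df):
            df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
        for col in DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = directory / fname
        df.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written
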