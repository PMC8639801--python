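"""Per-index-event covariate matrix assembly and external-site conformance.

Columns, in deterministic block order: demographics (age, male indicator,
age-band and season indicators), length of stay, Charlson index, one binary
indicator per condition-era concept group (ICD-10 truncated to 3 characters)
and per drug-era ingredient, and -- in the ``clinical_w`` configuration -- the
five W-score elements.  The label column is ``outcome``.  A manifest (ordered
feature-column list) is persisted with the training matrix so an external
site's matrix can be conformed to it exactly: unseen concept columns dropped,
missing concept columns zero-filled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exposure import W_COLUMNS

logger = logging.getLogger(__name__)

MODES = ("clinical", "clinical_w")
LABEL_COLUMN = "outcome"

AGE_BANDS = ("60s", "70s", "80s", "90s")
SEASONS = ("spring", "summer", "fall", "winter")

DEFAULT_MIN_CONCEPT_COUNT = 10
DEFAULT_CONDITION_GROUP_CHARS = 3


@dataclass
class FeatureMatrix:
    """Feature table keyed by visit_id with its ordered column manifest."""

    data: pd.DataFrame  # index: visit_id; columns: manifest + outcome
    manifest: list[str]
    mode: str = "clinical"

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.manifest]

    @property
    def y(self) -> pd.Series:
        return self.data[LABEL_COLUMN]

    def save(self, features_path: str | Path, manifest_path: str | Path) -> None:
        out = self.data.reset_index()
        out.to_csv(features_path, index=False, lineterminator="\n")
        Path(manifest_path).write_text(
            json.dumps({"mode": self.mode, "columns": self.manifest}, indent=1) + "\n"
        )

    @classmethod
    def load(cls, features_path: str | Path, manifest_path: str | Path) -> "FeatureMatrix":
        meta = json.loads(Path(manifest_path).read_text())
        df = pd.read_csv(features_path).set_index("visit_id")
        return cls(data=df, manifest=list(meta["columns"]), mode=meta["mode"])


def _era_indicators(
    events: pd.DataFrame, eras: pd.DataFrame, prefix: str, group_chars: int | None
) -> pd.DataFrame:
    """Binary indicator per concept group: 1 iff the person has an era of that
    group starting on or before the index discharge date."""
    if not len(eras):
        return pd.DataFrame(index=events["visit_id"])
    e = eras.copy()
    e["group"] = e["concept_code"].astype(str)
    if group_chars:
        e["group"] = e["group"].str[:group_chars]
    merged = events[["visit_id", "person_id", "discharge_date"]].merge(
        e[["person_id", "group", "start_date"]], on="person_id", how="inner"
    )
    merged = merged[pd.to_datetime(merged["start_date"]) <= merged["discharge_date"]]
    flags = (
        merged.assign(one=1)
        .pivot_table(index="visit_id", columns="group", values="one", aggfunc="max")
        .fillna(0)
        .astype(int)
    )
    flags.columns = [f"{prefix}{c}" for c in flags.columns]
    return flags.reindex(events["visit_id"], fill_value=0)[sorted(flags.columns)]


def assemble(
    events: pd.DataFrame,
    condition_eras: pd.DataFrame,
    drug_eras: pd.DataFrame,
    wscores: pd.DataFrame | None = None,
    mode: str = "clinical",
    min_concept_count: int = DEFAULT_MIN_CONCEPT_COUNT,
    condition_group_chars: int = DEFAULT_CONDITION_GROUP_CHARS,
) -> FeatureMatrix:
    """Assemble the covariate matrix for labelled index events.

    ``wscores`` is required (one row per event) when ``mode='clinical_w'``;
    era concept columns seen in fewer than ``min_concept_count`` events are
    dropped.  Missing cells are impossible by construction: indicators default
    to 0 and absent W-scores are fatal.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    ev = events.reset_index(drop=True)
    base = pd.DataFrame(index=pd.Index(ev["visit_id"], name="visit_id"))
    base["age"] = ev["age_at_index"].to_numpy(float)
    base["gender_male"] = (ev["gender"].to_numpy() == "male").astype(int)
    for b in AGE_BANDS:
        base[f"age_band_{b}"] = (ev["age_band"].to_numpy() == b).astype(int)
    for s in SEASONS:
        base[f"season_{s}"] = (ev["season"].to_numpy() == s).astype(int)
    base["length_of_stay"] = ev["length_of_stay"].to_numpy(float)
    base["charlson"] = ev["charlson"].to_numpy(float)

    cond = _era_indicators(ev, condition_eras, "cond_", condition_group_chars)
    drug = _era_indicators(ev, drug_eras, "drug_", None)
    for block in (cond, drug):
        keep = [c for c in block.columns if int(block[c].sum()) >= min_concept_count]
        dropped = set(block.columns) - set(keep)
        if dropped:
            logger.info("dropping %d rare concept columns (<%d events)", len(dropped), min_concept_count)
        base = base.join(block[keep])

    if mode == "clinical_w":
        if wscores is None:
            raise ValueError("clinical_w mode requires W-scores")
        w = wscores.set_index("visit_id")
        missing = base.index.difference(w.index)
        if len(missing):
            raise ValueError(f"events missing a W-score: {sorted(map(str, missing))[:10]}")
        for c in W_COLUMNS:
            base[c] = w.loc[base.index, c].to_numpy(float)

    base[LABEL_COLUMN] = ev[LABEL_COLUMN].to_numpy(int)
    manifest = [c for c in base.columns if c != LABEL_COLUMN]
    assert not base.isna().any().any()
    return FeatureMatrix(data=base, manifest=manifest, mode=mode)


def conform(matrix: FeatureMatrix, manifest: list[str]) -> FeatureMatrix:
    """Reorder/zero-fill/drop an external matrix's columns to match a training
    manifest exactly; the label column must be present."""
    if LABEL_COLUMN not in matrix.data.columns:
        raise ValueError("label column absent; cannot conform an unlabelled matrix")
    df = matrix.data
    extra = [c for c in matrix.manifest if c not in manifest]
    absent = [c for c in manifest if c not in df.columns]
    if extra:
        logger.info("conform: dropping %d columns not in training manifest: %s", len(extra), extra[:10])
    out = df.reindex(columns=[*manifest, LABEL_COLUMN], fill_value=0)
    if absent:
        logger.info("conform: zero-filled %d training columns absent externally: %s", len(absent), absent[:10])
    return FeatureMatrix(data=out, manifest=list(manifest), mode=matrix.mode)
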