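"""Charlson comorbidity index, Romano adaptation, from ICD-10 condition history.

The mapping ships as an editable prefix table (``data/charlson_map.csv``) with
17 comorbidity categories and weights in {1, 2, 3, 6}.  A condition code
matches a category if the code (dots stripped, upper-cased) starts with any of
the category's prefixes; each category counts once; severity-graded category
pairs (diabetes with/without complications, mild vs. moderate/severe liver
disease, metastatic solid tumour vs. any malignancy) contribute only the more
severe matched member.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

EXPECTED_CATEGORIES = 17
ALLOWED_WEIGHTS = {1, 2, 3, 6}

#: less severe category -> category that supersedes it when both match
HIERARCHY = {
    "diabetes_uncomplicated": "diabetes_complicated",
    "mild_liver_disease": "severe_liver_disease",
    "malignancy": "metastatic_solid_tumor",
}


@dataclass(frozen=True)
class CharlsonMap:
    """Prefix table: category -> (weight, tuple of ICD-10 prefixes)."""

    weights: dict[str, int]
    prefixes: dict[str, tuple[str, ...]]

    def validate(self) -> "CharlsonMap":
        if len(self.weights) != EXPECTED_CATEGORIES:
            raise ValueError(
                f"expected {EXPECTED_CATEGORIES} categories, got {len(self.weights)}"
            )
        bad = {c: w for c, w in self.weights.items() if w not in ALLOWED_WEIGHTS}
        if bad:
            raise ValueError(f"weights outside {sorted(ALLOWED_WEIGHTS)}: {bad}")
        for less, more in HIERARCHY.items():
            if less not in self.weights or more not in self.weights:
                raise ValueError(f"hierarchy pair {less}/{more} missing from map")
        return self


def load_charlson_map(path: str | Path | None = None) -> CharlsonMap:
    """Load the Romano prefix table (the shipped default when ``path`` is None)."""
    if path is None:
        with resources.as_file(
            resources.files("readmitwx.data") / "charlson_map.csv"
        ) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    df["weight"] = df["weight"].astype(int)
    weights: dict[str, int] = {}
    prefixes: dict[str, list[str]] = {}
    for cat, sub in df.groupby("category", sort=False):
        w = sub["weight"].unique()
        if len(w) != 1:
            raise ValueError(f"category {cat} has inconsistent weights {w}")
        weights[cat] = int(w[0])
        prefixes[cat] = [normalize_code(p) for p in sub["prefix"]]
    return CharlsonMap(
        weights=weights, prefixes={c: tuple(v) for c, v in prefixes.items()}
    ).validate()


def normalize_code(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


def matched_categories(
    codes, cmap: CharlsonMap, apply_hierarchy: bool = True
) -> set[str]:
    """Set of comorbidity categories matched by any code, after hierarchy."""
    norm = {normalize_code(c) for c in codes}
    cats = {
        cat
        for cat, prefs in cmap.prefixes.items()
        if any(code.startswith(p) for code in norm for p in prefs)
    }
    if apply_hierarchy:
        cats -= {less for less, more in HIERARCHY.items() if more in cats}
    return cats


def charlson_score(
    conditions: pd.DataFrame,
    as_of: pd.Timestamp | str,
    cmap: CharlsonMap | None = None,
) -> int:
    """Charlson index from condition rows with ``start_date <= as_of``.

    ``conditions`` needs columns ``icd10_code`` and ``start_date``.  Unmatched
    codes contribute 0.  The lookback cutoff is the caller's responsibility;
    the cohort stage passes the index discharge date so that nothing from the
    outcome window leaks into the covariate.
    """
    if cmap is None:
        cmap = load_charlson_map()
    if not len(conditions):
        return 0
    as_of = pd.Timestamp(as_of)
    eligible = conditions.loc[pd.to_datetime(conditions["start_date"]) <= as_of]
    cats = matched_categories(eligible["icd10_code"], cmap)
    return sum(cmap.weights[c] for c in cats)


def charlson_scores_bulk(
    conditions: pd.DataFrame,
    cutoffs: pd.DataFrame,
    cmap: CharlsonMap | None = None,
) -> pd.Series:
    """Vectorised Charlson scores for many (person, as_of) pairs.

    ``cutoffs`` has columns ``person_id`` and ``as_of``; the result is an
    integer Series aligned to ``cutoffs``'s index.  Equivalent to calling
    :func:`charlson_score` per row on that person's conditions.
    """
    if cmap is None:
        cmap = load_charlson_map()
    if not len(cutoffs):
        return pd.Series(dtype=int)
    if not len(conditions):
        return pd.Series(0, index=cutoffs.index, dtype=int)

    cond = conditions[["person_id", "icd10_code", "start_date"]].copy()
    cond["start_date"] = pd.to_datetime(cond["start_date"])
    cond["norm"] = cond["icd10_code"].map(normalize_code)
    # map each condition row to its (deduplicated later) category
    cat_of = {}
    for cat, prefs in cmap.prefixes.items():
        for p in prefs:
            cat_of.setdefault(p, cat)
    prefs_sorted = sorted(cat_of, key=len, reverse=True)  # longest prefix wins

    def _cat(code: str) -> str | None:
        for p in prefs_sorted:
            if code.startswith(p):
                return cat_of[p]
        return None

    uniq = {c: _cat(c) for c in cond["norm"].unique()}
    cond["category"] = cond["norm"].map(uniq)
    cond = cond.dropna(subset=["category"])

    out = pd.Series(0, index=cutoffs.index, dtype=int)
    if not len(cond):
        return out
    merged = cutoffs.reset_index(names="_row").merge(cond, on="person_id", how="inner")
    merged = merged[merged["start_date"] <= pd.to_datetime(merged["as_of"])]
    if not len(merged):
        return out
    got = merged.groupby("_row")["category"].agg(set)
    for row, cats in got.items():
        cats = cats - {l for l, m in HIERARCHY.items() if m in cats}
        out.loc[row] = sum(cmap.weights[c] for c in cats)
    return out
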