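"""Tree-based readmission classifiers with grid-search CV and AUROC validation.

Organised around two objects: :class:`ReadmissionModel` is built from a
:class:`~readmitwx.features.FeatureMatrix` plus a :class:`ModelSpec` (family +
hyper-parameter grid); ``fit()`` carves off a stratified held-out test split,
runs stratified k-fold cross-validation over every grid combination on the
training split, refits the best combination (ties break to the first point in
declared grid order) and returns a :class:`ReadmissionResults` carrying the
selected hyper-parameters, per-grid-point CV AUROC, held-out test AUROC, ROC
points, covariate summary and -- after :meth:`ReadmissionResults
.external_validate` -- the frozen model's AUROC on an external site's
conformed matrix.

Four families are supported: DT (decision tree), RF (random forest), ADA
(AdaBoost) and GBM (gradient boosting), with default grids mirroring the
published hyper-parameter table; grids are configuration, not code.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import LABEL_COLUMN, FeatureMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("DT", "RF", "ADA", "GBM")

#: default hyper-parameter grids (sklearn parameter names); values mirror the
#: published grid: DT explores class weighting; RF depth x features per tree
#: at 500 trees; ADA is a single point; GBM learning rate x depth x tree count
#: with 25-round early stopping on a seeded internal 10% validation fraction.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {
        "class_weight": ["balanced", None],
        "max_depth": [10],
        "min_samples_leaf": [10],
        "min_samples_split": [2],
        "min_impurity_decrease": [1e-7],
    },
    "RF": {
        "max_depth": [4, 10, 17],
        "max_features": ["sqrt", 5, 20],
        "n_estimators": [500],
    },
    "ADA": {
        "learning_rate": [1.0],
        "n_estimators": [4],
    },
    "GBM": {
        "learning_rate": [0.005, 0.01, 0.1],
        "max_depth": [4, 6, 17],
        "n_estimators": [100, 1000],
        "min_samples_leaf": [2],
        "n_iter_no_change": [25],
        "validation_fraction": [0.1],
    },
}

_ESTIMATORS = {
    "DT": DecisionTreeClassifier,
    "RF": RandomForestClassifier,
    "ADA": AdaBoostClassifier,
    "GBM": GradientBoostingClassifier,
}


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus hyper-parameter grid (insertion order is grid order)."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not self.grid:
            object.__setattr__(self, "grid", {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()})
        if any(not v for v in self.grid.values()):
            raise ValueError("every grid dimension needs at least one value")

    def points(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]

    def estimator(self, params: dict, seed: int):
        cls = _ESTIMATORS[self.family]
        return cls(random_state=seed, **params)


def auroc(scores, labels) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counting one half (Mann-Whitney rank
    formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def covariate_summary(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-covariate overall / with-outcome / without-outcome means, sorted by
    the absolute with-vs-without difference (largest separation first)."""
    df = matrix.data
    y = df[LABEL_COLUMN].astype(bool)
    X = df[matrix.manifest]
    out = pd.DataFrame(
        {
            "covariate": matrix.manifest,
            "mean": X.mean().to_numpy(),
            "mean_with_outcome": X[y].mean().to_numpy(),
            "mean_without_outcome": X[~y].mean().to_numpy(),
        }
    )
    out["abs_diff"] = (out["mean_with_outcome"] - out["mean_without_outcome"]).abs()
    return (
        out.sort_values(["abs_diff", "covariate"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC polyline from (0,0) to (1,1), one point per distinct threshold."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="mergesort")
    y = np.asarray(labels).astype(int)[order]
    s = np.asarray(scores, dtype=float)[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last] / tps[-1]]
    fpr = np.r_[0.0, fps[last] / fps[-1]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


class ReadmissionModel:
    """Readmission classifier to be fitted on a feature matrix.

    Parameters
    ----------
    matrix : FeatureMatrix
        Labelled training-site matrix.
    spec : ModelSpec or str
        Model family (with the default published grid) or a full spec.
    test_size : float
        Fraction held out, stratified by outcome, before cross-validation.
    """

    def __init__(self, matrix: FeatureMatrix, spec: ModelSpec | str, test_size: float = 0.25):
        self.matrix = matrix
        self.spec = ModelSpec(spec) if isinstance(spec, str) else spec
        self.test_size = test_size
        if matrix.y.nunique() < 2:
            raise ValueError("training data must contain both outcome classes")

    @classmethod
    def from_features(cls, matrix: FeatureMatrix, family: str = "GBM",
                      grid: dict | None = None, test_size: float = 0.25) -> "ReadmissionModel":
        return cls(matrix, ModelSpec(family, grid or {}), test_size=test_size)

    def fit(self, k: int = 10, seed: int = 0) -> "ReadmissionResults":
        if k < 2:
            raise ValueError("k-fold CV needs k >= 2")
        X = self.matrix.X.to_numpy(float)
        y = self.matrix.y.to_numpy(int)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=self.test_size, stratify=y, random_state=seed
        )
        points = self.spec.points()
        cv_rows = []
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X_tr, y_tr))
        for params in points:
            est = self.spec.estimator(params, seed)
            aucs = []
            for tr_idx, va_idx in folds:
                m = clone(est)
                m.fit(X_tr[tr_idx], y_tr[tr_idx])
                aucs.append(auroc(m.predict_proba(X_tr[va_idx])[:, 1], y_tr[va_idx]))
            cv_rows.append({**params, "cv_auc": float(np.mean(aucs))})
        cv_results = pd.DataFrame(cv_rows)
        best_idx = int(np.argmax(cv_results["cv_auc"].to_numpy()))  # first max wins ties
        best_params = points[best_idx]
        logger.info("%s: selected grid point %d/%d %s (cv_auc=%.4f)",
                    self.spec.family, best_idx + 1, len(points), best_params,
                    cv_results.loc[best_idx, "cv_auc"])
        final = self.spec.estimator(best_params, seed).fit(X_tr, y_tr)
        test_scores = final.predict_proba(X_te)[:, 1]
        return ReadmissionResults(
            family=self.spec.family,
            mode=self.matrix.mode,
            params=best_params,
            cv_results=cv_results,
            cv_auc=float(cv_results.loc[best_idx, "cv_auc"]),
            test_auc=auroc(test_scores, y_te),
            roc_internal=roc_points(test_scores, y_te),
            manifest=list(self.matrix.manifest),
            seed=seed,
            estimator=final,
            _train_matrix=self.matrix,
        )


@dataclass
class ReadmissionResults:
    """Fitted model: selected hyper-parameters, AUROCs and diagnostics."""

    family: str
    mode: str
    params: dict
    cv_results: pd.DataFrame
    cv_auc: float
    test_auc: float
    roc_internal: pd.DataFrame
    manifest: list[str]
    seed: int
    estimator: object
    external_auc: float | None = None
    roc_external: pd.DataFrame | None = None
    _train_matrix: FeatureMatrix | None = None

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        if list(matrix.manifest) != list(self.manifest):
            raise ValueError("matrix is not conformed to this run's manifest")
        return self.estimator.predict_proba(matrix.X.to_numpy(float))[:, 1]

    def external_validate(self, matrix: FeatureMatrix) -> "ReadmissionResults":
        """Score the frozen model on an external conformed matrix (no refit)."""
        scores = self.predict(matrix)
        y = matrix.y.to_numpy(int)
        self.external_auc = auroc(scores, y)
        self.roc_external = roc_points(scores, y)
        return self

    def covariate_summary(self) -> pd.DataFrame:
        if self._train_matrix is None:
            raise ValueError("training matrix not retained")
        return covariate_summary(self._train_matrix)

    def summary(self) -> str:
        lines = [
            f"Readmission model ({self.family}, features: {self.mode})",
            "=" * 48,
            f"selected hyper-parameters : {self.params}",
            f"grid points evaluated     : {len(self.cv_results)}",
            f"CV AUROC (selected point) : {self.cv_auc:.4f}",
            f"internal test AUROC       : {self.test_auc:.4f}",
        ]
        if self.external_auc is not None:
            lines.append(f"external AUROC            : {self.external_auc:.4f}")
        lines.append(f"seed                      : {self.seed}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mode": self.mode,
            "params": {k: (v if v is None or isinstance(v, (int, float, str, bool)) else str(v))
                       for k, v in self.params.items()},
            "cv_auc": round(self.cv_auc, 6),
            "test_auc": round(self.test_auc, 6),
            "external_auc": None if self.external_auc is None else round(self.external_auc, 6),
            "seed": self.seed,
            "n_features": len(self.manifest),
        }


def grid_search_cv(matrix: FeatureMatrix, spec: ModelSpec | str, k: int = 10, seed: int = 0) -> ReadmissionResults:
    """Functional surface over ReadmissionModel(...).fit(...)."""
    return ReadmissionModel(matrix, spec).fit(k=k, seed=seed)


def external_validate(run: ReadmissionResults, external_matrix: FeatureMatrix) -> ReadmissionResults:
    return run.external_validate(external_matrix)


def report(runs: list[ReadmissionResults], out: str | Path) -> pd.DataFrame:
    """Write the comparison grid (family x feature mode, internal/external
    AUROC, best-per-column flagged), ROC point files, run metadata and the
    covariate summary.  Deterministic output for fixed inputs."""
    if not runs:
        raise ValueError("report needs at least one run")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in runs:
        rows.append(
            {
                "family": r.family,
                "mode": r.mode,
                "internal_auc": round(r.test_auc, 6),
                "external_auc": None if r.external_auc is None else round(r.external_auc, 6),
            }
        )
    table = pd.DataFrame(rows)
    for col in ("internal_auc", "external_auc"):
        vals = table[col].astype(float)
        table[f"best_{col.split('_')[0]}"] = (
            (vals == vals.max()) & vals.notna() if vals.notna().any() else False
        )
    table = table.sort_values(["family", "mode"], kind="mergesort").reset_index(drop=True)
    table.to_csv(out / "table3.csv", index=False, lineterminator="\n")

    meta = []
    for r in runs:
        tag = f"{r.family.lower()}_{r.mode}"
        r.roc_internal.round(6).to_csv(out / f"roc_internal_{tag}.csv", index=False, lineterminator="\n")
        if r.roc_external is not None:
            r.roc_external.round(6).to_csv(out / f"roc_external_{tag}.csv", index=False, lineterminator="\n")
        if r._train_matrix is not None:
            r.covariate_summary().round(6).to_csv(
                out / f"covariate_summary_{tag}.csv", index=False, lineterminator="\n"
            )
        meta.append(r.to_dict())
    (out / "runs.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return table
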