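"""End-to-end study pipeline: simulate -> cohort -> W-score -> features ->
train -> external validation -> report.

Used by the command-line interface and by reproducibility checks; every stage
is also callable on its own.  All randomness derives from the simulation
config seed and the model seed, so a fixed (config, seed) pair reproduces
byte-identical report files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .charlson import CharlsonMap
from .cohort import PlannedCodeLists, build_cohort
from .eras import DEFAULT_GAP_DAYS, build_condition_eras, build_drug_eras
from .exposure import WarningCriteria, load_criteria, wscore_events
from .features import DEFAULT_MIN_CONCEPT_COUNT, FeatureMatrix, assemble, conform
from .model import ModelSpec, ReadmissionModel, ReadmissionResults, report
from .simulate import SimConfig, StudyData, generate_study, write_study

logger = logging.getLogger(__name__)

SITES = ("internal", "external")


@dataclass
class PipelineResult:
    study: StudyData
    cohorts: dict[str, pd.DataFrame]
    wscores: dict[str, pd.DataFrame]
    matrices: dict[tuple[str, str], FeatureMatrix]  # (site, mode) -> matrix
    runs: list[ReadmissionResults] = field(default_factory=list)
    table: pd.DataFrame | None = None

    def run(self, family: str, mode: str) -> ReadmissionResults:
        for r in self.runs:
            if r.family == family and r.mode == mode:
                return r
        raise KeyError((family, mode))


def featurize_site(
    bundle,
    cohort: pd.DataFrame,
    wscores: pd.DataFrame,
    mode: str,
    era_gap_days: int = DEFAULT_GAP_DAYS,
    min_concept_count: int = DEFAULT_MIN_CONCEPT_COUNT,
) -> FeatureMatrix:
    cond_eras = build_condition_eras(bundle.conditions, era_gap_days)
    drug_eras = build_drug_eras(bundle.drugs, era_gap_days)
    return assemble(
        cohort, cond_eras, drug_eras, wscores, mode=mode,
        min_concept_count=min_concept_count,
    )


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path | None = None,
    families: tuple[str, ...] = ("GBM",),
    modes: tuple[str, ...] = ("clinical", "clinical_w"),
    grids: dict[str, dict] | None = None,
    k: int = 10,
    model_seed: int | None = None,
    criteria: WarningCriteria | None = None,
    planned: PlannedCodeLists | None = None,
    charlson_map: CharlsonMap | None = None,
    era_gap_days: int = DEFAULT_GAP_DAYS,
    min_concept_count: int = DEFAULT_MIN_CONCEPT_COUNT,
) -> PipelineResult:
    """Run the whole study once and (optionally) write all artefacts under
    ``out_dir``: simulated CDM + weather files, per-site cohort/W-score/
    feature files and the report directory."""
    if criteria is None:
        criteria = load_criteria()
    if model_seed is None:
        model_seed = config.seed
    study = generate_study(config, criteria)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_study(study, out)

    cohorts, wscores, matrices = {}, {}, {}
    for site in SITES:
        bundle = study.bundle(site)
        cohort = build_cohort(bundle, window=config.window, planned=planned,
                              charlson_map=charlson_map)
        w = wscore_events(cohort, study.series[site], criteria)
        cohorts[site], wscores[site] = cohort, w
        if out is not None:
            c = cohort.copy()
            for col in ("admit_date", "discharge_date", "readmission_date"):
                c[col] = pd.to_datetime(c[col]).dt.strftime("%Y-%m-%d")
            c.to_csv(out / f"cohort_{site}.csv", index=False, lineterminator="\n")
            ww = w.copy()
            for col in ("window_start", "window_end"):
                ww[col] = pd.to_datetime(ww[col]).dt.strftime("%Y-%m-%d")
            ww.to_csv(out / f"wscores_{site}.csv", index=False, lineterminator="\n")

    for mode in modes:
        train = featurize_site(study.internal, cohorts["internal"], wscores["internal"],
                               mode, era_gap_days, min_concept_count)
        ext = featurize_site(study.external, cohorts["external"], wscores["external"],
                             mode, era_gap_days, min_concept_count=1)
        matrices[("internal", mode)] = train
        matrices[("external", mode)] = conform(ext, train.manifest)
        if out is not None:
            train.save(out / f"features_internal_{mode}.csv", out / f"manifest_{mode}.json")

    runs: list[ReadmissionResults] = []
    for family in families:
        spec = ModelSpec(family, (grids or {}).get(family, {}))
        for mode in modes:
            res = ReadmissionModel(matrices[("internal", mode)], spec).fit(k=k, seed=model_seed)
            res.external_validate(matrices[("external", mode)])
            runs.append(res)
            logger.info("%s/%s: internal AUROC %.3f, external %.3f",
                        family, mode, res.test_auc, res.external_auc)

    if out is not None:
        table = report(runs, out / "report")
    else:
        table = pd.DataFrame(
            [
                {"family": r.family, "mode": r.mode, "internal_auc": r.test_auc,
                 "external_auc": r.external_auc}
                for r in runs
            ]
        )
    return PipelineResult(study=study, cohorts=cohorts, wscores=wscores,
                          matrices=matrices, runs=runs, table=table)
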