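"""End-to-end orchestration: filter -> impute -> score -> fit weights -> sum.

The stages run in pipeline order: completeness filter, left-censored
imputation, cohort-wide min-max scoring with pseudo-log2 transform,
blood-pressure classification, proportional-odds weight fitting (per
requested scheme), then the acute / secondary / allostatic-load summations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import (
    BPScheme,
    CohortTable,
    DEMOGRAPHIC_COLUMNS,
    ValidationError,
    classify_bp_frame,
)
from .preprocess import FilterReport, ImputationResult, filter_biomarkers, impute_qrilc
from .scoring import (
    MediatorScoreMatrix,
    WeightVector,
    acute_stress_score,
    allostatic_load_score,
    default_secondary_weights,
    fit_ordinal_weights,
    minmax_score,
    secondary_mediator_score,
)

__all__ = ["PipelineResult", "score_pipeline"]

_SCHEME_SUFFIX = {"two_class": "two", "three_class": "three"}


@dataclass
class PipelineResult:
    """Everything a scoring run produces, for inspection and serialisation."""

    scores: pd.DataFrame
    weights: dict[BPScheme, WeightVector]
    filter_report: FilterReport
    imputation: ImputationResult
    score_matrix: MediatorScoreMatrix
    bp_classes: dict[BPScheme, pd.Series]


def score_pipeline(
    cohort: CohortTable,
    seed: int,
    schemes: tuple[BPScheme, ...] = ("two_class", "three_class"),
    filter_threshold: float = 0.25,
    tune_sigma: float = 1.0,
    impute_scale: str = "log",
    secondary_magnitude: float = 0.25,
    require_convergence: bool = False,
) -> PipelineResult:
    """Score a cohort end to end under one or both BP-class weight schemes.

    Participants without blood pressure are scored (their mediator scores do
    not need BP) but excluded from the weight fit.  ``seed`` drives the
    imputation draws only — everything else is deterministic.
    """
    report = filter_biomarkers(cohort, threshold=filter_threshold)
    cohort = report.apply(cohort)
    panel = cohort.panel
    imputation = impute_qrilc(cohort, seed=seed, tune_sigma=tune_sigma, scale=impute_scale)
    matrix = minmax_score(imputation.values)

    weights: dict[BPScheme, WeightVector] = {}
    acute: dict[str, pd.Series] = {}
    primary = list(panel.primary)
    for scheme in schemes:
        bp = classify_bp_frame(cohort.data, scheme)
        wv = fit_ordinal_weights(matrix.transformed[primary], bp, scheme)
        if require_convergence and not wv.fit_converged:
            raise ValidationError(f"ordinal fit did not converge for {scheme}")
        weights[scheme] = wv
        acute[_SCHEME_SUFFIX[scheme]] = acute_stress_score(matrix.transformed, wv)

    sw = default_secondary_weights(panel, magnitude=secondary_magnitude)
    secondary = secondary_mediator_score(matrix.transformed, sw)

    out = cohort.data[[c for c in DEMOGRAPHIC_COLUMNS if c in cohort.data.columns]].copy()
    for suffix, series in acute.items():
        out[f"acute_{suffix}"] = series
        out[f"al_{suffix}"] = allostatic_load_score(series, secondary)
    out["secondary"] = secondary
    # deterministic order regardless of which schemes ran
    score_cols = [c for c in ("acute_two", "acute_three", "secondary", "al_two", "al_three")
                  if c in out.columns]
    out = out[[c for c in out.columns if c not in score_cols] + score_cols]

    return PipelineResult(
        scores=out,
        weights=weights,
        filter_report=report,
        imputation=imputation,
        score_matrix=matrix,
        bp_classes={s: classify_bp_frame(cohort.data, s) for s in schemes},
    )
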