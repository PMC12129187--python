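"""Allostatic-load scoring: min-max mediator scores, pseudo-log2 transform,
ordinal-regression weight derivation, and the three score summations.

The construction follows a ToxPi-style weighted-slice scheme.  Each biomarker
is min-max normalised over the whole cohort to a dimensionless mediator score
in [0, 1], then pseudo-log2 transformed (``log2(x + 1)``, which is monotone
and fixes 0 and 1) to reduce skew.  The acute stress score is a convex
combination of the three primary-mediator scores, with weights taken from a
proportional-odds (cumulative-logit) ordinal regression predicting blood
pressure class: the absolute slope coefficients, rescaled to sum to 1.  The
secondary mediator score fixes |weight| = 0.25 for the four secondary
mediators, HDL entering negatively.  The allostatic load score is the exact
sum of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import BiomarkerPanel, BPScheme, ValidationError

__all__ = [
    "MediatorScoreMatrix",
    "WeightVector",
    "ScoreSet",
    "minmax_score",
    "pseudo_log2",
    "default_secondary_weights",
    "fit_ordinal_weights",
    "acute_stress_score",
    "secondary_mediator_score",
    "allostatic_load_score",
]


@dataclass
class MediatorScoreMatrix:
    """Participant x biomarker scores, raw and pseudo-log2 transformed.

    Raw scores are min-max normalised over the cohort, so per biomarker the
    minimum maps to 0 and the maximum to 1 (both attained).  ``minima`` and
    ``maxima`` record the concentration bounds used.
    """

    raw: pd.DataFrame
    transformed: pd.DataFrame
    minima: pd.Series
    maxima: pd.Series


@dataclass
class WeightVector:
    """Nonnegative primary-mediator weights summing to 1.

    Tagged with the blood-pressure class ``scheme`` that produced them, the
    raw slope ``coefficients`` of the proportional-odds fit, the number of
    participants fitted, and whether the optimiser converged.
    """

    scheme: BPScheme
    weights: dict[str, float]
    coefficients: dict[str, float]
    n_fitted: int
    fit_converged: bool

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be nonnegative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights)


#: per-participant scores; AL is exactly acute + secondary under each scheme
ScoreSet = pd.DataFrame


def minmax_score(values: pd.DataFrame) -> MediatorScoreMatrix:
    """Min-max normalise each biomarker over the cohort (Formula-1 style).

    ``score = (x - min) / (max - min)`` column-wise.  Requires a completed
    matrix (no NaN) with at least two distinct values per biomarker.
    """
    if values.isna().any().any():
        raise ValidationError("minmax_score requires a completed matrix (no missing)")
    minima = values.min(axis=0)
    maxima = values.max(axis=0)
    span = maxima - minima
    degenerate = span[span == 0]
    if len(degenerate):
        raise ValidationError(
            f"degenerate biomarker (constant over cohort): {list(degenerate.index)}"
        )
    raw = (values - minima) / span
    return MediatorScoreMatrix(
        raw=raw,
        transformed=pseudo_log2(raw),
        minima=minima,
        maxima=maxima,
    )


def pseudo_log2(score):
    """``log2(score + 1)`` on [0, 1]: monotone, fixes 0 and 1.

    Accepts scalars, arrays, Series or DataFrames of scores in [0, 1].
    """
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("pseudo_log2 input must lie in [0, 1]")
    out = np.log2(arr + 1.0)
    if isinstance(score, (pd.DataFrame, pd.Series)):
        return type(score)(out, index=score.index, **(
            {"columns": score.columns} if isinstance(score, pd.DataFrame) else {}
        ))
    if np.isscalar(score):
        return float(out)
    return out


def default_secondary_weights(panel: BiomarkerPanel, magnitude: float = 0.25) -> dict[str, float]:
    """Signed secondary weights: ``sign * magnitude`` per secondary mediator.

    The default magnitude 0.25 is the equal share over the four-marker
    secondary panel; with ``magnitude = 1/k`` the scheme generalises to k
    secondary mediators.
    """
    return {name: panel.sign(name) * magnitude for name in panel.secondary}


def fit_ordinal_weights(
    transformed: pd.DataFrame,
    bp_class: pd.Series,
    scheme: BPScheme,
) -> WeightVector:
    """Derive primary-mediator weights from a proportional-odds BP model.

    Fits a cumulative-logit model of the ordinal blood-pressure class on the
    transformed primary-mediator scores of participants with observed BP,
    then rescales the absolute slope coefficients to sum to 1.  The aim is
    the relative importance of the mediators, not BP prediction.  The number
    of classes is 2 or 3 according to ``scheme``; every class must be
    occupied.  Non-convergence is flagged (``fit_converged=False``), not
    hidden.
    """
    mask = bp_class.notna()
    n = int(mask.sum())
    if n < 10:
        raise ValidationError(
            f"need at least 10 participants with observed BP to fit weights, got {n}"
        )
    y = bp_class[mask].astype(int)
    n_classes = 3 if scheme == "three_class" else 2
    counts = y.value_counts()
    missing_classes = [k for k in range(n_classes) if counts.get(k, 0) == 0]
    if missing_classes:
        raise ValidationError(
            f"BP class(es) {missing_classes} have no members under {scheme}"
        )
    X = transformed.loc[mask.index[mask]]
    endog = pd.Categorical(y, categories=list(range(n_classes)), ordered=True)
    model = OrderedModel(endog, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    converged = bool(res.mle_retvals.get("converged", False))
    k = X.shape[1]
    beta = np.asarray(res.params)[:k]
    abs_beta = np.abs(beta)
    total = abs_beta.sum()
    if total == 0:
        weights = np.full(k, 1.0 / k)
    else:
        weights = abs_beta / total
    names = list(X.columns)
    return WeightVector(
        scheme=scheme,
        weights=dict(zip(names, weights.tolist())),
        coefficients=dict(zip(names, beta.tolist())),
        n_fitted=n,
        fit_converged=converged,
    )


def acute_stress_score(transformed: pd.DataFrame, weights: WeightVector) -> pd.Series:
    """Weighted sum of transformed primary-mediator scores (Formula-2 style)."""
    missing = [m for m in weights.weights if m not in transformed.columns]
    if missing:
        raise ValidationError(f"missing primary mediator column(s): {missing}")
    w = pd.Series(weights.weights)
    return transformed[list(w.index)].mul(w, axis=1).sum(axis=1).rename(
        f"acute_{'two' if weights.scheme == 'two_class' else 'three'}"
    )


def secondary_mediator_score(
    transformed: pd.DataFrame, secondary_weights: dict[str, float]
) -> pd.Series:
    """Signed fixed-weight sum of transformed secondary-mediator scores.

    With the default weights this is ``0.25 * (fibrinogen + CRP + HbA1c) -
    0.25 * HDL``, giving a range of [-0.25, 0.75].
    """
    missing = [m for m in secondary_weights if m not in transformed.columns]
    if missing:
        raise ValidationError(f"missing secondary mediator column(s): {missing}")
    w = pd.Series(secondary_weights)
    return transformed[list(w.index)].mul(w, axis=1).sum(axis=1).rename("secondary")


def allostatic_load_score(acute: pd.Series, secondary: pd.Series) -> pd.Series:
    """Allostatic load = acute stress score + secondary mediator score, exactly."""
    return (acute + secondary).rename("al")
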