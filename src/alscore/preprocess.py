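"""Completeness filtering and left-censored (QRILC-style) imputation.

Serum biomarkers that fall below an assay's detection limit are missing not
at random: the absent values are the *low* ones.  Imputing them from the
centre of the observed distribution would bias every downstream score, so
missing entries are instead drawn from the estimated left tail.

The procedure, per biomarker with missingness fraction ``c``:

1. work on natural-log concentrations (concentrations are positive and
   right-skewed; a raw-scale mode is available);
2. estimate the *uncensored* normal distribution's mean and SD by
   least-squares regression of the sorted observed log values on standard
   normal quantiles of plotting positions ``p_i = c + (1 - c)(i - 0.5)/n``,
   i.e. the observed values are taken to occupy the upper ``1 - c`` of the
   distribution;
3. draw each missing entry independently from
   ``Normal(mu, (tune_sigma * sigma)^2)`` truncated above at
   ``mu + sigma * Phi^{-1}(c)`` (the estimated censoring quantile), further
   capped at the observed minimum so imputed values never exceed it;
4. exponentiate back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, ValidationError

__all__ = ["FilterReport", "ImputationResult", "filter_biomarkers", "impute_qrilc"]


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the completeness filter over a cohort's panel."""

    kept: tuple[str, ...]
    dropped: tuple[str, ...]
    fraction_present: dict[str, float]
    threshold: float

    def apply(self, cohort: CohortTable) -> CohortTable:
        """Cohort restricted to the kept biomarkers."""
        if set(self.kept) == set(cohort.panel.names):
            return cohort
        df = cohort.data.drop(columns=list(self.dropped))
        return CohortTable(df, cohort.panel.subset(self.kept))


@dataclass
class ImputationResult:
    """Completed concentration matrix plus the fitted tail model.

    ``values`` has no missing entries for the imputed biomarkers; observed
    entries are carried through unchanged.  ``mu_hat``/``sigma_hat`` are the
    estimated uncensored log-scale mean/SD per biomarker (NaN where nothing
    was missing, hence nothing fitted).
    """

    values: pd.DataFrame
    imputed_mask: pd.DataFrame
    mu_hat: pd.Series
    sigma_hat: pd.Series
    seed: int
    tune_sigma: float
    scale: str = "log"


def filter_biomarkers(cohort: CohortTable, threshold: float = 0.25) -> FilterReport:
    """Drop biomarkers observed in fewer than ``threshold`` of participants.

    The default keeps any biomarker with at least 25% of its values present.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    conc = cohort.concentrations
    frac = (conc.notna().sum(axis=0) / len(conc)).to_dict()
    kept = tuple(n for n in cohort.panel.names if frac[n] >= threshold)
    dropped = tuple(n for n in cohort.panel.names if frac[n] < threshold)
    if not kept:
        raise ValidationError("no usable biomarkers: all failed the completeness filter")
    return FilterReport(kept, dropped, frac, threshold)


def _fit_censored_normal(observed: np.ndarray, c: float) -> tuple[float, float]:
    """Mean/SD of the uncensored normal via plotting-position regression.

    ``observed`` are the (already transformed) non-missing values; ``c`` is
    the censored fraction.  With no censoring this reduces to an ordinary
    normal-quantile (Q-Q) fit of the sample.
    """
    x = np.sort(np.asarray(observed, dtype=float))
    n = x.size
    p = c + (1.0 - c) * (np.arange(1, n + 1) - 0.5) / n
    q = stats.norm.ppf(p)
    sigma, mu = np.polyfit(q, x, 1)
    return float(mu), float(sigma)


def impute_qrilc(
    cohort: CohortTable,
    seed: int,
    tune_sigma: float = 1.0,
    scale: str = "log",
) -> ImputationResult:
    """Impute left-censored missing concentrations from the estimated left tail.

    Fully deterministic given ``seed``.  ``tune_sigma`` scales the SD of the
    truncated-normal draws (1.0 = the fitted SD).  ``scale`` is ``"log"``
    (default: fit and draw on natural-log concentrations) or ``"raw"``.
    """
    if tune_sigma <= 0:
        raise ValueError("tune_sigma must be positive")
    if scale not in ("log", "raw"):
        raise ValueError(f"scale must be 'log' or 'raw', got {scale!r}")
    rng = np.random.default_rng(seed)
    conc = cohort.concentrations.copy()
    mask = conc.isna()
    mu_hat = pd.Series(np.nan, index=list(conc.columns), dtype=float)
    sigma_hat = pd.Series(np.nan, index=list(conc.columns), dtype=float)

    for name in conc.columns:
        col = conc[name]
        miss = mask[name]
        n_missing = int(miss.sum())
        if n_missing == 0:
            continue
        obs = col[~miss].to_numpy(dtype=float)
        if obs.size < 3:
            raise ValidationError(
                f"biomarker {name!r} has only {obs.size} observed values; "
                "need at least 3 to impute"
            )
        c = n_missing / len(col)
        work = np.log(obs) if scale == "log" else obs
        mu, sigma = _fit_censored_normal(work, c)
        mu_hat[name] = mu
        sigma_hat[name] = sigma
        # upper bound: estimated censoring quantile, never above the observed min
        upper = min(mu + sigma * stats.norm.ppf(c), float(work.min()))
        sd = tune_sigma * sigma
        b = (upper - mu) / sd
        draws = stats.truncnorm.rvs(
            a=-np.inf, b=b, loc=mu, scale=sd, size=n_missing, random_state=rng
        )
        if scale == "log":
            draws = np.exp(draws)
        filled = col.to_numpy(dtype=float)
        filled[miss.to_numpy()] = draws
        conc[name] = filled

    return ImputationResult(
        values=conc,
        imputed_mask=mask,
        mu_hat=mu_hat,
        sigma_hat=sigma_hat,
        seed=seed,
        tune_sigma=tune_sigma,
        scale=scale,
    )
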