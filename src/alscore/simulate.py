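"""Synthetic stratified cohorts with the statistical structure the scoring
pipeline assumes, for end-to-end testing and parameter-recovery experiments.

The generator emulates a 63-participant serum-biomarker study design:

* eight strata (sex x race x smoking status) with per-stratum biomarker
  means/SDs matched by moment-matched log-normal marginals (concentrations
  are positive and right-skewed);
* MNAR left-censoring of one biomarker (default: epinephrine, 17.5%): the
  lowest cohort-wide values are set missing, mimicking assay detection
  limits;
* blood pressure generated from an ordinal-logistic latent model on the true
  (uncensored) transformed mediator scores, so that the weight-fitting stage
  has a known ground truth; a subset of participants (default 34) has BP
  observed, matching a design in which one contributing study did not
  collect it.

Everything is driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import BiomarkerPanel, CohortTable
from .scoring import minmax_score

__all__ = [
    "Stratum",
    "SyntheticConfig",
    "generate_cohort",
    "recovery_experiment",
    "scale_counts",
    "TABLE1_STRATA",
    "TABLE1_BIOMARKER_PARAMS",
    "TABLE1_AGE_PARAMS",
]

Stratum = tuple[str, str, str]  # (sex, race, smoking_status)

#: default stratum sizes: 8 cells of sex x race x smoking, total 63
TABLE1_STRATA: dict[Stratum, int] = {
    ("male", "White", "non-smoker"): 4,
    ("male", "White", "smoker"): 8,
    ("male", "Black", "non-smoker"): 3,
    ("male", "Black", "smoker"): 8,
    ("female", "White", "non-smoker"): 12,
    ("female", "White", "smoker"): 8,
    ("female", "Black", "non-smoker"): 11,
    ("female", "Black", "smoker"): 9,
}

_STRATUM_ORDER = tuple(TABLE1_STRATA)

# per-biomarker (mean, SD) on the concentration scale, one pair per stratum in
# _STRATUM_ORDER; units as in the default panel
_PARAMS = {
    "cortisol": [(58.6, 45.4), (92.8, 41.6), (94.3, 17.4), (96.1, 43.3),
                 (123.0, 77.7), (84.6, 52.8), (117.6, 71.7), (73.8, 28.7)],
    "epinephrine": [(7.9, 4.3), (6.5, 2.0), (7.2, 2.1), (5.9, 1.8),
                    (6.7, 1.4), (5.2, 0.84), (6.9, 1.5), (5.8, 1.3)],
    "noradrenaline": [(2.41, 1.47), (2.83, 1.77), (1.73, 0.60), (3.07, 1.46),
                      (2.60, 1.82), (1.04, 0.63), (2.20, 1.53), (1.86, 1.76)],
    "fibrinogen": [(1.18, 0.55), (1.01, 0.54), (0.86, 0.14), (1.32, 0.79),
                   (1.08, 0.83), (0.80, 0.69), (1.19, 0.75), (0.77, 0.31)],
    "crp": [(9.52, 15.21), (3.5, 5.14), (3.99, 5.71), (1.73, 1.36),
            (4.42, 8.26), (7.38, 12.40), (10.13, 14.08), (6.45, 9.42)],
    "hba1c": [(12.95, 10.03), (12.3, 8.96), (10.03, 7.49), (13.32, 10.85),
              (7.31, 7.10), (4.70, 7.24), (9.89, 8.26), (8.04, 7.84)],
    "hdl": [(1.68, 0.58), (1.7, 0.84), (1.80, 1.08), (2.24, 0.86),
            (1.96, 0.74), (2.62, 2.15), (1.83, 0.67), (1.87, 1.56)],
}

TABLE1_BIOMARKER_PARAMS: dict[str, dict[Stratum, tuple[float, float]]] = {
    name: dict(zip(_STRATUM_ORDER, pairs)) for name, pairs in _PARAMS.items()
}

TABLE1_AGE_PARAMS: dict[Stratum, tuple[float, float]] = dict(
    zip(_STRATUM_ORDER, [(23.5, 4.64), (28, 5.1), (33.3, 9.5), (29, 5.9),
                         (25.8, 4.4), (25.8, 7.3), (30.2, 6.6), (32.4, 4.2)])
)

#: generating slope coefficients of the latent BP model, proportional to the
#: target weight shares (epinephrine 73%, cortisol 22%, noradrenaline 4%)
DEFAULT_BP_BETAS: dict[str, float] = {
    "epinephrine": 8.0 * 0.73,
    "cortisol": 8.0 * 0.22,
    "noradrenaline": 8.0 * 0.04,
}

#: latent cut-points separating normal | elevated | stage 1 | stage 2,
#: calibrated once (pooled replicates of the default 63-participant design)
#: to the marginal class proportions 15:4:11:4
DEFAULT_BP_CUTPOINTS: tuple[float, float, float] = (2.6308, 3.2747, 5.6494)

# mm Hg sampling boxes for each raw BP category (sys_lo, sys_hi, dia_lo, dia_hi);
# each box lies strictly inside its category's defining region
_BP_BOXES = {
    0: (100.0, 119.0, 60.0, 79.0),
    1: (120.0, 129.0, 60.0, 79.0),
    2: (130.0, 139.0, 80.0, 89.0),
    3: (140.0, 160.0, 90.0, 105.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic cohort draw.

    ``biomarker_params`` maps biomarker -> stratum -> (mean, SD) on the
    concentration scale.  ``censor_fraction`` of the censor biomarker's
    values — the lowest ones, cohort-wide — are set missing.  ``bp_betas``
    and ``bp_cutpoints`` define the ordinal-logistic latent model generating
    the four raw BP categories; ``n_bp_observed`` participants (chosen at
    random) get actual readings, the rest have BP missing.
    """

    n_per_stratum: dict[Stratum, int] = field(
        default_factory=lambda: dict(TABLE1_STRATA)
    )
    biomarker_params: dict[str, dict[Stratum, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_BIOMARKER_PARAMS.items()}
    )
    age_params: dict[Stratum, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_AGE_PARAMS)
    )
    censor_biomarker: str = "epinephrine"
    censor_fraction: float = 0.175
    bp_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BP_BETAS))
    bp_cutpoints: tuple[float, float, float] = DEFAULT_BP_CUTPOINTS
    n_bp_observed: int | None = 34
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_stratum.values()):
            raise ValueError("stratum counts must be >= 0")
        if sum(self.n_per_stratum.values()) == 0:
            raise ValueError("zero total participants")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")
        for name, strata in self.biomarker_params.items():
            for st, (m, s) in strata.items():
                if s <= 0 or m <= 0:
                    raise ValueError(f"nonpositive mean/SD for {name} in {st}")
        cuts = self.bp_cutpoints
        if not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("bp_cutpoints must be strictly increasing")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_stratum.values())

    @property
    def generating_weight_proportions(self) -> dict[str, float]:
        """|beta| shares of the latent BP model — the ground truth that the
        ordinal-regression weight fit should recover."""
        total = sum(abs(b) for b in self.bp_betas.values())
        if total == 0:
            return {k: 1.0 / len(self.bp_betas) for k in self.bp_betas}
        return {k: abs(b) / total for k, b in self.bp_betas.items()}

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "n_per_stratum" in raw:
            kwargs["n_per_stratum"] = {tuple(k.split("|")): int(v)
                                       for k, v in raw["n_per_stratum"].items()}
        if "biomarker_params" in raw:
            kwargs["biomarker_params"] = {
                name: {tuple(k.split("|")): tuple(map(float, v)) for k, v in strata.items()}
                for name, strata in raw["biomarker_params"].items()
            }
        if "age_params" in raw:
            kwargs["age_params"] = {tuple(k.split("|")): tuple(map(float, v))
                                    for k, v in raw["age_params"].items()}
        for key in ("censor_biomarker", "censor_fraction", "bp_betas", "n_bp_observed", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "bp_cutpoints" in raw:
            kwargs["bp_cutpoints"] = tuple(map(float, raw["bp_cutpoints"]))
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "n_per_stratum": {"|".join(k): v for k, v in self.n_per_stratum.items()},
            "biomarker_params": {
                name: {"|".join(k): list(v) for k, v in strata.items()}
                for name, strata in self.biomarker_params.items()
            },
            "age_params": {"|".join(k): list(v) for k, v in self.age_params.items()},
            "censor_biomarker": self.censor_biomarker,
            "censor_fraction": self.censor_fraction,
            "bp_betas": dict(self.bp_betas),
            "bp_cutpoints": list(self.bp_cutpoints),
            "n_bp_observed": self.n_bp_observed,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def scale_counts(config: SyntheticConfig, n_total: int) -> SyntheticConfig:
    """Rescale stratum counts proportionally to a new total (largest-remainder
    rounding), e.g. to run recovery experiments at larger n."""
    old_total = config.n_total
    raw = {k: v * n_total / old_total for k, v in config.n_per_stratum.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return replace(config, n_per_stratum=counts)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal with given arithmetic mean/SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw one cohort under ``config``; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    panel = BiomarkerPanel.default()
    biomarkers = list(config.biomarker_params)

    rows: list[dict] = []
    pid = 0
    for stratum, n in config.n_per_stratum.items():
        sex, race, smoking = stratum
        for _ in range(n):
            pid += 1
            row: dict = {
                "participant_id": f"P{pid:03d}",
                "sex": sex,
                "race": race,
                "smoking_status": smoking,
            }
            am, asd = config.age_params.get(stratum, (28.0, 6.0))
            row["age"] = float(np.clip(rng.normal(am, asd), 18, 43))
            for name in biomarkers:
                m, s = config.biomarker_params[name][stratum]
                mu, sigma = _lognormal_params(m, s)
                row[name] = float(rng.lognormal(mu, sigma))
            rows.append(row)
    df = pd.DataFrame(rows)

    # latent ordinal BP from the true (uncensored) transformed mediator scores
    score_cols = list(config.bp_betas)
    matrix = minmax_score(df[score_cols])
    beta = pd.Series(config.bp_betas)
    latent = matrix.transformed[score_cols].mul(beta, axis=1).sum(axis=1)
    latent = latent + rng.logistic(size=len(df))
    raw_class = np.searchsorted(np.asarray(config.bp_cutpoints), latent.to_numpy())

    sys_bp = np.full(len(df), np.nan)
    dia_bp = np.full(len(df), np.nan)
    n_obs = len(df) if config.n_bp_observed is None else min(config.n_bp_observed, len(df))
    observed = np.sort(rng.choice(len(df), size=n_obs, replace=False))
    for i in observed:
        lo_s, hi_s, lo_d, hi_d = _BP_BOXES[int(raw_class[i])]
        sys_bp[i] = rng.uniform(lo_s, hi_s)
        dia_bp[i] = rng.uniform(lo_d, hi_d)
    df["systolic_bp"] = sys_bp
    df["diastolic_bp"] = dia_bp

    # MNAR left-censoring: bottom-k order statistics, cohort-wide
    k = int(round(config.censor_fraction * len(df)))
    if k > 0:
        vals = df[config.censor_biomarker].to_numpy()
        cut_idx = np.argsort(vals)[:k]
        df.loc[df.index[cut_idx], config.censor_biomarker] = np.nan

    return CohortTable(df, panel)


def recovery_experiment(
    config: SyntheticConfig,
    n_reps: int,
    scheme: str = "three_class",
) -> pd.DataFrame:
    """Run the full generate -> filter -> impute -> score -> fit pipeline
    ``n_reps`` times and summarise recovery of the generating quantities.

    Returns one row per primary mediator with the mean/SD of the recovered
    weight across replicates next to the generating proportion, plus rows
    summarising recovery of the censored biomarker's log-scale mean/SD by the
    imputation fit (truth = moments of the uncensored draw of each replicate).
    """
    from .pipeline import score_pipeline  # local import to avoid a cycle

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=n_reps)
    weight_rows: list[dict[str, float]] = []
    mu_err, sigma_err = [], []
    for rep_seed in seeds:
        cfg = replace(config, seed=int(rep_seed))
        cohort = generate_cohort(cfg)
        # truth for imputation recovery: log-moments of the uncensored draw
        full = generate_cohort(replace(cfg, censor_fraction=0.0))
        true_log = np.log(full.data[cfg.censor_biomarker].to_numpy())
        result = score_pipeline(cohort, seed=int(rep_seed) + 1, schemes=(scheme,))
        wv = result.weights[scheme]
        weight_rows.append(dict(wv.weights))
        imp = result.imputation
        if not np.isnan(imp.mu_hat[cfg.censor_biomarker]):
            mu_err.append(imp.mu_hat[cfg.censor_biomarker] - true_log.mean())
            sigma_err.append(imp.sigma_hat[cfg.censor_biomarker] - true_log.std(ddof=1))

    wdf = pd.DataFrame(weight_rows)
    truth = config.generating_weight_proportions
    rows = [
        {
            "quantity": f"weight_{name}",
            "mean": float(wdf[name].mean()),
            "sd": float(wdf[name].std(ddof=1)) if n_reps > 1 else 0.0,
            "truth": truth[name],
        }
        for name in wdf.columns
    ]
    for label, errs in (("imputation_mu_error", mu_err), ("imputation_sigma_error", sigma_err)):
        if errs:
            rows.append(
                {
                    "quantity": label,
                    "mean": float(np.mean(errs)),
                    "sd": float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0,
                    "truth": 0.0,
                }
            )
    return pd.DataFrame(rows)
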