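"""Group comparisons for stress scores: Welch t-tests, two-way ANOVA on
unbalanced designs, and FDR-adjusted pairwise post-hoc tests.

The battery mirrors a common epidemiological workflow: single-factor mean
differences by Welch's unequal-variance t-test; factor-pair analyses by a
two-factor linear model with interaction (Type II sums of squares, which are
well defined on unbalanced designs); and all-pairs post-hoc Welch tests among
the crossed cells with Benjamini-Hochberg adjustment applied within each
outcome x stratification family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "welch_t_test",
    "two_way_anova",
    "pairwise_posthoc",
    "bh_adjust",
    "significance_flag",
    "compare_scores",
]


@dataclass
class ComparisonResult:
    """One statistical comparison: test, statistic, df, p, optional adjusted p."""

    outcome: str
    grouping: str
    test: str  # welch_t | two_way_anova | pairwise_t
    statistic: float
    df: float
    p_value: float
    group_labels: tuple[str, ...] = ()
    group_ns: tuple[int, ...] = ()
    p_adjusted: float | None = None
    term: str | None = None  # ANOVA: which effect this row reports

    def as_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "grouping": self.grouping,
            "test": self.test,
            "term": self.term,
            "groups": " vs ".join(map(str, self.group_labels)),
            "ns": ",".join(map(str, self.group_ns)),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "flag": significance_flag(
                self.p_adjusted if self.p_adjusted is not None else self.p_value
            ),
        }
        return d


def significance_flag(p: float) -> str:
    """Boxplot-legend style flags: *** <0.001, ** <0.01, * <0.05, '∎' <0.1."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "∎"
    return ""


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def welch_t_test(
    x,
    y,
    outcome: str = "outcome",
    labels: tuple[str, str] = ("x", "y"),
) -> ComparisonResult:
    """Two-sided Welch unequal-variance t-test between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for arr, lab in ((x, labels[0]), (y, labels[1])):
        if arr.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    res = sps.ttest_ind(x, y, equal_var=False)
    stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if np.isnan(stat) and np.allclose(x.mean(), y.mean()):
        # degenerate zero-variance samples with equal means: no difference
        stat, p = 0.0, 1.0
    return ComparisonResult(
        outcome=outcome,
        grouping=" vs ".join(labels),
        test="welch_t",
        statistic=stat,
        df=df,
        p_value=p,
        group_labels=labels,
        group_ns=(x.size, y.size),
    )


def two_way_anova(
    data: pd.DataFrame,
    outcome: str,
    factor_a: str,
    factor_b: str,
    typ: int = 2,
) -> list[ComparisonResult]:
    """Two-factor ANOVA with interaction on a possibly unbalanced design.

    Returns one result per main effect and the interaction (Type II sums of
    squares by default; Type I/III selectable), plus the omnibus F of the full
    interaction model, which serves as the headline "overall p" of a
    stratified comparison.  Every cell of the cross must be nonempty.
    """
    df = data[[outcome, factor_a, factor_b]].dropna()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    cells = df.groupby([factor_a, factor_b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[factor_a].unique(), df[factor_b].unique()]
    )
    empty = [c for c in full if c not in cells.index]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")
    grouping = f"{factor_a} x {factor_b}"
    if np.var(df[outcome].to_numpy(), ddof=0) == 0:
        # no variance anywhere: every effect F is 0/0; flag rather than crash
        out = []
        for term in (factor_a, factor_b, f"{factor_a}:{factor_b}", "omnibus"):
            out.append(
                ComparisonResult(
                    outcome=outcome, grouping=grouping, test="two_way_anova",
                    statistic=np.nan, df=np.nan, p_value=np.nan, term=term,
                )
            )
        return out
    model = ols(
        f"Q('{outcome}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(model, typ=typ)
    term_names = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
    }
    results = []
    for row_name, pretty in term_names.items():
        row = table.loc[row_name]
        results.append(
            ComparisonResult(
                outcome=outcome,
                grouping=grouping,
                test="two_way_anova",
                statistic=float(row["F"]),
                df=float(row["df"]),
                p_value=float(row["PR(>F)"]),
                term=pretty,
            )
        )
    results.append(
        ComparisonResult(
            outcome=outcome,
            grouping=grouping,
            test="two_way_anova",
            statistic=float(model.fvalue),
            df=float(model.df_model),
            p_value=float(model.f_pvalue),
            term="omnibus",
        )
    )
    return results


def pairwise_posthoc(
    data: pd.DataFrame,
    outcome: str,
    factor_a: str,
    factor_b: str,
) -> list[ComparisonResult]:
    """All-pairs Welch t-tests among the factor_a x factor_b cells, BH-adjusted.

    Adjustment is applied within this family (one outcome, one
    stratification).  Cells with fewer than 2 members are skipped with a
    warning.
    """
    df = data[[outcome, factor_a, factor_b]].dropna()
    cell = df[factor_a].astype(str) + ":" + df[factor_b].astype(str)
    groups = {lab: grp[outcome].to_numpy() for lab, grp in df.groupby(cell)}
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 cells for pairwise comparisons")
    results: list[ComparisonResult] = []
    for a, b in itertools.combinations(labels, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            warnings.warn(
                f"skipping pair ({a}, {b}): a cell has fewer than 2 members",
                stacklevel=2,
            )
            continue
        r = welch_t_test(groups[a], groups[b], outcome=outcome, labels=(a, b))
        r.test = "pairwise_t"
        r.grouping = f"{factor_a} x {factor_b}"
        results.append(r)
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def compare_scores(
    scores: pd.DataFrame,
    outcomes: tuple[str, ...] = ("acute_two", "acute_three", "secondary", "al_two", "al_three"),
    factors: tuple[str, ...] = ("race", "sex", "smoking_status"),
    pairs: tuple[tuple[str, str], ...] | None = None,
) -> pd.DataFrame:
    """Run the full comparison battery over a score table.

    For every outcome: Welch t-tests across each two-level factor, and for
    every factor pair a two-way ANOVA plus BH-adjusted pairwise post-hoc
    tests.  Returns a tidy frame (one comparison per row).
    """
    for col in outcomes + factors:
        if col not in scores.columns:
            raise ValueError(f"scores table lacks required column {col!r}")
    if pairs is None:
        pairs = tuple(itertools.combinations(factors, 2))
    rows: list[dict] = []
    for outcome in outcomes:
        for factor in factors:
            levels = sorted(scores[factor].dropna().unique())
            if len(levels) != 2:
                continue
            a = scores.loc[scores[factor] == levels[0], outcome].dropna()
            b = scores.loc[scores[factor] == levels[1], outcome].dropna()
            r = welch_t_test(a, b, outcome=outcome, labels=(str(levels[0]), str(levels[1])))
            r.grouping = factor
            rows.append(r.as_dict())
        for fa, fb in pairs:
            for r in two_way_anova(scores, outcome, fa, fb):
                rows.append(r.as_dict())
            for r in pairwise_posthoc(scores, outcome, fa, fb):
                rows.append(r.as_dict())
    return pd.DataFrame(rows)
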