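"""Bivariate screening of SHC items against the health outcomes.

Each binary SHC item is tested against every outcome with the classical
test-selection rules: a 2x2 chi-square for binary outcomes, replaced by
Fisher's exact test when any expected cell count falls below five; a pooled
two-sample t-test for continuous outcomes, replaced by the Mann-Whitney
U-test when a Shapiro-Wilk check rejects normality in either group. Items
that are non-significant on *every* outcome form the "bivariate null set"
feeding the short-form derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SurveyDataset

__all__ = ["BivariateResult", "bivariate_test", "screen_all", "null_items"]

#: Shapiro-Wilk normality check significance level (per group).
NORMALITY_ALPHA = 0.05
#: Cap on the group size entering the normality check.
NORMALITY_N_CAP = 5000


@dataclass(frozen=True)
class BivariateResult:
    shc: str
    outcome: str
    test_used: str  # chi_square | fisher_exact | t_test | mann_whitney | degenerate
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _is_normalish(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.shapiro(x[:NORMALITY_N_CAP]).pvalue
    return p >= NORMALITY_ALPHA


def bivariate_test(
    shc: pd.Series,
    outcome: pd.Series,
    outcome_kind: str,
    shc_name: str = "",
    outcome_name: str = "",
) -> BivariateResult:
    """Test one binary SHC against one outcome with the selection rules above.

    Complete cases only. Degenerate inputs (either variable constant after
    dropping missing values) are flagged with a missing p-value rather than
    raising, so a full screen never aborts.
    """
    shc_name = shc_name or str(shc.name)
    outcome_name = outcome_name or str(outcome.name)
    mask = shc.notna() & outcome.notna()
    x = shc[mask].to_numpy()
    y = outcome[mask].to_numpy()

    def degenerate() -> BivariateResult:
        return BivariateResult(shc_name, outcome_name, "degenerate", np.nan, np.nan)

    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return degenerate()

    if outcome_kind == "binary":
        table = pd.crosstab(x, y).to_numpy()
        if table.shape != (2, 2) or table.sum(axis=1).min() < 2:
            return degenerate()
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        # the chi-square / Fisher switch depends only on expected counts
        if expected.min() < 5:
            res = stats.fisher_exact(table)
            return BivariateResult(
                shc_name, outcome_name, "fisher_exact", float(res.statistic), float(res.pvalue)
            )
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return BivariateResult(shc_name, outcome_name, "chi_square", float(stat), float(p))

    if outcome_kind == "continuous":
        g0, g1 = y[x == 0], y[x == 1]
        if len(g0) < 2 or len(g1) < 2:
            return degenerate()
        if _is_normalish(g0) and _is_normalish(g1):
            stat, p = stats.ttest_ind(g0, g1, equal_var=True)
            return BivariateResult(shc_name, outcome_name, "t_test", float(stat), float(p))
        stat, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        return BivariateResult(shc_name, outcome_name, "mann_whitney", float(stat), float(p))

    raise ValueError(f"unknown outcome kind {outcome_kind!r}")


def screen_all(
    dataset: SurveyDataset,
    shc_names: list[str] | None = None,
    outcome_names: list[str] | None = None,
) -> pd.DataFrame:
    """Run the full SHC-by-outcome screen (30 x 5 = 150 tests by default).

    Outcome kinds come from the dataset's variable specs; ordinal outcomes
    must have been dichotomized upstream (see
    :func:`mminet.data_model.dichotomized_view`). Returns a long-format
    table with columns ``shc, outcome, test_used, statistic, p_value``.
    """
    shc_names = shc_names if shc_names is not None else dataset.shc_names
    outcome_names = outcome_names if outcome_names is not None else dataset.outcome_names
    rows = []
    for shc in shc_names:
        for outcome in outcome_names:
            kind = dataset.spec(outcome).kind
            kind = "binary" if kind == "binary" else "continuous"
            res = bivariate_test(
                dataset.values[shc], dataset.values[outcome], kind,
                shc_name=shc, outcome_name=outcome,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def null_items(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """SHCs whose p-value is >= alpha on *all* outcomes.

    An item with missing pairs (e.g. degenerate tests) is excluded with a
    warning: all-outcome nullity cannot be established for it.
    """
    expected_outcomes = results["outcome"].nunique()
    out: set[str] = set()
    for shc, grp in results.groupby("shc"):
        if grp["p_value"].isna().any() or grp["outcome"].nunique() < expected_outcomes:
            warnings.warn(f"incomplete screen for {shc!r}; excluded from null set",
                          stacklevel=2)
            continue
        if (grp["p_value"] >= alpha).all():
            out.add(str(shc))
    return out
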