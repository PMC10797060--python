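"""Outcome regressions and full-vs-reduced index comparison.

Each health outcome is modelled on an index score (the multimorbidity sum)
plus the fixed covariate set {live in own home, incomplete SCI, sex, age,
days since injury}: multiple linear regression for the continuous
health-status scores, logistic regression for the binary outcomes, with
Wald standard errors and odds ratios OR = exp(beta),
CI = exp(beta +/- 1.96 SE). The comparison fits all five outcome models
for the full and the reduced index on identical complete-case rows and
summarizes sign and significance agreement of the index term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import MMIDefinition, MminetError, SurveyDataset, score_mmi

__all__ = [
    "RegressionResult",
    "IndexComparison",
    "CollinearityError",
    "ConvergenceError",
    "fit_logistic",
    "fit_linear",
    "compare_indices",
    "DEFAULT_COVARIATES",
]

#: Covariates entering every outcome model.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "own_home", "incomplete", "sex", "age", "days_since_injury",
)

_Z95 = 1.96  # Wald multiplier for the reported 95% intervals


class CollinearityError(MminetError):
    """Rank-deficient design matrix."""


class ConvergenceError(MminetError):
    """Maximum-likelihood fit failed (e.g. complete separation)."""


@dataclass
class RegressionResult:
    """One fitted outcome model.

    ``table`` has one row per term with columns ``beta``, ``se``,
    ``p_value`` and, for logistic models, ``or_`` (exp(beta)) with its 95%
    Wald interval.
    """

    outcome: str
    model_kind: str  # "linear" | "logistic"
    table: pd.DataFrame
    n_used: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _design(covariates: pd.DataFrame, index_scores: pd.Series | None) -> pd.DataFrame:
    X = covariates.copy()
    if index_scores is not None:
        X = X.assign(MMI=index_scores)
    return sm.add_constant(X.astype(float), has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the dependent terms: columns whose removal leaves rank unchanged
        dependent = [
            c for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank
        ]
        raise CollinearityError(f"design matrix rank deficient; dependent terms: {dependent}")


def fit_logistic(
    outcome: pd.Series,
    covariates: pd.DataFrame,
    index_scores: pd.Series | None = None,
    outcome_name: str = "",
) -> RegressionResult:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals."""
    outcome_name = outcome_name or str(outcome.name)
    y = outcome.astype(float)
    classes = set(y.dropna().unique())
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise MminetError(f"outcome {outcome_name!r} must be binary with both classes present")
    X = _design(covariates, index_scores)
    _check_rank(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises several separation/convergence types
        raise ConvergenceError(f"logistic fit failed for {outcome_name!r}: {exc}") from exc
    if not fit.mle_retvals.get("converged", True) or not np.all(np.isfinite(fit.bse)):
        raise ConvergenceError(
            f"logistic fit did not converge for {outcome_name!r} "
            f"(possible complete separation; |beta|_max = {np.abs(fit.params).max():.3g})"
        )
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "p_value": fit.pvalues,
            "or_": np.exp(fit.params),
            "ci_low": np.exp(fit.params - _Z95 * fit.bse),
            "ci_high": np.exp(fit.params + _Z95 * fit.bse),
        }
    )
    return RegressionResult(outcome_name, "logistic", table, int(fit.nobs))


def fit_linear(
    outcome: pd.Series,
    covariates: pd.DataFrame,
    index_scores: pd.Series | None = None,
    outcome_name: str = "",
) -> RegressionResult:
    """Ordinary least squares with coefficient t-tests."""
    outcome_name = outcome_name or str(outcome.name)
    X = _design(covariates, index_scores)
    _check_rank(X)
    fit = sm.OLS(outcome.astype(float), X).fit()
    table = pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "p_value": fit.pvalues}
    )
    return RegressionResult(outcome_name, "linear", table, int(fit.nobs))


@dataclass
class IndexComparison:
    """Paired full-index / reduced-index results per outcome.

    ``agreement`` has one row per outcome with the index-term coefficients
    of both arms, whether their signs match, and whether their significance
    calls (p < alpha) match.
    """

    results_full: dict
    results_reduced: dict
    agreement: pd.DataFrame
    alpha: float

    @property
    def all_agree(self) -> bool:
        return bool(self.agreement["sign_match"].all() and self.agreement["sig_match"].all())


def compare_indices(
    dataset: SurveyDataset,
    index_full: MMIDefinition,
    index_reduced: MMIDefinition,
    outcomes: list[str] | None = None,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> IndexComparison:
    """Fit all outcome models for both index variants on identical rows.

    For each outcome the complete-case mask is taken over the outcome, the
    covariates and the union of both indices' items, so both arms use the
    same participants (asserted). Failures for a single outcome are
    recorded without aborting the rest of the comparison.
    """
    outcomes = outcomes if outcomes is not None else dataset.outcome_names
    covariates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    all_items = sorted(set(index_full.item_names) | set(index_reduced.item_names))

    score_full = score_mmi(dataset, index_full)
    score_reduced = score_mmi(dataset, index_reduced)

    results_full: dict = {}
    results_reduced: dict = {}
    rows = []
    for outcome in outcomes:
        kind = dataset.spec(outcome).kind
        fit = fit_logistic if kind == "binary" else fit_linear
        cols = [outcome, *covariates, *all_items]
        mask = dataset.values[cols].notna().all(axis=1)
        y = dataset.values.loc[mask, outcome]
        X = dataset.values.loc[mask, covariates]
        try:
            res_a = fit(y, X, score_full[mask], outcome_name=outcome)
            res_b = fit(y, X, score_reduced[mask], outcome_name=outcome)
        except MminetError as exc:
            warnings.warn(f"comparison failed for {outcome!r}: {exc}", stacklevel=2)
            rows.append(
                {"outcome": outcome, "beta_full": np.nan, "beta_reduced": np.nan,
                 "p_full": np.nan, "p_reduced": np.nan,
                 "sign_match": False, "sig_match": False, "error": str(exc)}
            )
            continue
        assert res_a.n_used == res_b.n_used, "row masks diverged between arms"
        results_full[outcome] = res_a
        results_reduced[outcome] = res_b
        ta, tb = res_a.term("MMI"), res_b.term("MMI")
        rows.append(
            {
                "outcome": outcome,
                "beta_full": ta["beta"],
                "beta_reduced": tb["beta"],
                "p_full": ta["p_value"],
                "p_reduced": tb["p_value"],
                "sign_match": bool(np.sign(ta["beta"]) == np.sign(tb["beta"])),
                "sig_match": bool((ta["p_value"] < alpha) == (tb["p_value"] < alpha)),
                "error": "",
            }
        )
    return IndexComparison(
        results_full=results_full,
        results_reduced=results_reduced,
        agreement=pd.DataFrame(rows).set_index("outcome"),
        alpha=alpha,
    )
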