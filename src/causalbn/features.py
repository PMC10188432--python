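"""Weighted-least-squares screening of candidate drivers of the outcome.

A single WLS regression ``Y_i = a + X_i b + u_i`` of the (raw-scale or
ordinal-coded) outcome on reference-coded indicators of every candidate
variable, used purely as a ranking device: variables are ordered by the
smallest two-sided p-value among their indicator columns and the top-k kept
for structure learning.  This automates the strength-of-association
criterion of variable selection; substantive criteria (literature support,
intervenability) remain judgment calls expressed through the final list the
user passes on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import SurveyTable, complete_cases


@dataclass(frozen=True)
class WLSFit:
    """Coefficients, standard errors and p-values of the screening regression."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    resid_var: float
    n_used: int
    outcome: str
    predictors: tuple[str, ...]
    column_var: dict[str, str]  # design column -> source variable

    def variable_pvalues(self) -> pd.Series:
        """Smallest indicator p-value per predictor variable."""
        out = {}
        for col, var in self.column_var.items():
            p = self.pvalues[col]
            if var not in out or p < out[var]:
                out[var] = p
        return pd.Series({v: out.get(v, np.nan) for v in self.predictors})


def _design(table: SurveyTable, predictors: list[str]) -> tuple[pd.DataFrame, dict[str, str]]:
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(table.n_rows)}
    column_var: dict[str, str] = {}
    for name in predictors:
        s = table.schema(name)
        codes = table.column(name)
        for lvl in range(s.cardinality):
            if lvl == s.reference_level:
                continue
            col = f"{name}[{s.levels[lvl]}]"
            cols[col] = (codes == lvl).astype(float)
            column_var[col] = name
    return pd.DataFrame(cols), column_var


def fit_wls(table: SurveyTable, outcome: str, predictors: list[str]) -> WLSFit:
    """Fit the screening WLS on complete cases of outcome + predictors.

    The outcome enters on its stored scale (level codes for a coded table);
    categorical predictors expand to reference-coded indicators using each
    schema's reference level; row weights come from the table.  Raises on a
    rank-deficient design (reporting the aliased columns) and on zero total
    weight.
    """
    sub = complete_cases(table, [outcome] + list(predictors))
    if sub.n_rows == 0:
        raise ValueError("no complete cases")
    if sub.weights.sum() <= 0:
        raise ValueError("total weight is zero")
    X, column_var = _design(sub, list(predictors))
    y = sub.column(outcome).astype(float)

    wX = X.to_numpy() * np.sqrt(sub.weights)[:, None]
    rank = np.linalg.matrix_rank(wX)
    if rank < X.shape[1]:
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(wX[:, kept + [j]]) == len(kept):
                aliased.append(X.columns[j])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    res = sm.WLS(y, X, weights=sub.weights).fit()
    return WLSFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        resid_var=float(res.scale),
        n_used=sub.n_rows,
        outcome=outcome,
        predictors=tuple(predictors),
        column_var=column_var,
    )


def rank_features(fit: WLSFit, k: int) -> list[str]:
    """Top-``k`` predictors by smallest indicator p-value.

    Ties break deterministically by the predictor order of the fit (which
    follows schema order when built through :func:`fit_wls`).
    """
    if k > len(fit.predictors):
        raise ValueError("k exceeds the number of predictors")
    order = {v: i for i, v in enumerate(fit.predictors)}
    pvals = fit.variable_pvalues()
    ranked = sorted(fit.predictors, key=lambda v: (pvals[v], order[v]))
    return ranked[:k]
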