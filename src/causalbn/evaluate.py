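"""Structure-recovery metrics, DAG counting, and the correlational baseline.

V-structure precision/recall/F1 and the CPDAG structural Hamming distance
quantify how well a learned graph matches a known truth; the labelled-DAG
count makes the super-exponential size of the search space concrete; and a
multinomial-logit model of the outcome on the same discretized table plays
the role of the conventional correlational analysis against which the causal
results are contrasted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import SurveyTable, complete_cases
from .inference import InterventionResult
from .pc import CPDAG, cpdag_of_dag

logger = logging.getLogger(__name__)


# -- structure recovery ---------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    """V-structure and skeleton agreement between a learned and a true graph."""

    v_precision: float
    v_recall: float
    v_f1: float
    shd: int
    skeleton_precision: float
    skeleton_recall: float


def _as_cpdag(g: nx.DiGraph | CPDAG) -> CPDAG:
    return g if isinstance(g, CPDAG) else cpdag_of_dag(g)


def _ratio(inter: int, denom: int, other_empty: bool) -> float:
    if denom == 0:
        return 1.0 if other_empty else 0.0
    return inter / denom


def v_structure_metrics(learned: nx.DiGraph | CPDAG, truth: nx.DiGraph) -> RecoveryMetrics:
    """Compare unshielded colliders and skeletons of ``learned`` vs ``truth``.

    Precision/recall follow the convention 0/0 := 1 when the other side is
    also empty, 0 otherwise.  SHD is computed between CPDAGs: each node pair
    whose status (absent / undirected / either direction) differs counts 1.
    """
    lc = _as_cpdag(learned)
    tc = _as_cpdag(truth)
    if set(lc.nodes) != set(tc.nodes):
        raise ValueError("node sets differ")
    lv, tv = lc.colliders(), tc.colliders()
    inter = len(lv & tv)
    precision = _ratio(inter, len(lv), not tv)
    recall = _ratio(inter, len(tv), not lv)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0

    def status(c: CPDAG, u: str, v: str) -> str:
        if (u, v) in c.directed:
            return ">"
        if (v, u) in c.directed:
            return "<"
        if tuple(sorted((u, v))) in c.undirected:
            return "-"
        return "."

    shd = sum(
        status(lc, u, v) != status(tc, u, v)
        for u, v in combinations(sorted(lc.nodes), 2)
    )
    ls, ts = lc.skeleton(), tc.skeleton()
    sk_inter = len(ls & ts)
    return RecoveryMetrics(
        v_precision=precision,
        v_recall=recall,
        v_f1=f1,
        shd=int(shd),
        skeleton_precision=_ratio(sk_inter, len(ls), not ts),
        skeleton_recall=_ratio(sk_inter, len(ts), not ls),
    )


@lru_cache(maxsize=None)
def count_dags(n: int) -> int:
    """Exact number of labelled DAGs on ``n`` nodes (Robinson's recurrence).

    ``a(n) = Σ_{k=1..n} (−1)^{k+1} binom(n,k) 2^{k(n−k)} a(n−k)``, ``a(0)=1``,
    evaluated in arbitrary-precision integers.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 1
    return sum(
        (-1) ** (k + 1) * math.comb(n, k) * 2 ** (k * (n - k)) * count_dags(n - k)
        for k in range(1, n + 1)
    )


# -- multinomial-logit baseline ------------------------------------------


@dataclass(frozen=True)
class BaselineFit:
    """Multinomial-logit coefficients, Wald tests and bookkeeping.

    ``coefficients``/``std_errors``/``p_values`` are DataFrames indexed by
    design column with one column per non-reference outcome level.
    """

    coefficients: pd.DataFrame
    std_errors: pd.DataFrame
    p_values: pd.DataFrame
    outcome: str
    reference_level: str
    predictors: tuple[str, ...]
    column_var: dict[str, str]
    separation_flags: tuple[str, ...]
    converged: bool
    n_used: int


def multinomial_logit_fit(
    table: SurveyTable,
    outcome: str,
    predictors: list[str],
) -> BaselineFit:
    """ML multinomial logit of the outcome on reference-coded predictors.

    The outcome's schema reference level is the baseline category; Wald z
    tests give per-coefficient two-sided p-values.  Coefficients drifting to
    extreme magnitudes (|b| > 15) or with non-finite standard errors are
    flagged as separation-affected.
    """
    sub = complete_cases(table, [outcome] + list(predictors))
    if sub.n_rows == 0:
        raise ValueError("no complete cases")
    ys = sub.schema(outcome)
    observed = sorted(set(np.unique(sub.column(outcome))))
    if ys.reference_level not in observed:
        raise ValueError(f"reference level of {outcome!r} not observed")
    if len(observed) < 2:
        raise ValueError(f"outcome {outcome!r} is constant")
    # recode so the reference level becomes category 0 (statsmodels baseline)
    remap = [ys.reference_level] + [l for l in observed if l != ys.reference_level]
    inv = np.zeros(ys.cardinality, dtype=int)
    for new, old in enumerate(remap):
        inv[old] = new
    y = inv[sub.column(outcome)]
    from .features import _design

    X, column_var = _design(sub, list(predictors))
    model = sm.MNLogit(y, X)
    level_names = [ys.levels[j] for j in remap[1:]]

    def _extract(res):
        coefs = pd.DataFrame(np.asarray(res.params), index=X.columns, columns=level_names)
        bse = pd.DataFrame(np.asarray(res.bse), index=X.columns, columns=level_names)
        pvals = pd.DataFrame(np.asarray(res.pvalues), index=X.columns, columns=level_names)
        return coefs, bse, pvals

    try:
        res = model.fit(method="newton", maxiter=200, disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:  # singular Hessian under separation: refit quasi-Newton
        res = model.fit(method="bfgs", maxiter=500, disp=0)
        converged = False
    try:
        coefs, bse, pvals = _extract(res)
    except Exception:  # covariance unavailable (perfect separation)
        converged = False
        coefs = pd.DataFrame(np.asarray(res.params), index=X.columns, columns=level_names)
        bse = coefs * np.nan
        pvals = coefs * 0 + 1.0
    flags = sorted(
        set(
            coefs.index[(coefs.abs() > 15).any(axis=1)]
        )
        | set(coefs.index[~np.isfinite(bse).all(axis=1)])
    )
    if flags:
        logger.warning("possible separation in columns: %s", flags)
    return BaselineFit(
        coefficients=coefs,
        std_errors=bse,
        p_values=pvals,
        outcome=outcome,
        reference_level=ys.levels[ys.reference_level],
        predictors=tuple(predictors),
        column_var=column_var,
        separation_flags=tuple(flags),
        converged=converged,
        n_used=sub.n_rows,
    )


def significant_correlates(fit: BaselineFit, alpha: float = 0.05) -> set[str]:
    """Variables with at least one logit p-value below ``alpha`` (unadjusted).

    This is the conventional any-significant-coefficient screen: a variable
    counts as a significant correlate if any of its indicator columns is
    significant for any outcome contrast.
    """
    out = set()
    for col, var in fit.column_var.items():
        if (fit.p_values.loc[col] < alpha).any():
            out.add(var)
    return out


def compare_reports(
    bn_results: list[InterventionResult],
    baseline: BaselineFit,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-variable cross-tabulation of causal vs correlational significance.

    Returns a table with one row per variable in the shared universe and
    counts of: significant correlates, significant causal factors, and the
    two discordant classes.
    """
    causal = {r.query.evidence for r in bn_results if r.significant}
    correlates = significant_correlates(baseline)
    universe = sorted(
        {r.query.evidence for r in bn_results} | set(baseline.predictors)
    )
    rows = []
    for v in universe:
        c, r = v in causal, v in correlates
        rows.append(
            {
                "variable": v,
                "significant_correlate": r,
                "significant_causal": c,
                "causal_not_correlate": c and not r,
                "correlate_not_causal": r and not c,
            }
        )
    df = pd.DataFrame(rows).set_index("variable")
    counts = {
        "significant_correlates": int(df["significant_correlate"].sum()),
        "significant_causal": int(df["significant_causal"].sum()),
        "causal_not_correlate": int(df["causal_not_correlate"].sum()),
        "correlate_not_causal": int(df["correlate_not_causal"].sum()),
    }
    return df, counts
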