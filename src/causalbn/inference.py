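"""Parameter fitting, graph-surgery inference, and interventional odds ratios.

Interventional semantics follow Pearl's truncated factorization: to evaluate
``P(target | do(X = x))`` the incoming edges of ``X`` are deleted, ``X`` is
clamped to ``x``, and the target marginal is computed by exact variable
elimination over the ancestors of the target in the surgered graph.  The
interventional odds ratio of a query contrasts the target's high-vs-low odds
under two forced settings of the evidence variable:

    OR = [P(Y=hi | do(X=to)) / P(Y=lo | do(X=to))]
       / [P(Y=hi | do(X=from)) / P(Y=lo | do(X=from))]

Uncertainty comes from a nonparametric bootstrap with the structure held
fixed: rows are resampled (with replacement, using sampling weights as
resampling probabilities when present), CPTs are refit and the OR recomputed
per replicate; the 95% CI is the percentile interval and the p-value the
two-sided bootstrap tail probability of the log-OR against 0.  Structure
uncertainty is deliberately not propagated into these intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .bn import BayesianNetwork
from .data import MISSING, SurveyTable, VariableSchema

logger = logging.getLogger(__name__)

__all__ = [
    "BayesianNetwork",
    "InterventionQuery",
    "InterventionResult",
    "ScanReport",
    "fit_cpts",
    "do_distribution",
    "interventional_or",
    "bootstrap_result",
    "causal_factor_scan",
]


@dataclass(frozen=True)
class InterventionQuery:
    """A (evidence level-shift -> outcome level-contrast) interventional query.

    Levels are given as labels; ``contrast`` is the (low, high) outcome pair
    whose odds are compared.
    """

    evidence: str
    from_level: str
    to_level: str
    outcome: str
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        if self.from_level == self.to_level:
            raise ValueError("from_level and to_level must differ")
        if self.evidence == self.outcome:
            raise ValueError("evidence and outcome must differ")
        lo, hi = self.contrast
        if lo == hi:
            raise ValueError("outcome contrast levels must differ")

    def swapped(self) -> "InterventionQuery":
        return InterventionQuery(
            self.evidence, self.to_level, self.from_level, self.outcome, self.contrast
        )


@dataclass(frozen=True)
class InterventionResult:
    """Interventional OR with bootstrap CI, p-value and significance flag."""

    query: InterventionQuery
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    dist_from: np.ndarray
    dist_to: np.ndarray
    n_boot: int


@dataclass(frozen=True)
class ScanReport:
    """Causal-factor scan: one result per (ancestor, level shift, contrast)."""

    target: str
    results: tuple[InterventionResult, ...]
    non_causal: tuple[str, ...]

    def significant_factors(self) -> set[str]:
        return {r.query.evidence for r in self.results if r.significant}


# -- CPT estimation -------------------------------------------------------


def fit_cpts(
    table: SurveyTable,
    dag: nx.DiGraph,
    pseudo_count: float = 1.0,
) -> BayesianNetwork:
    """Maximum-likelihood CPTs with additive (Laplace) smoothing.

    Each conditional probability is ``(count + pseudo_count) /
    (config_count + pseudo_count * levels)``; with ``pseudo_count > 0``
    every probability is strictly positive, which keeps downstream odds
    ratios finite.  A parent configuration never observed yields the uniform
    distribution.
    """
    if set(dag.nodes) != set(table.names):
        raise ValueError("DAG nodes do not match table variables")
    if (table.codes == MISSING).any():
        raise ValueError("fit_cpts requires a complete-case table")
    cpts: dict[str, np.ndarray] = {}
    parents = {v: tuple(sorted(dag.predecessors(v))) for v in dag.nodes}
    for v in dag.nodes:
        counts = _family_counts(table, v, parents[v])
        cpts[v] = _smooth(counts, pseudo_count)
    return BayesianNetwork(dag, table.schemas, cpts, parents)


def _family_counts(table: SurveyTable, child: str, parents: Sequence[str]) -> np.ndarray:
    cards = [table.schema(p).cardinality for p in parents] + [
        table.schema(child).cardinality
    ]
    idx = np.zeros(table.n_rows, dtype=np.int64)
    for name, card in zip(list(parents) + [child], cards):
        idx = idx * card + table.column(name)
    return np.bincount(idx, minlength=int(np.prod(cards))).reshape(cards).astype(float)


def _smooth(counts: np.ndarray, pseudo_count: float) -> np.ndarray:
    k = counts.shape[-1]
    num = counts + pseudo_count
    den = counts.sum(axis=-1, keepdims=True) + pseudo_count * k
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0 / k)
    return probs


# -- batched variable elimination ----------------------------------------
# A factor is (vars, array) with array shape (B, *cards_of_vars): axis 0 is a
# bootstrap-replicate batch (B = 1 for plain queries).


def _fmul(f1: tuple, f2: tuple, card: Mapping[str, int]) -> tuple:
    v1, a1 = f1
    v2, a2 = f2
    out_vars = list(v1) + [v for v in v2 if v not in v1]
    sh1 = [a1.shape[0]] + [card[v] if v in v1 else 1 for v in out_vars]
    sh2 = [a2.shape[0]] + [card[v] if v in v2 else 1 for v in out_vars]
    b1 = np.moveaxis(
        a1.reshape(a1.shape + (1,) * (len(out_vars) - len(v1))),
        range(1, len(v1) + 1),
        [1 + out_vars.index(v) for v in v1],
    )
    b2 = np.moveaxis(
        a2.reshape(a2.shape + (1,) * (len(out_vars) - len(v2))),
        range(1, len(v2) + 1),
        [1 + out_vars.index(v) for v in v2],
    )
    return tuple(out_vars), b1 * b2


def _fsum(f: tuple, var: str) -> tuple:
    fvars, arr = f
    ax = 1 + fvars.index(var)
    return tuple(v for v in fvars if v != var), arr.sum(axis=ax)


def _eliminate(
    factors: list[tuple], keep: str, card: Mapping[str, int]
) -> np.ndarray:
    """Sum out every variable except ``keep``; greedy smallest-factor order."""
    factors = list(factors)
    while True:
        elim_vars = {v for fv, _ in factors for v in fv} - {keep}
        if not elim_vars:
            break
        # pick the variable whose elimination builds the smallest product factor
        best_var, best_size = None, None
        for v in sorted(elim_vars):
            scope = {w for fv, _ in factors if v in fv for w in fv}
            size = float(np.prod([card[w] for w in scope]))
            if best_size is None or size < best_size:
                best_var, best_size = v, size
        group = [f for f in factors if best_var in f[0]]
        rest = [f for f in factors if best_var not in f[0]]
        prod = group[0]
        for f in group[1:]:
            prod = _fmul(prod, f, card)
        factors = rest + [_fsum(prod, best_var)]
    out = factors[0]
    for f in factors[1:]:
        out = _fmul(out, f, card)
    arr = out[1]
    if out[0] != (keep,):
        raise AssertionError("elimination left unexpected variables")
    return arr


def _surgered_factors(
    bn: BayesianNetwork,
    do: Mapping[str, int],
    target: str,
    cpt_override: Mapping[str, np.ndarray] | None = None,
    batch: int = 1,
) -> tuple[list[tuple], Mapping[str, int]]:
    """Factor list for P(target | do(...)) restricted to the relevant subgraph."""
    surgered = bn.dag.copy()
    for x in do:
        surgered.remove_edges_from(list(surgered.in_edges(x)))
    relevant = nx.ancestors(surgered, target) | {target}
    card = {v: bn.card(v) for v in bn.dag.nodes}
    factors: list[tuple] = []
    for v in relevant:
        if v in do:
            continue  # clamped; appears only through children's CPTs
        pa = bn.parents[v]
        arr = np.asarray(
            (cpt_override or {}).get(v, bn.cpts[v]), dtype=float
        )
        if arr.ndim == len(pa) + 1:  # add batch axis
            arr = np.broadcast_to(arr, (batch,) + arr.shape)
        scope = list(pa) + [v]
        # clamp any intervened variable appearing in this CPT's scope
        for x, lvl in do.items():
            if x in scope:
                ax = 1 + scope.index(x)
                arr = np.take(arr, lvl, axis=ax)
                scope = [s for s in scope if s != x]
        factors.append((tuple(scope), arr))
    return factors, card


def do_distribution(
    bn: BayesianNetwork,
    do: Mapping[str, str | int],
    target: str,
) -> np.ndarray:
    """Post-intervention marginal of ``target`` under ``do`` (truncated
    factorization via exact variable elimination)."""
    if target in do:
        raise ValueError("target cannot be intervened on")
    levels = {x: _level_code(bn.schema(x), lvl) for x, lvl in do.items()}
    factors, card = _surgered_factors(bn, levels, target)
    if not factors:
        raise AssertionError("no factors for target")
    arr = _eliminate(factors, target, card)[0]
    total = arr.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate post-intervention distribution")
    return arr / total


def _level_code(schema: VariableSchema, level: str | int) -> int:
    if isinstance(level, (int, np.integer)):
        if not 0 <= int(level) < schema.cardinality:
            raise KeyError(f"level code {level} out of range for {schema.name!r}")
        return int(level)
    return schema.code_of(level)


def interventional_or(bn: BayesianNetwork, query: InterventionQuery) -> float:
    """Point interventional odds ratio of ``query`` under ``bn``."""
    y = bn.schema(query.outcome)
    lo, hi = (_level_code(y, l) for l in query.contrast)
    d_to = do_distribution(bn, {query.evidence: query.to_level}, query.outcome)
    d_from = do_distribution(bn, {query.evidence: query.from_level}, query.outcome)
    for d in (d_to, d_from):
        if d[lo] <= 0 or d[hi] <= 0:
            raise ValueError("zero probability in an odds denominator; use smoothing")
    return float((d_to[hi] / d_to[lo]) / (d_from[hi] / d_from[lo]))


# -- bootstrap ------------------------------------------------------------


def bootstrap_result(
    table: SurveyTable,
    dag: nx.DiGraph,
    query: InterventionQuery,
    B: int = 1000,
    seed: int = 0,
    pseudo_count: float = 1.0,
) -> InterventionResult:
    """Nonparametric bootstrap OR with percentile 95% CI and two-sided p.

    The DAG is held fixed; each replicate resamples rows with replacement
    (weights, if non-uniform, act as resampling probabilities), refits the
    CPTs touched by the query, and recomputes the OR.  Deterministic given
    ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    bn = fit_cpts(table, dag, pseudo_count)
    point = interventional_or(bn, query)
    x = query.evidence
    levels = {
        "to": _level_code(bn.schema(x), query.to_level),
        "from": _level_code(bn.schema(x), query.from_level),
    }
    d_from = do_distribution(bn, {x: query.from_level}, query.outcome)
    d_to = do_distribution(bn, {x: query.to_level}, query.outcome)

    surgered = dag.copy()
    surgered.remove_edges_from(list(surgered.in_edges(x)))
    relevant = (nx.ancestors(surgered, query.outcome) | {query.outcome}) - {x}
    parents = {v: bn.parents[v] for v in relevant}

    rng = np.random.default_rng(seed)
    n = table.n_rows
    probs = None
    if not table.has_uniform_weights:
        probs = table.weights / table.weights.sum()
    idx = rng.choice(n, size=(B, n), replace=True, p=probs)

    # batched refit of the relevant families
    overrides: dict[str, np.ndarray] = {}
    for v in relevant:
        pa = parents[v]
        cards = [table.schema(p).cardinality for p in pa] + [
            table.schema(v).cardinality
        ]
        flat = np.zeros(n, dtype=np.int64)
        for name, c in zip(list(pa) + [v], cards):
            flat = flat * c + table.column(name)
        size = int(np.prod(cards))
        counts = np.zeros((B, size))
        for b in range(B):
            counts[b] = np.bincount(flat[idx[b]], minlength=size)
        overrides[v] = _smooth(counts.reshape([B] + cards), pseudo_count)

    card = {v: bn.card(v) for v in dag.nodes}
    y = bn.schema(query.outcome)
    lo, hi = (_level_code(y, l) for l in query.contrast)
    ors = np.empty(B)
    dists = {}
    for tag, lvl in levels.items():
        factors, _ = _surgered_factors(bn, {x: lvl}, query.outcome, overrides, batch=B)
        arr = _eliminate(factors, query.outcome, card)
        dists[tag] = arr / arr.sum(axis=1, keepdims=True)
    ors = (dists["to"][:, hi] / dists["to"][:, lo]) / (
        dists["from"][:, hi] / dists["from"][:, lo]
    )
    log_or = np.log(ors)
    ci_low, ci_high = np.percentile(ors, [2.5, 97.5])
    p_lo = (1 + int((log_or <= 0).sum())) / (B + 1)
    p_hi = (1 + int((log_or >= 0).sum())) / (B + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return InterventionResult(
        query=query,
        odds_ratio=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        significant=bool(p < 0.05),
        dist_from=d_from,
        dist_to=d_to,
        n_boot=B,
    )


def causal_factor_scan(
    table: SurveyTable,
    dag: nx.DiGraph,
    target: str,
    B: int = 1000,
    seed: int = 0,
    contrasts: Sequence[tuple[str, str]] | None = None,
    pseudo_count: float = 1.0,
) -> ScanReport:
    """Interventional ORs for every ancestor (causal factor) of ``target``.

    For each ancestor, one query per shift from its reference level to each
    other level, per outcome contrast.  Default contrasts pit each lower
    outcome level against the top level (e.g. Low-vs-High and
    Moderate-vs-High for a 3-level outcome).  Non-ancestors are reported as
    non-causal.  Any variable — not only the survey outcome — may serve as
    the target, which is how causes-of-cause questions are answered without
    refitting.
    """
    if target not in dag.nodes:
        raise KeyError(f"{target!r} not in the DAG")
    y = table.schema(target)
    if contrasts is None:
        contrasts = [(lvl, y.levels[-1]) for lvl in y.levels[:-1]]
    ancestors = sorted(nx.ancestors(dag, target))
    non_causal = tuple(
        v for v in sorted(dag.nodes) if v != target and v not in ancestors
    )
    ss = np.random.SeedSequence(seed)
    results = []
    for a in ancestors:
        sa = table.schema(a)
        ref = sa.levels[sa.reference_level]
        for to in sa.levels:
            if to == ref:
                continue
            for contrast in contrasts:
                sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                q = InterventionQuery(a, ref, to, target, tuple(contrast))
                results.append(
                    bootstrap_result(table, dag, q, B=B, seed=sub_seed, pseudo_count=pseudo_count)
                )
    return ScanReport(target=target, results=tuple(results), non_causal=non_causal)
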