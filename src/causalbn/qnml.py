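"""Quotient normalized maximum likelihood (qNML) structure score.

The qNML local score of a family (child with parent set) is the difference of
two multinomial NML codelengths: the joint contingency table of
``{child} ∪ parents`` flattened to a single multinomial, minus the flattened
table of the parents alone.  The NML codelength of a count vector with total
``n`` over ``K`` categories is the maximized log-likelihood minus the regret
``REG(n, K) = ln C(n, K)``, where ``C(n, K)`` is the multinomial parametric
complexity.  ``C`` is computed exactly (no asymptotic approximation) via the
Kontkanen-Myllymäki linear recurrence, in log space so large ``K`` cannot
overflow.

Zero-count cells of a flattened table are dropped before scoring, so the
effective alphabet is the observed support.  This makes the score invariant
to structurally empty configurations (e.g. an all-constant parent adds
nothing), keeps exact score equivalence across Markov-equivalent DAGs, and
coincides with the full-cell-set definition whenever every configuration is
observed — the usual situation at survey scale with at most 3 levels.

The network score is the sum of local scores over nodes (decomposable), with
a per-family cache so search algorithms only pay for new families.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .data import MISSING, SurveyTable

logger = logging.getLogger(__name__)


class RegretTable:
    """Memoized multinomial NML regrets ``REG(n, K) = ln C(n, K)``.

    ``C(n, 1) = 1``; ``C(n, 2)`` is the exact binomial sum
    ``Σ_h binom(n, h) (h/n)^h ((n-h)/n)^(n-h)``; and for ``K >= 3`` the
    linear recurrence ``C(n, K) = C(n, K-1) + n/(K-2) · C(n, K-2)`` extends
    the column, evaluated with log-sum-exp.
    """

    def __init__(self) -> None:
        self._rows: dict[int, list[float]] = {}

    def __call__(self, n: int, K: int) -> float:
        if K < 1:
            raise ValueError("K must be >= 1")
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0 or K == 1:
            return 0.0
        row = self._rows.setdefault(n, [0.0, self._log_c2(n)])
        while len(row) < K:
            k = len(row) + 1  # extending to alphabet size k
            row.append(
                np.logaddexp(row[-1], math.log(n / (k - 2)) + row[-2])
            )
        return row[K - 1]

    @staticmethod
    def _log_c2(n: int) -> float:
        h = np.arange(n + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(h > 0, h * np.log(h / n), 0.0)
            t2 = np.where(n - h > 0, (n - h) * np.log((n - h) / n), 0.0)
        terms = gammaln(n + 1) - gammaln(h + 1) - gammaln(n - h + 1) + t1 + t2
        return float(logsumexp(terms))


#: Shared module-level regret table.
REGRET = RegretTable()


def multinomial_regret(n: int, K: int) -> float:
    """Exact log parametric complexity ``ln C(n, K)`` of an n-sample,
    K-category multinomial."""
    return REGRET(n, K)


def log_nml(counts: Iterable[int]) -> float:
    """NML codelength of a multinomial count vector (natural log scale).

    ``Σ_k c_k ln(c_k / n) − REG(n, K)`` with ``0·ln 0 := 0``, ``K`` the
    length of the vector and ``n`` its total.
    """
    c = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    if c.ndim != 1 or c.size < 1:
        raise ValueError("counts must be a non-empty 1-D vector")
    if (c < 0).any():
        raise ValueError("negative count")
    n = int(c.sum())
    if n == 0:
        return 0.0
    pos = c[c > 0].astype(float)
    ll = float(np.sum(pos * np.log(pos / n)))
    return ll - multinomial_regret(n, int(c.size))


# -- scoring from coded arrays -------------------------------------------


def _flat_counts(codes: np.ndarray, cols: list) -> np.ndarray:
    """Nonzero joint counts of the named columns of a coded matrix."""
    if not cols:
        return np.array([codes.shape[0]], dtype=np.int64)
    idx = np.zeros(codes.shape[0], dtype=np.int64)
    for name, card, col in cols:
        idx = idx * card + col
    total = 1
    for _, card, _ in cols:
        total *= card
    counts = np.bincount(idx, minlength=total)
    return counts[counts > 0]


class ScoreCache:
    """Per-family qNML score cache bound to one coded dataset.

    Cache hits are bitwise-identical to fresh recomputation: the cache stores
    the computed float keyed by ``(child, frozenset(parents))``.
    """

    def __init__(self, table: SurveyTable) -> None:
        if (table.codes == MISSING).any():
            raise ValueError("scoring requires a complete-case table")
        if not table.has_uniform_weights:
            logger.info(
                "qNML scoring ignores non-uniform sampling weights: the score "
                "assumes i.i.d. multinomial counts"
            )
        self.table = table
        self._cols = {
            s.name: (s.name, s.cardinality, table.column(s.name).astype(np.int64))
            for s in table.schemas
        }
        self._cache: dict[tuple[str, frozenset], float] = {}

    def family_score(self, child: str, parents: Iterable[str]) -> float:
        key = (child, frozenset(parents))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        pa = sorted(key[1])
        joint = _flat_counts(self.table.codes, [self._cols[child]] + [self._cols[p] for p in pa])
        score = log_nml(joint)
        if pa:
            score -= log_nml(_flat_counts(self.table.codes, [self._cols[p] for p in pa]))
        self._cache[key] = score
        return score

    def network_score(self, dag: nx.DiGraph) -> float:
        return sum(self.family_score(v, dag.predecessors(v)) for v in dag.nodes)

    def __len__(self) -> int:
        return len(self._cache)


def family_score(table: SurveyTable, child: str, parents: Iterable[str]) -> float:
    """qNML local score of ``child`` given ``parents`` on a complete table."""
    parents = list(parents)
    if child in parents:
        raise ValueError("child cannot be its own parent")
    return ScoreCache(table).family_score(child, parents)


def network_score(table: SurveyTable, dag: nx.DiGraph, cache: ScoreCache | None = None) -> float:
    """Decomposable network score: sum of family scores over all nodes."""
    if cache is None:
        cache = ScoreCache(table)
    return cache.network_score(dag)
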