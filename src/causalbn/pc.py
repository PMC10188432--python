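"""Conditional-independence testing and the PC algorithm.

The G² likelihood-ratio test drives a stable-PC skeleton search (neighbour
sets frozen per depth, so the output does not depend on column order),
followed by unshielded-collider orientation from the recorded separating
sets and Meek's closure rules.  The result is a CPDAG used to initialise the
score-based structure search; expert knowledge enters as forbidden/required
edges and ordered tiers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import chi2

from .data import MISSING, SurveyTable, VariableSchema

logger = logging.getLogger(__name__)


# -- expert constraints ---------------------------------------------------


@dataclass(frozen=True)
class ConstraintSet:
    """Forbidden/required directed edges plus optional ordered tiers.

    Tiers are ordered variable groups: an edge may never point from a later
    tier into an earlier one.  Variables absent from all tiers are
    unconstrained by the tier rule.
    """

    forbidden: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    required: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    tiers: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "forbidden", frozenset(map(tuple, self.forbidden)))
        object.__setattr__(self, "required", frozenset(map(tuple, self.required)))
        object.__setattr__(self, "tiers", tuple(tuple(t) for t in self.tiers))
        bad = self.required & self.all_forbidden(self.required)
        if bad:
            raise ValueError(f"edges both required and forbidden: {sorted(bad)}")

    def _tier_of(self, v: str) -> int | None:
        for i, tier in enumerate(self.tiers):
            if v in tier:
                return i
        return None

    def is_forbidden(self, u: str, v: str) -> bool:
        if (u, v) in self.forbidden:
            return True
        tu, tv = self._tier_of(u), self._tier_of(v)
        return tu is not None and tv is not None and tu > tv

    def all_forbidden(self, edges: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
        return {e for e in edges if self.is_forbidden(*e)}

    @classmethod
    def from_json(cls, path: str | Path) -> "ConstraintSet":
        doc = json.loads(Path(path).read_text())
        return cls(
            forbidden=frozenset(tuple(e) for e in doc.get("forbidden", [])),
            required=frozenset(tuple(e) for e in doc.get("required", [])),
            tiers=tuple(tuple(t) for t in doc.get("tiers", [])),
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "forbidden": sorted(map(list, self.forbidden)),
            "required": sorted(map(list, self.required)),
            "tiers": [list(t) for t in self.tiers],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def demographics_prior(schemas: Sequence[VariableSchema]) -> ConstraintSet:
    """Forbid edges into demographic variables from non-demographic ones.

    Encodes the common-sense prior that survey beliefs or behaviours cannot
    cause a respondent's demographics (e.g. worry about infection cannot
    cause race); demographic-to-demographic edges stay unconstrained.
    """
    demo = tuple(s.name for s in schemas if s.category == "demographics")
    rest = tuple(s.name for s in schemas if s.category != "demographics")
    if not demo or not rest:
        return ConstraintSet()
    return ConstraintSet(tiers=(demo, rest))


# -- G^2 conditional-independence test -----------------------------------


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one G² conditional-independence test."""

    statistic: float
    df: int
    p_value: float
    n_eff: float
    cond: tuple[str, ...]

    @property
    def independent(self) -> bool:
        """Convenience flag at the conventional 5% level."""
        return self.p_value > 0.05


def g2_test(table: SurveyTable, x: str, y: str, cond: Sequence[str] = ()) -> CITestResult:
    """G² test of ``x ⫫ y | cond`` on weighted categorical data.

    The statistic is ``2 Σ O ln(O/E)`` over the contingency table stratified
    by the conditioning variables, with degrees of freedom
    ``Σ_strata (|x|−1)(|y|−1)`` over strata with positive total (forced to at
    least 1).  With non-uniform weights, weighted cell counts are rescaled to
    the effective sample size ``(Σw)² / Σw²``.
    """
    cond = tuple(cond)
    if x == y or x in cond or y in cond:
        raise ValueError("x, y and conditioning set must be distinct")
    cols = [x, y, *cond]
    idx = [table.column_index(c) for c in cols]
    keep = (table.codes[:, idx] != MISSING).all(axis=1)
    codes = table.codes[keep][:, idx]
    w = table.weights[keep]
    if codes.shape[0] == 0:
        raise ValueError("no complete cases for the requested test")

    cards = [table.schema(c).cardinality for c in cols]
    rx, ry = cards[0], cards[1]
    n_strata = int(np.prod(cards[2:])) if cond else 1
    flat = np.zeros(codes.shape[0], dtype=np.int64)
    for j in range(2, len(cols)):
        flat = flat * cards[j] + codes[:, j]
    cell = (flat * rx + codes[:, 0]) * ry + codes[:, 1]

    if table.has_uniform_weights:
        counts = np.bincount(cell, minlength=n_strata * rx * ry).astype(float)
        n_eff = float(codes.shape[0])
    else:
        counts = np.bincount(cell, weights=w, minlength=n_strata * rx * ry)
        sw = float(w.sum())
        n_eff = sw * sw / float((w * w).sum())
        counts *= n_eff / sw

    obs = counts.reshape(n_strata, rx, ry)
    tot = obs.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expect = obs.sum(axis=2, keepdims=True) * obs.sum(axis=1, keepdims=True) / tot
        ratio = np.where(obs > 0, obs / np.where(expect > 0, expect, 1.0), 1.0)
        g2 = 2.0 * float(np.sum(np.where(obs > 0, obs * np.log(ratio), 0.0)))
    df = int((tot[:, 0, 0] > 0).sum()) * (rx - 1) * (ry - 1)
    df = max(df, 1)
    p = float(chi2.sf(g2, df))
    return CITestResult(statistic=max(g2, 0.0), df=df, p_value=p, n_eff=n_eff, cond=cond)


# -- CPDAG ----------------------------------------------------------------


@dataclass(frozen=True)
class CPDAG:
    """Partially directed graph: directed (compelled) and undirected edges.

    Undirected edges are stored once as sorted tuples.
    """

    nodes: tuple[str, ...]
    directed: frozenset[tuple[str, str]]
    undirected: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        und = frozenset(tuple(sorted(e)) for e in self.undirected)
        object.__setattr__(self, "undirected", und)
        object.__setattr__(self, "directed", frozenset(map(tuple, self.directed)))
        object.__setattr__(self, "nodes", tuple(self.nodes))
        overlap = {tuple(sorted(e)) for e in self.directed} & und
        if overlap:
            raise ValueError(f"edges both directed and undirected: {sorted(overlap)}")
        g = nx.DiGraph(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed part contains a cycle")

    def skeleton(self) -> frozenset[tuple[str, str]]:
        return frozenset({tuple(sorted(e)) for e in self.directed} | self.undirected)

    def adjacent(self, u: str, v: str) -> bool:
        return tuple(sorted((u, v))) in self.skeleton()

    def colliders(self) -> frozenset[tuple[str, str, str]]:
        """Unshielded colliders as (a, b, c) with a < b, a→c←b, a,b non-adjacent."""
        out = set()
        parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.directed:
            parents[v].add(u)
        for c, ps in parents.items():
            for a, b in combinations(sorted(ps), 2):
                if not self.adjacent(a, b):
                    out.add((a, b, c))
        return frozenset(out)

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)


def _has_directed_path(directed: set[tuple[str, str]], src: str, dst: str) -> bool:
    children: dict[str, list[str]] = {}
    for a, b in directed:
        children.setdefault(a, []).append(b)
    stack, seen = [src], {src}
    while stack:
        node = stack.pop()
        if node == dst:
            return True
        for nxt in children.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _meek_closure(
    nodes: Iterable[str],
    directed: set[tuple[str, str]],
    undirected: set[tuple[str, str]],
    constraints: ConstraintSet | None = None,
) -> None:
    """Apply Meek's orientation rules R1-R3 to a fixpoint, in place.

    An orientation is skipped when the constraint set forbids it or when it
    would close a directed cycle (possible on finite samples after
    conflicting collider orientations); with background knowledge the
    closure is therefore conservative — it never orients an inadmissible
    edge, at the price of possibly leaving a compelled edge undirected.
    """

    def adjacent(u, v):
        return (u, v) in directed or (v, u) in directed or tuple(sorted((u, v))) in undirected

    def orient(u, v) -> bool:
        if constraints is not None and constraints.is_forbidden(u, v):
            return False
        if _has_directed_path(directed, v, u):
            return False
        undirected.discard(tuple(sorted((u, v))))
        directed.add((u, v))
        return True

    changed = True
    while changed:
        changed = False
        for a, b in sorted(undirected):
            for u, v in ((a, b), (b, a)):
                # R1: w -> u, u - v, w and v non-adjacent  =>  u -> v
                if any(
                    w != v and not adjacent(w, v)
                    for w, t in directed
                    if t == u
                ):
                    if orient(u, v):
                        changed = True
                        break
                # R2: u -> w -> v and u - v  =>  u -> v
                if any((u, w) in directed and (w, v) in directed for w in nodes):
                    if orient(u, v):
                        changed = True
                        break
                # R3: u - w1, u - w2, w1 -> v, w2 -> v, w1,w2 non-adjacent => u -> v
                spouses = [
                    w
                    for w in nodes
                    if tuple(sorted((u, w))) in undirected and (w, v) in directed
                ]
                if any(
                    not adjacent(w1, w2)
                    for w1, w2 in combinations(sorted(spouses), 2)
                ):
                    if orient(u, v):
                        changed = True
                        break
            if changed:
                break


def cpdag_of_dag(dag: nx.DiGraph) -> CPDAG:
    """Completed partially directed representative of ``dag``'s equivalence class.

    Skeleton plus v-structure orientations, closed under Meek's rules:
    exactly the compelled edges end up directed.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("input has a directed cycle")
    directed: set[tuple[str, str]] = set()
    undirected: set[tuple[str, str]] = {tuple(sorted(e)) for e in dag.edges}
    for c in dag.nodes:
        for a, b in combinations(sorted(dag.predecessors(c)), 2):
            if not (dag.has_edge(a, b) or dag.has_edge(b, a)):
                for u in (a, b):
                    undirected.discard(tuple(sorted((u, c))))
                    directed.add((u, c))
    _meek_closure(list(dag.nodes), directed, undirected)
    return CPDAG(tuple(dag.nodes), frozenset(directed), frozenset(undirected))


# -- PC algorithm ---------------------------------------------------------


def pc_learn(
    table: SurveyTable,
    alpha: float = 0.05,
    max_cond: int = 3,
    constraints: ConstraintSet | None = None,
) -> CPDAG:
    """Stable-PC CPDAG estimate from G² tests at level ``alpha``.

    Skeleton pruning freezes neighbour sets at the start of each conditioning
    depth (order-independent), records separating sets at first acceptance,
    then orients unshielded colliders and applies Meek's rules.  Forbidden
    edges (both directions) are removed from the initial complete graph;
    required edges are never tested and end up oriented as specified.
    """
    names = sorted(table.names)
    if len(names) < 2:
        raise ValueError("need at least two variables")
    cons = constraints or ConstraintSet()
    required_pairs = {tuple(sorted(e)) for e in cons.required}

    adj: dict[str, set[str]] = {v: set() for v in names}
    for u, v in combinations(names, 2):
        if cons.is_forbidden(u, v) and cons.is_forbidden(v, u):
            continue
        adj[u].add(v)
        adj[v].add(u)

    sepset: dict[tuple[str, str], tuple[str, ...]] = {}
    depth = 0
    while depth <= max_cond:
        frozen = {v: set(nb) for v, nb in adj.items()}
        if not any(len(nb) - 1 >= depth for nb in frozen.values()):
            break
        for u in names:
            for v in sorted(frozen[u]):
                if u >= v or v not in adj[u]:
                    continue
                if (u, v) in required_pairs:
                    continue
                removed = False
                for a, b in ((u, v), (v, u)):
                    for S in combinations(sorted(frozen[a] - {b}), depth):
                        res = g2_test(table, a, b, S)
                        if res.p_value > alpha:
                            sepset[(u, v)] = tuple(sorted(S))
                            adj[u].discard(v)
                            adj[v].discard(u)
                            removed = True
                            break
                    if removed:
                        break
        depth += 1

    directed: set[tuple[str, str]] = set()
    undirected: set[tuple[str, str]] = {
        (u, v) for u in names for v in adj[u] if u < v
    }
    for u, v in sorted(cons.required):
        undirected.discard(tuple(sorted((u, v))))
        directed.add((u, v))

    # orient unshielded colliders u -> w <- v when w is outside sep(u, v)
    for w in names:
        for u, v in combinations(sorted(adj[w]), 2):
            if v in adj[u]:
                continue
            key = (u, v) if u < v else (v, u)
            if w in sepset.get(key, ()):
                continue
            for a in (u, v):
                if (w, a) in directed:
                    logger.warning(
                        "conflicting collider orientations at %s - %s; keeping first", a, w
                    )
                    continue
                if cons.is_forbidden(a, w) or _has_directed_path(directed, w, a):
                    continue
                undirected.discard(tuple(sorted((a, w))))
                directed.add((a, w))

    _meek_closure(names, directed, undirected, cons)
    return CPDAG(tuple(names), frozenset(directed), frozenset(undirected))


# -- consistent extension -------------------------------------------------


def dag_extension(
    cpdag: CPDAG,
    constraints: ConstraintSet | None = None,
    seed: int = 0,
) -> nx.DiGraph:
    """A consistent DAG extension of ``cpdag`` honouring the constraints.

    Uses the Dor-Tarsi sink-elimination scheme with seed-shuffled candidate
    order; raises ``ValueError`` when no admissible extension exists (e.g.
    contradictory constraints or a compelled forbidden edge).
    """
    cons = constraints or ConstraintSet()
    bad = [e for e in cpdag.directed if cons.is_forbidden(*e)]
    bad += [e for e in cons.required if (e[1], e[0]) in cpdag.directed]
    bad += [
        e
        for e in cons.required
        if not cpdag.adjacent(*e) and set(e) <= set(cpdag.nodes)
    ]
    if bad:
        raise ValueError(f"constraints contradict the CPDAG: {sorted(set(bad))}")

    rng = np.random.default_rng(seed)
    directed = set(cpdag.directed)
    undirected = set(cpdag.undirected)
    out = nx.DiGraph()
    out.add_nodes_from(cpdag.nodes)
    out.add_edges_from(directed)

    remaining = set(cpdag.nodes)

    def nbrs(x):
        und = {b if a == x else a for a, b in undirected if x in (a, b)}
        din = {u for u, v in directed if v == x}
        dout = {v for u, v in directed if u == x}
        return und, din, dout

    while remaining:
        candidates = sorted(remaining)
        order = [candidates[i] for i in rng.permutation(len(candidates))]
        for x in order:
            und, din, dout = nbrs(x)
            if dout:
                continue
            adjx = und | din
            # every undirected neighbour must be adjacent to all of x's neighbours
            if not all(
                cpdag.adjacent(y, z) for y in und for z in adjx - {y}
            ):
                continue
            if any(cons.is_forbidden(y, x) or (x, y) in cons.required for y in und):
                continue
            for y in und:
                undirected.discard(tuple(sorted((x, y))))
                out.add_edge(y, x)
            directed = {e for e in directed if x not in e}
            undirected = {e for e in undirected if x not in e}
            remaining.discard(x)
            break
        else:
            raise ValueError("CPDAG admits no constraint-respecting extension")
    return out
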