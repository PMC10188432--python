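"""Score-based structure MCMC over DAGs, with PC initialisation.

The sampler is a Metropolis-Hastings random walk whose states are DAGs and
whose stationary density is proportional to ``exp(network qNML score)``.  A
proposal picks uniformly among the currently *valid* single-edge moves —
additions, deletions and reversals that keep the graph acyclic, respect
forbidden/required edges and the parent cap — and the Hastings correction is
the ratio of valid-move counts before and after the move.  The hybrid
learner initialises the chain at a consistent extension of the PC CPDAG and
reports the best-scoring DAG visited, together with post-burn-in
edge-selection frequencies as a stability diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from .data import SurveyTable
from .pc import ConstraintSet, dag_extension, pc_learn
from .qnml import ScoreCache

logger = logging.getLogger(__name__)

ScoreFn = Callable[[str, frozenset], float]


@dataclass
class SearchConfig:
    """Structure-search settings.

    ``iterations`` counts MCMC steps, ``burn_in`` of which are discarded
    before edge frequencies accumulate; ``thinning`` keeps every k-th
    post-burn-in state.  ``init`` is ``"pc"`` (default), ``"empty"``, or a
    DAG to start from.  ``max_parents`` caps in-degrees, bounding the size of
    the flattened contingency tables the score touches.
    """

    iterations: int = 200_000
    burn_in: int = 50_000
    thinning: int = 1
    seed: int = 0
    constraints: ConstraintSet | None = None
    max_parents: int = 4
    init: str | nx.DiGraph = "pc"
    pc_alpha: float = 0.05
    pc_max_cond: int = 3
    record_states: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.max_parents < 0 or self.thinning < 1:
            raise ValueError("max_parents >= 0 and thinning >= 1 required")


@dataclass
class MCMCTrace:
    """Per-iteration scores/acceptances plus the best DAG and edge frequencies."""

    scores: np.ndarray
    accepted: np.ndarray
    best_dag: nx.DiGraph
    best_score: float
    edge_frequency: pd.DataFrame
    n_kept: int
    states: list[frozenset] | None = None


class _SearchState:
    """Adjacency/reachability bookkeeping for fast valid-move enumeration."""

    ADD, DELETE, REVERSE = 0, 1, 2

    def __init__(
        self,
        names: list[str],
        dag: nx.DiGraph,
        constraints: ConstraintSet,
        max_parents: int,
    ) -> None:
        self.names = names
        self.index = {v: i for i, v in enumerate(names)}
        p = len(names)
        self.adj = np.zeros((p, p), dtype=bool)
        for u, v in dag.edges:
            self.adj[self.index[u], self.index[v]] = True
        self.forbidden = np.zeros((p, p), dtype=bool)
        self.required = np.zeros((p, p), dtype=bool)
        for i, u in enumerate(names):
            for j, v in enumerate(names):
                if i != j and constraints.is_forbidden(u, v):
                    self.forbidden[i, j] = True
        for u, v in constraints.required:
            if u in self.index and v in self.index:
                self.required[self.index[u], self.index[v]] = True
        np.fill_diagonal(self.forbidden, True)
        self.max_parents = max_parents
        self._refresh_reach()
        self._check(dag)

    def _check(self, dag: nx.DiGraph) -> None:
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("initial graph is cyclic")
        if (self.adj & self.forbidden).any():
            raise ValueError("initial graph contains a forbidden edge")
        if (self.required & ~self.adj).any():
            raise ValueError("initial graph lacks a required edge")
        if (self.adj.sum(axis=0) > self.max_parents).any():
            raise ValueError("initial graph exceeds max_parents")

    def _refresh_reach(self) -> None:
        """Strict reachability closure (paths of length >= 1)."""
        reach = self.adj.copy()
        while True:
            nxt = reach | (reach @ self.adj)
            if (nxt == reach).all():
                break
            reach = nxt
        self.reach = reach

    def valid_moves(self) -> list[tuple[int, int, int]]:
        adj, reach = self.adj, self.reach
        indeg = adj.sum(axis=0)
        can_gain = indeg < self.max_parents
        addable = (
            ~adj
            & ~adj.T
            & ~self.forbidden
            & ~reach.T  # adding u->v with v ~> u would close a cycle
            & can_gain[None, :]
        )
        moves = [(self.ADD, int(u), int(v)) for u, v in np.argwhere(addable)]
        for u, v in np.argwhere(adj & ~self.required):
            moves.append((self.DELETE, int(u), int(v)))
            if self.forbidden[v, u] or not can_gain[u]:
                continue
            # reversal closes a cycle iff some other out-neighbour of u reaches v
            via = adj[u] & reach[:, v]
            via[v] = False
            if not via.any():
                moves.append((self.REVERSE, int(u), int(v)))
        return moves

    def apply(self, move: tuple[int, int, int]) -> None:
        kind, u, v = move
        self._saved_reach = self.reach
        if kind == self.ADD:
            self.adj[u, v] = True
        elif kind == self.DELETE:
            self.adj[u, v] = False
        else:
            self.adj[u, v] = False
            self.adj[v, u] = True
        self._refresh_reach()

    def undo(self, move: tuple[int, int, int]) -> None:
        kind, u, v = move
        if kind == self.ADD:
            self.adj[u, v] = False
        elif kind == self.DELETE:
            self.adj[u, v] = True
        else:
            self.adj[v, u] = False
            self.adj[u, v] = True
        self.reach = self._saved_reach

    def parent_set(self, v: int) -> frozenset:
        return frozenset(self.names[u] for u in np.flatnonzero(self.adj[:, v]))

    def to_dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        g.add_edges_from(
            (self.names[u], self.names[v]) for u, v in np.argwhere(self.adj)
        )
        return g

    def edge_key(self) -> frozenset:
        return frozenset((int(u), int(v)) for u, v in np.argwhere(self.adj))


def propose_move(
    dag: nx.DiGraph,
    constraints: ConstraintSet | None = None,
    rng: np.random.Generator | None = None,
    max_parents: int | None = None,
) -> tuple[nx.DiGraph, float]:
    """One uniform add/delete/reverse proposal and its Hastings ratio.

    Returns the proposed DAG together with ``|valid moves from g| / |valid
    moves from g'|``; with no valid move the DAG is returned unchanged with
    ratio 1.
    """
    rng = rng or np.random.default_rng()
    cons = constraints or ConstraintSet()
    names = sorted(dag.nodes)
    cap = max_parents if max_parents is not None else len(names)
    state = _SearchState(names, dag, cons, cap)
    moves = state.valid_moves()
    if not moves:
        return dag.copy(), 1.0
    n_from = len(moves)
    move = moves[int(rng.integers(n_from))]
    state.apply(move)
    n_to = len(state.valid_moves())
    return state.to_dag(), n_from / n_to


def _greedy_orient(cpdag, cons: ConstraintSet) -> nx.DiGraph:
    """Orient a (possibly inconsistent) PC pattern into some admissible DAG.

    Directed edges are kept when they neither violate constraints nor close a
    cycle; undirected edges are oriented in whichever admissible direction
    exists, else dropped.  V-structure preservation is not attempted.
    """
    g = nx.DiGraph()
    g.add_nodes_from(cpdag.nodes)
    for u, v in sorted(cpdag.directed):
        if not cons.is_forbidden(u, v) and not nx.has_path(g, v, u):
            g.add_edge(u, v)
    for u, v in sorted(cpdag.undirected):
        for a, b in ((u, v), (v, u)):
            if not cons.is_forbidden(a, b) and not nx.has_path(g, b, a):
                g.add_edge(a, b)
                break
    return g


def _initial_dag(table: SurveyTable, config: SearchConfig) -> nx.DiGraph:
    cons = config.constraints or ConstraintSet()
    if isinstance(config.init, nx.DiGraph):
        return config.init.copy()
    if config.init == "empty":
        g = nx.DiGraph()
        g.add_nodes_from(table.names)
        g.add_edges_from(cons.required)
        return g
    if config.init == "pc":
        cpdag = pc_learn(table, config.pc_alpha, config.pc_max_cond, cons)
        try:
            dag = dag_extension(cpdag, cons, seed=config.seed)
        except ValueError:
            # finite-sample PC output need not be extendable; any admissible
            # orientation serves as a chain start
            logger.warning("PC pattern not extendable; orienting greedily")
            dag = _greedy_orient(cpdag, cons)
        # the PC result may exceed the search's parent cap; trim surplus
        for v in list(dag.nodes):
            extra = [
                u
                for u in sorted(dag.predecessors(v))
                if (u, v) not in cons.required
            ]
            while dag.in_degree(v) > config.max_parents and extra:
                dag.remove_edge(extra.pop(), v)
        return dag
    raise ValueError(f"unknown init {config.init!r}")


def mcmc_search(
    table: SurveyTable,
    config: SearchConfig,
    score_fn: ScoreFn | None = None,
) -> MCMCTrace:
    """Metropolis-Hastings over DAG space with stationary density ∝ exp(score).

    ``score_fn(child, parent_set)`` defaults to the cached qNML local score
    on ``table``; a different callable may be supplied for testing (e.g. a
    constant score, which makes the stationary law uniform over DAGs).
    """
    cons = config.constraints or ConstraintSet()
    if score_fn is None:
        cache = ScoreCache(table)
        score_fn = cache.family_score
    rng = np.random.default_rng(config.seed)
    init = _initial_dag(table, config)
    names = sorted(table.names)
    state = _SearchState(names, init, cons, config.max_parents)

    family = np.array(
        [score_fn(v, state.parent_set(i)) for i, v in enumerate(names)]
    )
    score = float(family.sum())
    best_score, best_adj = score, state.adj.copy()
    p = len(names)
    scores = np.empty(config.iterations)
    accepted = np.zeros(config.iterations, dtype=bool)
    edge_counts = np.zeros((p, p), dtype=np.int64)
    states: list[frozenset] | None = [] if config.record_states else None
    n_kept = 0

    moves = state.valid_moves()
    for it in range(config.iterations):
        if moves:
            n_from = len(moves)
            move = moves[int(rng.integers(n_from))]
            kind, u, v = move
            touched = (v,) if kind != state.REVERSE else (u, v)
            state.apply(move)
            new_fam = {j: score_fn(names[j], state.parent_set(j)) for j in touched}
            delta = sum(new_fam[j] - family[j] for j in touched)
            moves_to = state.valid_moves()
            log_accept = delta + math.log(n_from / len(moves_to))
            if log_accept >= 0 or rng.random() < math.exp(log_accept):
                for j, s in new_fam.items():
                    family[j] = s
                score += delta
                accepted[it] = True
                moves = moves_to
                if score > best_score:
                    best_score, best_adj = score, state.adj.copy()
            else:
                state.undo(move)
        scores[it] = score
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            edge_counts += state.adj
            n_kept += 1
            if states is not None:
                states.append(state.edge_key())
        if (it + 1) % 10_000 == 0:
            logger.info(
                "iteration %d/%d score %.2f best %.2f",
                it + 1,
                config.iterations,
                score,
                best_score,
            )

    best = nx.DiGraph()
    best.add_nodes_from(names)
    best.add_edges_from((names[u], names[v]) for u, v in np.argwhere(best_adj))
    freq = pd.DataFrame(
        edge_counts / max(n_kept, 1), index=names, columns=names
    )
    return MCMCTrace(
        scores=scores,
        accepted=accepted,
        best_dag=best,
        best_score=best_score,
        edge_frequency=freq,
        n_kept=n_kept,
        states=states,
    )


def hybrid_learn(
    table: SurveyTable,
    config: SearchConfig | None = None,
    score_fn: ScoreFn | None = None,
) -> tuple[nx.DiGraph, MCMCTrace]:
    """PC-initialised qNML structure MCMC; returns (best DAG, trace)."""
    config = config or SearchConfig()
    trace = mcmc_search(table, config, score_fn)
    return trace.best_dag, trace
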