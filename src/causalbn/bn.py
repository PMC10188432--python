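"""Discrete Bayesian-network container: DAG + per-node conditional tables.

The same container serves as the ground truth in simulations and as the
fitted model in inference: a :class:`networkx.DiGraph` over variable names,
one :class:`~causalbn.data.VariableSchema` per node, and one conditional
probability table per node stored as an array whose leading axes run over the
parent levels (parents in the stored order) and whose last axis runs over the
node's own levels.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .data import SurveyTable, VariableSchema


class BayesianNetwork:
    """DAG plus per-node conditional probability tables.

    Parameters
    ----------
    dag
        Acyclic directed graph over variable names.
    schemas
        One schema per node, in the column order of associated tables.
    cpts
        Mapping ``name -> array``; shape ``(*parent_cards, own_card)`` with
        parent axes following ``parents[name]``.
    parents
        Mapping ``name -> ordered tuple of parent names`` fixing the axis
        order of each CPT.  Defaults to sorted predecessors.
    """

    def __init__(
        self,
        dag: nx.DiGraph,
        schemas: Sequence[VariableSchema],
        cpts: Mapping[str, np.ndarray],
        parents: Mapping[str, tuple[str, ...]] | None = None,
    ) -> None:
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("graph has a directed cycle")
        self.dag = dag
        self.schemas = list(schemas)
        self._schema = {s.name: s for s in self.schemas}
        if set(dag.nodes) != set(self._schema):
            raise ValueError("schema names do not match graph nodes")
        if parents is None:
            parents = {v: tuple(sorted(dag.predecessors(v))) for v in dag.nodes}
        self.parents = {v: tuple(parents[v]) for v in dag.nodes}
        self.cpts = {}
        for v in dag.nodes:
            if set(self.parents[v]) != set(dag.predecessors(v)):
                raise ValueError(f"parent order for {v!r} does not match the graph")
            want = tuple(self._schema[p].cardinality for p in self.parents[v]) + (
                self._schema[v].cardinality,
            )
            arr = np.asarray(cpts[v], dtype=float)
            if arr.shape != want:
                raise ValueError(f"CPT shape for {v!r}: got {arr.shape}, want {want}")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows for {v!r} do not sum to 1")
            self.cpts[v] = arr
        self.order = list(nx.topological_sort(dag))

    def schema(self, name: str) -> VariableSchema:
        return self._schema[name]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.schemas]

    def card(self, name: str) -> int:
        return self._schema[name].cardinality

    # -- sampling ---------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> SurveyTable:
        """Ancestral (topological-order) forward sampling of ``n`` rows."""
        col = {s.name: j for j, s in enumerate(self.schemas)}
        codes = np.zeros((n, len(self.schemas)), dtype=np.int16)
        if n:
            for v in self.order:
                cpt = self.cpts[v]
                pa = self.parents[v]
                if pa:
                    flat = cpt.reshape(-1, cpt.shape[-1])
                    idx = np.zeros(n, dtype=np.int64)
                    for p in pa:
                        idx = idx * self.card(p) + codes[:, col[p]]
                    probs = flat[idx]
                else:
                    probs = np.broadcast_to(cpt, (n, cpt.shape[-1]))
                u = rng.random(n)
                codes[:, col[v]] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return SurveyTable(self.schemas, codes)

    # -- exact joint (small networks) -------------------------------------

    def joint(self) -> np.ndarray:
        """Full joint distribution, axes in schema order.  Exponential in p;
        intended for oracle checks on small networks."""
        names = self.names
        axis = {v: i for i, v in enumerate(names)}
        cards = [self.card(v) for v in names]
        joint = np.ones(cards)
        for v in names:
            cpt = self.cpts[v]
            src = [axis[p] for p in self.parents[v]] + [axis[v]]
            expanded = np.moveaxis(
                cpt.reshape(cpt.shape + (1,) * (len(names) - cpt.ndim)),
                range(cpt.ndim),
                src,
            )
            joint = joint * expanded
        return joint
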