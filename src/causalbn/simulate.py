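"""Ground-truth network and survey-data generation.

Structure learning and interventional queries can only be validated against a
known truth, so this module generates discrete Bayesian networks with
controllable density and effect strength and forward-samples survey-like
tables from them.  A random truth is built in three steps:

1. ``random_dag`` draws a uniform topological order, then keeps each
   order-respecting edge independently with probability ``edge_prob``
   (truncating in-degrees to ``max_indegree`` by random removal and skipping
   forbidden edges).
2. ``random_cpts`` equips each node with a base distribution drawn from a
   symmetric Dirichlet and exponentially tilts it per parent configuration:
   the conditional for configuration ``c`` is proportional to
   ``base * exp(effect_strength * z_c)`` with ``z_c`` a fixed random
   unit-norm logit direction.  ``effect_strength`` therefore scales the
   Kullback-Leibler separation between parent configurations, from
   independence at 0 to near-deterministic children as it grows.
3. ``forward_sample`` draws rows by ancestral sampling.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bn import BayesianNetwork
from .data import SurveyTable, VariableSchema

#: A ground-truth network is an ordinary BayesianNetwork whose CPTs are known.
GroundTruthBN = BayesianNetwork


@dataclass(frozen=True)
class GeneratorConfig:
    """Controls for the synthetic ground-truth generator.

    ``dirichlet_alpha`` sets the sharpness of the base distributions (small
    alpha = extreme probabilities); ``effect_strength`` sets how far apart the
    conditionals for distinct parent configurations sit.
    """

    n_vars: int = 10
    levels_per_var: int = 3
    edge_prob: float = 0.3
    max_indegree: int = 4
    dirichlet_alpha: float = 1.0
    effect_strength: float = 2.0
    seed: int = 0
    forbidden: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_prob <= 1.0):
            raise ValueError("edge_prob must lie in [0, 1]")
        if self.max_indegree < 0:
            raise ValueError("max_indegree must be >= 0")
        if self.dirichlet_alpha <= 0 or self.effect_strength < 0:
            raise ValueError("dirichlet_alpha must be > 0 and effect_strength >= 0")
        if self.levels_per_var not in (2, 3):
            raise ValueError("levels_per_var must be 2 or 3")

    def variable_names(self) -> list[str]:
        return [f"X{i}" for i in range(self.n_vars)]

    def schemas(self) -> list[VariableSchema]:
        labels = ("L0", "L1", "L2")[: self.levels_per_var]
        return [
            VariableSchema(name, labels, "beliefs and perceptions")
            for name in self.variable_names()
        ]


def random_dag(config: GeneratorConfig) -> nx.DiGraph:
    """Random DAG over ``X0..X{n-1}``: uniform topological order, independent
    order-respecting edges at ``edge_prob``, in-degree capped at
    ``max_indegree`` by random removal, forbidden edges excluded."""
    rng = np.random.default_rng(config.seed)
    names = config.variable_names()
    order = [names[i] for i in rng.permutation(config.n_vars)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for j, v in enumerate(order):
        candidates = [
            u for u in order[:j] if (u, v) not in config.forbidden
        ]
        keep = [u for u in candidates if rng.random() < config.edge_prob]
        while len(keep) > config.max_indegree:
            keep.pop(int(rng.integers(len(keep))))
        g.add_edges_from((u, v) for u in keep)
    return g


def random_cpts(dag: nx.DiGraph, config: GeneratorConfig) -> GroundTruthBN:
    """Attach exponentially tilted Dirichlet CPTs to ``dag`` (see module doc)."""
    rng = np.random.default_rng((config.seed, 1))
    schemas = config.schemas()
    card = config.levels_per_var
    cpts: dict[str, np.ndarray] = {}
    parents: dict[str, tuple[str, ...]] = {}
    for v in sorted(dag.nodes):  # fixed iteration order for seed determinism
        pa = tuple(sorted(dag.predecessors(v)))
        parents[v] = pa
        n_cfg = card ** len(pa)
        base = rng.dirichlet(np.full(card, config.dirichlet_alpha))
        if pa:
            z = rng.standard_normal((n_cfg, card))
            z /= np.linalg.norm(z, axis=1, keepdims=True)
            tilted = base * np.exp(config.effect_strength * z)
            tilted /= tilted.sum(axis=1, keepdims=True)
            cpts[v] = tilted.reshape((card,) * len(pa) + (card,))
        else:
            cpts[v] = base
    return GroundTruthBN(dag, schemas, cpts, parents)


def generate(config: GeneratorConfig) -> GroundTruthBN:
    """Convenience: ``random_cpts(random_dag(config), config)``."""
    return random_cpts(random_dag(config), config)


def forward_sample(bn: BayesianNetwork, n: int, seed: int) -> SurveyTable:
    """Ancestral sampling of ``n`` complete rows from ``bn``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return bn.sample(n, np.random.default_rng(seed))
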