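"""Shared builders for the test suite: tiny schemas, tables and DAG tools."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from causalbn import SurveyTable, VariableSchema


def make_schemas(names, levels=("a", "b", "c"), category="beliefs and perceptions"):
    return [VariableSchema(n, tuple(levels), category) for n in names]


def make_table(codes, names=None, levels=None, weights=None):
    codes = np.asarray(codes)
    names = names or [f"V{i}" for i in range(codes.shape[1])]
    card = int(codes.max()) + 1 if codes.size else 2
    levels = levels or ("a", "b", "c")[: max(card, 2)]
    return SurveyTable(make_schemas(names, levels), codes, weights)


def all_three_node_dags(names=("A", "B", "C")):
    """All 25 labelled DAGs on three nodes."""
    pairs = [(a, b) for a, b in itertools.combinations(names, 2)]
    dags = []
    for mask in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), m in zip(pairs, mask):
            if m == 1:
                edges.append((a, b))
            elif m == 2:
                edges.append((b, a))
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            dags.append(g)
    return dags


def all_dags(n):
    """Brute-force enumeration of labelled DAGs on ``n`` nodes (n <= 4)."""
    names = [f"N{i}" for i in range(n)]
    pairs = list(itertools.combinations(names, 2))
    count = 0
    for mask in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), m in zip(pairs, mask):
            if m == 1:
                edges.append((a, b))
            elif m == 2:
                edges.append((b, a))
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            count += 1
    return count


@pytest.fixture(scope="session")
def three_node_dags():
    return all_three_node_dags()


@pytest.fixture(scope="session")
def fixture_bn():
    from causalbn import vaccine_fixture

    return vaccine_fixture()
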