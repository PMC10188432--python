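"""Schemas, coded survey tables, discretization and graph/table I/O.

Every other module consumes :class:`SurveyTable`: a rectangular block of
categorical survey responses coded as small integers (one code per declared
level, in schema order), an optional vector of per-row sampling weights, and
the list of :class:`VariableSchema` describing each column.  Missing responses
are carried as the reserved sentinel :data:`MISSING` and are never a level of
any schema; analyses operate on complete cases only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Sentinel code for a missing cell.  Never a valid level code.
MISSING: int = -1

#: Causal-factor categories used to organise survey variables.
CATEGORIES = (
    "outcome expectation",
    "emotions",
    "beliefs and perceptions",
    "influencers/channels",
    "social influence",
    "structural enablers/barriers",
    "demographics",
    "behaviours",
    "intentions",
    "dependent variable",
)

#: Name of the optional CSV column holding per-row sampling weights.
WEIGHT_COLUMN = "weight"


@dataclass(frozen=True)
class VariableSchema:
    """A named categorical/ordinal survey variable with ordered levels.

    Parameters
    ----------
    name
        Unique variable identifier (the CSV column header).
    levels
        Ordered level labels; two or three of them.  Codes are the 0-based
        positions in this tuple.
    category
        Causal-factor category, one of :data:`CATEGORIES`.
    reference_level
        Index of the level treated as the baseline in regression coding and
        interventional queries.
    """

    name: str
    levels: tuple[str, ...]
    category: str
    reference_level: int = 0

    def __post_init__(self) -> None:
        if not (1 <= len(self.levels) <= 3):
            raise ValueError(f"{self.name}: needs 1-3 levels, got {len(self.levels)}")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate level labels")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        if not (0 <= self.reference_level < len(self.levels)):
            raise ValueError(f"{self.name}: reference_level out of range")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    def code_of(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise KeyError(f"{label!r} is not a level of {self.name!r}") from None


@dataclass(frozen=True)
class DiscretizationSpec:
    """Closed-interval binning of a raw numeric scale onto ordered levels.

    ``bins`` is an ordered sequence of ``(lower, upper, level_label)`` with
    both endpoints included, e.g. the 0-10 intent item maps through
    ``[(0, 3, "Low"), (4, 6, "Moderate"), (7, 10, "High")]``.
    """

    variable: str
    bins: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        bins = tuple((float(lo), float(hi), str(lv)) for lo, hi, lv in self.bins)
        if not bins:
            raise ValueError("empty bin list")
        for lo, hi, _ in bins:
            if lo > hi:
                raise ValueError(f"bin [{lo}, {hi}] is empty")
        for (_, hi0, _), (lo1, _, _) in zip(bins, bins[1:]):
            if lo1 <= hi0:
                raise ValueError("bins overlap or are out of order")
        object.__setattr__(self, "bins", bins)

    def apply(self, value: float) -> str:
        """Map a raw value to its level label; raises on out-of-range values."""
        for lo, hi, level in self.bins:
            if lo <= value <= hi:
                return level
        raise ValueError(
            f"{self.variable}: raw value {value!r} falls outside all bins"
        )


class SurveyTable:
    """Coded categorical survey responses plus schemas and row weights.

    ``codes`` is an ``(n, p)`` integer array; cell ``codes[i, j]`` is the
    0-based level code of variable ``j`` for respondent ``i``, or
    :data:`MISSING`.
    """

    def __init__(
        self,
        schemas: Sequence[VariableSchema],
        codes: np.ndarray,
        weights: np.ndarray | None = None,
    ) -> None:
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 2 or codes.shape[1] != len(schemas):
            raise ValueError("codes shape does not match schema list")
        names = [s.name for s in schemas]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        for j, s in enumerate(schemas):
            col = codes[:, j]
            bad = (col != MISSING) & ((col < 0) | (col >= s.cardinality))
            if bad.any():
                raise ValueError(f"invalid level code in column {s.name!r}")
        if weights is None:
            weights = np.ones(codes.shape[0])
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (codes.shape[0],):
            raise ValueError("weights length does not match row count")
        if (weights < 0).any():
            raise ValueError("negative weight")
        self.schemas = list(schemas)
        self.codes = codes
        self.weights = weights
        self._index = {s.name: j for j, s in enumerate(self.schemas)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.schemas]

    def schema(self, name: str) -> VariableSchema:
        return self.schemas[self.column_index(name)]

    def column_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.column_index(name)]

    @property
    def has_uniform_weights(self) -> bool:
        w = self.weights
        return bool(w.size == 0 or np.all(w == w[0]))

    def to_dataframe(self, labels: bool = False) -> pd.DataFrame:
        """Export as a pandas DataFrame of codes, or of level labels."""
        df = pd.DataFrame(self.codes, columns=self.names)
        if labels:
            for s in self.schemas:
                lab = np.array(s.levels, dtype=object)
                col = self.codes[:, self.column_index(s.name)]
                out = np.where(col == MISSING, None, lab[np.clip(col, 0, None)])
                df[s.name] = out
        return df


def complete_cases(table: SurveyTable, columns: Iterable[str] | None = None) -> SurveyTable:
    """Rows with no missing value in the named columns (default: all columns)."""
    cols = list(columns) if columns is not None else table.names
    idx = [table.column_index(c) for c in cols]
    keep = (table.codes[:, idx] != MISSING).all(axis=1) if idx else np.ones(table.n_rows, bool)
    return SurveyTable(table.schemas, table.codes[keep], table.weights[keep])


# -- schema / table file I/O ---------------------------------------------


def read_schema(path: str | Path) -> tuple[list[VariableSchema], dict[str, DiscretizationSpec]]:
    """Read a JSON variable schema (and optional discretization specs)."""
    with open(path) as fh:
        doc = json.load(fh)
    schemas = [
        VariableSchema(
            name=v["name"],
            levels=tuple(v["levels"]),
            category=v["category"],
            reference_level=v.get("reference_level", 0),
        )
        for v in doc["variables"]
    ]
    specs = {
        d["variable"]: DiscretizationSpec(d["variable"], tuple(map(tuple, d["bins"])))
        for d in doc.get("discretize", [])
    }
    unknown = set(specs) - {s.name for s in schemas}
    if unknown:
        raise ValueError(f"discretization for unknown variables: {sorted(unknown)}")
    return schemas, specs


def write_schema(
    schemas: Sequence[VariableSchema],
    path: str | Path,
    discretize: Iterable[DiscretizationSpec] = (),
) -> None:
    doc = {
        "variables": [
            {
                "name": s.name,
                "levels": list(s.levels),
                "category": s.category,
                "reference_level": s.reference_level,
            }
            for s in schemas
        ],
    }
    discretize = list(discretize)
    if discretize:
        doc["discretize"] = [
            {"variable": d.variable, "bins": [list(b) for b in d.bins]} for d in discretize
        ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_table(csv_path: str | Path, schema_path: str | Path) -> SurveyTable:
    """Read a CSV of level labels (or raw numerics, for binned columns) as a coded table.

    The CSV header must name a subset-free superset match of the schema: every
    schema variable must appear; an optional ``weight`` column supplies row
    weights; empty cells become the missing sentinel.  Columns that carry a
    :class:`DiscretizationSpec` hold raw numeric values and are binned before
    coding.
    """
    schemas, specs = read_schema(schema_path)
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    missing_cols = [s.name for s in schemas if s.name not in df.columns]
    if missing_cols:
        raise ValueError(f"CSV lacks schema columns: {missing_cols}")
    extra = set(df.columns) - {s.name for s in schemas} - {WEIGHT_COLUMN}
    if extra:
        raise ValueError(f"CSV has columns absent from schema: {sorted(extra)}")
    n = len(df)
    codes = np.full((n, len(schemas)), MISSING, dtype=np.int16)
    for j, s in enumerate(schemas):
        raw = df[s.name].to_numpy(dtype=object)
        spec = specs.get(s.name)
        for i, cell in enumerate(raw):
            cell = cell.strip() if isinstance(cell, str) else cell
            if cell in ("", None):
                continue
            if spec is not None:
                cell = spec.apply(float(cell))
            codes[i, j] = s.code_of(cell)
    weights = None
    if WEIGHT_COLUMN in df.columns:
        weights = pd.to_numeric(df[WEIGHT_COLUMN]).to_numpy(dtype=float)
    return SurveyTable(schemas, codes, weights)


def write_table(table: SurveyTable, path: str | Path) -> None:
    """Write level labels (and weights if non-uniform) as CSV; inverse of read_table."""
    df = table.to_dataframe(labels=True)
    df = df.where(pd.notna(df), "")
    if not table.has_uniform_weights:
        df[WEIGHT_COLUMN] = table.weights
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


# -- graph file I/O -------------------------------------------------------

GRAPH_FORMATS = ("dot", "edge-list", "adjacency-csv")


def _quote(name: str) -> str:
    return '"' + name.replace('"', r"\"") + '"'


def write_graph(dag: nx.DiGraph, path: str | Path, format: str = "edge-list") -> None:
    """Write a directed graph as DOT, a node/edge list, or an adjacency CSV.

    Each format round-trips through :func:`read_graph`, preserving node names
    (including isolated nodes) and the exact edge set.
    """
    path = Path(path)
    if format == "dot":
        lines = ["digraph {"]
        lines += [f"  {_quote(v)};" for v in sorted(dag.nodes)]
        lines += [f"  {_quote(u)} -> {_quote(v)};" for u, v in sorted(dag.edges)]
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "edge-list":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for v in sorted(dag.nodes):
                w.writerow(["NODE", v])
            for u, v in sorted(dag.edges):
                w.writerow(["EDGE", u, v])
    elif format == "adjacency-csv":
        names = sorted(dag.nodes)
        mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
        for u, v in dag.edges:
            mat.loc[u, v] = 1
        mat.to_csv(path)
    else:
        raise ValueError(f"unknown graph format {format!r}; use one of {GRAPH_FORMATS}")


def read_graph(path: str | Path, format: str = "edge-list") -> nx.DiGraph:
    """Read a graph written by :func:`write_graph`."""
    path = Path(path)
    g = nx.DiGraph()
    if format == "dot":
        import re

        text = path.read_text()
        node_re = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*;\s*$')
        edge_re = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*->\s*"((?:[^"\\]|\\.)*)"\s*;\s*$')
        unescape = lambda s: s.replace(r"\"", '"')
        for line in text.splitlines():
            m = edge_re.match(line)
            if m:
                g.add_edge(unescape(m.group(1)), unescape(m.group(2)))
                continue
            m = node_re.match(line)
            if m:
                g.add_node(unescape(m.group(1)))
    elif format == "edge-list":
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row:
                    continue
                if row[0] == "NODE":
                    g.add_node(row[1])
                elif row[0] == "EDGE":
                    g.add_edge(row[1], row[2])
                else:
                    raise ValueError(f"bad edge-list row: {row!r}")
    elif format == "adjacency-csv":
        mat = pd.read_csv(path, index_col=0)
        g.add_nodes_from(str(c) for c in mat.columns)
        for u in mat.index:
            for v in mat.columns:
                if mat.loc[u, v]:
                    g.add_edge(str(u), str(v))
    else:
        raise ValueError(f"unknown graph format {format!r}; use one of {GRAPH_FORMATS}")
    return g


#: The paper-style binning of the 0-10 vaccine-intent scale.
INTENT_BINS = DiscretizationSpec(
    "Vaccine intention", ((0, 3, "Low"), (4, 6, "Moderate"), (7, 10, "High"))
)
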