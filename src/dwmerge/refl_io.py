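"""Reflection-table data model, I/O, and dataset-graph handling.

The core works on asymmetric-unit-mapped Miller indices with centric flags and
symmetry multiplicities ε supplied as columns; it never applies space-group
operations itself. Unmerged observations travel as a
:class:`ReflectionTable` — a validated pandas DataFrame with the fixed schema
``h,k,l,friedel_sign,dataset_id,image_id,I,sigI,centric,epsilon,d`` plus any
number of real-valued metadata columns (detector position, wavelength, ...).

Related datasets are organized in a :class:`DatasetGraph`: a single-parent DAG
whose edges carry the double-Wilson correlation r between a child dataset and
its parent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import GraphError, SchemaError, ValidationError

__all__ = [
    "REQUIRED_COLUMNS", "KEY_COLUMNS", "MERGED_KEY_COLUMNS",
    "ReflectionTable", "GraphEdge", "DatasetGraph",
    "read_reflection_table", "write_reflection_table",
    "split_friedel_halves", "assign_test_set", "validate_graph",
    "duplicate_control_node",
]

REQUIRED_COLUMNS = (
    "h", "k", "l", "friedel_sign", "dataset_id", "image_id",
    "I", "sigI", "centric", "epsilon", "d",
)
#: columns identifying one observation
KEY_COLUMNS = ("dataset_id", "h", "k", "l", "friedel_sign", "image_id")
#: columns identifying one merged reflection
MERGED_KEY_COLUMNS = ("dataset_id", "h", "k", "l", "friedel_sign")


@dataclass
class ReflectionTable:
    """Validated unmerged reflection observations."""

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "ReflectionTable":
        t = cls(df.reset_index(drop=True))
        if validate:
            t.validate()
        return t

    def validate(self) -> "ReflectionTable":
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        bad = np.flatnonzero(~(df["sigI"].to_numpy(dtype=float) > 0))
        if bad.size:
            raise ValidationError(f"sigI must be > 0; first offending row: {bad[0]}")
        if np.any(df["epsilon"].to_numpy(dtype=float) < 1):
            raise ValidationError("epsilon must be >= 1")
        if np.any(df["d"].to_numpy(dtype=float) <= 0):
            raise ValidationError("resolution d must be > 0")
        signs = set(df["friedel_sign"].astype(str).unique())
        if not signs <= {"+", "-"}:
            raise ValidationError(f"friedel_sign must be '+' or '-', got {signs - {'+', '-'}}")
        if len(df) and df.duplicated(subset=list(KEY_COLUMNS)).any():
            raise ValidationError(
                "duplicate (dataset_id, hkl, friedel_sign, image_id) observation")
        if len(df):
            per_hkl = df.groupby(["h", "k", "l"], sort=False)[["centric", "epsilon"]].nunique()
            inconsistent = per_hkl[(per_hkl > 1).any(axis=1)]
            if len(inconsistent):
                raise ValidationError(
                    f"centric/epsilon inconsistent within hkl {inconsistent.index[0]}")
        return self

    # -- conveniences ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_COLUMNS]

    @property
    def dataset_ids(self) -> list[str]:
        return list(pd.unique(self.data["dataset_id"]))

    def for_dataset(self, dataset_id: str) -> "ReflectionTable":
        return ReflectionTable(self.data[self.data["dataset_id"] == dataset_id]
                               .reset_index(drop=True))

    def copy(self) -> "ReflectionTable":
        return ReflectionTable(self.data.copy())


@dataclass(frozen=True)
class GraphEdge:
    parent: str
    child: str
    r: float


@dataclass
class DatasetGraph:
    """Single-parent DAG of dataset nodes with a double-Wilson r per edge."""

    nodes: list[str]
    edges: list[GraphEdge] = field(default_factory=list)
    order: list[str] | None = None  # topological order, set by validate_graph

    def __post_init__(self):
        for e in self.edges:
            if not (0.0 <= e.r < 1.0):
                raise GraphError(f"edge {e.parent}->{e.child}: r={e.r} outside [0, 1)")
            if e.parent not in self.nodes or e.child not in self.nodes:
                raise GraphError(f"edge {e.parent}->{e.child} references unknown node")
        children = [e.child for e in self.edges]
        if len(children) != len(set(children)):
            raise GraphError("a node has more than one parent")

    def parent_of(self, node: str) -> str | None:
        for e in self.edges:
            if e.child == node:
                return e.parent
        return None

    def r_of(self, node: str) -> float | None:
        for e in self.edges:
            if e.child == node:
                return e.r
        return None

    @property
    def roots(self) -> list[str]:
        children = {e.child for e in self.edges}
        return [n for n in self.nodes if n not in children]

    def with_r(self, r: float) -> "DatasetGraph":
        """Copy with every edge's r replaced (used by r-scans)."""
        return DatasetGraph(list(self.nodes),
                            [replace(e, r=r) for e in self.edges])

    # -- config round-trip -------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "DatasetGraph":
        nodes = list(cfg["nodes"])
        edges = [GraphEdge(parent=str(spec["parent"]), child=str(child),
                           r=float(spec["r"]))
                 for child, spec in (cfg.get("edges") or {}).items()]
        return cls(nodes, edges)

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes),
                "edges": {e.child: {"parent": e.parent, "r": e.r} for e in self.edges}}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SEPS = {"csv": ",", "tsv": "\t"}


def read_reflection_table(path, dialect: str = "csv") -> ReflectionTable:
    """Read a delimited-text reflection table and validate it whole-file."""
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}")
    df = pd.read_csv(path, sep=_SEPS[dialect])
    for col in ("h", "k", "l", "image_id", "epsilon"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "centric" in df.columns:
        df["centric"] = df["centric"].astype(bool)
    if "friedel_sign" in df.columns:
        df["friedel_sign"] = df["friedel_sign"].astype(str)
    if "dataset_id" in df.columns:
        df["dataset_id"] = df["dataset_id"].astype(str)
    return ReflectionTable.from_frame(df)


def write_reflection_table(t: ReflectionTable, path, dialect: str = "csv") -> None:
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}")
    t.data.to_csv(path, sep=_SEPS[dialect], index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def split_friedel_halves(t: ReflectionTable) -> tuple[ReflectionTable, ReflectionTable]:
    """Split Bijvoet pairs into '+' and '−' half datasets.

    Each half's ``dataset_id`` gains a suffix so the halves can serve as
    distinct nodes of a :class:`DatasetGraph` (e.g. for a bivariate prior on
    Bijvoet mates).
    """
    df = t.data
    plus = df[df["friedel_sign"] == "+"].copy()
    minus = df[df["friedel_sign"] == "-"].copy()
    if len(df) and (len(plus) == 0 or len(minus) == 0):
        warnings.warn("only one Friedel sign present; one half is empty")
    plus["dataset_id"] = plus["dataset_id"].astype(str) + "_plus"
    minus["dataset_id"] = minus["dataset_id"].astype(str) + "_minus"
    return (ReflectionTable(plus.reset_index(drop=True)),
            ReflectionTable(minus.reset_index(drop=True)))


def assign_test_set(t: ReflectionTable, fraction: float, seed: int
                    ) -> tuple[ReflectionTable, ReflectionTable]:
    """Observation-level random train/test partition; |test| = round(f·N)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    n = len(t)
    n_test = int(round(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return (ReflectionTable(t.data.iloc[train_idx].reset_index(drop=True)),
            ReflectionTable(t.data.iloc[test_idx].reset_index(drop=True)))


def validate_graph(g: DatasetGraph, t: ReflectionTable) -> DatasetGraph:
    """Check acyclicity/single-parenthood against the data; store a topological order."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    dg.add_edges_from((e.parent, e.child) for e in g.edges)
    if not nx.is_directed_acyclic_graph(dg):
        cycle = nx.find_cycle(dg)
        raise GraphError(f"dataset graph contains a cycle: {cycle}")
    present = set(t.data["dataset_id"].astype(str).unique())
    for node in g.nodes:
        if node not in present:
            raise GraphError(f"node '{node}' has no rows in the reflection table")
    g.order = list(nx.lexicographical_topological_sort(
        dg, key=lambda n: g.nodes.index(n)))
    return g


def duplicate_control_node(t: ReflectionTable, g: DatasetGraph, source: str,
                           sigma_multiplier: float = 2.0, r: float = 0.99,
                           new_id: str | None = None
                           ) -> tuple[ReflectionTable, DatasetGraph]:
    """Append a duplicate of ``source`` as its own child, with inflated errors.

    The duplicated control node lets difference maps be computed against a
    reference that went through the same structured prior as the perturbed
    datasets; intensity errors are multiplied (default ×2) to compensate for
    the double use of the data.
    """
    if source not in g.nodes:
        raise GraphError(f"unknown source node '{source}'")
    new_id = new_id or f"{source}_ctrl"
    if new_id in g.nodes:
        raise GraphError(f"node '{new_id}' already exists")
    ctrl = t.data[t.data["dataset_id"] == source].copy()
    ctrl["dataset_id"] = new_id
    ctrl["sigI"] = ctrl["sigI"] * float(sigma_multiplier)
    out = pd.concat([t.data, ctrl], ignore_index=True)
    new_graph = DatasetGraph(list(g.nodes) + [new_id],
                             list(g.edges) + [GraphEdge(source, new_id, r)])
    return ReflectionTable.from_frame(out), new_graph
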