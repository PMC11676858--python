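"""Edge-table parsing, network assembly and file formats.

Two tab-separated edge dialects are supported: a STRING-like table
(``protein1``, ``protein2``, ``experimental``, ``combined_score``) and an
RNAinter-like table (``gene1``, ``gene2``, ``score``).  Rows are thresholded
with *strict* inequalities (combined score > 300, confidence > 0.25 by
default), after which the surviving pairs are collapsed into one undirected,
unweighted simple graph over upper-cased gene symbols.  Gene-set collections
use the standard GMT dialect (name, description, tab-separated members).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import BuildError, FormatError

logger = logging.getLogger(__name__)

STRING_COLUMNS = ("protein1", "protein2", "experimental", "combined_score")
RNAINTER_COLUMNS = ("gene1", "gene2", "score")

#: sentinel prefix for the isolated-node sidecar line in canonical network TSVs
_ISOLATED_PREFIX = "#isolated"


@dataclass(frozen=True)
class EdgeRecord:
    """One thresholded interaction between two gene symbols.

    ``source`` records provenance (``string_like``, ``rnainter_like`` or
    ``generic``); duplicates across sources collapse at build time.
    """

    gene_a: str
    gene_b: str
    score: float
    source: str = "generic"


class GeneNetwork:
    """Undirected simple graph over gene symbols with a canonical node order.

    The node order is lexicographic over symbols and fixed at construction,
    so the adjacency matrix ``A`` (binary, symmetric, zero diagonal), the
    degree vector and everything derived from them are reproducible
    byte-for-byte.
    """

    def __init__(self, graph: nx.Graph):
        if nx.number_of_selfloops(graph):
            raise BuildError("gene network must not contain self-loops")
        self._graph = graph
        self.nodes: tuple[str, ...] = tuple(sorted(graph.nodes))

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], isolated: Iterable[str] = ()
    ) -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(isolated)
        g.add_edges_from(edges)
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self._graph.edges}

    @cached_property
    def adjacency(self) -> np.ndarray:
        a = nx.to_numpy_array(self._graph, nodelist=self.nodes, dtype=float)
        return (a > 0).astype(float)

    @cached_property
    def degree_vector(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def component_sizes(self) -> list[int]:
        return sorted((len(c) for c in nx.connected_components(self._graph)), reverse=True)

    def isolated_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self._graph.degree[n] == 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneNetwork(|V|={self.n_nodes}, |E|={self.n_edges})"


class PathwayCollection(Mapping):
    """Named gene sets (GMT-style) with optional per-set descriptions."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            fs = frozenset(genes)
            if not fs:
                raise ValueError(f"pathway {name!r} is empty")
            self._sets[name] = fs
        self.descriptions: dict[str, str] = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self._sets == other._sets

    def names(self) -> list[str]:
        return list(self._sets)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PathwayCollection({len(self)} sets)"


def _read_edge_table(
    path: str | Path,
    columns: tuple[str, ...],
    score_column: str,
    min_score: float,
    source: str,
    extra_filter_column: str | None = None,
) -> list[EdgeRecord]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("edge table %s is empty; returning no records", path)
        return []
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    numeric_cols = [score_column] + ([extra_filter_column] if extra_filter_column else [])
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[numeric_cols].isna().any(axis=1) | df[columns[0]].isna() | df[columns[1]].isna()
    if bad.any():
        logger.warning("%s: skipped %d unreadable row(s)", path, int(bad.sum()))
        df = df[~bad]

    keep = df[score_column] > min_score
    if extra_filter_column is not None:
        keep &= df[extra_filter_column] > 0
    df = df[keep]
    records = [
        EdgeRecord(str(a), str(b), float(s), source)
        for a, b, s in zip(df[columns[0]], df[columns[1]], df[score_column])
    ]
    if not records:
        logger.warning("%s: no edge records survived filtering", path)
    return records


def read_string_edges(
    path: str | Path,
    min_combined_score: float = 300,
    require_experimental: bool = True,
) -> list[EdgeRecord]:
    """Parse a STRING-like TSV, keeping rows with combined score strictly
    above ``min_combined_score`` and, when ``require_experimental`` is on,
    a positive experimental-channel score."""
    return _read_edge_table(
        path,
        STRING_COLUMNS,
        score_column="combined_score",
        min_score=min_combined_score,
        source="string_like",
        extra_filter_column="experimental" if require_experimental else None,
    )


def read_rnainter_edges(path: str | Path, min_confidence: float = 0.25) -> list[EdgeRecord]:
    """Parse an RNAinter-like TSV, keeping rows with confidence strictly above
    ``min_confidence``."""
    return _read_edge_table(
        path,
        RNAINTER_COLUMNS,
        score_column="score",
        min_score=min_confidence,
        source="rnainter_like",
    )


def build_network(records: Iterable[EdgeRecord]) -> GeneNetwork:
    """Assemble the undirected simple gene network from edge records.

    Symbols are upper-cased and trimmed; self-loops are dropped; (a,b)/(b,a)
    and cross-source duplicates collapse to a single unweighted edge.  Raises
    :class:`BuildError` if no edge survives cleaning.
    """
    records = list(records)
    if not records:
        raise ValueError("build_network requires at least one edge record")
    pairs: set[tuple[str, str]] = set()
    dropped_self = 0
    for rec in records:
        a = rec.gene_a.strip().upper()
        b = rec.gene_b.strip().upper()
        if not a or not b:
            continue
        if a == b:
            dropped_self += 1
            continue
        pairs.add((a, b) if a < b else (b, a))
    if dropped_self:
        logger.info("dropped %d self-loop record(s)", dropped_self)
    if not pairs:
        raise BuildError("no edges survived cleaning; cannot build a network")
    return GeneNetwork.from_edges(pairs)


def write_network(network: GeneNetwork, path: str | Path) -> None:
    """Write the canonical two-column TSV edge list.

    Isolated nodes (legal in synthetic graphs) are preserved through a sidecar
    comment line so |V| round-trips.
    """
    path = Path(path)
    lines = []
    isolated = network.isolated_nodes()
    if isolated:
        lines.append(_ISOLATED_PREFIX + "\t" + "\t".join(isolated))
    lines.append("gene1\tgene2")
    for pair in sorted(tuple(sorted(e)) for e in network.edges()):
        lines.append(f"{pair[0]}\t{pair[1]}")
    path.write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> GeneNetwork:
    """Read a canonical network TSV written by :func:`write_network`."""
    path = Path(path)
    isolated: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(_ISOLATED_PREFIX):
                isolated.extend(line.split("\t")[1:])
                continue
            if line.startswith("gene1\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            edges.append((parts[0], parts[1]))
    return GeneNetwork.from_edges(edges, isolated=isolated)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file (name, description, then member genes, tab-separated)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT lines need >= 3 fields")
            name, desc, genes = parts[0], parts[1], parts[2:]
            sets[name] = set(g for g in genes if g)
            descriptions[name] = desc
    return PathwayCollection(sets, descriptions)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Write a collection as GMT with sorted names and members (deterministic)."""
    path = Path(path)
    lines = []
    for name in sorted(collection):
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc] + sorted(collection[name])))
    path.write_text("\n".join(lines) + "\n")
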