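"""Gene-interaction networks and their normalized Laplacian.

A pathway database exported as an edge list is read into a
:class:`GeneNetwork`, aligned against the gene set of an expression
matrix, and turned into the normalized graph Laplacian

    L[u, v] = 1                      if u == v and d_u > 0,
              -w(u, v)/sqrt(d_u d_v) if u ~ v,
              0                      otherwise,

with d_u the weighted degree.  Rows and columns of isolated genes are
zero, so genes present in the expression data but absent from the
network fall back to plain sparsity-only shrinkage in the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "NormalizedLaplacian",
    "read_edge_list",
    "align_to_genes",
    "build_normalized_laplacian",
]


@dataclass
class GeneNetwork:
    """Undirected weighted graph over gene identifiers.

    Parameters
    ----------
    nodes : list of str
        Gene identifiers in a fixed order (dictates Laplacian indexing).
    graph : networkx.Graph
        Edge container; edge weights live in the ``"weight"`` attribute.
    """

    nodes: list[str]
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate gene identifiers in node list")
        for u, v, w in self.graph.edges(data="weight", default=1.0):
            if u == v:
                raise ValueError(f"self-loop on {u!r} is not allowed")
            if u not in self.graph or v not in self.graph:  # pragma: no cover
                raise ValueError("edge endpoint missing from graph")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has invalid weight {w!r}")
        missing = set(self.graph.nodes) - set(self.nodes)
        if missing:
            raise ValueError(f"graph contains nodes absent from node order: {sorted(missing)}")
        # isolated genes must still be present in the graph container
        self.graph.add_nodes_from(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def weight(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v].get("weight", 1.0))

    def degree(self, u: str) -> float:
        return float(self.graph.degree(u, weight="weight"))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Sequence[str] | None = None,
    ) -> "GeneNetwork":
        """Build a network from ``(u, v)`` or ``(u, v, weight)`` tuples."""
        g = nx.Graph()
        for edge in edges:
            u, v = edge[0], edge[1]
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if u == v:
                logger.warning("dropping self-loop on %s", u)
                g.add_node(u)
                continue
            g.add_edge(u, v, weight=w)
        order = list(nodes) if nodes is not None else sorted(g.nodes)
        g.add_nodes_from(order)
        return cls(nodes=order, graph=g)


@dataclass(frozen=True)
class NormalizedLaplacian:
    """Normalized Laplacian matrix with its gene order."""

    matrix: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Laplacian must be square")
        if m.shape[0] != len(self.node_order):
            raise ValueError("node order length does not match matrix size")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("Laplacian must be symmetric")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def zeros(cls, genes: Sequence[str]) -> "NormalizedLaplacian":
        """The L = 0 case: no network information (lasso-type prior)."""
        p = len(genes)
        return cls(matrix=np.zeros((p, p)), node_order=tuple(genes))

    @classmethod
    def identity(cls, genes: Sequence[str]) -> "NormalizedLaplacian":
        """The L = I case: ridge-plus-lasso (elastic-net-type) prior."""
        return cls(matrix=np.eye(len(genes)), node_order=tuple(genes))


def read_edge_list(path: str | Path, delimiter: str | None = None) -> GeneNetwork:
    """Read a gene-interaction edge list from delimited text.

    Each non-comment line holds ``gene_a gene_b [weight]``; the weight
    defaults to 1.0.  Duplicate pairs (in either orientation) collapse to
    one undirected edge keeping the last weight seen.  Self-loops are
    dropped with a warning.

    Parameters
    ----------
    path : path-like
        File to read.  Lines starting with ``#`` are ignored.
    delimiter : str, optional
        Field separator; ``None`` splits on any whitespace.
    """
    path = Path(path)
    g = nx.Graph()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}")
            u, v = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from exc
            else:
                w = 1.0
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"{path}:{lineno}: weight must be finite and >= 0, got {w}")
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, u)
                g.add_node(u)
                continue
            g.add_edge(u, v, weight=w)
    return GeneNetwork(nodes=sorted(g.nodes), graph=g)


def align_to_genes(net: GeneNetwork, genes: Sequence[str]) -> GeneNetwork:
    """Induced subgraph of ``net`` on ``genes``, in that exact order.

    Genes absent from the network become isolated nodes so the feature
    set of the expression matrix is never silently reduced.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate identifiers in gene list")
    sub = nx.Graph(net.graph.subgraph(genes).copy())
    sub.add_nodes_from(genes)
    return GeneNetwork(nodes=genes, graph=sub)


def build_normalized_laplacian(net: GeneNetwork) -> NormalizedLaplacian:
    """Normalized Laplacian of the network, in the network's node order."""
    p = net.n_nodes
    if p == 0:
        return NormalizedLaplacian(matrix=np.zeros((0, 0)), node_order=())
    for u, v, w in net.graph.edges(data="weight", default=1.0):
        if w < 0:
            raise ValueError(f"negative weight on edge ({u!r}, {v!r})")
    mat = nx.normalized_laplacian_matrix(net.graph, nodelist=net.nodes, weight="weight")
    mat = np.asarray(mat.todense(), dtype=float)
    # exact symmetry for downstream eigenvalue/Cholesky work
    mat = (mat + mat.T) / 2.0
    return NormalizedLaplacian(matrix=mat, node_order=tuple(net.nodes))
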