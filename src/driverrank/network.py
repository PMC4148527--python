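"""Directed gene-interaction networks and edge-list I/O.

A network is stored as an ordered gene list plus a sparse 0-1 adjacency
matrix ``A`` with the convention ``A[i, j] = 1`` iff gene ``i`` regulates
gene ``j`` (an edge i -> j).  The in-degree of a gene is the number of
edges pointing into it, self-loops included; it drives the per-gene
damping factor used by the ranking model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneNetwork",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "aggregate_networks",
    "degree_summary",
    "induced_subnetwork",
    "DegreeSummary",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass
class GeneNetwork:
    """A directed network over gene symbols.

    Parameters
    ----------
    genes
        Unique gene symbols in a fixed order; defines the row/column
        order of ``adjacency``.
    adjacency
        Sparse CSR 0-1 matrix; ``adjacency[i, j] = 1`` means
        ``genes[i]`` links to ``genes[j]``.  Self-loops are permitted.
    """

    genes: list[str]
    adjacency: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        n = len(self.genes)
        if n < 1:
            raise ValueError("a GeneNetwork needs at least one gene")
        if len(set(self.genes)) != n:
            raise ValueError("duplicate gene symbols in network")
        adj = sp.csr_matrix(self.adjacency, dtype=np.int8)
        if adj.shape != (n, n):
            raise ValueError(f"adjacency shape {adj.shape} != ({n}, {n})")
        adj.data[:] = 1  # collapse any duplicate entries to 0-1
        adj.sum_duplicates()
        adj.data[:] = 1
        self.adjacency = adj
        self._index = {g: i for i, g in enumerate(self.genes)}

    # -- constructors -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        genes: Sequence[str] | None = None,
    ) -> "GeneNetwork":
        """Build a network from (source, target) pairs.

        Gene order is first appearance in the edge stream unless an
        explicit ``genes`` sequence is given (which must cover all
        endpoints).  Duplicate edges are collapsed.
        """
        edge_list = list(edges)
        if genes is None:
            seen: dict[str, None] = {}
            for u, v in edge_list:
                seen.setdefault(u)
                seen.setdefault(v)
            genes = list(seen)
        if not genes:
            raise ValueError("no genes")
        index = {g: i for i, g in enumerate(genes)}
        rows = [index[u] for u, v in edge_list]
        cols = [index[v] for u, v in edge_list]
        n = len(genes)
        adj = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
        )
        return cls(list(genes), adj)

    # -- basic queries ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    @property
    def in_degree(self) -> np.ndarray:
        """Number of incoming edges per gene (self-loops counted)."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel().astype(np.int64)

    @property
    def out_degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edges(self) -> Iterator[tuple[str, str]]:
        coo = self.adjacency.tocoo()
        for i, j in zip(coo.row, coo.col):
            yield self.genes[i], self.genes[j]

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.genes == other.genes and self.edge_set() == other.edge_set()

    # -- derived networks ---------------------------------------------

    def with_genes(self, extra: Iterable[str]) -> "GeneNetwork":
        """Return a network extended with ``extra`` genes as isolated nodes.

        Genes already present are ignored; isolated genes have zero
        in-degree, so the ranking model scores them purely by their own
        differential expression.
        """
        new = [g for g in dict.fromkeys(extra) if g not in self._index]
        if not new:
            return self
        n_old, n_new = self.n_genes, self.n_genes + len(new)
        adj = sp.csr_matrix(self.adjacency, copy=True)
        adj.resize((n_new, n_new))
        return GeneNetwork(self.genes + new, adj)

    def transpose(self) -> "GeneNetwork":
        """Network with every edge reversed (same gene order)."""
        return GeneNetwork(list(self.genes), self.adjacency.T.tocsr())


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            yield from fh
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        yield from source
    else:  # iterable of lines
        yield from source


def read_edge_list(source, format: str = "auto") -> GeneNetwork:
    """Parse a 2- or 3-column tab-separated edge list.

    ``two_col`` lines are ``source<TAB>target``; ``three_col`` lines are
    ``source<TAB>interaction<TAB>target``.  With ``format="auto"`` the
    first data line fixes the column count.  Lines starting with ``#``
    and blank lines are skipped.  Duplicate edges are collapsed;
    self-loops are retained.
    """
    if format not in ("auto", "two_col", "three_col"):
        raise ValueError(f"unknown edge-list format {format!r}")
    want = {"two_col": 2, "three_col": 3}.get(format)
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if want is None:
            if len(fields) not in (2, 3):
                raise EdgeListParseError(
                    f"line {lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            want = len(fields)
        if len(fields) != want:
            raise EdgeListParseError(
                f"line {lineno}: expected {want} tab-separated fields, "
                f"got {len(fields)}"
            )
        if want == 2:
            u, v = fields
        else:
            u, _, v = fields
        if not u or not v:
            raise EdgeListParseError(f"line {lineno}: empty gene symbol")
        edges.append((u, v))
    if not edges:
        raise EdgeListParseError("empty edge list")
    return GeneNetwork.from_edges(edges)


def write_edge_list(network: GeneNetwork, dest) -> None:
    """Write a canonical 2-column edge list, lexicographically sorted."""
    lines = sorted(f"{u}\t{v}\n" for u, v in network.edges())
    if isinstance(dest, (str, Path)):
        with open(dest, "wt", encoding="utf-8") as fh:
            fh.writelines(lines)
    else:
        dest.writelines(lines)


def aggregate_networks(networks: Sequence[GeneNetwork]) -> GeneNetwork:
    """Union several networks; redundant edges collapse to single edges.

    Gene order is first appearance across the inputs.
    """
    if not networks:
        raise ValueError("need at least one network to aggregate")
    genes: dict[str, None] = {}
    for net in networks:
        for g in net.genes:
            genes.setdefault(g)
    edges: dict[tuple[str, str], None] = {}
    for net in networks:
        for e in net.edges():
            edges.setdefault(e)
    return GeneNetwork.from_edges(list(edges), genes=list(genes))


@dataclass
class DegreeSummary:
    """Degree statistics for genes inside versus outside a gene set."""

    table: pd.DataFrame
    n_unmatched: int


def _degree_stats(out_deg: np.ndarray, in_deg: np.ndarray) -> dict[str, float]:
    if out_deg.size == 0:
        nan = float("nan")
        return {
            "n_genes": 0,
            "out_mean": nan,
            "out_median": nan,
            "in_mean": nan,
            "in_median": nan,
        }
    return {
        "n_genes": int(out_deg.size),
        "out_mean": float(np.mean(out_deg)),
        "out_median": float(np.median(out_deg)),
        "in_mean": float(np.mean(in_deg)),
        "in_median": float(np.median(in_deg)),
    }


def degree_summary(network: GeneNetwork, gene_set: Iterable[str]) -> DegreeSummary:
    """Mean/median in- and out-degree inside vs outside ``gene_set``.

    Symbols in ``gene_set`` absent from the network are ignored but
    counted in ``n_unmatched``.
    """
    gene_set = set(gene_set)
    matched = gene_set & set(network.genes)
    n_unmatched = len(gene_set) - len(matched)
    inside = np.array([network.index_of(g) for g in sorted(matched)], dtype=int)
    mask = np.zeros(network.n_genes, dtype=bool)
    mask[inside] = True
    out_deg, in_deg = network.out_degree, network.in_degree
    table = pd.DataFrame(
        [
            _degree_stats(out_deg[mask], in_deg[mask]),
            _degree_stats(out_deg[~mask], in_deg[~mask]),
        ],
        index=["inside", "outside"],
    )
    return DegreeSummary(table=table, n_unmatched=n_unmatched)


def induced_subnetwork(network: GeneNetwork, keep: Iterable[str]) -> GeneNetwork:
    """Restrict to genes in ``keep`` and edges with both endpoints kept."""
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty")
    kept = [g for g in network.genes if g in keep]
    if not kept:
        raise ValueError("no gene in the keep set is present in the network")
    idx = np.array([network.index_of(g) for g in kept], dtype=int)
    sub = network.adjacency[np.ix_(idx, idx)].tocsr()
    return GeneNetwork(kept, sub)
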