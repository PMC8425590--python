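"""Annotated-network data model, file I/O and descriptive statistics.

The central object is :class:`AnnotatedNetwork`, a four-part bundle of
protein identifiers, a symmetric binary adjacency matrix, per-protein
annotation lists of ``(category, value)`` pairs, and the catalog of
categories with their admissible values.

File formats are deliberately plain: a two-column whitespace-separated
edge list, and a three-column TSV annotation table (``protein``,
``category``, ``value``).  GAF 2.x is accepted through a reader flag,
mapping the aspect column (P/F/C) to the category and the GO ID to the
value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

ANNOTATION_HEADER = ("protein", "category", "value")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass
class GOCatalog:
    """Catalog of annotation categories and their value domains.

    Parameters
    ----------
    categories
        Ordered unique category identifiers.
    domains
        For each category, the ordered list of admissible values.
    """

    categories: list[str]
    domains: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.categories) != len(set(self.categories)):
            raise ValueError("category identifiers must be unique")
        if len(self.domains) != len(self.categories):
            raise ValueError("one domain list required per category")
        for cat, dom in zip(self.categories, self.domains):
            if not dom:
                raise ValueError(f"category {cat!r} has an empty domain")
            if len(dom) != len(set(dom)):
                raise ValueError(f"category {cat!r} has duplicate domain values")
        self._cat_index = {c: m for m, c in enumerate(self.categories)}
        self._val_index = [
            {v: t for t, v in enumerate(dom)} for dom in self.domains
        ]

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def domain_sizes(self) -> list[int]:
        return [len(d) for d in self.domains]

    def category_index(self, category: str) -> int:
        return self._cat_index[category]

    def value_index(self, category: str, value: str) -> int:
        return self._val_index[self._cat_index[category]][value]

    def domain(self, category: str) -> list[str]:
        return self.domains[self._cat_index[category]]

    @classmethod
    def from_annotations(
        cls, annotations: Iterable[tuple[str, str, str]]
    ) -> "GOCatalog":
        """Build a catalog from observed (protein, category, value) rows."""
        seen: dict[str, set[str]] = {}
        for _, cat, val in annotations:
            seen.setdefault(cat, set()).add(val)
        categories = sorted(seen)
        domains = [sorted(seen[c]) for c in categories]
        return cls(categories=categories, domains=domains)


@dataclass
class AnnotatedNetwork:
    """Undirected PPI network with per-protein categorical annotations.

    ``proteins`` is the sorted list of identifiers; all matrix/array
    structures are indexed 0-based over that order.  ``annotations[i]``
    is the (possibly empty) list of ``(category, value)`` pairs of
    protein ``proteins[i]``.
    """

    proteins: list[str]
    adjacency: np.ndarray
    annotations: list[list[tuple[str, str]]]
    catalog: GOCatalog

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        self._index = {p: i for i, p in enumerate(self.proteins)}
        self._neighbors: list[np.ndarray] | None = None
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        annotations: Iterable[tuple[str, str, str]] = (),
        extra_proteins: Iterable[str] = (),
        catalog: GOCatalog | None = None,
    ) -> "AnnotatedNetwork":
        """Build a network from edge pairs plus optional annotation rows.

        Self-loops are dropped with a warning; duplicate and reversed
        edges collapse.  Proteins seen only in annotations or in
        ``extra_proteins`` become isolated nodes.
        """
        ann_rows = list(annotations)
        protein_set: set[str] = set(extra_proteins)
        edge_set: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                logger.warning("dropping self-loop on protein %r", a)
                protein_set.add(a)
                continue
            protein_set.update((a, b))
            edge_set.add((a, b) if a < b else (b, a))
        protein_set.update(row[0] for row in ann_rows)
        proteins = sorted(protein_set)
        index = {p: i for i, p in enumerate(proteins)}
        n = len(proteins)
        adjacency = np.zeros((n, n), dtype=np.int8)
        for a, b in edge_set:
            adjacency[index[a], index[b]] = 1
            adjacency[index[b], index[a]] = 1
        per_protein: list[list[tuple[str, str]]] = [[] for _ in range(n)]
        for prot, cat, val in ann_rows:
            per_protein[index[prot]].append((cat, val))
        if catalog is None:
            catalog = GOCatalog.from_annotations(ann_rows) if ann_rows else GOCatalog([], [])
        return cls(
            proteins=proteins,
            adjacency=adjacency,
            annotations=per_protein,
            catalog=catalog,
        )

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        n = len(self.proteins)
        if len(self._index) != n:
            raise ValueError("protein identifiers must be unique")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match protein count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if len(self.annotations) != n:
            raise ValueError("one annotation list required per protein")
        for i, ann in enumerate(self.annotations):
            for cat, val in ann:
                if cat not in self.catalog._cat_index:
                    raise ValueError(
                        f"protein {self.proteins[i]!r}: unknown category {cat!r}"
                    )
                if val not in self.catalog.domain(cat):
                    raise ValueError(
                        f"protein {self.proteins[i]!r}: value {val!r} "
                        f"outside domain of {cat!r}"
                    )

    # -- accessors -----------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index(self, protein: str) -> int:
        try:
            return self._index[protein]
        except KeyError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def degree(self, i: int) -> int:
        return int(self.adjacency[i].sum())

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted neighbor indices of node ``i`` (cached)."""
        if self._neighbors is None:
            self._neighbors = [
                np.flatnonzero(self.adjacency[j]) for j in range(self.n_proteins)
            ]
        return self._neighbors[i]

    def edges(self) -> list[tuple[int, int]]:
        """Index pairs (i < j) of all edges."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return list(zip(ii.tolist(), jj.tolist()))

    def edge_ids(self) -> list[tuple[str, str]]:
        return [(self.proteins[i], self.proteins[j]) for i, j in self.edges()]

    def has_edge(self, a: str, b: str) -> bool:
        return bool(self.adjacency[self.index(a), self.index(b)])

    def without_edges(self, pairs: Iterable[tuple[str, str]]) -> "AnnotatedNetwork":
        """Copy of the network with the given edges removed."""
        adjacency = self.adjacency.copy()
        for a, b in pairs:
            i, j = self.index(a), self.index(b)
            adjacency[i, j] = 0
            adjacency[j, i] = 0
        return AnnotatedNetwork(
            proteins=list(self.proteins),
            adjacency=adjacency,
            annotations=[list(a) for a in self.annotations],
            catalog=self.catalog,
        )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_proteins))
        g.add_edges_from(self.edges())
        return g


@dataclass
class NetworkStats:
    """Headline descriptive statistics of a network."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    clustering: float


def network_stats(net: AnnotatedNetwork) -> NetworkStats:
    """Node/edge counts, mean degree 2E/N and mean local clustering.

    Nodes of degree < 2 contribute a local clustering coefficient of 0
    (the Watts-Strogatz convention).
    """
    if net.n_proteins == 0:
        raise ValueError("network is empty")
    n, e = net.n_proteins, net.n_edges
    cc = nx.average_clustering(net.to_graph(), count_zeros=True)
    return NetworkStats(
        n_nodes=n, n_edges=e, avg_degree=2.0 * e / n, clustering=float(cc)
    )


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------


def _read_edge_lines(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
    return edges


def _read_annotation_table(path: str | Path) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and tuple(f.lower() for f in fields) == ANNOTATION_HEADER:
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            rows.append((fields[0], fields[1], fields[2]))
    return rows


_GAF_ASPECTS = {"P", "F", "C"}


def _read_gaf(path: str | Path) -> list[tuple[str, str, str]]:
    """GAF 2.x: column 2 = DB Object ID, 5 = GO ID, 9 = Aspect."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 9 GAF columns, got {len(fields)}"
                )
            aspect = fields[8]
            if aspect not in _GAF_ASPECTS:
                raise ParseError(f"{path}:{lineno}: unknown aspect {aspect!r}")
            rows.append((fields[1], aspect, fields[4]))
    return rows


def read_network(
    edge_path: str | Path,
    annotation_path: str | Path | None = None,
    gaf: bool = False,
) -> AnnotatedNetwork:
    """Read an edge list plus optional annotations into a network.

    Duplicate edges collapse; self-loops are dropped with a warning;
    proteins appearing only in the annotation file are kept as isolated
    nodes.  An empty edge list is an error.
    """
    edges = _read_edge_lines(edge_path)
    if not edges:
        raise ParseError(f"{edge_path}: empty edge list")
    annotations: list[tuple[str, str, str]] = []
    if annotation_path is not None:
        reader = _read_gaf if gaf else _read_annotation_table
        annotations = reader(annotation_path)
    return AnnotatedNetwork.from_edges(edges, annotations)


def write_network(
    net: AnnotatedNetwork,
    edge_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write the edge list and the annotation table (round-trip safe)."""
    with open(edge_path, "w") as fh:
        for a, b in net.edge_ids():
            fh.write(f"{a}\t{b}\n")
    with open(annotation_path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for prot, ann in zip(net.proteins, net.annotations):
            for cat, val in ann:
                fh.write(f"{prot}\t{cat}\t{val}\n")
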