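"""Membership-weighted, decay-penalized path scoring for protein pairs.

A candidate pair is scored by summing, over all simple paths between
the two proteins with at least one and at most ``max_interior``
intermediate proteins, the product of the intermediates' memberships in
the query's module divided by a length decay.  The module is the argmax
module of the *first* protein of the pair.

The direct edge itself is never a scoring path, so known interactions
do not trivially score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .infer import MembershipMatrix, derive_labels
from .netio import AnnotatedNetwork

__all__ = [
    "Path",
    "ScoredPair",
    "enumerate_paths",
    "path_weight",
    "path_decay",
    "score_pair",
    "score_pairs",
    "brute_force_score",
]


@dataclass(frozen=True)
class Path:
    """A simple path between two query proteins, as node indices."""

    nodes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(set(self.nodes)):
            raise ValueError("path nodes must be distinct")

    @property
    def n_interior(self) -> int:
        return len(self.nodes) - 2

    @property
    def interior(self) -> tuple[int, ...]:
        return self.nodes[1:-1]


@dataclass(frozen=True)
class ScoredPair:
    pair: tuple[str, str]
    score: float
    n_paths: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be nonnegative")
        if (self.score == 0) != (self.n_paths == 0) and self.n_paths == 0:
            raise ValueError("zero paths must give zero score")


def _node_index(net: AnnotatedNetwork, node: str | int) -> int:
    if isinstance(node, str):
        return net.index(node)
    if not 0 <= node < net.n_proteins:
        raise KeyError(f"node index {node} out of range")
    return int(node)


def enumerate_paths(
    net: AnnotatedNetwork, i: str | int, j: str | int, max_interior: int
) -> list[Path]:
    """All simple i-j paths with 1..max_interior interior proteins.

    Output order is lexicographic by node sequence (DFS over sorted
    neighbor lists); the direct edge is excluded.
    """
    if max_interior < 1:
        raise ValueError("max_interior must be >= 1")
    src = _node_index(net, i)
    dst = _node_index(net, j)
    if src == dst:
        raise ValueError("source and target must differ")
    paths: list[Path] = []
    stack = [src]
    on_path = {src}

    def _walk(u: int, interior: int) -> None:
        for v in net.neighbors(u):
            v = int(v)
            if v == dst:
                if interior >= 1:
                    paths.append(Path(nodes=tuple(stack) + (dst,)))
            elif v not in on_path and interior < max_interior:
                stack.append(v)
                on_path.add(v)
                _walk(v, interior + 1)
                on_path.remove(v)
                stack.pop()

    _walk(src, 0)
    return paths


def path_weight(
    path: Path, membership: MembershipMatrix | np.ndarray, k: int
) -> float:
    """Product of interior proteins' memberships in module k (1-based)."""
    values = (
        membership.values
        if isinstance(membership, MembershipMatrix)
        else np.asarray(membership)
    )
    if not 1 <= k <= values.shape[1]:
        raise ValueError(f"module index {k} out of range 1..{values.shape[1]}")
    weight = 1.0
    for z in path.interior:
        weight *= float(values[z, k - 1])
    return weight


def path_decay(n_interior: int, phi: float, mode: str = "linear") -> float:
    """Length penalty: phi * n (linear, default) or phi ** n (exp)."""
    if n_interior < 1:
        raise ValueError("decay is undefined for paths without interior proteins")
    if phi < 1:
        raise ValueError("phi must be >= 1")
    if mode == "linear":
        return phi * n_interior
    if mode == "exp":
        return float(phi) ** n_interior
    raise ValueError(f"unknown decay mode {mode!r}")


def _path_length_for_decay(n_interior: int, lw_mode: str) -> int:
    if lw_mode == "interior":
        return n_interior
    if lw_mode == "total":
        return n_interior + 2
    raise ValueError(f"unknown lw mode {lw_mode!r}")


def score_pair(
    net: AnnotatedNetwork,
    membership: MembershipMatrix | np.ndarray,
    i: str | int,
    j: str | int,
    phi: float = 1.0,
    max_interior: int = 3,
    decay_mode: str = "linear",
    lw_mode: str = "interior",
) -> ScoredPair:
    """Sum of weight/decay over all admissible i-j paths.

    The module is fixed to the argmax module of protein ``i``.  Pairs
    with no admissible path score exactly 0.
    """
    src = _node_index(net, i)
    dst = _node_index(net, j)
    if src == dst:
        raise ValueError("source and target must differ")
    values = (
        membership.values
        if isinstance(membership, MembershipMatrix)
        else np.asarray(membership)
    )
    k = int(derive_labels(values)[src])
    col = values[:, k - 1]

    total = 0.0
    n_paths = 0
    on_path = {src}

    def _walk(u: int, interior: int, weight: float) -> None:
        nonlocal total, n_paths
        for v in net.neighbors(u):
            v = int(v)
            if v == dst:
                if interior >= 1:
                    decay = path_decay(
                        _path_length_for_decay(interior, lw_mode), phi, decay_mode
                    )
                    total += weight / decay
                    n_paths += 1
            elif v not in on_path and interior < max_interior:
                on_path.add(v)
                _walk(v, interior + 1, weight * float(col[v]))
                on_path.remove(v)

    _walk(src, 0, 1.0)
    pair_ids = (
        net.proteins[src] if isinstance(i, int) else i,
        net.proteins[dst] if isinstance(j, int) else j,
    )
    return ScoredPair(pair=pair_ids, score=total, n_paths=n_paths)


def score_pairs(
    net: AnnotatedNetwork,
    membership: MembershipMatrix | np.ndarray,
    pairs,
    phi: float = 1.0,
    max_interior: int = 3,
    decay_mode: str = "linear",
    lw_mode: str = "interior",
) -> list[ScoredPair]:
    """Element-wise :func:`score_pair`; order-independent by construction."""
    return [
        score_pair(net, membership, a, b, phi, max_interior, decay_mode, lw_mode)
        for a, b in pairs
    ]


def brute_force_score(
    net: AnnotatedNetwork,
    membership: MembershipMatrix | np.ndarray,
    i: str | int,
    j: str | int,
    phi: float = 1.0,
    max_interior: int = 3,
    decay_mode: str = "linear",
    lw_mode: str = "interior",
) -> float:
    """Independent exhaustive oracle over networkx's simple-path iterator."""
    src = _node_index(net, i)
    dst = _node_index(net, j)
    values = (
        membership.values
        if isinstance(membership, MembershipMatrix)
        else np.asarray(membership)
    )
    k = int(np.argmax(values[src])) + 1
    g = net.to_graph()
    total = 0.0
    for nodes in nx.all_simple_paths(g, src, dst, cutoff=max_interior + 1):
        n_interior = len(nodes) - 2
        if n_interior < 1:
            continue
        weight = 1.0
        for z in nodes[1:-1]:
            weight *= float(values[z, k - 1])
        decay = path_decay(_path_length_for_decay(n_interior, lw_mode), phi, decay_mode)
        total += weight / decay
    return total
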