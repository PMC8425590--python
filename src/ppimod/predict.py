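"""Rank-window calibration of raw pair scores into probabilities.

All scored pairs — known interactions from the training network and
candidate pairs alike — are ranked by score.  A pair's probability is
the fraction of known interactions among its ``half_width`` upper and
``half_width`` lower rank neighbors (the pair itself excluded, windows
truncated at the ends of the board).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .infer import MembershipMatrix
from .netio import AnnotatedNetwork
from .score import score_pair

__all__ = [
    "BoardEntry",
    "RankedScoreboard",
    "build_scoreboard",
    "window_probability",
    "predict_probabilities",
    "canonical_pair",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Sorted-identifier form of an unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class BoardEntry:
    pair: tuple[str, str]
    score: float
    is_known_ppi: bool


@dataclass
class RankedScoreboard:
    """Score-descending board of pairs; ties ordered by canonical pair id."""

    entries: list[BoardEntry]
    half_width: int = 50

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        key = [(-e.score, e.pair) for e in self.entries]
        if key != sorted(key):
            raise ValueError("entries must be sorted by descending score")
        self._rank = {e.pair: r for r, e in enumerate(self.entries)}
        if len(self._rank) != len(self.entries):
            raise ValueError("duplicate pairs on the board")

    def rank(self, pair: tuple[str, str]) -> int:
        cp = canonical_pair(*pair)
        try:
            return self._rank[cp]
        except KeyError:
            raise KeyError(f"pair {cp} not on the scoreboard") from None

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in self._rank

    def __len__(self) -> int:
        return len(self.entries)


def build_scoreboard(
    train_net: AnnotatedNetwork,
    membership: MembershipMatrix,
    candidate_pairs: Iterable[tuple[str, str]],
    phi: float = 1.0,
    max_interior: int = 3,
    half_width: int = 50,
    decay_mode: str = "linear",
    lw_mode: str = "interior",
) -> RankedScoreboard:
    """Score training edges plus candidates and rank them together.

    Training edges are flagged as known interactions; a candidate that
    happens to be a training edge inherits the flag.  Pairs are scored
    in canonical (sorted-identifier) order for reproducibility.
    """
    pairs: dict[tuple[str, str], bool] = {}
    for a, b in train_net.edge_ids():
        pairs[canonical_pair(a, b)] = True
    for a, b in candidate_pairs:
        cp = canonical_pair(a, b)
        if cp not in pairs:
            pairs[cp] = train_net.has_edge(*cp)
    entries = []
    for cp, known in pairs.items():
        sp = score_pair(
            train_net, membership, cp[0], cp[1], phi, max_interior,
            decay_mode, lw_mode,
        )
        entries.append(BoardEntry(pair=cp, score=sp.score, is_known_ppi=known))
    entries.sort(key=lambda e: (-e.score, e.pair))
    return RankedScoreboard(entries=entries, half_width=half_width)


def window_probability(board: RankedScoreboard, pair: tuple[str, str]) -> float:
    """Fraction of known interactions in the pair's rank window.

    The window spans up to ``half_width`` entries above and below the
    pair's rank, truncated at the board's ends; the queried pair itself
    never counts.  An empty window gives probability 0.
    """
    r = board.rank(pair)
    lo = max(0, r - board.half_width)
    hi = min(len(board), r + board.half_width + 1)
    window = [e for idx in range(lo, hi) if idx != r for e in (board.entries[idx],)]
    if not window:
        return 0.0
    return sum(e.is_known_ppi for e in window) / len(window)


def predict_probabilities(
    board: RankedScoreboard, query_pairs: Sequence[tuple[str, str]]
) -> list[tuple[tuple[str, str], float]]:
    """Window probability per query.

    Pairs absent from the board, and pairs whose raw score is 0 (no
    connecting path), get probability 0 — without a path the method
    cannot support an interaction.
    """
    score_of = {e.pair: e.score for e in board.entries}
    out = []
    for a, b in query_pairs:
        cp = canonical_pair(a, b)
        if cp in board and score_of[cp] > 0.0:
            prob = window_probability(board, cp)
        else:
            prob = 0.0
        out.append((cp, prob))
    return out
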