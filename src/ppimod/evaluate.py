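"""Evaluation harness: cross-validated link prediction with constrained
negative sampling and standard classification/ranking metrics.

Negative pairs are drawn once per network: a fixed number must contain
at least one protein from the top candidate pairs of a degree-normalized
length-3-path baseline, the remainder uniformly from pairs touching no
such protein.  Positive edges are split into folds; each fold's edges
are removed from the training adjacency before inference, then test
positives and negatives are scored and calibrated and metrics computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .generate import Hyperparams
from .infer import fit
from .netio import AnnotatedNetwork
from .predict import build_scoreboard, canonical_pair, predict_probabilities

__all__ = [
    "EvaluationReport",
    "l3_score",
    "l3_matrix",
    "sample_negatives",
    "classification_metrics",
    "ranking_metrics",
    "five_fold_cv",
    "k_sweep",
]

METRIC_NAMES = ("precision", "recall", "f_measure", "roc_auc", "pr_auc")


@dataclass
class EvaluationReport:
    folds: list[list[tuple[str, str]]]
    negatives: list[tuple[str, str]]
    threshold: float
    per_fold: list[dict[str, float]]
    mean: dict[str, float]


# ---------------------------------------------------------------------
# L3 baseline
# ---------------------------------------------------------------------


def l3_score(net: AnnotatedNetwork, i: str | int, j: str | int) -> float:
    """Degree-normalized count of length-3 paths between i and j.

    Sum over intermediate edges (x, y) with i-x and y-j edges of
    1/sqrt(deg(x) deg(y)).
    """
    a = net.index(i) if isinstance(i, str) else i
    b = net.index(j) if isinstance(j, str) else j
    if a == b:
        raise ValueError("proteins must differ")
    total = 0.0
    for x in net.neighbors(a):
        dx = net.degree(int(x))
        for y in net.neighbors(int(x)):
            if net.adjacency[int(y), b]:
                total += 1.0 / np.sqrt(dx * net.degree(int(y)))
    return total


def l3_matrix(net: AnnotatedNetwork) -> np.ndarray:
    """All-pairs L3 scores via A @ (D^-1/2 A D^-1/2) @ A."""
    A = np.asarray(net.adjacency, dtype=float)
    deg = A.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    Aw = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    return A @ Aw @ A


def _non_adjacent_pairs(net: AnnotatedNetwork) -> list[tuple[int, int]]:
    A = net.adjacency
    n = net.n_proteins
    mask = np.triu(np.ones((n, n), dtype=bool), k=1) & (A == 0)
    ii, jj = np.nonzero(mask)
    return list(zip(ii.tolist(), jj.tolist()))


def top_l3_proteins(net: AnnotatedNetwork, top_n: int = 500) -> set[str]:
    """Proteins occurring in the top_n non-adjacent pairs by L3 score."""
    scores = l3_matrix(net)
    pool = _non_adjacent_pairs(net)
    ranked = sorted(
        pool,
        key=lambda p: (-scores[p[0], p[1]], net.proteins[p[0]], net.proteins[p[1]]),
    )
    out: set[str] = set()
    for a, b in ranked[:top_n]:
        out.add(net.proteins[a])
        out.add(net.proteins[b])
    return out


def sample_negatives(
    net: AnnotatedNetwork,
    rng_seed=None,
    n_total: int = 244,
    n_constrained: int = 100,
    top_n: int = 500,
) -> list[tuple[str, str]]:
    """Draw non-adjacent pairs; a fixed quota must touch baseline-top proteins.

    Exactly ``n_constrained`` of the ``n_total`` returned pairs contain
    at least one protein from the top ``top_n`` L3-ranked candidate
    pairs; the rest are uniform over pairs touching none of them.
    """
    if n_constrained > n_total:
        raise ValueError("n_constrained cannot exceed n_total")
    rng = np.random.default_rng(rng_seed)
    hot = top_l3_proteins(net, top_n)
    pool = _non_adjacent_pairs(net)
    constrained = []
    unconstrained = []
    for a, b in pool:
        pa, pb = net.proteins[a], net.proteins[b]
        if pa in hot or pb in hot:
            constrained.append(canonical_pair(pa, pb))
        else:
            unconstrained.append(canonical_pair(pa, pb))
    n_free = n_total - n_constrained
    if len(constrained) < n_constrained or len(unconstrained) < n_free:
        raise ValueError(
            f"infeasible negative sample: need {n_constrained} constrained "
            f"(have {len(constrained)}) and {n_free} unconstrained "
            f"(have {len(unconstrained)}) non-adjacent pairs"
        )
    picked_c = [constrained[t] for t in rng.choice(len(constrained), n_constrained, replace=False)]
    picked_u = [unconstrained[t] for t in rng.choice(len(unconstrained), n_free, replace=False)]
    return picked_c + picked_u


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------


def classification_metrics(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> tuple[float, float, float]:
    """(precision, recall, f_measure) at a probability threshold.

    Degenerate denominators yield 0 by convention.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def ranking_metrics(
    probabilities: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """(ROC-AUC, PR-AUC); ROC uses the tie-corrected Mann-Whitney form,
    PR uses the average-precision step convention."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, probs)), float(average_precision_score(y, probs))


# ---------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------


def make_folds(
    net: AnnotatedNetwork, n_folds: int, rng_seed=None
) -> list[list[tuple[str, str]]]:
    """Random partition of the positive edges into n_folds test sets."""
    edges = net.edge_ids()
    if len(edges) < n_folds:
        raise ValueError(f"need at least {n_folds} edges")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(edges))
    folds: list[list[tuple[str, str]]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(edges[idx])
    if any(not f for f in folds):
        raise ValueError("a fold has no test edges")
    return folds


def _evaluate_fold(
    net: AnnotatedNetwork,
    test_edges: list[tuple[str, str]],
    negatives: list[tuple[str, str]],
    hyper: Hyperparams,
    K: int,
    phi: float,
    threshold: float,
    max_interior: int,
    half_width: int,
    fit_kwargs: dict,
    rng_seed,
) -> dict[str, float]:
    train = net.without_edges(test_edges)
    result = fit(train, K, hyper, rng_seed=rng_seed, **fit_kwargs)
    candidates = [canonical_pair(*p) for p in test_edges + list(negatives)]
    board = build_scoreboard(
        train, result.membership, candidates,
        phi=phi, max_interior=max_interior, half_width=half_width,
    )
    queries = candidates
    probs = [p for _, p in predict_probabilities(board, queries)]
    labels = [1] * len(test_edges) + [0] * len(negatives)
    precision, recall, f = classification_metrics(probs, labels, threshold)
    roc, pr = ranking_metrics(probs, labels)
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f,
        "roc_auc": roc,
        "pr_auc": pr,
    }


def five_fold_cv(
    net: AnnotatedNetwork,
    hyper: Hyperparams,
    K: int,
    phi: float = 1.0,
    rng_seed=None,
    n_folds: int = 5,
    threshold: float = 0.5,
    max_interior: int = 3,
    half_width: int = 50,
    n_negatives: int = 244,
    n_constrained: int = 100,
    l3_top: int = 500,
    folds: list[list[tuple[str, str]]] | None = None,
    negatives: list[tuple[str, str]] | None = None,
    fit_kwargs: dict | None = None,
) -> EvaluationReport:
    """Cross-validated evaluation of the full prediction pipeline.

    Negatives are drawn once on the full network and reused across
    folds; per fold the test edges are removed from the training
    adjacency before fitting.  ``folds``/``negatives`` may be supplied
    to share them across runs (used by :func:`k_sweep`).
    """
    fit_kwargs = dict(fit_kwargs or {})
    seq = np.random.SeedSequence(rng_seed)
    s_fold, s_neg, s_fit = seq.spawn(3)
    if folds is None:
        folds = make_folds(net, n_folds, np.random.default_rng(s_fold))
    if negatives is None:
        negatives = sample_negatives(
            net, np.random.default_rng(s_neg),
            n_total=n_negatives, n_constrained=n_constrained, top_n=l3_top,
        )
    fit_seeds = s_fit.spawn(len(folds))
    per_fold = []
    for fold_edges, seed in zip(folds, fit_seeds):
        per_fold.append(
            _evaluate_fold(
                net, fold_edges, negatives, hyper, K, phi, threshold,
                max_interior, half_width, fit_kwargs,
                np.random.default_rng(seed),
            )
        )
    mean = {
        name: float(np.mean([m[name] for m in per_fold])) for name in METRIC_NAMES
    }
    return EvaluationReport(
        folds=folds,
        negatives=list(negatives),
        threshold=threshold,
        per_fold=per_fold,
        mean=mean,
    )


def k_sweep(
    net: AnnotatedNetwork,
    hyper_factory,
    K_values: Sequence[int],
    phi: float = 1.0,
    rng_seed=None,
    **cv_kwargs,
) -> list[dict]:
    """Run the cross-validation once per K with shared folds/negatives.

    ``hyper_factory`` maps K to a :class:`Hyperparams`; rows carry the
    K, the mean metrics, and the shared fold assignment.
    """
    if not K_values:
        raise ValueError("K_values must be non-empty")
    seq = np.random.SeedSequence(rng_seed)
    s_fold, s_neg, s_cv = seq.spawn(3)
    n_folds = cv_kwargs.get("n_folds", 5)
    folds = make_folds(net, n_folds, np.random.default_rng(s_fold))
    negatives = sample_negatives(
        net,
        np.random.default_rng(s_neg),
        n_total=cv_kwargs.get("n_negatives", 244),
        n_constrained=cv_kwargs.get("n_constrained", 100),
        top_n=cv_kwargs.get("l3_top", 500),
    )
    rows = []
    for K in K_values:
        hyper = hyper_factory(K) if callable(hyper_factory) else Hyperparams(K=K)
        report = five_fold_cv(
            net, hyper, K, phi=phi,
            rng_seed=np.random.default_rng(s_cv.spawn(1)[0]).integers(2**31),
            folds=folds, negatives=negatives, **cv_kwargs,
        )
        row = {"K": K, "folds": folds}
        row.update(report.mean)
        rows.append(row)
    return rows
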