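"""Generative model for annotated PPI networks and its simulator.

The model has K latent functional modules.  Module proportions come
from a Dirichlet prior; each protein draws a module label, then draws
annotations in two stages (category from a per-module multinomial,
value from a per-module-per-category multinomial) and edges from a
stochastic block model whose block probabilities carry Beta priors.

One global seed drives a hierarchical RNG: each sampler gets its own
child stream so the sub-samplers are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .netio import AnnotatedNetwork, GOCatalog

__all__ = [
    "Hyperparams",
    "ModelParams",
    "sample_params",
    "sample_labels",
    "sample_annotations",
    "sample_adjacency",
    "generate",
    "planted_params",
]


@dataclass
class Hyperparams:
    """Prior hyperparameters of the generative model.

    ``zeta``, ``lam`` and ``mu`` may be scalars (broadcast to the
    required shape) or full arrays.  ``tau`` is a pair of Beta shape
    parameters shared by all module pairs, or a (K, K, 2) array that
    must be symmetric in its first two axes.

    ``annotation_rule`` controls the number of annotations per protein:
    ``"fixed"`` gives exactly ``annotation_count`` each, ``"poisson"``
    draws Poisson(``annotation_count``) counts.  ``phi`` is the path
    decay coefficient consumed by the scoring stage.
    """

    K: int
    zeta: float | np.ndarray = 1.0
    lam: float | np.ndarray = 1.0
    mu: float | Sequence[np.ndarray] = 1.0
    tau: tuple[float, float] | np.ndarray = (1.0, 1.0)
    annotation_rule: str = "poisson"
    annotation_count: float = 5.0
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.phi < 1:
            raise ValueError("phi must be >= 1")
        if self.annotation_rule not in ("fixed", "poisson"):
            raise ValueError("annotation_rule must be 'fixed' or 'poisson'")
        if self.annotation_count < 0:
            raise ValueError("annotation_count must be >= 0")
        for name in ("zeta", "lam", "mu", "tau"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr <= 0):
                raise ValueError(f"{name} concentrations must be positive")

    # -- broadcast helpers --------------------------------------------

    def zeta_vector(self) -> np.ndarray:
        z = np.broadcast_to(np.asarray(self.zeta, dtype=float), (self.K,))
        return np.array(z)

    def lam_matrix(self, n_categories: int) -> np.ndarray:
        lam = np.broadcast_to(
            np.asarray(self.lam, dtype=float), (self.K, n_categories)
        )
        return np.array(lam)

    def mu_vectors(self, domain_sizes: Sequence[int]) -> list[np.ndarray]:
        """Per category m: a (K, |dom(m)|) concentration matrix."""
        if np.isscalar(self.mu):
            return [np.full((self.K, d), float(self.mu)) for d in domain_sizes]
        out = [np.asarray(m, dtype=float) for m in self.mu]
        if len(out) != len(domain_sizes):
            raise ValueError("mu must provide one block per category")
        return out

    def tau_array(self) -> np.ndarray:
        tau = np.asarray(self.tau, dtype=float)
        if tau.shape == (2,):
            tau = np.broadcast_to(tau, (self.K, self.K, 2)).copy()
        if tau.shape != (self.K, self.K, 2):
            raise ValueError("tau must be a pair or a (K, K, 2) array")
        if not np.allclose(tau, np.transpose(tau, (1, 0, 2))):
            raise ValueError("tau must be symmetric in its module axes")
        return np.array(tau)


@dataclass
class ModelParams:
    """A concrete draw of the model's latent variables.

    ``labels`` is 1-based (module k in 1..K) and is ``None`` until
    labels are sampled.
    """

    alpha: np.ndarray
    theta: np.ndarray
    beta: list[np.ndarray]
    epsilon: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        K = self.alpha.shape[0]
        if not np.isclose(self.alpha.sum(), 1.0):
            raise ValueError("alpha must sum to 1")
        if not np.allclose(self.theta.sum(axis=1), 1.0):
            raise ValueError("theta rows must sum to 1")
        for b in self.beta:
            if not np.allclose(np.asarray(b).sum(axis=1), 1.0):
                raise ValueError("beta blocks must be row-stochastic")
        if self.epsilon.shape != (K, K):
            raise ValueError("epsilon must be K x K")
        if not np.allclose(self.epsilon, self.epsilon.T):
            raise ValueError("epsilon must be symmetric")
        if np.any((self.epsilon < 0) | (self.epsilon > 1)):
            raise ValueError("epsilon entries must be in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size and (
                self.labels.min() < 1 or self.labels.max() > K
            ):
                raise ValueError("labels must lie in 1..K")

    @property
    def K(self) -> int:
        return self.alpha.shape[0]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_params(
    hyper: Hyperparams,
    n_categories: int,
    domain_sizes: Sequence[int],
    rng_seed=None,
) -> ModelParams:
    """Draw alpha, theta, beta, epsilon from their priors (no labels).

    Each epsilon entry is drawn once per unordered module pair and
    mirrored, so the matrix is exactly symmetric.
    """
    if n_categories < 1 or any(d < 1 for d in domain_sizes):
        raise ValueError("need at least one category and non-empty domains")
    rng = _rng(rng_seed)
    K = hyper.K
    alpha = rng.dirichlet(hyper.zeta_vector())
    lam = hyper.lam_matrix(n_categories)
    theta = np.vstack([rng.dirichlet(lam[k]) for k in range(K)])
    mu = hyper.mu_vectors(domain_sizes)
    beta = [
        np.vstack([rng.dirichlet(mu[m][k]) for k in range(K)])
        for m in range(n_categories)
    ]
    tau = hyper.tau_array()
    epsilon = np.zeros((K, K))
    for k in range(K):
        for l in range(k, K):
            e = rng.beta(tau[k, l, 0], tau[k, l, 1])
            epsilon[k, l] = epsilon[l, k] = e
    return ModelParams(alpha=alpha, theta=theta, beta=beta, epsilon=epsilon)


def sample_labels(alpha: np.ndarray, n_proteins: int, rng_seed=None) -> np.ndarray:
    """i.i.d. 1-based module labels, P(C_i = k) = alpha_k."""
    alpha = np.asarray(alpha, dtype=float)
    if not np.isclose(alpha.sum(), 1.0):
        raise ValueError("alpha must sum to 1")
    rng = _rng(rng_seed)
    return rng.choice(alpha.size, size=n_proteins, p=alpha) + 1


def sample_annotations(
    labels: np.ndarray,
    theta: np.ndarray,
    beta: list[np.ndarray],
    annotation_rule: str = "poisson",
    annotation_count: float = 5.0,
    rng_seed=None,
) -> list[list[tuple[int, int]]]:
    """Two-stage annotation draws, returned as (category, value) index pairs.

    For each annotation slot of protein i the category is drawn from the
    label's row of ``theta`` and the value from the matching row of that
    category's ``beta`` block.
    """
    rng = _rng(rng_seed)
    labels = np.asarray(labels, dtype=int)
    theta = np.asarray(theta, dtype=float)
    n_categories = theta.shape[1]
    out: list[list[tuple[int, int]]] = []
    for ci in labels:
        k = ci - 1
        if annotation_rule == "fixed":
            count = int(annotation_count)
        else:
            count = int(rng.poisson(annotation_count))
        ann: list[tuple[int, int]] = []
        for _ in range(count):
            m = int(rng.choice(n_categories, p=theta[k]))
            t = int(rng.choice(beta[m].shape[1], p=beta[m][k]))
            ann.append((m, t))
        out.append(ann)
    return out


def sample_adjacency(labels: np.ndarray, epsilon: np.ndarray, rng_seed=None) -> np.ndarray:
    """Bernoulli block-model adjacency: A_ij ~ Bern(eps[C_i, C_j]), i < j."""
    epsilon = np.asarray(epsilon, dtype=float)
    if not np.allclose(epsilon, epsilon.T):
        raise ValueError("epsilon must be symmetric")
    if np.any((epsilon < 0) | (epsilon > 1)):
        raise ValueError("epsilon entries must be in [0, 1]")
    rng = _rng(rng_seed)
    labels = np.asarray(labels, dtype=int) - 1
    n = labels.size
    probs = epsilon[np.ix_(labels, labels)]
    upper = np.triu(rng.random((n, n)) < probs, k=1)
    adj = (upper | upper.T).astype(np.int8)
    return adj


def _category_names(n_categories: int) -> list[str]:
    return [f"cat{m + 1}" for m in range(n_categories)]


def _value_names(n_categories: int, domain_sizes: Sequence[int]) -> list[list[str]]:
    return [
        [f"cat{m + 1}:val{t + 1}" for t in range(domain_sizes[m])]
        for m in range(n_categories)
    ]


def generate(
    hyper: Hyperparams,
    n_proteins: int,
    n_categories: int,
    domain_sizes: Sequence[int],
    rng_seed=None,
    params: ModelParams | None = None,
) -> tuple[AnnotatedNetwork, ModelParams]:
    """Simulate a full annotated network; returns it with ground truth.

    ``params`` may pin the latent variables (labels are redrawn unless
    present); otherwise they are sampled from the priors.  Identical
    seeds give identical output.
    """
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    seq = np.random.SeedSequence(rng_seed)
    s_par, s_lab, s_ann, s_adj = seq.spawn(4)
    if params is None:
        params = sample_params(
            hyper, n_categories, domain_sizes, np.random.default_rng(s_par)
        )
    if params.labels is None:
        labels = sample_labels(
            params.alpha, n_proteins, np.random.default_rng(s_lab)
        )
    else:
        labels = params.labels
    ann_idx = sample_annotations(
        labels,
        params.theta,
        params.beta,
        hyper.annotation_rule,
        hyper.annotation_count,
        np.random.default_rng(s_ann),
    )
    adjacency = sample_adjacency(
        labels, params.epsilon, np.random.default_rng(s_adj)
    )

    width = len(str(n_proteins - 1))
    proteins = [f"P{i:0{width}d}" for i in range(n_proteins)]
    categories = _category_names(n_categories)
    values = _value_names(n_categories, domain_sizes)
    catalog = GOCatalog(categories=categories, domains=values)
    annotations = [
        [(categories[m], values[m][t]) for m, t in ann] for ann in ann_idx
    ]
    net = AnnotatedNetwork(
        proteins=proteins,
        adjacency=adjacency,
        annotations=annotations,
        catalog=catalog,
    )
    full = ModelParams(
        alpha=params.alpha,
        theta=params.theta,
        beta=params.beta,
        epsilon=params.epsilon,
        labels=labels,
    )
    return net, full


def planted_params(
    K: int,
    n_categories: int,
    domain_sizes: Sequence[int],
    eps_in: float,
    eps_out: float,
    sharpness: float = 0.9,
) -> ModelParams:
    """Deterministic well-separated parameters for recovery experiments.

    Uniform module proportions, assortative block probabilities
    (``eps_in`` on the diagonal, ``eps_out`` off it), uniform category
    choice, and value distributions in which module k concentrates mass
    ``sharpness`` on value ``k mod |dom|`` of every category.
    """
    alpha = np.full(K, 1.0 / K)
    theta = np.full((K, n_categories), 1.0 / n_categories)
    beta = []
    for m in range(n_categories):
        d = domain_sizes[m]
        block = np.full((K, d), (1.0 - sharpness) / max(d - 1, 1))
        for k in range(K):
            block[k, k % d] = sharpness if d > 1 else 1.0
        block /= block.sum(axis=1, keepdims=True)
        beta.append(block)
    epsilon = np.full((K, K), eps_out)
    np.fill_diagonal(epsilon, eps_in)
    return ModelParams(alpha=alpha, theta=theta, beta=beta, epsilon=epsilon)
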