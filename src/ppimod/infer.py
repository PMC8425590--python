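"""Posterior module-membership inference by mean-field coordinate ascent.

The variational family factorizes as q(C) q(alpha) q(theta) q(beta)
q(epsilon) with a categorical factor per protein and conjugate
Dirichlet/Beta factors for the global variables.  A sweep updates every
protein's categorical factor sequentially (so each step is an exact
coordinate maximization and the ELBO cannot decrease), then refreshes
the global factors from expected sufficient statistics.

Both channels of evidence enter each protein's update: annotation
counts against the expected log category/value distributions, and
edges *and* non-edges against the expected log block probabilities —
non-edges are required for the block matrix to be identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, digamma, gammaln

from .generate import Hyperparams
from .netio import AnnotatedNetwork

__all__ = ["MembershipMatrix", "FitResult", "VariationalState", "fit", "derive_labels", "elbo"]

_LOG_FLOOR = 1e-300


@dataclass
class MembershipMatrix:
    """Row-stochastic posterior module memberships, one row per protein."""

    values: np.ndarray
    proteins: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("membership must be a 2-D matrix")
        if np.any(self.values < 0):
            raise ValueError("membership entries must be nonnegative")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass
class VariationalState:
    """All variational parameters at one point of the optimization."""

    resp: np.ndarray                 # n x K categorical factors
    zeta_hat: np.ndarray             # Dirichlet posterior for alpha
    lam_hat: np.ndarray              # K x n_cat Dirichlet posteriors for theta
    mu_hat: list[np.ndarray]         # per category: K x |dom| posteriors for beta
    eps_a: np.ndarray                # K x K Beta posterior shape 1
    eps_b: np.ndarray                # K x K Beta posterior shape 2


@dataclass
class FitResult:
    membership: MembershipMatrix
    elbo_trace: list[float]
    posterior_params: VariationalState
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------
# sufficient statistics of the data
# ---------------------------------------------------------------------


class _DataStats:
    """Annotation count matrices and adjacency in index form."""

    def __init__(self, net: AnnotatedNetwork):
        cat = net.catalog
        n = net.n_proteins
        self.n = n
        self.n_cat = cat.n_categories
        self.dom_sizes = cat.domain_sizes
        self.A = np.asarray(net.adjacency, dtype=float)
        self.neighbors = [net.neighbors(i) for i in range(n)]
        self.cat_counts = np.zeros((n, self.n_cat))
        self.val_counts = [np.zeros((n, d)) for d in self.dom_sizes]
        for i, ann in enumerate(net.annotations):
            for c, v in ann:
                m = cat.category_index(c)
                t = cat.value_index(c, v)
                self.cat_counts[i, m] += 1
                self.val_counts[m][i, t] += 1


class _Priors:
    def __init__(self, hyper: Hyperparams, stats: _DataStats):
        self.zeta = hyper.zeta_vector()
        self.lam = hyper.lam_matrix(stats.n_cat)
        self.mu = hyper.mu_vectors(stats.dom_sizes)
        self.tau = hyper.tau_array()


# ---------------------------------------------------------------------
# conjugate updates
# ---------------------------------------------------------------------


def _global_update(stats: _DataStats, priors: _Priors, resp: np.ndarray) -> VariationalState:
    """Refresh the Dirichlet/Beta factors from expected counts."""
    R = resp
    zeta_hat = priors.zeta + R.sum(axis=0)
    lam_hat = priors.lam + R.T @ stats.cat_counts
    mu_hat = [priors.mu[m] + R.T @ stats.val_counts[m] for m in range(stats.n_cat)]

    m_tot = R.sum(axis=0)
    S_ord = R.T @ stats.A @ R                       # ordered-pair edge mass
    M_ord = np.outer(m_tot, m_tot) - R.T @ R        # ordered-pair count
    edges = S_ord.copy()
    pairs = M_ord.copy()
    np.fill_diagonal(edges, np.diag(S_ord) / 2.0)
    np.fill_diagonal(pairs, np.diag(M_ord) / 2.0)
    pairs = np.maximum(pairs, 0.0)
    eps_a = priors.tau[..., 0] + edges
    eps_b = priors.tau[..., 1] + np.maximum(pairs - edges, 0.0)
    return VariationalState(
        resp=R, zeta_hat=zeta_hat, lam_hat=lam_hat, mu_hat=mu_hat,
        eps_a=eps_a, eps_b=eps_b,
    )


def _expected_logs(state: VariationalState):
    el_alpha = digamma(state.zeta_hat) - digamma(state.zeta_hat.sum())
    el_theta = digamma(state.lam_hat) - digamma(
        state.lam_hat.sum(axis=1, keepdims=True)
    )
    el_beta = [
        digamma(mh) - digamma(mh.sum(axis=1, keepdims=True))
        for mh in state.mu_hat
    ]
    tot = digamma(state.eps_a + state.eps_b)
    el_eps = digamma(state.eps_a) - tot
    el_1meps = digamma(state.eps_b) - tot
    return el_alpha, el_theta, el_beta, el_eps, el_1meps


def _annotation_scores(stats: _DataStats, el_theta, el_beta) -> np.ndarray:
    """n x K matrix of expected annotation log-likelihood per module."""
    scores = stats.cat_counts @ el_theta.T
    for m in range(stats.n_cat):
        scores += stats.val_counts[m] @ el_beta[m].T
    return scores


def _local_sweep(stats, resp, ann_scores, el_alpha, el_eps, el_1meps) -> np.ndarray:
    """Sequentially re-optimize every protein's categorical factor.

    Edge/non-edge sums against the other proteins' current factors are
    maintained incrementally so a sweep is O(n (K^2 + deg K)).
    """
    R = resp.copy()
    AR = stats.A @ R
    m_tot = R.sum(axis=0)
    for i in range(stats.n):
        edge_part = AR[i] @ el_eps.T
        non_edge_counts = m_tot - R[i] - AR[i]
        non_edge_part = non_edge_counts @ el_1meps.T
        log_rho = el_alpha + ann_scores[i] + edge_part + non_edge_part
        log_rho -= log_rho.max()
        new = np.exp(log_rho)
        new /= new.sum()
        delta = new - R[i]
        nbr = stats.neighbors[i]
        if nbr.size:
            AR[nbr] += delta
        m_tot += delta
        R[i] = new
    return R


# ---------------------------------------------------------------------
# evidence lower bound
# ---------------------------------------------------------------------


def _dirichlet_lognorm(conc: np.ndarray) -> np.ndarray:
    """log of the Dirichlet normalizing constant C(conc), rows = vectors."""
    conc = np.asarray(conc, dtype=float)
    return gammaln(conc.sum(axis=-1)) - gammaln(conc).sum(axis=-1)


def _elbo_from_state(stats: _DataStats, priors: _Priors, state: VariationalState) -> float:
    R = state.resp
    el_alpha, el_theta, el_beta, el_eps, el_1meps = _expected_logs(state)

    # labels: E[log p(C | alpha)] + H[q(C)]
    safe = np.maximum(R, _LOG_FLOOR)
    value = float((R * (el_alpha[None, :] - np.log(safe))).sum())

    # annotations
    value += float((R * _annotation_scores(stats, el_theta, el_beta)).sum())

    # edges / non-edges over unordered pairs (half the ordered sums)
    m_tot = R.sum(axis=0)
    S_ord = R.T @ stats.A @ R
    M_ord = np.outer(m_tot, m_tot) - R.T @ R
    value += 0.5 * float((S_ord * el_eps).sum())
    value += 0.5 * float(((M_ord - S_ord) * el_1meps).sum())

    # -KL(q || p) for each conjugate factor
    value += float(
        _dirichlet_lognorm(priors.zeta) - _dirichlet_lognorm(state.zeta_hat)
        + (priors.zeta - state.zeta_hat) @ el_alpha
    )
    if stats.n_cat > 0:
        value += float(
            (_dirichlet_lognorm(priors.lam) - _dirichlet_lognorm(state.lam_hat)).sum()
            + ((priors.lam - state.lam_hat) * el_theta).sum()
        )
    for m in range(stats.n_cat):
        value += float(
            (_dirichlet_lognorm(priors.mu[m]) - _dirichlet_lognorm(state.mu_hat[m])).sum()
            + ((priors.mu[m] - state.mu_hat[m]) * el_beta[m]).sum()
        )
    iu = np.triu_indices(R.shape[1])
    t1 = priors.tau[..., 0][iu]
    t2 = priors.tau[..., 1][iu]
    a = state.eps_a[iu]
    b = state.eps_b[iu]
    value += float(
        (betaln(a, b) - betaln(t1, t2)).sum()
        + ((t1 - a) * el_eps[iu]).sum()
        + ((t2 - b) * el_1meps[iu]).sum()
    )
    return value


def elbo(net: AnnotatedNetwork, state: VariationalState, hyper: Hyperparams) -> float:
    """Evidence lower bound of the joint model at a variational state."""
    stats = _DataStats(net)
    priors = _Priors(hyper, stats)
    return _elbo_from_state(stats, priors, state)


# ---------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------


def fit(
    net: AnnotatedNetwork,
    K: int,
    hyper: Hyperparams | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    rng_seed=None,
) -> FitResult:
    """Fit the membership posterior; returns the best restart by ELBO.

    Each restart initializes the categorical factors from a flat
    Dirichlet draw, then alternates sequential per-protein updates with
    conjugate global updates until the relative ELBO change drops below
    ``tol`` or ``max_iter`` sweeps elapse.
    """
    if hyper is None:
        hyper = Hyperparams(K=K)
    if hyper.K != K:
        raise ValueError("hyper.K must match K")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > net.n_proteins:
        raise ValueError(f"K={K} exceeds the number of proteins ({net.n_proteins})")

    stats = _DataStats(net)
    priors = _Priors(hyper, stats)
    rng = np.random.default_rng(rng_seed)

    best: FitResult | None = None
    for _ in range(n_restarts):
        if K == 1:
            resp = np.ones((stats.n, 1))
        else:
            resp = rng.dirichlet(np.ones(K), size=stats.n)
        state = _global_update(stats, priors, resp)
        trace: list[float] = []
        prev = -np.inf
        converged = False
        n_iter = 0
        for sweep in range(max_iter):
            n_iter = sweep + 1
            el_alpha, el_theta, el_beta, el_eps, el_1meps = _expected_logs(state)
            ann_scores = _annotation_scores(stats, el_theta, el_beta)
            resp = _local_sweep(
                stats, state.resp, ann_scores, el_alpha, el_eps, el_1meps
            )
            state = _global_update(stats, priors, resp)
            current = _elbo_from_state(stats, priors, state)
            if not np.isfinite(current):
                raise FloatingPointError(
                    f"ELBO became non-finite at sweep {n_iter}"
                )
            trace.append(current)
            if prev > -np.inf and abs(current - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
            prev = current
            if K == 1:
                converged = True
                break
        result = FitResult(
            membership=MembershipMatrix(values=state.resp, proteins=list(net.proteins)),
            elbo_trace=trace,
            posterior_params=state,
            n_iter=n_iter,
            converged=converged,
        )
        if best is None or result.elbo_trace[-1] > best.elbo_trace[-1]:
            best = result
        if K == 1:
            break
    assert best is not None
    return best


def derive_labels(membership: MembershipMatrix | np.ndarray) -> np.ndarray:
    """1-based argmax labels; ties break toward the lowest module index."""
    values = membership.values if isinstance(membership, MembershipMatrix) else np.asarray(membership)
    return np.argmax(values, axis=1) + 1
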