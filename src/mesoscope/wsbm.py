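"""Sparse weighted stochastic blockmodel (WSBM): likelihood and variational
Bayes inference.

Model
-----
Each unordered dyad (i, j) between communities r = z_i, s = z_j exists with
probability theta_e[r, s] (Bernoulli); an existing edge carries a weight
drawn from Normal(mu[r, s], sigma2[r, s]).  The log-likelihood combines both
factors with a mixing weight alpha in [0, 1]:

    L = alpha * sum_{dyads} log Bern(a_ij | theta_e)
      + (1 - alpha) * sum_{existing edges} normal kernel(x_ij | mu, sigma2)

Absent dyads contribute only to the Bernoulli factor (a zero entry encodes
"no connection", not "weight zero").  alpha = 0.5, the default throughout,
balances existence and weight information.

Inference
---------
Mean-field variational Bayes with conjugate priors: Beta(1, 1) on each
theta_e[r, s], Normal-Gamma(m0 = sample mean of weights, kappa0 = 1,
a0 = 1, b0 = sample variance) on (mu, precision), and a flat prior over
labels.  The alpha weighting enters as factor exponents 2*alpha and
2*(1 - alpha), so alpha = 0.5 is the exact (untempered) posterior and other
values tilt the likelihood while preserving conjugacy.  Each iteration
updates node responsibilities sequentially (guaranteeing a monotone evidence
bound) and then the block-parameter posteriors.

Initialization matters: re-estimated block parameters carry a contrast that
is quadratic in the responsibilities' alignment with any real structure, so
the uninformative symmetric fixed point has a large basin of attraction and
purely random responsibilities collapse into it.  Each restart therefore
starts from a randomized k-means clustering of the nodes' connectivity
profiles (rows of the weight matrix), softened into responsibilities; a
plain Dirichlet(1) draw remains available via ``init="dirichlet"``.
Per-restart randomness comes from split seed streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .netio import Partition, WeightedNetwork

__all__ = ["WSBMParams", "WSBMFit", "sbm_log_likelihood", "wsbm_log_likelihood", "fit_wsbm"]


def _as_seed_seq(seed):
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class WSBMParams:
    """Point parameters of a K-block sparse WSBM."""

    K: int
    edge_theta: np.ndarray  # K x K Bernoulli rates
    mu: np.ndarray  # K x K weight means
    sigma2: np.ndarray  # K x K weight variances
    alpha: float = 0.5

    def __post_init__(self) -> None:
        self.edge_theta = np.asarray(self.edge_theta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        for name, m in (("edge_theta", self.edge_theta), ("mu", self.mu), ("sigma2", self.sigma2)):
            if m.shape != (self.K, self.K):
                raise ValueError(f"{name} must be K x K")
        if np.any(self.edge_theta < 0) or np.any(self.edge_theta > 1):
            raise ValueError("edge_theta must lie in [0, 1]")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def _dyad_terms(network: WeightedNetwork):
    """Iterate (i, j, a, x) over unordered (undirected) or ordered (directed) dyads."""
    A = network.weights
    n = network.n_nodes
    if network.directed:
        for i in range(n):
            for j in range(n):
                if i != j:
                    yield i, j, float(A[i, j] > 0), float(A[i, j])
    else:
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j, float(A[i, j] > 0), float(A[i, j])


def sbm_log_likelihood(
    network: WeightedNetwork, partition: Partition, edge_theta: np.ndarray
) -> float:
    """Bernoulli blockmodel log-likelihood of the binarized network.

    sum over dyads of a*log(theta) + (1-a)*log(1-theta); a boundary theta of
    0 or 1 contradicted by an observation yields -inf (not an exception).
    """
    edge_theta = np.asarray(edge_theta, dtype=float)
    z = partition.labels - 1
    total = 0.0
    with np.errstate(divide="ignore"):
        log_t = np.log(edge_theta)
        log_1t = np.log1p(-edge_theta)
    for i, j, a, _ in _dyad_terms(network):
        # a is 0/1, so only one factor applies (0 * log 0 never arises)
        term = log_t[z[i], z[j]] if a > 0 else log_1t[z[i], z[j]]
        if not np.isfinite(term):
            return float("-inf")
        total += term
    return float(total)


def wsbm_log_likelihood(
    network: WeightedNetwork, partition: Partition, params: WSBMParams
) -> float:
    """Weighted blockmodel log-likelihood with existence/weight mixing.

    alpha * (full Bernoulli log-pmf over all dyads)
    + (1 - alpha) * (normal kernel x*mu/s2 - x^2/(2 s2) - mu^2/(2 s2) over
    existing edges).  With alpha = 1 this equals ``sbm_log_likelihood``
    exactly (our Bernoulli factor keeps its log-partition term); with
    alpha = 0 only the weight kernel remains.
    """
    z = partition.labels - 1
    bern = sbm_log_likelihood(network, partition, params.edge_theta)
    if params.alpha == 1.0:
        return params.alpha * bern
    weight = 0.0
    mu, s2 = params.mu, params.sigma2
    for i, j, a, x in _dyad_terms(network):
        if a > 0:
            r, s = z[i], z[j]
            weight += x * mu[r, s] / s2[r, s] - x * x / (2 * s2[r, s]) - mu[r, s] ** 2 / (
                2 * s2[r, s]
            )
    if params.alpha == 0.0:
        return (1 - params.alpha) * weight
    return params.alpha * bern + (1 - params.alpha) * weight


@dataclass
class WSBMFit:
    responsibilities: np.ndarray  # N x K
    map_partition: Partition
    log_evidence: float  # best evidence lower bound over restarts
    params: WSBMParams  # posterior-mean block parameters of the best restart
    n_restarts_used: int
    converged: np.ndarray  # bool per restart
    restart_evidence: np.ndarray
    elbo_history: np.ndarray  # per-iteration bound of the best restart
    k_effective: int = 0


# ---------------------------------------------------------------------------
# variational Bayes internals
# ---------------------------------------------------------------------------


@dataclass
class _Priors:
    p0: float = 1.0  # Beta
    q0: float = 1.0
    m0: float = 0.0  # Normal-Gamma
    kappa0: float = 1.0
    a0: float = 1.0
    b0: float = 1.0


def _block_stats(tau, Ab, X, X2):
    """Ordered-pair block sums M[r,s] = sum_{i != j} tau_ir tau_js f_ij."""
    s0 = tau.sum(axis=0)
    M_n = np.outer(s0, s0) - tau.T @ tau  # f = 1, excluding i = j
    M_e = tau.T @ Ab @ tau
    M_x = tau.T @ X @ tau
    M_x2 = tau.T @ X2 @ tau
    return M_n, M_e, M_x, M_x2


def _unordered_mass(M: np.ndarray) -> np.ndarray:
    """Ordered-pair block sums -> unordered-dyad masses per block pair.

    An off-diagonal ordered entry M[r, s] already aggregates the full mass
    tau_ir tau_js + tau_is tau_jr of every unordered dyad; within-block
    diagonal entries count each dyad twice, so only they are halved.  The
    result is symmetric, storing each block-pair parameter's mass at both
    (r, s) and (s, r).
    """
    out = M.copy()
    np.fill_diagonal(out, np.diag(M) / 2.0)
    return out


def _posteriors(M_n, M_e, M_x, M_x2, pri: _Priors, we: float, ww: float):
    """Conjugate posterior parameters from ordered-pair block masses."""
    n = _unordered_mass(M_n)
    e = _unordered_mass(M_e)
    sx = _unordered_mass(M_x)
    sx2 = _unordered_mass(M_x2)
    p = pri.p0 + we * e
    q = pri.q0 + we * (n - e)
    nn = ww * e
    kappa = pri.kappa0 + nn
    m = (pri.kappa0 * pri.m0 + ww * sx) / kappa
    a = pri.a0 + nn / 2.0
    b = pri.b0 + 0.5 * (ww * sx2 + pri.kappa0 * pri.m0**2 - kappa * m**2)
    b = np.maximum(b, 1e-12)
    return p, q, m, kappa, a, b


def _coeffs(p, q, m, kappa, a, b, we: float, ww: float):
    """Per-block-pair dyad log-likelihood expectations as C0 + a*C1 + ax*C2 + ax2*C3."""
    e_log_t = digamma(p) - digamma(p + q)
    e_log_1t = digamma(q) - digamma(p + q)
    e_log_lam = digamma(a) - np.log(b)
    e_lam = a / b
    g0 = 0.5 * (e_log_lam - np.log(2 * np.pi) - e_lam * m**2 - 1.0 / kappa)
    g1 = e_lam * m
    g2 = -0.5 * e_lam
    C0 = we * e_log_1t
    C1 = we * (e_log_t - e_log_1t) + ww * g0
    C2 = ww * g1
    C3 = ww * g2
    return C0, C1, C2, C3


def _kl_beta(p, q, p0, q0):
    return (
        gammaln(p + q) - gammaln(p) - gammaln(q)
        - (gammaln(p0 + q0) - gammaln(p0) - gammaln(q0))
        + (p - p0) * digamma(p)
        + (q - q0) * digamma(q)
        + (p0 + q0 - p - q) * digamma(p + q)
    )


def _kl_normal_gamma(m, kappa, a, b, pri: _Priors):
    e_lam = a / b
    kl_gamma = (
        (a - pri.a0) * digamma(a)
        - gammaln(a)
        + gammaln(pri.a0)
        + pri.a0 * (np.log(b) - np.log(pri.b0))
        + e_lam * (pri.b0 - b)
    )
    kl_normal = 0.5 * (
        pri.kappa0 / kappa
        + pri.kappa0 * e_lam * (m - pri.m0) ** 2
        - 1.0
        + np.log(kappa / pri.kappa0)
    )
    return kl_gamma + kl_normal


def _elbo(tau, Ab, X, X2, pri: _Priors, we, ww, K):
    M_n, M_e, M_x, M_x2 = _block_stats(tau, Ab, X, X2)
    p, q, m, kappa, a, b = _posteriors(M_n, M_e, M_x, M_x2, pri, we, ww)
    C0, C1, C2, C3 = _coeffs(p, q, m, kappa, a, b, we, ww)
    e_ll = 0.5 * float((C0 * M_n + C1 * M_e + C2 * M_x + C3 * M_x2).sum())
    # block-pair priors: each unordered block pair {r,s} (and each diagonal r)
    # owns one Beta and one Normal-Gamma factor; sum the upper triangle
    iu = np.triu_indices(K)
    kl = float(_kl_beta(p, q, pri.p0, pri.q0)[iu].sum()) + float(
        _kl_normal_gamma(m, kappa, a, b, pri)[iu].sum()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-(tau * np.where(tau > 0, np.log(tau), 0.0)).sum())
    n = tau.shape[0]
    return e_ll - kl + ent - n * np.log(K), (p, q, m, kappa, a, b)


def _init_tau(rng: np.random.Generator, A: np.ndarray, K: int, init: str) -> np.ndarray:
    n = A.shape[0]
    if init == "dirichlet":
        return rng.dirichlet(np.ones(K), size=n)
    if init != "profiles":
        raise ValueError("init must be 'profiles' or 'dirichlet'")
    from scipy.cluster.vq import kmeans2

    labels = kmeans2(A, K, minit="++", seed=rng)[1]
    soft = 0.05
    tau = np.full((n, K), soft / K)
    tau[np.arange(n), labels] += 1.0 - soft
    return tau


def fit_wsbm(
    network: WeightedNetwork,
    K: int,
    alpha: float = 0.5,
    restarts: int = 250,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    collect_history: bool = True,
    init: str = "profiles",
    initial_tau: np.ndarray | None = None,
) -> WSBMFit:
    """Fit the sparse WSBM by mean-field variational Bayes, best of restarts.

    ``initial_tau`` (N x K) overrides the randomized initialization and
    forces a single restart; useful for evaluating the bound from a chosen
    starting point.
    """
    if network.directed:
        raise NotImplementedError("fit_wsbm is implemented for undirected networks")
    n = network.n_nodes
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError("K must not exceed the number of nodes")
    if not (network.weights > 0).any():
        raise ValueError("network must contain at least one edge")

    A = network.weights
    Ab = (A > 0).astype(float)
    X = A
    X2 = A**2
    w = A[np.triu_indices(n, k=1)]
    w = w[w > 0]
    pri = _Priors(m0=float(w.mean()), b0=float(max(w.var(), 1e-6)))
    we = 2.0 * alpha
    ww = 2.0 * (1.0 - alpha)

    if initial_tau is not None:
        restarts = 1
    ss = _as_seed_seq(seed)
    best = None
    converged = np.zeros(restarts, dtype=bool)
    restart_ev = np.full(restarts, -np.inf)

    for rep, child in enumerate(ss.spawn(restarts)):
        rng = np.random.default_rng(child)
        if initial_tau is not None:
            tau = np.asarray(initial_tau, dtype=float).copy()
            if tau.shape != (n, K):
                raise ValueError("initial_tau must be N x K")
        else:
            tau = _init_tau(rng, A, K, init)
        elbo_prev = -np.inf
        history = []
        for _ in range(max_iter):
            # block-parameter update, then coefficient refresh
            M = _block_stats(tau, Ab, X, X2)
            post = _posteriors(*M, pri, we, ww)
            C0, C1, C2, C3 = _coeffs(*post, we, ww)
            # sequential responsibility updates with incrementally
            # maintained field statistics
            S0 = tau.sum(axis=0)
            P1 = Ab @ tau
            P2 = X @ tau
            P3 = X2 @ tau
            for i in range(n):
                field = (
                    (S0 - tau[i]) @ C0.T
                    + P1[i] @ C1.T
                    + P2[i] @ C2.T
                    + P3[i] @ C3.T
                )
                new = np.exp(field - logsumexp(field))
                delta = new - tau[i]
                if np.abs(delta).max() > 0:
                    S0 += delta
                    P1 += np.outer(Ab[:, i], delta)
                    P2 += np.outer(X[:, i], delta)
                    P3 += np.outer(X2[:, i], delta)
                    tau[i] = new
            elbo, post = _elbo(tau, Ab, X, X2, pri, we, ww, K)
            if collect_history:
                history.append(elbo)
            if np.isfinite(elbo_prev) and abs(elbo - elbo_prev) < tol:
                converged[rep] = True
                elbo_prev = elbo
                break
            elbo_prev = elbo
        restart_ev[rep] = elbo_prev
        if best is None or elbo_prev > best[0]:
            best = (elbo_prev, tau.copy(), post, np.asarray(history))

    elbo_best, tau_best, (p, q, m, kappa, a, b), history = best
    # reorder responsibility columns so block parameters align with the
    # canonically relabeled map partition (labels 1..K by first appearance)
    raw = tau_best.argmax(axis=1)
    order = list(dict.fromkeys(raw))
    order += [c for c in range(K) if c not in order]  # empty blocks last
    tau_best = tau_best[:, order]
    perm = np.ix_(order, order)
    theta_hat = (p / (p + q))[perm]
    sigma2_hat = (b / a)[perm]  # plug-in 1 / E[precision]
    params = WSBMParams(K=K, edge_theta=theta_hat, mu=m[perm], sigma2=sigma2_hat, alpha=alpha)
    map_part = Partition(tau_best.argmax(axis=1) + 1)
    return WSBMFit(
        responsibilities=tau_best,
        map_partition=map_part,
        log_evidence=float(elbo_best),
        params=params,
        n_restarts_used=restarts,
        converged=converged,
        restart_evidence=restart_ev,
        elbo_history=history,
        k_effective=map_part.K,
    )
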