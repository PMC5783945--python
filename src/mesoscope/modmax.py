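"""Modularity quality function and a greedy fixed-K maximizer.

Q contrasts the observed within-community weight with a configuration-model
expectation P_ij = k_i k_j / 2m and is reported with the conventional 1/2m
normalization (which never changes the maximizing partition).  "Degree" in
the null defaults to weighted strength, matching application to weighted
matrices; a binary-degree mode is available.

The maximizer is deliberately simple, mirroring common practice for
partitions with a fixed number of communities: start from a uniformly random
K-labeling, propose single-node label switches uniformly at random, accept a
switch only if Q strictly increases, and keep the best partition over
restarts.  Communities may empty out; the effective number of communities is
reported by the canonical relabeling of the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netio import Partition, WeightedNetwork

__all__ = ["ModularityConfig", "QmaxFit", "modularity", "greedy_fixed_k"]


def _as_seed_seq(seed):
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class ModularityConfig:
    gamma: float = 1.0
    n_moves: int = 10_000
    restarts: int = 250
    degree: str = "strength"  # or "binary"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.n_moves < 1:
            raise ValueError("n_moves must be >= 1")
        if self.degree not in ("strength", "binary"):
            raise ValueError("degree must be 'strength' or 'binary'")


@dataclass
class QmaxFit:
    partition: Partition
    q: float
    restart_qs: np.ndarray
    k_effective: int


def _null_degree(network: WeightedNetwork, mode: str) -> np.ndarray:
    return network.strength if mode == "strength" else network.degree.astype(float)


def modularity(
    network: WeightedNetwork,
    partition: Partition,
    gamma: float = 1.0,
    degree: str = "strength",
) -> float:
    """Normalized modularity Q = (1/2m) sum_ij [A_ij - gamma k_i k_j / 2m] delta(z_i, z_j)."""
    if network.directed:
        raise ValueError("modularity is defined here for undirected networks")
    k = _null_degree(network, degree)
    two_m = float(k.sum())
    if two_m <= 0:
        raise ValueError("network has zero total weight")
    z = partition.labels
    same = z[:, None] == z[None, :]
    return float(((network.weights - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def greedy_fixed_k(
    network: WeightedNetwork,
    K: int,
    config: ModularityConfig | None = None,
    seed: int | None = None,
) -> QmaxFit:
    """Best-of-restarts greedy fixed-K modularity maximization."""
    if config is None:
        config = ModularityConfig()
    n = network.n_nodes
    if K < 2 or K > n:
        raise ValueError("require 2 <= K <= N")
    if network.directed:
        raise ValueError("greedy_fixed_k is defined here for undirected networks")
    A = network.weights
    k = _null_degree(network, config.degree)
    two_m = float(k.sum())
    if two_m <= 0:
        raise ValueError("network has zero total weight")
    gamma = config.gamma

    ss = _as_seed_seq(seed)
    children = ss.spawn(config.restarts)
    best_q = -np.inf
    best_labels = None
    restart_qs = np.empty(config.restarts)

    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        labels = rng.integers(0, K, size=n)
        # W[i, c] = sum of A_ij over j in community c; S[c] = sum of k_j in c
        onehot = np.zeros((n, K))
        onehot[np.arange(n), labels] = 1.0
        W = A @ onehot
        S = k @ onehot
        q = _q_from_state(A, k, two_m, gamma, labels)
        nodes = rng.integers(0, n, size=config.n_moves)
        targets = rng.integers(0, K, size=config.n_moves)
        for i, c_new in zip(nodes, targets):
            c_old = labels[i]
            if c_new == c_old:
                continue
            dq = (
                2.0 * (W[i, c_new] - W[i, c_old])
                - 2.0 * gamma * k[i] * (S[c_new] - S[c_old] + k[i]) / two_m
            ) / two_m
            if dq > 0.0:
                labels[i] = c_new
                col = A[:, i]
                W[:, c_old] -= col
                W[:, c_new] += col
                S[c_old] -= k[i]
                S[c_new] += k[i]
                q += dq
        restart_qs[rep] = q
        if q > best_q:
            best_q = q
            best_labels = labels.copy()

    part = Partition(best_labels + 1)
    return QmaxFit(partition=part, q=float(best_q), restart_qs=restart_qs, k_effective=part.K)


def _q_from_state(A, k, two_m, gamma, labels) -> float:
    same = labels[:, None] == labels[None, :]
    return float(((A - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)
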