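"""Block densities, community/regional assortativity, and the maximally
assortative set (MAS).

The weighted block density between communities r and s is

    omega_rs = (1 / (n_r n_s)) * sum_{i in r, j in s} A_ij

over ordered node pairs.  Within-community blocks follow this formula
literally: the zero diagonal is included and the denominator is n_r^2
("include_diagonal"); an exclude-diagonal mode with denominator
n_r (n_r - 1) is available since either convention is defensible.

Community assortativity is A_r = omega_rr - max_{s != r} omega_rs; its
node-level analogue is phi_i = a_{i z_i} - max_{r != z_i} a_{ir} with
a_{ir} the mean weight from node i into community r.  Singleton communities
are excluded (scores are NaN, never zero).

The maximally assortative set is the node-count-maximizing subset of >= 2
communities whose minimum within-community density exceeds the maximum
between-community density inside the subset, found by exhaustive subset
search (K <= 20).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .netio import Partition, WeightedNetwork

__all__ = [
    "BlockDensityMatrix",
    "block_densities",
    "community_assortativity",
    "all_community_assortativity",
    "regional_assortativity",
    "delta_regional_assortativity",
    "maximally_assortative_set",
    "mas_node_frequency",
    "assortativity_size_curve",
]


@dataclass
class BlockDensityMatrix:
    omega: np.ndarray
    sizes: np.ndarray
    omega_in: np.ndarray | None = None
    omega_out: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.omega.shape[0]

    @property
    def directed(self) -> bool:
        return self.omega_in is not None


def block_densities(
    network: WeightedNetwork, partition: Partition, include_diagonal: bool = True
) -> BlockDensityMatrix:
    """Weighted connection densities omega_rs between all community pairs."""
    if partition.n_nodes != network.n_nodes:
        raise ValueError("partition does not match network size")
    Z = partition.indicator()
    sizes = partition.sizes.astype(float)

    def _omega(mat: np.ndarray) -> np.ndarray:
        s = Z.T @ mat @ Z
        denom = np.outer(sizes, sizes)
        if not include_diagonal:
            d = sizes * (sizes - 1.0)
            np.fill_diagonal(denom, np.where(d > 0, d, np.nan))
        return s / denom

    if network.directed:
        out = _omega(network.weights)
        inn = _omega(network.weights.T)
        return BlockDensityMatrix(
            omega=(out + inn) / 2.0,
            sizes=partition.sizes,
            omega_in=inn,
            omega_out=out,
        )
    return BlockDensityMatrix(omega=_omega(network.weights), sizes=partition.sizes)


def community_assortativity(bdm: BlockDensityMatrix, r: int) -> float:
    """A_r = omega_rr - max_{s != r} omega_rs for community r (1-based).

    Singletons are excluded and return NaN.  For directed networks the
    subtrahend is the greater of the in- and out-density maxima.
    """
    if bdm.K < 2:
        raise ValueError("assortativity needs K >= 2")
    idx = r - 1
    if not 0 <= idx < bdm.K:
        raise ValueError(f"no community {r}")
    if bdm.sizes[idx] < 2:
        return float("nan")
    others = np.arange(bdm.K) != idx
    if bdm.directed:
        off = max(bdm.omega_in[idx, others].max(), bdm.omega_out[idx, others].max())
        own = bdm.omega_out[idx, idx]  # symmetric within-block density
    else:
        off = bdm.omega[idx, others].max()
        own = bdm.omega[idx, idx]
    return float(own - off)


def all_community_assortativity(bdm: BlockDensityMatrix) -> np.ndarray:
    return np.array([community_assortativity(bdm, r) for r in range(1, bdm.K + 1)])


def _node_community_density(network: WeightedNetwork, partition: Partition) -> np.ndarray:
    """a_{ir} = (1/n_r) sum_{j in r} A_ij, for all nodes and communities."""
    Z = partition.indicator()
    return (network.weights @ Z) / partition.sizes.astype(float)


def regional_assortativity(
    network: WeightedNetwork, partition: Partition, node: int | None = None
):
    """phi_i = a_{i z_i} - max_{r != z_i} a_{ir}; NaN for singleton communities.

    Returns the full per-node vector, or a scalar when ``node`` is given.
    Directed networks use the lesser of in/out own-community densities minus
    the greater of the in/out foreign maxima.
    """
    if partition.K < 2:
        raise ValueError("regional assortativity needs K >= 2")
    z = partition.labels - 1
    n = network.n_nodes
    sizes = partition.sizes

    if network.directed:
        a_out = _node_community_density(network, partition)
        a_in = (network.weights.T @ partition.indicator()) / sizes.astype(float)
        own = np.minimum(a_out[np.arange(n), z], a_in[np.arange(n), z])
        mask_out = a_out.copy()
        mask_in = a_in.copy()
        mask_out[np.arange(n), z] = -np.inf
        mask_in[np.arange(n), z] = -np.inf
        foreign = np.maximum(mask_out.max(axis=1), mask_in.max(axis=1))
    else:
        a = _node_community_density(network, partition)
        own = a[np.arange(n), z]
        masked = a.copy()
        masked[np.arange(n), z] = -np.inf
        foreign = masked.max(axis=1)

    phi = own - foreign
    phi[sizes[z] < 2] = np.nan
    if node is not None:
        return float(phi[node])
    return phi


def delta_regional_assortativity(
    ensemble_wsbm: list[Partition],
    ensemble_qmax: list[Partition],
    network: WeightedNetwork,
) -> np.ndarray:
    """Per-node mean phi_i under one ensemble minus the other (NaN-aware)."""
    if not ensemble_wsbm or not ensemble_qmax:
        raise ValueError("both ensembles must be non-empty")

    def _mean_phi(ens: list[Partition]) -> np.ndarray:
        mat = np.vstack([regional_assortativity(network, p) for p in ens])
        with np.errstate(invalid="ignore"):
            return np.nanmean(mat, axis=0)

    return _mean_phi(ensemble_wsbm) - _mean_phi(ensemble_qmax)


def maximally_assortative_set(
    bdm: BlockDensityMatrix, min_communities: int = 2
) -> frozenset[int]:
    """Largest-by-node-count community subset with min-within > max-between.

    Exhaustive over all subsets of >= ``min_communities`` communities
    (1-based ids).  Ties on node count break by the larger margin
    (min-within minus max-between), then lexicographically.  Returns an
    empty frozenset when no subset qualifies.
    """
    K = bdm.K
    if K > 20:
        raise ValueError("exhaustive MAS search is limited to K <= 20")
    omega = bdm.omega
    sizes = bdm.sizes
    best: tuple | None = None
    for k in range(min_communities, K + 1):
        for subset in combinations(range(K), k):
            idx = np.array(subset)
            diag = omega[idx, idx]
            off = omega[np.ix_(idx, idx)].copy()
            np.fill_diagonal(off, -np.inf)
            margin = diag.min() - off.max()
            if margin <= 0:
                continue
            n_nodes = int(sizes[idx].sum())
            key = (n_nodes, margin, tuple(-i for i in subset))
            if best is None or key > best[0]:
                best = (key, subset)
    if best is None:
        return frozenset()
    return frozenset(c + 1 for c in best[1])


def mas_node_frequency(
    ensemble: list[Partition], network: WeightedNetwork, include_diagonal: bool = True
) -> np.ndarray:
    """Per-node fraction of partitions whose MAS contains the node's community."""
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    counts = np.zeros(network.n_nodes)
    for part in ensemble:
        bdm = block_densities(network, part, include_diagonal=include_diagonal)
        mas = maximally_assortative_set(bdm)
        counts += np.isin(part.labels, list(mas))
    return counts / len(ensemble)


def assortativity_size_curve(
    communities: list[tuple[int, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean assortativity per integer community size, pooled across partitions.

    Returns (sizes, mean scores); NaN scores (singletons) are dropped.
    """
    if not communities:
        raise ValueError("need at least one community")
    data = [(n, a) for n, a in communities if np.isfinite(a)]
    sizes = np.array(sorted({n for n, _ in data}))
    means = np.array([np.mean([a for n, a in data if n == s]) for s in sizes])
    return sizes, means
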