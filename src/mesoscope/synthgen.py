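"""Planted block-structured weighted networks and the two null models.

The generator mirrors the sparse weighted blockmodel used for inference: each
dyad between communities r and s exists with probability ``edge_prob[r, s]``
and, when present, carries a weight drawn from Normal(mu[r, s], var[r, s])
truncated below at zero (connectome weights are nonnegative; presets keep
mu >= 3*sigma so the truncation is negligible).

Two nulls accompany it: Maslov-Sneppen degree-preserving rewiring in which
weights travel with their edges, and uniform permutation of partition labels,
which preserves the number and sizes of communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .netio import Partition, WeightedNetwork

__all__ = [
    "BlockSpec",
    "sample_planted_network",
    "motif_preset",
    "mixed_motif_preset",
    "rewire_preserving_degree",
    "permute_partition_labels",
]


@dataclass
class BlockSpec:
    """Generative parameters of a planted K-block weighted network.

    ``edge_prob[r, s]`` is the Bernoulli edge-existence probability between
    blocks r and s; existing edges draw weights from a normal with mean
    ``weight_mean[r, s]`` and variance ``weight_var[r, s]``.
    """

    K: int
    sizes: tuple[int, ...]
    edge_prob: np.ndarray
    weight_mean: np.ndarray
    weight_var: np.ndarray
    directed: bool = False
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        self.edge_prob = np.asarray(self.edge_prob, dtype=float)
        self.weight_mean = np.asarray(self.weight_mean, dtype=float)
        self.weight_var = np.asarray(self.weight_var, dtype=float)
        if len(self.sizes) != self.K:
            raise ValueError("sizes must have length K")
        if any(s < 1 for s in self.sizes):
            raise ValueError("block sizes must be >= 1")
        if sum(self.sizes) < 2:
            raise ValueError("total network size must be >= 2")
        for name, m in (
            ("edge_prob", self.edge_prob),
            ("weight_mean", self.weight_mean),
            ("weight_var", self.weight_var),
        ):
            if m.shape != (self.K, self.K):
                raise ValueError(f"{name} must be K x K")
            if not self.directed and not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric for undirected specs")
        if np.any(self.edge_prob < 0) or np.any(self.edge_prob > 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if np.any(self.weight_var <= 0):
            raise ValueError("weight variances must be positive")

    @property
    def n_nodes(self) -> int:
        return sum(self.sizes)

    def planted_partition(self) -> Partition:
        return Partition(np.repeat(np.arange(1, self.K + 1), self.sizes))

    def expected_block_density(self, include_diagonal: bool = True) -> np.ndarray:
        """Expected empirical block density omega under this spec.

        Uses the mean of the (possibly truncated) weight distribution.  The
        within-block expectation accounts for the zero diagonal when
        ``include_diagonal`` (the ordered-pair density convention).
        """
        mean = self._effective_mean()
        omega = self.edge_prob * mean
        if include_diagonal:
            n = np.asarray(self.sizes, dtype=float)
            adj = np.where(n > 1, (n - 1.0) / n, 0.0)
            omega = omega.copy()
            np.fill_diagonal(omega, np.diag(omega) * adj)
        return omega

    def _effective_mean(self) -> np.ndarray:
        if not self.truncate_at_zero:
            return self.weight_mean
        sd = np.sqrt(self.weight_var)
        a = (0.0 - self.weight_mean) / sd
        return truncnorm.mean(a, np.inf, loc=self.weight_mean, scale=sd)

    def to_json(self) -> dict:
        return {
            "K": self.K,
            "sizes": list(self.sizes),
            "edge_prob": self.edge_prob.tolist(),
            "weight_mean": self.weight_mean.tolist(),
            "weight_var": self.weight_var.tolist(),
            "directed": self.directed,
            "truncate_at_zero": self.truncate_at_zero,
        }

    @classmethod
    def from_json(cls, d: dict) -> "BlockSpec":
        return cls(
            K=d["K"],
            sizes=tuple(d["sizes"]),
            edge_prob=np.asarray(d["edge_prob"]),
            weight_mean=np.asarray(d["weight_mean"]),
            weight_var=np.asarray(d["weight_var"]),
            directed=d.get("directed", False),
            truncate_at_zero=d.get("truncate_at_zero", True),
        )


def sample_planted_network(spec: BlockSpec, seed: int) -> tuple[WeightedNetwork, Partition]:
    """Draw a network from a :class:`BlockSpec`; bit-reproducible given seed."""
    rng = np.random.default_rng(seed)
    part = spec.planted_partition()
    z = part.labels - 1
    n = spec.n_nodes
    theta = spec.edge_prob[np.ix_(z, z)]
    mu = spec.weight_mean[np.ix_(z, z)]
    sd = np.sqrt(spec.weight_var)[np.ix_(z, z)]

    exists = rng.random((n, n)) < theta
    if spec.truncate_at_zero:
        # inverse-CDF truncated-normal draw, vectorized over dyads
        u = rng.random((n, n))
        a = (0.0 - mu) / sd
        weights = truncnorm.ppf(u, a, np.inf, loc=mu, scale=sd)
    else:
        weights = rng.normal(mu, sd)
    mat = np.where(exists, weights, 0.0)
    np.fill_diagonal(mat, 0.0)
    if not spec.directed:
        mat = np.triu(mat, k=1)
        mat = mat + mat.T
    return WeightedNetwork(mat, directed=spec.directed), part


_PRESET_THETA = {
    "assortative": {"within": 0.4, "between": 0.1},
    "core_periphery": {"core": 0.6, "cp": 0.35, "periphery": 0.05},
    "disassortative": {"within": 0.05, "between": 0.4},
}


def motif_preset(
    kind: str,
    K: int = 2,
    sizes: tuple[int, ...] = (50, 50),
    mu: float = 1.0,
    var: float = 0.04,
) -> BlockSpec:
    """Preset :class:`BlockSpec` planting one of the three interaction motifs.

    Edge-existence probabilities dominate the density contrast (all weight
    means equal), so the expected block densities satisfy the corresponding
    classification rule with a margin of at least 3 sampling standard errors
    at the requested sizes; smaller sizes are rejected.
    """
    if kind not in _PRESET_THETA:
        raise ValueError(f"unknown preset kind {kind!r}")
    if len(sizes) != K:
        raise ValueError("sizes must have length K")
    if kind == "core_periphery":
        if K != 2:
            raise ValueError("core_periphery preset is defined for K=2")
        p = _PRESET_THETA[kind]
        theta = np.array([[p["core"], p["cp"]], [p["cp"], p["periphery"]]])
    else:
        p = _PRESET_THETA[kind]
        theta = np.full((K, K), p["between"])
        np.fill_diagonal(theta, p["within"])
    spec = BlockSpec(
        K=K,
        sizes=tuple(sizes),
        edge_prob=theta,
        weight_mean=np.full((K, K), mu),
        weight_var=np.full((K, K), var),
    )
    _check_margin(spec, kind)
    return spec


def _omega_se(spec: BlockSpec, r: int, s: int) -> float:
    """Sampling standard error of the empirical block density omega_rs."""
    n = spec.sizes
    theta = spec.edge_prob[r, s]
    mu = spec._effective_mean()[r, s]
    # per-dyad variance of (existence * weight)
    v = theta * spec.weight_var[r, s] + theta * (1 - theta) * mu**2
    if r == s:
        n_pairs = n[r] * (n[r] - 1) / 2
        if n_pairs == 0:
            return np.inf
        # ordered-pair omega_rr = (2 / n_r^2) * sum over dyads
        return float(np.sqrt(4 * n_pairs * v) / n[r] ** 2)
    return float(np.sqrt(v / (n[r] * n[s])))


def _check_margin(spec: BlockSpec, kind: str, n_se: float = 3.0) -> None:
    omega = spec.expected_block_density()
    ok = True
    for r in range(spec.K):
        for s in range(r + 1, spec.K):
            se = np.hypot(
                np.hypot(_omega_se(spec, r, r), _omega_se(spec, s, s)),
                _omega_se(spec, r, s),
            )
            wrr, wss, wrs = omega[r, r], omega[s, s], omega[r, s]
            if kind == "assortative":
                gap = min(wrr, wss) - wrs
            elif kind == "disassortative":
                gap = wrs - max(wrr, wss)
            else:  # core_periphery, community r=0 is the core
                gap = min(wrr - wrs, wrs - wss)
            ok = ok and gap >= n_se * se
    if not ok:
        raise ValueError(
            f"block sizes {spec.sizes} too small to guarantee a {n_se}-SE "
            f"classification margin for kind={kind!r}; increase sizes"
        )


def mixed_motif_preset(
    block_size: int = 30, mu: float = 1.0, var: float = 0.04
) -> BlockSpec:
    """Four equal blocks planting all three interaction motifs at once.

    Block 3 is a globally dense core, block 4 a sparse periphery, and blocks
    1-2 an assortative pair; block 1 also links densely to 4.  Expected
    pairwise classifications: (1,2) assortative; (1,3), (2,3), (2,4), (3,4)
    core-periphery; (1,4) disassortative.  Because the core is dense to
    every other block, even coarse 2-community merges of this network are
    non-assortative, making it the heterogeneous test bed where a purely
    assortative method and a blockmodel should disagree at every K.
    """
    theta = np.array(
        [
            [0.45, 0.05, 0.50, 0.50],
            [0.05, 0.45, 0.50, 0.10],
            [0.50, 0.50, 0.70, 0.45],
            [0.50, 0.10, 0.45, 0.05],
        ]
    )
    K = 4
    return BlockSpec(
        K=K,
        sizes=(block_size,) * K,
        edge_prob=theta,
        weight_mean=np.full((K, K), mu),
        weight_var=np.full((K, K), var),
    )


def rewire_preserving_degree(
    network: WeightedNetwork, n_swaps_per_edge: int = 10, seed: int | None = None
) -> WeightedNetwork:
    """Maslov-Sneppen double-edge swaps; weights travel with their edges.

    The binary degree sequence, the edge count and the multiset of edge
    weights are preserved exactly.  Swap attempts producing self-loops or
    multi-edges are rejected (they still count as attempts).
    """
    if network.directed:
        raise NotImplementedError("rewiring is implemented for undirected networks")
    if n_swaps_per_edge < 1:
        raise ValueError("n_swaps_per_edge must be >= 1")
    edges = network.edges()
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    edge_arr = [(i, j, w) for i, j, w in edges]
    present = {(i, j) for i, j, _ in edge_arr}
    n_attempts = n_swaps_per_edge * len(edge_arr)
    m = len(edge_arr)
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b, w1 = edge_arr[e1]
        c, d, w2 = edge_arr[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-d, c-b (keeps each node's degree)
        if len({a, b, c, d}) < 4:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in present or new2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(new1)
        present.add(new2)
        edge_arr[e1] = (new1[0], new1[1], w1)
        edge_arr[e2] = (new2[0], new2[1], w2)
    n = network.n_nodes
    mat = np.zeros((n, n))
    for i, j, w in edge_arr:
        mat[i, j] = w
        mat[j, i] = w
    return WeightedNetwork(mat, directed=False, node_ids=list(network.node_ids))


def permute_partition_labels(partition: Partition, seed: int | None = None) -> Partition:
    """Uniformly permute node assignments; community sizes are preserved."""
    rng = np.random.default_rng(seed)
    return Partition(rng.permutation(partition.labels))
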