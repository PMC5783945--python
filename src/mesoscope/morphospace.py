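"""Community-interaction motifs, the community morphospace, node motif
participation, and the diversity (entropy) index.

Every pair of communities {r, s} is a point (omega_rr, omega_ss, omega_rs)
in a 3-D morphospace and is classified by the piecewise rule

    assortative      if min(omega_rr, omega_ss) > omega_rs
    core-periphery   if omega_rr > omega_rs > omega_ss   (r is the core)
    core-periphery   if omega_ss > omega_rs > omega_rr   (s is the core)
    disassortative   if omega_rs > max(omega_rr, omega_ss)

Exact ties between densities have measure zero for continuous weights but do
occur on toy inputs; they are resolved by the precedence assortative >
core-periphery > disassortative and flagged.

Node-level participation counts how often a node's community takes part in
each of four roles (assortative, core, periphery, disassortative),
normalized by the total motif count K(K-1)/2 (K(K-1) when directed).
Community-level motif probabilities (P_a, P_c, P_p, P_d) are the class
frequencies among that community's K-1 interactions; their entropy
H_r = -sum P log2 P (in [0, 2] bits) is the diversity index, assigned to
every member node.  Both normalizations are exposed because they answer
slightly different questions (share of all motifs vs composition of a
community's own interactions).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .assort import BlockDensityMatrix
from .netio import Partition

__all__ = [
    "MotifClass",
    "PairMotif",
    "ParticipationProfile",
    "classify_motif",
    "morphospace_points",
    "motif_participation",
    "diversity_index",
    "node_diversity",
    "average_node_scores",
]


class MotifClass(str, Enum):
    ASSORTATIVE = "assortative"
    CORE_PERIPHERY = "core_periphery"
    DISASSORTATIVE = "disassortative"


@dataclass
class PairMotif:
    r: int
    s: int
    omega_rr: float
    omega_ss: float
    omega_rs: float
    motif: MotifClass
    core: int | None  # community id of the core, iff core_periphery
    tie: bool = False


def classify_motif(
    omega_rr: float, omega_ss: float, omega_rs: float
) -> tuple[MotifClass, str | None, bool]:
    """Classify one community dyad; returns (class, core side 'r'/'s'/None, tie flag)."""
    vals = (omega_rr, omega_ss, omega_rs)
    if any(not np.isfinite(v) for v in vals):
        raise ValueError(f"densities must be finite, got {vals}")
    if min(omega_rr, omega_ss) > omega_rs:
        return MotifClass.ASSORTATIVE, None, False
    if omega_rr > omega_rs > omega_ss:
        return MotifClass.CORE_PERIPHERY, "r", False
    if omega_ss > omega_rs > omega_rr:
        return MotifClass.CORE_PERIPHERY, "s", False
    if omega_rs > max(omega_rr, omega_ss):
        return MotifClass.DISASSORTATIVE, None, False
    # ties: strict rules exhausted; precedence assortative > CP > disassortative
    if min(omega_rr, omega_ss) >= omega_rs:
        return MotifClass.ASSORTATIVE, None, True
    if omega_rr >= omega_rs >= omega_ss:
        return MotifClass.CORE_PERIPHERY, "r", True
    if omega_ss >= omega_rs >= omega_rr:
        return MotifClass.CORE_PERIPHERY, "s", True
    return MotifClass.DISASSORTATIVE, None, True


def morphospace_points(bdm: BlockDensityMatrix) -> list[PairMotif]:
    """Classified morphospace points, one per community pair.

    Undirected: K(K-1)/2 unordered pairs.  Directed: K(K-1) ordered pairs,
    each classified from the directed between-density.
    """
    K = bdm.K
    if K < 2:
        raise ValueError("need K >= 2 communities")
    pairs = (
        permutations(range(K), 2) if bdm.directed else combinations(range(K), 2)
    )
    points = []
    for r, s in pairs:
        omega = bdm.omega_out if bdm.directed else bdm.omega
        wrr, wss, wrs = omega[r, r], omega[s, s], omega[r, s]
        cls, core_side, tie = classify_motif(wrr, wss, wrs)
        core = {None: None, "r": r + 1, "s": s + 1}[core_side]
        points.append(
            PairMotif(
                r=r + 1, s=s + 1, omega_rr=wrr, omega_ss=wss, omega_rs=wrs,
                motif=cls, core=core, tie=tie,
            )
        )
    return points


_ROLES = ("assortative", "core", "periphery", "disassortative")


@dataclass
class ParticipationProfile:
    """Node- and community-level motif participation for one partition."""

    node_participation: pd.DataFrame  # N x 4, normalized by total motif count
    node_counts: pd.DataFrame  # N x 4 raw counts
    community_probabilities: pd.DataFrame  # K x 4, rows sum to 1 (over K-1 interactions)
    total_motifs: int


def _pair_roles(point: PairMotif) -> dict[int, str]:
    """Role played by each community of a classified pair."""
    if point.motif is MotifClass.ASSORTATIVE:
        return {point.r: "assortative", point.s: "assortative"}
    if point.motif is MotifClass.DISASSORTATIVE:
        return {point.r: "disassortative", point.s: "disassortative"}
    periph = point.s if point.core == point.r else point.r
    return {point.core: "core", periph: "periphery"}


def motif_participation(
    points: list[PairMotif], partition: Partition, directed: bool = False
) -> ParticipationProfile:
    """Per-node and per-community motif participation from classified pairs."""
    K = partition.K
    if K < 2:
        raise ValueError("participation undefined for a single community (no interactions)")
    total = K * (K - 1) if directed else K * (K - 1) // 2
    if len(points) != total:
        raise ValueError("classification does not match the partition's K")
    comm_counts = pd.DataFrame(
        0.0, index=np.arange(1, K + 1), columns=list(_ROLES)
    )
    for pt in points:
        for comm, role in _pair_roles(pt).items():
            comm_counts.loc[comm, role] += 1.0
    interactions = K - 1 if not directed else 2 * (K - 1)
    comm_probs = comm_counts / interactions

    node_counts = comm_counts.loc[partition.labels].reset_index(drop=True)
    node_part = node_counts / total
    return ParticipationProfile(
        node_participation=node_part,
        node_counts=node_counts,
        community_probabilities=comm_probs,
        total_motifs=total,
    )


def diversity_index(probabilities) -> float:
    """Entropy H = -sum P log2 P over the four motif classes, in bits.

    Zero when a single class is used; 2 bits at the uniform maximum.
    """
    p = np.asarray(probabilities, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("motif probabilities must sum to 1")
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def node_diversity(profile: ParticipationProfile, partition: Partition) -> np.ndarray:
    """Assign each community's diversity H_r to all of its member nodes."""
    h = {
        r: diversity_index(profile.community_probabilities.loc[r].to_numpy())
        for r in profile.community_probabilities.index
    }
    return np.array([h[lab] for lab in partition.labels])


def average_node_scores(score_vectors: list[np.ndarray]) -> np.ndarray:
    """Mean per-node score across partitions, omitting NaN pairwise."""
    if not score_vectors:
        raise ValueError("need at least one score vector")
    mat = np.vstack(score_vectors)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(mat, axis=0)
    return out
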