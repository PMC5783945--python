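"""Information-theoretic partition comparison.

Variation of information VI(P1, P2) = H(P1) + H(P2) - 2 I(P1, P2), computed
from the label contingency table in bits.  VI is a metric on partitions
(zero iff the partitions agree up to relabeling, symmetric, triangle
inequality) bounded above by log2(N).

`vi_within_between` packages the within- versus between-technique
dissimilarity comparison: all pairwise VI values inside each partition
ensemble and across the two, with one-tailed Welch t-tests of whether the
within-technique mean is smaller than the between-technique mean.  Note the
pairwise VI values share partitions and are therefore not independent
samples; the t-tests are reported as-is with that caveat attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats

from .netio import Partition

__all__ = ["VIMatrixSummary", "variation_of_information", "vi_within_between"]


def variation_of_information(p1: Partition, p2: Partition) -> float:
    """VI between two partitions of the same node set, in bits."""
    if p1.n_nodes != p2.n_nodes:
        raise ValueError("partitions must cover the same number of nodes")
    n = p1.n_nodes
    cont = np.zeros((p1.K, p2.K))
    np.add.at(cont, (p1.labels - 1, p2.labels - 1), 1.0)
    pxy = cont / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    nz = pxy > 0
    mi = float((pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz])).sum())
    vi = _ent(px) + _ent(py) - 2.0 * mi
    # clip float noise at the metric's lower bound so VI = 0 iff identical
    return vi if vi > 1e-12 else 0.0


@dataclass
class VIMatrixSummary:
    within_A: np.ndarray
    within_B: np.ndarray
    between: np.ndarray
    t_A: float
    p_A: float
    t_B: float
    p_B: float
    note: str = (
        "pairwise VI values share partitions and are not independent samples; "
        "t-tests reported as specified"
    )


def vi_within_between(
    ensemble_A: list[Partition], ensemble_B: list[Partition]
) -> VIMatrixSummary:
    """Within- vs between-technique VI with one-tailed Welch t-tests (within < between)."""
    if len(ensemble_A) < 2 or len(ensemble_B) < 2:
        raise ValueError("each ensemble needs at least 2 partitions")
    n_nodes = {p.n_nodes for p in ensemble_A + ensemble_B}
    if len(n_nodes) != 1:
        raise ValueError("all partitions must cover the same node set")
    ks = {p.K for p in ensemble_A + ensemble_B}
    if len(ks) != 1:
        raise ValueError("partitions are only compared at equal K")

    within_A = np.array(
        [variation_of_information(a, b) for a, b in combinations(ensemble_A, 2)]
    )
    within_B = np.array(
        [variation_of_information(a, b) for a, b in combinations(ensemble_B, 2)]
    )
    between = np.array(
        [variation_of_information(a, b) for a, b in product(ensemble_A, ensemble_B)]
    )
    t_A, p_A = stats.ttest_ind(within_A, between, equal_var=False, alternative="less")
    t_B, p_B = stats.ttest_ind(within_B, between, equal_var=False, alternative="less")
    return VIMatrixSummary(
        within_A=within_A,
        within_B=within_B,
        between=between,
        t_A=float(t_A),
        p_A=float(p_A),
        t_B=float(t_B),
        p_B=float(p_B),
    )
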