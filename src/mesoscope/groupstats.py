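"""Comparative statistics: curve-difference permutation tests, metadata
within/between contrasts, system-level permutation tests, strength-binned
motif dominance, degree-standardized assortativity, and the
diversity-behavior correlation.

Permutation p-values use the add-one convention (b + 1) / (n_perm + 1),
which is exact under exchangeability and never zero at finite n_perm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assort import regional_assortativity
from .netio import Partition, WeightedNetwork
from .synthgen import rewire_preserving_degree

__all__ = [
    "CurveTestResult",
    "BehaviorCorrelationResult",
    "fda_curve_test",
    "curve_difference_statistic",
    "motif_proportions",
    "motif_proportions_vs_k",
    "within_between_contrast",
    "contrast_ensembles",
    "system_permutation_test",
    "strength_binned_dominance",
    "degree_standardized_assortativity",
    "behavior_correlation",
]


def _as_seed_seq(seed):
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# functional-data curve comparison
# ---------------------------------------------------------------------------


def _pool_curve(samples: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """(x, value) samples -> mean value at each observed x, sorted by x."""
    df = pd.DataFrame(samples, columns=["x", "v"])
    g = df.groupby("x")["v"].mean()
    return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)


def curve_difference_statistic(
    samples_A: Sequence[tuple[float, float]], samples_B: Sequence[tuple[float, float]]
) -> float:
    """Summed pointwise difference (A - B) of the two pooled curves.

    The grid is the union of observed x values; each curve is linearly
    interpolated inside its own support and grid points outside either
    support are skipped pairwise.
    """
    xa, va = _pool_curve(samples_A)
    xb, vb = _pool_curve(samples_B)
    grid = np.union1d(xa, xb)
    ok = (grid >= xa.min()) & (grid <= xa.max()) & (grid >= xb.min()) & (grid <= xb.max())
    if not ok.any():
        raise ValueError("curves have no overlapping support")
    ga = np.interp(grid[ok], xa, va)
    gb = np.interp(grid[ok], xb, vb)
    return float((ga - gb).sum())


@dataclass
class CurveTestResult:
    statistic: float
    p_value: float
    null_statistics: np.ndarray
    n_perm: int
    alternative: str


def fda_curve_test(
    samples_A: Sequence[tuple[float, float]],
    samples_B: Sequence[tuple[float, float]],
    permute: Callable[[np.random.Generator], tuple[Sequence, Sequence]],
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> CurveTestResult:
    """Permutation test on the summed pointwise curve difference.

    ``permute(rng)`` must regenerate a (samples_A, samples_B) pair under the
    null (e.g., curves recomputed after uniformly permuting partition
    labels).  The statistic is antisymmetric in its arguments.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not samples_A or not samples_B:
        raise ValueError("both sample sets must be non-empty")
    obs = curve_difference_statistic(samples_A, samples_B)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        na, nb = permute(rng)
        null[b] = curve_difference_statistic(na, nb)
    if alternative == "two-sided":
        extreme = np.abs(null) >= abs(obs)
    elif alternative == "less":
        extreme = null <= obs
    elif alternative == "greater":
        extreme = null >= obs
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + extreme.sum()) / (n_perm + 1.0)
    return CurveTestResult(
        statistic=obs, p_value=float(p), null_statistics=null,
        n_perm=n_perm, alternative=alternative,
    )


# ---------------------------------------------------------------------------
# motif proportions across K
# ---------------------------------------------------------------------------

_CLASSES = ("assortative", "core_periphery", "disassortative")


def motif_proportions(class_labels: Sequence[str]) -> dict[str, float]:
    """Fraction of community pairs per motif class (sums to 1)."""
    n = len(class_labels)
    if n == 0:
        raise ValueError("no classified pairs")
    return {c: sum(1 for x in class_labels if str(x) == c) / n for c in _CLASSES}


def motif_proportions_vs_k(
    ensembles_A: Mapping[int, Sequence[str]],
    ensembles_B: Mapping[int, Sequence[str]],
    permute: Callable[[np.random.Generator], tuple[Mapping, Mapping]] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Per-K motif-class proportion curves and their aggregate difference.

    ``ensembles_X[K]`` pools the class labels of all community pairs over
    restarts at that K.  The aggregate statistic sums, over the three
    classes, the absolute summed pointwise difference of the proportion
    curves.  When ``permute`` is given, a permutation null on the aggregate
    statistic is run and a :class:`CurveTestResult` is attached.
    """
    if set(ensembles_A) != set(ensembles_B):
        raise ValueError("both methods must cover the same K levels")

    def _curves(ens: Mapping[int, Sequence[str]]) -> pd.DataFrame:
        rows = {k: motif_proportions(v) for k, v in sorted(ens.items())}
        return pd.DataFrame(rows).T  # index K, columns classes

    def _stat(ea, eb) -> float:
        ca, cb = _curves(ea), _curves(eb)
        return float(np.abs((ca - cb).sum(axis=0)).sum())

    curves_A = _curves(ensembles_A)
    curves_B = _curves(ensembles_B)
    obs = _stat(ensembles_A, ensembles_B)
    result = {"curves_A": curves_A, "curves_B": curves_B, "statistic": obs}
    if permute is not None:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            na, nb = permute(rng)
            null[b] = _stat(na, nb)
        p = (1.0 + (null >= obs).sum()) / (n_perm + 1.0)
        result["test"] = CurveTestResult(
            statistic=obs, p_value=float(p), null_statistics=null,
            n_perm=n_perm, alternative="greater",
        )
    return result


# ---------------------------------------------------------------------------
# metadata (e.g., functional connectivity) contrasts
# ---------------------------------------------------------------------------


def within_between_contrast(
    metadata: np.ndarray, partition: Partition
) -> tuple[float, float, float]:
    """(mean within, mean between, within - between) over unordered node pairs.

    ``metadata`` is any symmetric node-pair matrix (functional connectivity,
    co-expression, ...); the diagonal is excluded.
    """
    metadata = np.asarray(metadata, dtype=float)
    n = partition.n_nodes
    if metadata.shape != (n, n):
        raise ValueError("metadata matrix does not match the partition")
    iu = np.triu_indices(n, k=1)
    same = (partition.labels[:, None] == partition.labels[None, :])[iu]
    if same.all():
        raise ValueError("partition has no between-community pairs")
    vals = metadata[iu]
    mean_within = float(vals[same].mean())
    mean_between = float(vals[~same].mean())
    return mean_within, mean_between, mean_within - mean_between


def contrast_ensembles(
    metadata: np.ndarray,
    ensemble_A: Sequence[Partition],
    ensemble_B: Sequence[Partition],
) -> dict:
    """Per-partition within-between differences for two methods + Welch t-test."""
    da = np.array([within_between_contrast(metadata, p)[2] for p in ensemble_A])
    db = np.array([within_between_contrast(metadata, p)[2] for p in ensemble_B])
    t, p = stats.ttest_ind(da, db, equal_var=False)
    return {"diff_A": da, "diff_B": db, "t": float(t), "p": float(p)}


# ---------------------------------------------------------------------------
# system-level permutation test
# ---------------------------------------------------------------------------


def system_permutation_test(
    node_values: np.ndarray,
    system_labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-system mean of a node score against a value-permutation null.

    Node values are permuted across nodes (system sizes fixed).  One-sided
    p-values are reported in both directions with BH-FDR across systems.
    """
    node_values = np.asarray(node_values, dtype=float)
    system_labels = np.asarray(system_labels)
    if node_values.shape != system_labels.shape:
        raise ValueError("values and labels must align")
    systems, inverse = np.unique(system_labels, return_inverse=True)
    n_sys = systems.size
    counts = np.bincount(inverse)
    if (counts == 0).any():
        raise ValueError("every system needs at least one node")
    obs = np.array([node_values[inverse == s].mean() for s in range(n_sys)])
    rng = np.random.default_rng(seed)
    ge = np.zeros(n_sys)
    le = np.zeros(n_sys)
    onehot = np.zeros((node_values.size, n_sys))
    onehot[np.arange(node_values.size), inverse] = 1.0
    onehot /= counts
    for _ in range(n_perm):
        null_means = rng.permutation(node_values) @ onehot
        ge += null_means >= obs
        le += null_means <= obs
    p_high = (1.0 + ge) / (n_perm + 1.0)
    p_low = (1.0 + le) / (n_perm + 1.0)
    q_high = stats.false_discovery_control(p_high)
    q_low = stats.false_discovery_control(p_low)
    return pd.DataFrame(
        {
            "system": systems,
            "n_nodes": counts,
            "mean": obs,
            "p_high": p_high,
            "q_high": q_high,
            "significant_high": q_high < fdr_alpha,
            "p_low": p_low,
            "q_low": q_low,
            "significant_low": q_low < fdr_alpha,
        }
    )


# ---------------------------------------------------------------------------
# strength-binned motif dominance
# ---------------------------------------------------------------------------


def strength_binned_dominance(
    node_strengths: np.ndarray, participation: pd.DataFrame, n_bins: int
) -> pd.DataFrame:
    """Mean motif participation per quantile strength bin + bin entropy (bits)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = np.asarray(node_strengths, dtype=float)
    if np.unique(s).size < n_bins:
        raise ValueError("fewer distinct strengths than bins")
    try:
        bins = pd.qcut(s, n_bins, labels=False, duplicates="raise")
    except ValueError as exc:
        raise ValueError("strength distribution does not support equal-count bins") from exc
    df = participation.copy()
    df["_bin"] = bins
    means = df.groupby("_bin").mean()
    probs = means.div(means.sum(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(probs > 0, np.log2(probs), 0.0)
    means["entropy_bits"] = -(probs.to_numpy() * logp).sum(axis=1)
    means.index.name = "strength_bin"
    return means


# ---------------------------------------------------------------------------
# degree-standardized regional assortativity
# ---------------------------------------------------------------------------


def degree_standardized_assortativity(
    network: WeightedNetwork,
    partition_ensemble: Sequence[Partition],
    n_null: int = 100,
    seed: int | None = None,
    n_swaps_per_edge: int = 10,
) -> np.ndarray:
    """Per-node z-score of mean regional assortativity against rewired nulls.

    z_i = (mean observed phi_i - mean phi_i over degree-preserving rewired
    networks) / null standard deviation.  This standardization against a
    degree-preserving ensemble is one defensible reading of a
    "corrected for degree" score; it is labeled as such in outputs.
    """
    if not partition_ensemble:
        raise ValueError("partition ensemble must be non-empty")

    def _mean_phi(net: WeightedNetwork) -> np.ndarray:
        mat = np.vstack([regional_assortativity(net, p) for p in partition_ensemble])
        with np.errstate(invalid="ignore"):
            return np.nanmean(mat, axis=0)

    obs = _mean_phi(network)
    ss = _as_seed_seq(seed)
    nulls = np.vstack(
        [
            _mean_phi(rewire_preserving_degree(network, n_swaps_per_edge, child))
            for child in ss.spawn(n_null)
        ]
    )
    mu = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mu) / sd
    z[sd == 0] = np.nan
    return z


# ---------------------------------------------------------------------------
# diversity-behavior correlation
# ---------------------------------------------------------------------------


@dataclass
class BehaviorCorrelationResult:
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    residuals: np.ndarray  # subjects x regions


def behavior_correlation(
    region_diversity: np.ndarray,
    total_weight: np.ndarray,
    accuracy: np.ndarray,
    fdr_alpha: float = 0.05,
) -> BehaviorCorrelationResult:
    """Spearman correlation of accuracy with total-weight-partialed diversity.

    ``region_diversity`` is subjects x regions; each region's diversity is
    residualized on subjects' total connection weight (least squares with
    intercept) and the residuals are rank-correlated with the composite
    accuracy score.  Two-sided p-values, BH-FDR across regions.
    """
    D = np.atleast_2d(np.asarray(region_diversity, dtype=float))
    tw = np.asarray(total_weight, dtype=float)
    acc = np.asarray(accuracy, dtype=float)
    n_subj, n_reg = D.shape
    if tw.shape != (n_subj,) or acc.shape != (n_subj,):
        raise ValueError("covariate arrays must have one entry per subject")
    if n_subj < 4:
        raise ValueError("need at least 4 subjects")
    design = np.column_stack([np.ones(n_subj), tw])
    coef, *_ = np.linalg.lstsq(design, D, rcond=None)
    resid = D - design @ coef
    rho = np.full(n_reg, np.nan)
    p = np.full(n_reg, np.nan)
    for r in range(n_reg):
        if np.allclose(resid[:, r], resid[0, r]):
            continue  # constant residuals: correlation undefined
        res = stats.spearmanr(resid[:, r], acc)
        rho[r], p[r] = res.statistic, res.pvalue
    q = np.full(n_reg, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok])
    significant = np.where(np.isfinite(q), q < fdr_alpha, False)
    return BehaviorCorrelationResult(rho=rho, p=p, q=q, significant=significant, residuals=resid)
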