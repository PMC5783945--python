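"""Curve-difference permutation tests, contrasts, and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mesoscope import (
    Partition,
    WeightedNetwork,
    behavior_correlation,
    curve_difference_statistic,
    degree_standardized_assortativity,
    fda_curve_test,
    motif_proportions,
    motif_proportions_vs_k,
    strength_binned_dominance,
    system_permutation_test,
    within_between_contrast,
)
from mesoscope.groupstats import contrast_ensembles

from conftest import make_random_network, make_random_partition


class TestCurveDifference:
    def test_identical_samples_statistic_zero_p_one(self):
        samples = [(1, 0.5), (2, 0.7), (3, 0.2)]
        res = fda_curve_test(
            samples, list(samples),
            permute=lambda rng: (samples, list(samples)),
            n_perm=50, seed=0,
        )
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_offset_flat_curves(self):
        g = 5
        a = [(x, 2.0) for x in range(g)]
        b = [(x, 1.5) for x in range(g)]
        assert curve_difference_statistic(a, b) == pytest.approx(g * 0.5)

    def test_antisymmetry(self, rng):
        a = [(x, rng.normal()) for x in range(6)]
        b = [(x, rng.normal()) for x in range(6)]
        assert curve_difference_statistic(a, b) == pytest.approx(
            -curve_difference_statistic(b, a)
        )

    def test_null_p_values_uniform(self):
        # data and permutation from the same exchangeable null: p uniform
        # within Monte-Carlo error (KS check)
        rng_master = np.random.default_rng(5)
        pvals = []
        for _ in range(500):
            y = rng_master.normal(size=30)
            x = np.repeat(np.arange(5), 6)

            def split(values, rng):
                perm = rng.permutation(30)
                return (
                    list(zip(x, values[perm[:15]])),
                    list(zip(x, values[perm[15:]])),
                )

            a, b = split(y, rng_master)
            res = fda_curve_test(
                a, b, permute=lambda rng: split(y, rng), n_perm=39,
                seed=int(rng_master.integers(2**31)),
            )
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            curve_difference_statistic([(1, 0.0)], [(5, 0.0)])


class TestMotifProportions:
    def test_proportions_sum_to_one(self):
        labels = ["assortative", "core_periphery", "assortative", "disassortative"]
        p = motif_proportions(labels)
        assert sum(p.values()) == pytest.approx(1.0)
        assert p["assortative"] == pytest.approx(0.5)

    def test_identical_ensembles_zero_statistic(self):
        ens = {2: ["assortative"], 3: ["assortative"] * 3}
        out = motif_proportions_vs_k(ens, {k: list(v) for k, v in ens.items()})
        assert out["statistic"] == 0.0

    def test_mismatched_k_levels_error(self):
        with pytest.raises(ValueError, match="same K"):
            motif_proportions_vs_k({2: ["assortative"]}, {3: ["assortative"]})


class TestWithinBetweenContrast:
    def test_constructed_contrast(self):
        n = 6
        part = Partition(np.repeat([1, 2], 3))
        same = part.labels[:, None] == part.labels[None, :]
        mat = np.where(same, 0.8, 0.2).astype(float)
        np.fill_diagonal(mat, 0.0)
        w, b, d = within_between_contrast(mat, part)
        assert (w, b, d) == (pytest.approx(0.8), pytest.approx(0.2), pytest.approx(0.6))

    def test_constant_matrix_zero_difference(self):
        part = Partition(np.array([1, 1, 2, 2]))
        mat = np.full((4, 4), 0.3)
        np.fill_diagonal(mat, 0.0)
        # use constant off-diagonal values
        mat2 = np.full((4, 4), 0.3)
        assert within_between_contrast(mat2, part)[2] == pytest.approx(0.0)

    def test_random_matrix_random_partition_near_zero(self, rng):
        diffs = []
        for _ in range(200):
            m = rng.normal(size=(12, 12))
            m = (m + m.T) / 2
            part = make_random_partition(rng, 12, 3)
            diffs.append(within_between_contrast(m, part)[2])
        assert abs(np.mean(diffs)) < 0.05

    def test_one_community_errors(self):
        with pytest.raises(ValueError, match="between"):
            within_between_contrast(np.zeros((4, 4)), Partition(np.ones(4, dtype=int)))

    def test_ensemble_contrast_detects_alignment(self, rng):
        part = Partition(np.repeat([1, 2, 3], 5))
        same = part.labels[:, None] == part.labels[None, :]
        fc = np.where(same, 0.8, 0.1) + rng.normal(0, 0.05, (15, 15))
        fc = (fc + fc.T) / 2
        aligned = [part] * 5
        random_ens = [make_random_partition(rng, 15, 3) for _ in range(5)]
        out = contrast_ensembles(fc, aligned, random_ens)
        assert out["diff_A"].mean() > out["diff_B"].mean()
        assert out["p"] < 0.01


class TestSystemPermutationTest:
    def test_constant_values_p_one(self):
        labels = np.repeat(["a", "b"], 5)
        out = system_permutation_test(np.ones(10), labels, n_perm=99, seed=0)
        assert (out["p_high"] == 1.0).all()

    def test_shifted_system_detected(self, rng):
        labels = np.repeat(["a", "b", "c"], 10)
        vals = rng.normal(size=30)
        vals[:10] += 5.0
        out = system_permutation_test(vals, labels, n_perm=199, seed=1)
        row = out[out["system"] == "a"].iloc[0]
        assert row["p_high"] == pytest.approx(1 / 200)
        assert row["significant_high"]

    def test_means_match_groupby(self, rng):
        labels = rng.choice(["x", "y", "z"], size=20)
        vals = rng.normal(size=20)
        out = system_permutation_test(vals, labels, n_perm=19, seed=2)
        for _, row in out.iterrows():
            assert row["mean"] == pytest.approx(vals[labels == row["system"]].mean())


class TestStrengthBinnedDominance:
    def _profiles(self, n, rng):
        p = rng.dirichlet(np.ones(4), size=n)
        return pd.DataFrame(p, columns=["assortative", "core", "periphery", "disassortative"])

    def test_identical_profiles_flat(self, rng):
        prof = pd.DataFrame(
            np.tile([0.25, 0.25, 0.25, 0.25], (20, 1)),
            columns=["assortative", "core", "periphery", "disassortative"],
        )
        out = strength_binned_dominance(np.arange(20, dtype=float), prof, n_bins=4)
        np.testing.assert_allclose(out["core"], 0.25)
        np.testing.assert_allclose(out["entropy_bits"], 2.0)

    def test_entropy_bounds(self, rng):
        out = strength_binned_dominance(
            rng.normal(size=30), self._profiles(30, rng), n_bins=3
        )
        assert ((out["entropy_bits"] >= 0) & (out["entropy_bits"] <= 2)).all()

    def test_high_strength_core_dominates_top_bin(self, rng):
        n = 30
        strengths = np.linspace(1, 10, n)
        prof = self._profiles(n, rng)
        prof.loc[n - 10 :, :] = 0.0
        prof.loc[n - 10 :, "core"] = 1.0
        out = strength_binned_dominance(strengths, prof, n_bins=3)
        top = out.iloc[-1]
        assert top["core"] == top[["assortative", "core", "periphery", "disassortative"]].max()

    def test_too_few_distinct_strengths(self):
        prof = pd.DataFrame(np.full((4, 4), 0.25),
                            columns=["assortative", "core", "periphery", "disassortative"])
        with pytest.raises(ValueError, match="distinct"):
            strength_binned_dominance(np.array([1.0, 1.0, 1.0, 1.0]), prof, n_bins=2)


class TestDegreeStandardizedAssortativity:
    def test_planted_blocks_positive_z_and_scale_invariance(self, planted_assortative):
        net, planted = planted_assortative
        z = degree_standardized_assortativity(net, [planted], n_null=20, seed=0)
        assert np.nanmean(z) > 1.0
        z2 = degree_standardized_assortativity(
            WeightedNetwork(net.weights * 4.0), [planted], n_null=20, seed=0
        )
        np.testing.assert_allclose(z2, z, rtol=1e-8)


class TestBehaviorCorrelation:
    def test_monotone_region_gives_rho_one(self, rng):
        n = 20
        div = rng.normal(size=(n, 3))
        tw = np.zeros(n)
        acc = div[:, 1] ** 3  # strictly monotone in region 1's residuals
        out = behavior_correlation(div, tw, acc)
        assert out.rho[1] == pytest.approx(1.0)

    def test_orthogonal_covariate_leaves_rho_unchanged(self, rng):
        n = 40
        tw = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        div_raw = rng.normal(size=(n, 2))
        div = div_raw - tw[:, None] * (tw @ div_raw) / n  # orthogonalize to tw
        acc = rng.normal(size=n)
        out = behavior_correlation(div, tw, acc)
        for r in range(2):
            raw_rho = stats.spearmanr(div[:, r], acc).statistic
            assert out.rho[r] == pytest.approx(raw_rho)

    def test_null_fdr_significant_set_usually_empty(self, rng):
        hits = 0
        for _ in range(100):
            div = rng.normal(size=(20, 6))
            out = behavior_correlation(div, rng.normal(size=20), rng.normal(size=20))
            hits += out.significant.any()
        assert hits <= 10

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="4 subjects"):
            behavior_correlation(rng.normal(size=(3, 2)), np.zeros(3), np.zeros(3))
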