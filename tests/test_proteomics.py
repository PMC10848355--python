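import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bpomics import (
    LFQMatrix,
    dep_counts,
    detection_filter,
    gen_lfq,
    impute,
    moderated_t,
    repeated_imputation_de,
    significance_curve,
)
from bpomics.stats import bh_adjust


def _lfq(vals, n_a=4):
    vals = np.asarray(vals, dtype=float)
    df = pd.DataFrame(
        vals,
        index=[f"p{i}" for i in range(vals.shape[0])],
        columns=[f"s{i}" for i in range(vals.shape[1])],
    )
    groups = {f"s{i}": ("A" if i < n_a else "B") for i in range(vals.shape[1])}
    return LFQMatrix.from_intensities(df, groups)


class TestDetectionFilter:
    def test_single_detection_per_group_dropped(self):
        vals = np.full((1, 8), np.nan)
        vals[0, 0] = 20.0
        vals[0, 4] = 21.0
        base = np.random.default_rng(0).normal(20, 1, size=(3, 8))
        lfq = _lfq(np.vstack([vals, base]))
        kept = detection_filter(lfq)
        assert "p0" not in kept.proteins and len(kept.proteins) == 3

    def test_fully_observed_kept(self, small_lfq):
        assert "p4" in detection_filter(small_lfq).proteins

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 2, size=(40, 8))
        vals[rng.random(vals.shape) < 0.45] = np.nan
        lfq = _lfq(vals)
        kept = set(detection_filter(lfq, min_detect=2).proteins)
        expected = set()
        for i, p in enumerate(lfq.proteins):
            for cols in (range(0, 4), range(4, 8)):
                if sum(not np.isnan(vals[i, j]) for j in cols) >= 2:
                    expected.add(p)
        assert kept == expected


class TestImpute:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(2)
        lfq = _lfq(rng.normal(20, 1, size=(5, 8)))
        completed, imputed = impute(lfq, seed=1)
        assert completed.equals(lfq.intensities)
        assert not imputed.to_numpy().any()

    def test_observed_entries_never_modified(self, small_lfq):
        completed, imputed = impute(small_lfq, seed=3)
        obs = ~small_lfq.mask.to_numpy()
        assert np.array_equal(
            completed.to_numpy()[obs], small_lfq.intensities.to_numpy()[obs]
        )
        assert np.array_equal(imputed.to_numpy(), small_lfq.mask.to_numpy())

    def test_tier2_imputes_group_mle_mean(self):
        vals = np.array([
            [18.0, 20.0, np.nan, 21.0, 22.0, 23.0],
            [19.0, 19.0, 19.0, 20.0, 20.0, 20.0],
            [17.0, 18.0, 19.0, 21.0, 20.0, 19.0],
            [16.0, 17.0, 18.0, 19.0, 20.0, 21.0],
        ])
        lfq = _lfq(vals, n_a=3)
        completed, _ = impute(lfq, seed=0)
        # group A observed {18, 20} -> MLE mean 19
        assert np.isclose(completed.iloc[0, 2], 19.0)

    def test_deterministic_under_seed(self, small_lfq):
        a, _ = impute(small_lfq, seed=11)
        b, _ = impute(small_lfq, seed=11)
        c, _ = impute(small_lfq, seed=12)
        assert a.equals(b)
        assert not a.equals(c)

    def test_sparse_column_rejected(self):
        vals = np.full((4, 6), np.nan)
        vals[:, 1:] = 20.0
        vals[0, 0] = 20.0
        with pytest.raises(ValueError, match="s0"):
            impute(_lfq(vals, n_a=3), seed=0)

    def test_tier1_downshift_distribution(self):
        """Tier-1 draws follow Normal(mean - 2.5 SD, (0.3 SD)^2) of the column."""
        rng = np.random.default_rng(10)
        n_obs, n_t1 = 2000, 50_000
        observed = rng.normal(20, 2, size=(n_obs, 4))
        hidden = np.full((n_t1, 4), np.nan)
        hidden[:, 2:] = rng.normal(20, 2, size=(n_t1, 2))
        lfq = _lfq(np.vstack([observed, hidden]), n_a=2)
        completed, _ = impute(lfq, seed=4)
        col = lfq.intensities.iloc[:, 0]
        mu, sd = col.mean(), col.std(ddof=1)
        draws = completed.iloc[n_obs:, 0].to_numpy()
        z = (draws.mean() - (mu - 2.5 * sd)) / (0.3 * sd / np.sqrt(n_t1))
        assert abs(z) < 4
        assert abs(draws.std(ddof=1) / (0.3 * sd) - 1) < 0.02


class TestModeratedT:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(7)
        vals = rng.normal(20, 1, size=(200, 6))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(200)],
                          columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        return df, groups

    def test_infinite_prior_df_gives_pooled_variance_t(self):
        df, groups = self._toy()
        res = moderated_t(df, ("B", "A"), groups, prior=(np.inf, 0.8))
        lfc = df.iloc[:, 3:].mean(axis=1) - df.iloc[:, :3].mean(axis=1)
        t = lfc / np.sqrt(0.8 * (1 / 3 + 1 / 3))
        assert np.allclose(res["t"], t, atol=1e-10)

    def test_zero_prior_df_gives_ordinary_t(self):
        df, groups = self._toy()
        res = moderated_t(df, ("B", "A"), groups, prior=(0.0, 1.0))
        ref = sps.ttest_ind(df.iloc[:, 3:], df.iloc[:, :3], axis=1)
        assert np.allclose(res["t"], ref.statistic, atol=1e-10)
        assert np.allclose(res["p"], ref.pvalue, atol=1e-10)

    def test_injected_prior_matches_hand_formula(self):
        vals = np.array([
            [10.0, 12.0, 11.0, 14.0, 15.0, 16.0],
            [20.0, 20.5, 19.5, 22.0, 21.0, 23.0],
        ])
        df = pd.DataFrame(vals, index=["p0", "p1"], columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        d0, s0sq = 4.0, 1.0
        res = moderated_t(df, ("B", "A"), groups, prior=(d0, s0sq))
        for i in range(2):
            a, b = vals[i, :3], vals[i, 3:]
            sg2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
            st2 = (d0 * s0sq + 4 * sg2) / (d0 + 4)
            t = (b.mean() - a.mean()) / np.sqrt(st2 * (2 / 3))
            assert abs(res["t"].iloc[i] - t) < 1e-10
            assert abs(res["df"].iloc[i] - 8.0) < 1e-12

    def test_null_pvalues_uniform(self):
        """Moderated-t p is ~uniform on null data with heterogeneous variances."""
        rng = np.random.default_rng(42)
        sd = np.exp(rng.normal(-0.5, 0.4, 5000))
        vals = rng.normal(20, 1, size=(5000, 1)) + sd[:, None] * rng.standard_normal((5000, 8))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(5000)],
                          columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        res = moderated_t(df, ("B", "A"), groups)
        assert sps.kstest(res["p"], "uniform").pvalue > 0.01

    def test_small_groups_rejected(self):
        df = pd.DataFrame(np.ones((3, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            moderated_t(df, ("B", "A"), {"a": "A", "b": "A", "c": "B"})


class TestSignificanceCurve:
    def test_fold_change_at_threshold_never_significant(self):
        assert not significance_curve(1.0, 1e-300)
        assert not significance_curve(-1.0, 1e-300)

    def test_asymptote_reaches_alpha(self):
        assert significance_curve(1e6, 0.049)
        assert not significance_curve(1e6, 0.051)

    def test_zero_curvature_is_rectangular_rule(self):
        lfc = np.array([0.5, 1.01, 2.0, -3.0])
        padj = np.array([0.01, 0.05, 0.2, 0.04])
        got = significance_curve(lfc, padj, curvature=0.0)
        assert got.tolist() == [False, True, False, True]

    def test_significant_set_shrinks_with_curvature(self):
        rng = np.random.default_rng(3)
        lfc = rng.normal(0, 2, 500)
        padj = rng.uniform(1e-6, 1, 500)
        prev = None
        for curv in (0.0, 0.25, 0.5, 1.0):
            cur = set(np.where(significance_curve(lfc, padj, curvature=curv))[0])
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            significance_curve(2.0, 0.01, curvature=-1)
        with pytest.raises(ValueError):
            significance_curve(2.0, 0.0)


class TestRepeatedImputation:
    def test_no_missing_makes_consistent_equal_significant(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(20, 1, size=(60, 8))
        vals[:10, 4:] += 3.0  # planted shift
        dep = repeated_imputation_de(_lfq(vals), ("B", "A"), n_cycles=5, base_seed=0)
        assert dep.table["significant"].equals(dep.table["consistent"])
        assert dep.table["significant"].sum() >= 8

    def test_single_cycle_consistency_is_significance(self):
        lfq, _ = gen_lfq(80, {"A": 4, "B": 4}, frac_de=0.2, delta=3.0, seed=2)
        dep = repeated_imputation_de(lfq, ("B", "A"), n_cycles=1, base_seed=5)
        assert dep.table["significant"].equals(dep.table["consistent"])

    def test_consistent_subset_of_every_cycle(self):
        """Recomputing each cycle confirms consistent = intersection of cycles."""
        lfq, _ = gen_lfq(100, {"A": 4, "B": 4}, frac_de=0.2, delta=3.0, seed=8)
        n_cycles, base = 4, 31
        dep = repeated_imputation_de(lfq, ("B", "A"), n_cycles=n_cycles, base_seed=base)
        filtered = detection_filter(lfq)
        inter = None
        for i in range(n_cycles):
            completed, _ = impute(filtered, seed=base + i)
            res = moderated_t(completed, ("B", "A"), filtered.groups)
            padj = bh_adjust(res["p"].to_numpy())
            sig = significance_curve(res["log2fc"].to_numpy(), padj)
            inter = sig if inter is None else (inter & sig)
        assert np.array_equal(dep.table["consistent"].to_numpy(), inter)

    def test_recovers_planted_proteins(self):
        """20-cycle consistency flag: recall >= 0.8, FDR <= 0.1 on planted
        3-log2-unit shifts with ~30% left-censored missingness (4 vs 4)."""
        lfq, truth = gen_lfq(
            400, {"control": 4, "T": 4}, frac_de=0.2, censor_quantile=0.3,
            delta=3.0, seed=3,
        )
        dep = repeated_imputation_de(lfq, ("T", "control"), n_cycles=20, base_seed=11)
        flagged = dep.consistent()
        planted = truth.de_features["T_vs_control"]
        assert len(flagged & planted) / len(planted) >= 0.8
        assert len(flagged - planted) / max(1, len(flagged)) <= 0.1

    def test_invalid_cycles(self, small_lfq):
        with pytest.raises(ValueError):
            repeated_imputation_de(small_lfq, ("B", "A"), n_cycles=0)


def test_dep_counts_split_by_sign():
    df = pd.DataFrame(
        {"log2fc": [2.0, -1.5, 3.0, -0.5], "significant": [True, True, False, True]},
        index=[f"p{i}" for i in range(4)],
    )
    c = dep_counts(df)
    assert c == {"up": 1, "down": 2, "total": 3}
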