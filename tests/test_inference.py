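import itertools

import numpy as np
import pytest

from oddwave.datasets import behavioral_group_stats
from oddwave.inference import (
    ClusterTestConfig,
    bootstrap_latency_test,
    onset_and_peak_latency,
    paired_difference_cluster_test,
    pooled_t_and_d,
    sign_permutation_cluster_test,
    two_sample_cluster_test,
)


def enumeration_cluster_p(dev, alpha=0.05):
    """Independent brute-force oracle: exact one-sample sign-flip cluster test.

    Enumerates all 2^n sign patterns, forms the exact permutation distribution,
    thresholds pointwise at `alpha`, and returns the corrected p of the
    observed cluster with the largest mass (1.0 if none).
    """
    n, T = dev.shape
    signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
    M = signs @ dev / n  # (2^n, T); the all-ones row is the observed map
    count_ge = (M[None, :, :] >= M[:, None, :]).sum(axis=1)  # rows with value >= M[r, t]
    mask = count_ge / signs.shape[0] <= alpha

    def cluster_masses(mask_row, m_row):
        out, t = [], 0
        while t < T:
            if mask_row[t]:
                s = t
                while t < T and mask_row[t]:
                    t += 1
                out.append(float(m_row[s:t].sum()))
            else:
                t += 1
        return out

    max_masses = np.array(
        [max(cluster_masses(mask[r], M[r]), default=0.0) for r in range(signs.shape[0])]
    )
    obs_row = int(np.flatnonzero((signs == 1).all(axis=1))[0])
    obs = cluster_masses(mask[obs_row], M[obs_row])
    if not obs:
        return 1.0
    return float((max_masses >= max(obs)).sum() / signs.shape[0])


class TestSignPermutationClusterTest:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        dev = rng.normal(-0.02, 0.05, (10, 8))
        dev[:, 3:6] += 0.05
        times = np.arange(8, dtype=float) * 10
        exact = enumeration_cluster_p(dev)
        cfg = ClusterTestConfig(
            n_permutations=5000, null_value=0.0, analysis_window=(0, 70), seed=1
        )
        res = sign_permutation_cluster_test(dev, times, cfg)
        approx = res.min_corrected_p
        mc_se = np.sqrt(exact * (1 - exact) / 5000)
        assert abs(approx - exact) < 3 * mc_se + 1e-3

    def test_all_zero_series_has_no_clusters(self):
        times = np.arange(20, dtype=float)
        res = sign_permutation_cluster_test(
            np.zeros((6, 20)), times,
            ClusterTestConfig(n_permutations=200, null_value=0.0, analysis_window=(0, 19), seed=0),
        )
        assert res.clusters == []
        assert not res.significant_mask.any()

    def test_unbeatable_mass_hits_permutation_floor(self):
        times = np.arange(30, dtype=float) * 10
        series = np.full((20, 30), 0.75)
        cfg = ClusterTestConfig(n_permutations=1000, analysis_window=(0, 290), seed=3)
        res = sign_permutation_cluster_test(series, times, cfg)
        assert len(res.clusters) == 1
        assert res.clusters[0].corrected_p == pytest.approx(1.0 / 1000)

    def test_type_one_error_rate_controlled(self):
        # null accuracy series (mean 0.5): familywise rejection rate <= 7%
        rng = np.random.default_rng(7)
        times = np.arange(20, dtype=float) * 25
        cfg = ClusterTestConfig(n_permutations=300, analysis_window=(0, 500))
        hits = 0
        n_sim = 200
        for sim in range(n_sim):
            series = rng.normal(0.5, 0.05, (12, 20))
            res = sign_permutation_cluster_test(series, times, cfg.__class__(
                n_permutations=300, analysis_window=(0, 500), seed=sim))
            hits += bool(res.significant_mask.any())
        assert hits / n_sim <= 0.07

    def test_constant_shift_moves_statistic_map(self):
        rng = np.random.default_rng(5)
        series = rng.normal(0.5, 0.02, (8, 10))
        times = np.arange(10, dtype=float)
        cfg = ClusterTestConfig(n_permutations=200, analysis_window=(0, 9), seed=2)
        r1 = sign_permutation_cluster_test(series, times, cfg)
        r2 = sign_permutation_cluster_test(series + 0.1, times, cfg)
        assert np.allclose(r2.statistic_map - r1.statistic_map, 0.1)

    def test_needs_at_least_two_subjects(self):
        with pytest.raises(ValueError):
            sign_permutation_cluster_test(np.zeros((1, 5)), np.arange(5.0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sign_permutation_cluster_test(
                np.zeros((3, 5)), np.arange(5.0),
                ClusterTestConfig(analysis_window=(100.0, 200.0)),
            )


class TestTwoSampleClusterTest:
    def test_identical_groups_give_zero_map(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0.5, 0.05, (6, 12))
        times = np.arange(12, dtype=float) * 50
        res = two_sample_cluster_test(
            g, g.copy(), times,
            ClusterTestConfig(n_permutations=200, null_value=0.0, analysis_window=(0, 550), seed=0),
        )
        assert np.allclose(res.statistic_map, 0.0)
        assert not res.significant_mask.any()

    def test_detects_injected_group_difference(self):
        # 5-point difference over a 100 ms window, n = 24/24, subject SD 5 pts
        rng = np.random.default_rng(2)
        times = np.arange(0, 550, 10, dtype=float)
        hits = 0
        for sim in range(25):
            a = rng.normal(0.5, 0.05, (24, times.size))
            b = rng.normal(0.5, 0.05, (24, times.size))
            window = (times >= 200) & (times < 300)
            a[:, window] += 0.05
            res = two_sample_cluster_test(
                a, b, times,
                ClusterTestConfig(n_permutations=300, null_value=0.0, seed=sim,
                                  alternative="two-sided"),
            )
            detected = any(
                c.corrected_p <= 0.05 and c.start_ms <= 290 and c.end_ms >= 200
                for c in res.clusters
            )
            hits += detected
        assert hits / 25 >= 0.9

    def test_group_shift_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 0.04, (8, 10))
        b = rng.normal(0.5, 0.04, (8, 10))
        times = np.arange(10, dtype=float)
        cfg = ClusterTestConfig(n_permutations=300, null_value=0.0, analysis_window=(0, 9), seed=1)
        r1 = two_sample_cluster_test(a, b, times, cfg)
        r2 = two_sample_cluster_test(a + 0.2, b + 0.2, times, cfg)
        assert np.allclose(r1.statistic_map, r2.statistic_map)
        assert [c.corrected_p for c in r1.clusters] == [c.corrected_p for c in r2.clusters]


class TestPairedDifference:
    def test_identical_series_no_clusters(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.6, 0.05, (6, 15))
        times = np.arange(15, dtype=float) * 10
        res = paired_difference_cluster_test(
            a, a.copy(), times,
            ClusterTestConfig(n_permutations=200, analysis_window=(0, 140), seed=0),
        )
        assert not res.clusters


class TestLatency:
    @staticmethod
    def _accuracy_series(rng, n_sub, times, onset, plateau=0.12, noise=0.01):
        rise = plateau / (1 + np.exp(-(times - onset - 15) / 6.0))
        rise[times < onset] = 0.0
        return 0.5 + rise[None, :] + rng.normal(0, noise, (n_sub, times.size))

    def test_onset_and_peak_by_construction(self):
        times = np.arange(0, 551, 1, dtype=float)
        rng = np.random.default_rng(0)
        series = self._accuracy_series(rng, 12, times, onset=120)
        series += 0.05 * np.exp(-((times - 280) / 40.0) ** 2)[None, :]  # peak at 280
        cfg = ClusterTestConfig(n_permutations=300, seed=1)
        res = sign_permutation_cluster_test(series, times, cfg)
        est = onset_and_peak_latency(series, res)
        assert est.onset_defined
        assert 100 <= est.onset_ms <= 140
        assert est.peak_ms == pytest.approx(280, abs=10)

    def test_no_significant_cluster_flags_onset(self):
        rng = np.random.default_rng(1)
        times = np.arange(0, 551, 10, dtype=float)
        series = rng.normal(0.5, 0.05, (6, times.size))
        res = sign_permutation_cluster_test(
            series, times, ClusterTestConfig(n_permutations=300, seed=0)
        )
        if not res.significant_mask.any():  # overwhelmingly the case under null
            est = onset_and_peak_latency(series, res)
            assert not est.onset_defined
            assert np.isnan(est.onset_ms)
            assert not np.isnan(est.peak_ms)

    def test_identical_sets_give_p_one(self):
        rng = np.random.default_rng(2)
        times = np.arange(0, 551, 5, dtype=float)
        series = self._accuracy_series(rng, 10, times, onset=150)
        res = bootstrap_latency_test(
            series, series.copy(), times, latency_kind="peak", n_boot=100, paired=True, seed=0
        )
        assert res.p_two_sided == pytest.approx(1.0)
        assert np.all(res.bootstrap_differences == 0)

    def test_null_peak_latency_rejection_rate(self):
        # two independent cohorts from the same distribution: false-positive
        # rate of the peak-latency bootstrap stays near alpha
        rng = np.random.default_rng(3)
        times = np.arange(0, 551, 5, dtype=float)
        bump = np.exp(-((times - 280) / 60.0) ** 2)
        hits = 0
        n_sim = 100
        for sim in range(n_sim):
            a = 0.5 + 0.1 * bump[None, :] + rng.normal(0, 0.02, (12, times.size))
            b = 0.5 + 0.1 * bump[None, :] + rng.normal(0, 0.02, (12, times.size))
            res = bootstrap_latency_test(a, b, times, latency_kind="peak", n_boot=100, seed=sim)
            hits += res.p_two_sided < 0.05
        assert hits / n_sim <= 0.07


class TestPooledTAndD:
    def test_printed_worked_examples(self):
        t, p, d = pooled_t_and_d(110.17, 7.87, 24, 90.63, 9.39, 24)
        assert d == pytest.approx(2.26, abs=0.005)
        t2, _, _ = pooled_t_and_d(101.50, 8.29, 24, 78.83, 9.95, 24)
        assert t2 == pytest.approx(8.58, abs=0.01)

    def test_equal_means_give_zero(self):
        t, p, d = pooled_t_and_d(10.0, 2.0, 24, 10.0, 3.0, 24)
        assert t == 0.0 and d == 0.0
        assert p == pytest.approx(1.0)

    def test_full_table_regression(self):
        table = behavioral_group_stats()
        for _, row in table.iterrows():
            t, _, d = pooled_t_and_d(
                row.control_mean, row.control_sd, int(row.n_control),
                row.dyslexia_mean, row.dyslexia_sd, int(row.n_dyslexia),
            )
            assert t == pytest.approx(row.printed_t, abs=0.015), row.subtest
            assert d == pytest.approx(row.printed_d, abs=0.006), row.subtest

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pooled_t_and_d(1, 1, 1, 2, 1, 24)
        with pytest.raises(ValueError):
            pooled_t_and_d(1, 0, 24, 2, 1, 24)
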