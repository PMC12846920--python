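"""Inference-machinery tests: Fisher z, Wilcoxon, cluster permutation, RM-ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fearext.stats import (
    bonferroni,
    cluster_permutation,
    fisher_z,
    learning_curve_test,
    posthoc_paired_t,
    rm_anova_2way,
    signed_rank_test,
)


class TestFisherBonferroni:
    def test_fisher_z_reference_values(self):
        assert fisher_z(0.0) == pytest.approx(0.0)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert np.isfinite(fisher_z(1.0))

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(deadline=None, max_examples=50)
    def test_fisher_z_monotone(self, a, b):
        if a < b:
            assert fisher_z(a) < fisher_z(b)

    def test_bonferroni_five_rois(self):
        assert bonferroni(0.05, 5) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestSignedRank:
    def test_matches_exact_enumeration_oracle(self, rng):
        """Exact p agrees with brute-force enumeration of all sign patterns."""
        for n in (4, 6, 8, 10):
            for _ in range(5):
                d = rng.standard_normal(n).round(1)
                d = d[d != 0]
                if d.size == 0:
                    continue
                s, z, p = signed_rank_test(d)
                ranks = sps.rankdata(np.abs(d))
                stats = [
                    np.sum(np.array(signs) * ranks)
                    for signs in itertools.product([-1, 1], repeat=d.size)
                ]
                p_exact = np.mean(np.abs(stats) >= abs(s) - 1e-9)
                assert p == pytest.approx(p_exact, abs=1e-12)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(10):
            x = rng.standard_normal(9)
            y = rng.standard_normal(9)
            _, _, p = signed_rank_test(x, y)
            p_scipy = sps.wilcoxon(x, y, mode="exact").pvalue
            assert p == pytest.approx(p_scipy, abs=1e-9)

    def test_all_zero_differences(self):
        s, z, p = signed_rank_test(np.zeros(5))
        assert (s, z, p) == (0.0, 0.0, 1.0)


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self, rng):
        data = [rng.standard_normal((20, 4, 5)) for _ in range(6)]
        labels = []
        for i, d in enumerate(data):
            half = d[:10]
            data[i] = np.concatenate([half, half])
            labels.append(np.r_[np.ones(10, bool), np.zeros(10, bool)])
        res = cluster_permutation(data, labels, n_perm=100, seed=0)
        assert np.allclose(res.t_map, 0.0)
        assert res.clusters == []

    def test_large_effect_block_detected(self, rng):
        """A contiguous 10-bin block with d = 3 across 12 participants."""
        n_detect = 0
        for run in range(10):
            rng_r = np.random.default_rng(run)
            data, labels = [], []
            for _ in range(12):
                x = rng_r.standard_normal((30, 40))
                lab = np.zeros(30, bool)
                lab[:15] = True
                x[lab, 10:20] += 3.0
                data.append(x)
                labels.append(lab)
            res = cluster_permutation(data, labels, n_perm=200, seed=run)
            if res.significant(0.05):
                n_detect += 1
        assert n_detect >= 9

    def test_p_values_respect_permutation_convention(self, rng):
        data = [rng.standard_normal((10, 6)) for _ in range(5)]
        labels = [np.r_[np.ones(5, bool), np.zeros(5, bool)] for _ in range(5)]
        res = cluster_permutation(data, labels, n_perm=200, seed=1)
        for c in res.clusters:
            assert 1 / 201 <= c.p <= 1.0

    def test_cluster_mass_monotone_in_extension(self):
        """Adding an adjacent suprathreshold bin never shrinks cluster mass."""
        from fearext.stats import _observed_clusters

        t = np.zeros(10)
        t[3:6] = 4.0
        base = max(abs(c[1]) for c in _observed_clusters(t, 2.0))
        t[6] = 3.0
        grown = max(abs(c[1]) for c in _observed_clusters(t, 2.0))
        assert grown > base

    def test_sign_homogeneous_clusters(self):
        from fearext.stats import _observed_clusters

        t = np.array([4.0, 4.0, -4.0, -4.0, 4.0])
        clusters = _observed_clusters(t, 2.0)
        assert len(clusters) == 3
        for mask, mass, sign in clusters:
            assert np.sign(mass) == sign

    def test_low_permutation_count_warns(self, rng):
        data = [rng.standard_normal((8, 3)) for _ in range(4)]
        labels = [np.r_[np.ones(4, bool), np.zeros(4, bool)] for _ in range(4)]
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_permutation(data, labels, n_perm=50, seed=0)

    def test_fwer_calibrated_under_gaussian_null(self):
        """Family-wise error close to the nominal 5% (reduced-scale check;
        the full calibration runs in the acceptance suite)."""
        false_pos = 0
        n_datasets = 150
        for ds in range(n_datasets):
            rng_d = np.random.default_rng(1000 + ds)
            data = [rng_d.standard_normal((16, 4, 6)) for _ in range(8)]
            labels = [np.r_[np.ones(8, bool), np.zeros(8, bool)] for _ in range(8)]
            res = cluster_permutation(data, labels, n_perm=200, seed=ds)
            false_pos += bool(res.significant(0.05))
        assert false_pos / n_datasets <= 0.09


class TestLearningCurve:
    def test_identical_streams_no_clusters(self, rng):
        a = rng.integers(1, 5, size=(10, 12)).astype(float)
        res = learning_curve_test(a, a.copy(), n_perm=200, seed=0)
        assert res.clusters == []
        assert np.allclose(res.t_map, 0.0)

    def test_divergence_onset_recovered(self):
        rng = np.random.default_rng(4)
        n_part, n_pos, onset = 14, 12, 6
        a = np.full((n_part, n_pos), 2.5)
        b = np.full((n_part, n_pos), 2.5)
        a[:, onset - 1:] = 1.0
        b[:, onset - 1:] = 4.0
        a += 0.3 * rng.standard_normal(a.shape)
        b += 0.3 * rng.standard_normal(b.shape)
        res = learning_curve_test(a, b, n_perm=300, seed=1)
        sig = res.significant(0.05)
        assert sig
        first = int(np.argwhere(sig[0].bins).min()) + 1
        assert abs(first - onset) <= 1

    def test_positions_with_few_pairs_skipped(self, rng):
        a = rng.standard_normal((6, 5))
        b = rng.standard_normal((6, 5))
        a[:4, 2] = np.nan  # only 2 valid pairs at position 2
        res = learning_curve_test(a, b, n_perm=100, seed=0, min_pairs=5)
        assert res.t_map[2] == 0.0


class TestRmAnova:
    @staticmethod
    def make_table(values):
        rows = []
        for p, part in enumerate(values):
            for c, cue in zip(part, ("CS++", "CS+-", "CS--")):
                for v, ph in zip(c, ("acquisition", "extinction", "test")):
                    rows.append({"participant": p, "cue": cue, "phase": ph, "rating": v})
        return pd.DataFrame(rows)

    def test_all_equal_cells_give_zero_f(self):
        table = self.make_table(np.full((4, 3, 3), 2.0))
        res = rm_anova_2way(table)
        assert (res["F"] == 0.0).all()

    def test_matches_textbook_sum_of_squares(self):
        """Hand-computed two-way RM decomposition on a 3-participant table."""
        vals = np.array(
            [[[1, 2, 3], [2, 3, 4], [3, 4, 5]],
             [[2, 2, 2], [3, 4, 3], [2, 4, 4]],
             [[1, 3, 2], [2, 2, 5], [4, 3, 3]]], dtype=float)
        table = self.make_table(vals)
        res = rm_anova_2way(table)

        # oracle: classical sums of squares
        gm = vals.mean()
        ss_a = 3 * 3 * ((vals.mean(axis=(0, 2)) - gm) ** 2).sum()      # cue
        ss_b = 3 * 3 * ((vals.mean(axis=(0, 1)) - gm) ** 2).sum()      # phase
        subj = vals.mean(axis=(1, 2))
        cell_ab = vals.mean(axis=0)
        ss_ab = 3 * ((cell_ab - vals.mean(axis=(0, 2))[:, None]
                      - vals.mean(axis=(0, 1))[None, :] + gm) ** 2).sum()
        pa = vals.mean(axis=2)
        ss_err_a = 3 * ((pa - vals.mean(axis=(0, 2))[None, :]
                         - subj[:, None] + gm) ** 2).sum()
        pb = vals.mean(axis=1)
        ss_err_b = 3 * ((pb - vals.mean(axis=(0, 1))[None, :]
                         - subj[:, None] + gm) ** 2).sum()
        ss_tot = ((vals - gm) ** 2).sum()
        ss_subj = 9 * ((subj - gm) ** 2).sum()
        ss_err_ab = ss_tot - ss_subj - ss_a - ss_b - ss_ab - ss_err_a - ss_err_b

        f_a = (ss_a / 2) / (ss_err_a / 4)
        f_b = (ss_b / 2) / (ss_err_b / 4)
        f_ab = (ss_ab / 4) / (ss_err_ab / 8)
        assert res.loc["cue", "F"] == pytest.approx(f_a, rel=1e-6)
        assert res.loc["phase", "F"] == pytest.approx(f_b, rel=1e-6)
        assert res.loc["cue:phase", "F"] == pytest.approx(f_ab, rel=1e-6)
        # partial eta squared from F and dfs
        assert res.loc["cue", "partial_eta_sq"] == pytest.approx(
            f_a * 2 / (f_a * 2 + 4), rel=1e-6)

    def test_additive_effects_keep_interaction_calibrated(self):
        ns = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            cue_eff = np.array([0.5, 0.0, -0.5])
            phase_eff = np.array([-0.3, 0.0, 0.3])
            vals = (2.5 + cue_eff[None, :, None] + phase_eff[None, None, :]
                    + 0.4 * rng.standard_normal((10, 3, 3)))
            res = rm_anova_2way(self.make_table(vals))
            ns += res.loc["cue:phase", "p"] >= 0.05
        assert ns / 60 >= 0.9

    def test_fewer_than_three_participants_refused(self):
        table = self.make_table(np.random.default_rng(0).standard_normal((2, 3, 3)))
        with pytest.raises(ValueError, match="3 participants"):
            rm_anova_2way(table)

    def test_posthoc_bonferroni_alpha(self):
        table = self.make_table(np.random.default_rng(1).standard_normal((6, 3, 3)))
        ph = posthoc_paired_t(table, "rating", "cue", "participant")
        assert np.allclose(ph["alpha_corrected"], 0.05 / 3)
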