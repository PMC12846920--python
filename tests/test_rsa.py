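"""Pattern-similarity metric tests with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fearext.rsa import (
    PatternSeries,
    build_feature_vectors,
    condition_stability,
    context_specificity_series,
    item_stability_series,
    pairwise_spearman,
    single_trial_context_specificity,
    single_trial_item_stability,
)
from fearext.stats import fisher_z


def series_from(vectors):
    v = np.asarray(vectors, float)
    if v.ndim == 2:
        v = v[:, None, :]
    return PatternSeries(vectors=v, centers=np.arange(v.shape[1]) * 0.05 + 0.25,
                         lock="cue_onset")


class TestFeatureVectors:
    def test_single_channel_vector_length_is_44(self, ext_cohort):
        tft = ext_cohort[0].tensors["lPFC"]
        one_ch = tft
        from dataclasses import replace

        one_ch = replace(tft, power=tft.power[:, :1])
        pat = build_feature_vectors(one_ch)
        assert pat.vectors.shape[2] == 44

    def test_window_overlap_is_90_percent(self, ext_cohort):
        pat = build_feature_vectors(ext_cohort[0].tensors["AMY"])
        step = np.diff(pat.centers)
        assert np.allclose(step, 0.05)
        overlap = 1 - 0.05 / 0.5
        assert overlap == pytest.approx(0.90)
        assert pat.centers[0] == pytest.approx(0.25)  # 0-500 ms -> 250 ms

    def test_constant_tensor_gives_identical_vectors(self, ext_cohort):
        from dataclasses import replace

        tft = ext_cohort[0].tensors["AMY"]
        const = replace(tft, power=np.ones_like(tft.power))
        pat = build_feature_vectors(const)
        assert np.allclose(pat.vectors, pat.vectors[:, :1, :])

    def test_window_outside_epoch_rejected(self, ext_cohort):
        with pytest.raises(ValueError, match="epoch"):
            build_feature_vectors(ext_cohort[0].tensors["AMY"], span=(3.5, 5.0))


class TestPairwiseSpearman:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 5], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
        ],
    )
    def test_reference_pairs(self, a, b, expected):
        sim = pairwise_spearman(series_from([a, b]))
        assert sim.rho[0, 1, 0] == pytest.approx(expected)

    def test_agrees_with_scipy(self, rng):
        v = rng.standard_normal((6, 2, 20))
        sim = pairwise_spearman(series_from(v.reshape(6, 2, 20)))
        for i in range(6):
            for j in range(i + 1, 6):
                for w in range(2):
                    expect = sps.spearmanr(v[i, w], v[j, w]).statistic
                    assert sim.rho[i, j, w] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_with_nan_diagonal(self, rng):
        sim = pairwise_spearman(series_from(rng.standard_normal((5, 8))))
        assert np.allclose(sim.rho[:, :, 0], sim.rho[:, :, 0].T, equal_nan=True)
        assert np.isnan(np.diagonal(sim.rho[:, :, 0])).all()

    def test_zero_variance_vector_recorded_missing(self, rng):
        v = rng.standard_normal((3, 5))
        v[1] = 2.0
        sim = pairwise_spearman(series_from(v))
        assert np.isnan(sim.rho[0, 1, 0])
        assert not np.isnan(sim.rho[0, 2, 0])

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=15)
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((4, 6))
        sim1 = pairwise_spearman(series_from(v))
        sim2 = pairwise_spearman(series_from(np.exp(2 * v)))
        assert np.allclose(sim1.rho, sim2.rho, equal_nan=True, atol=1e-12)


class TestItemStability:
    def test_identical_patterns_give_clamped_maximum(self, rng):
        base = rng.standard_normal(10)
        v = np.stack([base, base, rng.standard_normal(10), rng.standard_normal(10)])
        sim = pairwise_spearman(series_from(v))
        st_ = item_stability_series(sim, [1, 1, 2, 2])
        assert st_[1][0] == pytest.approx(float(fisher_z(1.0)))

    def test_two_trial_item_single_trial_value_is_mutual_rho(self, rng):
        v = rng.standard_normal((4, 8))
        sim = pairwise_spearman(series_from(v))
        single = single_trial_item_stability(sim, [1, 1, 2, 2])
        fz01 = fisher_z(sim.rho[0, 1, 0])
        assert single[0, 0] == pytest.approx(fz01)
        assert single[1, 0] == pytest.approx(fz01)

    def test_single_trial_mean_equals_pair_mean(self, rng):
        """Averaging single-trial values reproduces the pairwise within-item
        mean (each pair counted twice, symmetric)."""
        v = rng.standard_normal((6, 10))
        cues = np.array([1, 1, 1, 2, 2, 2])
        sim = pairwise_spearman(series_from(v))
        single = single_trial_item_stability(sim, cues)
        per_item = item_stability_series(sim, cues)
        for cue in (1, 2):
            assert single[cues == cue].mean() == pytest.approx(per_item[cue][0])

    def test_brute_force_four_trial_toy(self, rng):
        v = rng.standard_normal((4, 7))
        cues = np.array([1, 1, 1, 2])
        sim = pairwise_spearman(series_from(v))
        single = single_trial_item_stability(sim, cues)
        # trial 0: mean Fz of rho(0,1), rho(0,2)
        expect = np.mean([fisher_z(sps.spearmanr(v[0], v[1]).statistic),
                          fisher_z(sps.spearmanr(v[0], v[2]).statistic)])
        assert single[0, 0] == pytest.approx(expect, abs=1e-12)
        assert np.isnan(single[3, 0])  # no other trial of cue 2

    def test_per_item_then_average_rule(self, rng):
        """The two-cue class averages per-item stabilities, it never pools
        pairs, so an item with more trials does not dominate."""
        va = rng.standard_normal((2, 9))
        vb = rng.standard_normal((6, 9))
        vc = rng.standard_normal((3, 9))
        v = np.concatenate([va, vb, vc])
        cues = np.array([1] * 2 + [2] * 6 + [3] * 3)
        valence = np.array(["CS+"] * 8 + ["CS-"] * 3)
        sim = pairwise_spearman(series_from(v))
        out = condition_stability(sim, cues, valence)
        per_item = item_stability_series(sim, cues)
        assert out["CS+"][0] == pytest.approx(
            (per_item[1][0] + per_item[2][0]) / 2
        )


class TestContextSpecificity:
    def test_identical_patterns_give_zero(self):
        v = np.tile(np.arange(8.0), (6, 1))
        v = v + np.arange(6)[:, None] * 0  # identical
        sim = pairwise_spearman(series_from(v))
        out = context_specificity_series(sim, [1, 1, 2, 2, 3, 3])
        assert out[0] == pytest.approx(0.0)

    def test_brute_force_two_context_toy(self, rng):
        v = rng.standard_normal((4, 6))
        ctx = np.array([1, 1, 2, 2])
        sim = pairwise_spearman(series_from(v))
        fz = fisher_z(sim.rho[:, :, 0])
        same = np.mean([fz[0, 1], fz[2, 3]])
        diff = np.mean([fz[0, 2], fz[0, 3], fz[1, 2], fz[1, 3]])
        out = context_specificity_series(sim, ctx)
        assert out[0] == pytest.approx(same - diff, abs=1e-12)

    def test_permuted_labels_centre_on_zero(self, rng):
        v = rng.standard_normal((24, 12))
        sim = pairwise_spearman(series_from(v))
        vals = [
            context_specificity_series(sim, rng.permutation([1, 2, 3, 4] * 6))[0]
            for _ in range(50)
        ]
        assert abs(np.mean(vals)) < 2 * np.std(vals) / np.sqrt(len(vals)) + 0.02

    def test_single_trial_matches_brute_force(self, rng):
        v = rng.standard_normal((4, 6))
        ctx = np.array([1, 1, 2, 2])
        sim = pairwise_spearman(series_from(v))
        single = single_trial_context_specificity(sim, ctx)
        fz = fisher_z(sim.rho[:, :, 0])
        expect = fz[0, 1] - np.mean([fz[0, 2], fz[0, 3]])
        assert single[0, 0] == pytest.approx(expect, abs=1e-12)

    def test_different_cue_restriction_drops_same_cue_pairs(self, rng):
        v = rng.standard_normal((4, 6))
        ctx = np.array([1, 1, 2, 2])
        cues = np.array([1, 1, 2, 3])
        sim = pairwise_spearman(series_from(v))
        fz = fisher_z(sim.rho[:, :, 0])
        # same-context pairs with different cues: only (2,3); same-cue (0,1) excluded
        expect = fz[2, 3] - np.mean([fz[0, 2], fz[0, 3], fz[1, 2], fz[1, 3]])
        out = context_specificity_series(sim, ctx, cue_ids=cues, different_cue_only=True)
        assert out[0] == pytest.approx(expect, abs=1e-12)


class TestGroupContrasts:
    def test_planted_item_effect_detected(self, ext_cohort, analysis_cfg):
        from fearext.pipeline import cohort_item_stability

        out = cohort_item_stability(ext_cohort, "AMY", cfg=analysis_cfg)
        assert out["test"].significant(0.05)
        assert out["test"].significant(0.05)[0].sign == 1  # CS+ > CS-

    def test_planted_context_effect_detected(self, ext_cohort, analysis_cfg):
        from fearext.pipeline import cohort_context_specificity

        out = cohort_context_specificity(ext_cohort, "lPFC", cfg=analysis_cfg)
        assert out["test"].significant(0.05)
        assert out["test"].significant(0.05)[0].sign == 1

    def test_label_shuffle_destroys_item_effect(self, ext_cohort, analysis_cfg, rng):
        """With cue labels randomly re-assigned, the planted stability
        difference disappears (permutation sensitivity)."""
        from fearext.pipeline import _phase_similarity
        from fearext.rsa import group_item_stability_contrast

        sims, cues, vals = [], [], []
        for data in ext_cohort:
            sim, meta = _phase_similarity(data, "AMY", "extinction", analysis_cfg)
            perm = rng.permutation(len(meta))
            sims.append(sim)
            cues.append(meta["cue_id"].to_numpy()[perm])
            vals.append(meta["valence"].to_numpy()[perm])
        res, obs, _ = group_item_stability_contrast(
            sims, cues, vals, n_perm=200, seed=0
        )
        assert not res.significant(0.05)
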