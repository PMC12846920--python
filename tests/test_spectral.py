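"""Frequency grid, Morlet decomposition and power-normalization tests."""

import numpy as np
import pandas as pd
import pytest

from fearext.preprocess import ChannelInfo, Epochs
from fearext.spectral import (
    build_grid,
    cluster_mean_power,
    morlet_tfr,
    tf_condition_contrast,
    zscore_power,
)

FS = 500.0


def make_epochs(data, fs=FS, tmin=-3.0):
    data = np.asarray(data, float)
    n_tr, n_ch, n_t = data.shape
    times = tmin + np.arange(n_t) / fs
    meta = pd.DataFrame({
        "phase": "extinction", "index": np.arange(1, n_tr + 1),
        "cue_id": 1, "role": "CS++", "valence": "CS+", "context_id": 1, "us": False,
    })
    chans = [ChannelInfo(f"A{i+1}", "A", i + 1, "AMY") for i in range(n_ch)]
    return Epochs(data=data, times=times, sampling_rate=fs, channels=chans,
                  metadata=meta, rejected=meta.iloc[:0])


class TestGrid:
    def test_grid_has_44_frequencies(self):
        g = build_grid()
        assert len(g) == 44

    @pytest.mark.parametrize(
        "freq,cycles",
        [(1, 3.0), (29, 6.0), (30, 6.0), (100, 12.0), (15, 4.5), (65, 9.0)],
    )
    def test_cycle_interpolation(self, freq, cycles):
        g = build_grid()
        idx = np.argmin(np.abs(g.frequencies - freq))
        assert g.frequencies[idx] == freq
        assert g.cycles[idx] == pytest.approx(cycles)

    def test_band_selection(self):
        g = build_grid()
        assert len(g.band(3, 10)) == 8
        assert len(g.band(1, 12)) == 12


class TestMorlet:
    def test_sinusoid_peaks_at_its_frequency(self, rng):
        t = np.arange(int(7 * FS)) / FS - 3.0
        sig = np.sin(2 * np.pi * 6.0 * t) + 0.05 * rng.standard_normal(t.size)
        tft = morlet_tfr(make_epochs(sig[None, None, :]), decim=5)
        tidx = tft.time_indices(-0.5, 0.5)
        prof = tft.power[0, 0][:, tidx].mean(axis=1)
        peak = tft.grid.frequencies[np.argmax(prof)]
        assert abs(peak - 6.0) <= 1.0

    def test_zero_signal_gives_zero_power(self):
        tft = morlet_tfr(make_epochs(np.zeros((1, 1, int(7 * FS)))), decim=5)
        assert np.allclose(tft.power, 0.0)

    def test_power_scales_with_amplitude_squared(self):
        t = np.arange(int(7 * FS)) / FS - 3.0
        powers = []
        for amp in (1.0, 2.0, 4.0):
            sig = amp * np.sin(2 * np.pi * 10.0 * t)
            tft = morlet_tfr(make_epochs(sig[None, None, :]), decim=5)
            tidx = tft.time_indices(-0.5, 0.5)
            fidx = [np.argmin(np.abs(tft.grid.frequencies - 10.0))]
            powers.append(tft.power[0, 0][np.ix_(fidx, tidx)].mean())
        slope = np.polyfit(np.log([1, 2, 4]), np.log(powers), 1)[0]
        assert abs(slope - 2.0) < 0.05

    def test_cue_window_valid_down_to_1hz(self):
        tft = morlet_tfr(make_epochs(np.zeros((1, 1, int(7 * FS)))), decim=5)
        fidx = np.arange(44)
        tidx = tft.time_indices(0.0, 1.75)
        tft.check_valid(fidx, tidx)  # must not raise

    def test_edge_window_rejected(self):
        tft = morlet_tfr(make_epochs(np.zeros((1, 1, int(7 * FS)))), decim=5)
        with pytest.raises(ValueError, match="edge"):
            tft.check_valid(np.arange(44), tft.time_indices(-3.0, -2.5))


class TestZscore:
    def test_hand_sized_tensor_matches_bruteforce(self, rng):
        tft = morlet_tfr(make_epochs(rng.standard_normal((2, 1, int(7 * FS)))), decim=5)
        z = zscore_power(tft, reference_window=(0.0, 1.0))
        tidx = tft.time_indices(0.0, 1.0)
        ref = tft.power[:, 0, 7, tidx]
        expect = (tft.power[0, 0, 7, tidx[0]] - ref.mean()) / ref.std()
        assert z.power[0, 0, 7, tidx[0]] == pytest.approx(expect, rel=1e-5)

    def test_constant_offset_invariance(self, rng):
        tft = morlet_tfr(make_epochs(rng.standard_normal((3, 1, int(7 * FS)))), decim=5)
        z1 = zscore_power(tft)
        from dataclasses import replace

        tft2 = replace(tft, power=tft.power + 5.0)
        z2 = zscore_power(tft2)
        assert np.allclose(z1.power, z2.power, atol=1e-4)

    def test_tensor_equal_to_reference_mean_gives_zeros(self):
        tft = morlet_tfr(make_epochs(np.zeros((2, 1, int(7 * FS)))), decim=5)
        from dataclasses import replace

        tft = replace(tft, power=np.ones_like(tft.power))
        with pytest.raises(ValueError, match="zero reference SD"):
            zscore_power(tft)

    def test_double_zscore_rejected(self, rng):
        tft = morlet_tfr(make_epochs(rng.standard_normal((2, 1, int(7 * FS)))), decim=5)
        z = zscore_power(tft)
        with pytest.raises(ValueError, match="already"):
            zscore_power(z)


class TestContrast:
    def test_identical_conditions_give_no_clusters(self, ext_cohort, analysis_cfg):
        tensors, labels = [], []
        for data in ext_cohort:
            tft = data.tensors["AMY"].select(phase="extinction")
            tensors.append(tft)
            lab = np.zeros(tft.n_trials, bool)
            lab[::2] = True  # arbitrary split unrelated to any planted effect
            # duplicate the same trials into both conditions: identical data
            from dataclasses import replace

            half = tft.power[lab]
            tft2 = replace(tft, power=np.concatenate([half, half]),
                           metadata=pd.concat([tft.metadata[lab]] * 2, ignore_index=True))
            tensors[-1] = tft2
            labels.append(np.r_[np.ones(half.shape[0], bool), np.zeros(half.shape[0], bool)])
        res = tf_condition_contrast(tensors, labels, n_perm=100, seed=0, min_trials=2)
        assert np.allclose(res.t_map, 0.0)
        assert res.test.clusters == []

    def test_participant_missing_a_condition_raises(self, ext_cohort):
        tft = ext_cohort[0].tensors["AMY"]
        with pytest.raises(ValueError, match="lacks"):
            tf_condition_contrast([tft], [np.ones(tft.n_trials, bool)])


class TestClusterMeanPower:
    def test_single_bin_cluster_equals_that_bin(self, rng):
        tft = morlet_tfr(make_epochs(rng.standard_normal((3, 1, int(7 * FS)))), decim=5)
        v = cluster_mean_power(tft, [5], [100])
        assert np.allclose(v, tft.power[:, 0, 5, 100], atol=1e-6)

    def test_block_cluster_matches_hand_mean(self, rng):
        tft = morlet_tfr(make_epochs(rng.standard_normal((2, 1, int(7 * FS)))), decim=5)
        v = cluster_mean_power(tft, [3, 4], [10, 11])
        hand = tft.power[:, :, [3, 4]][:, :, :, [10, 11]].mean(axis=(1, 2, 3))
        assert np.allclose(v, hand, atol=1e-6)

    def test_empty_cluster_rejected(self, rng):
        tft = morlet_tfr(make_epochs(rng.standard_normal((2, 1, int(7 * FS)))), decim=5)
        with pytest.raises(ValueError, match="empty"):
            cluster_mean_power(tft, [], [1])

    def test_within_condition_zscore_centres_each_group(self, rng):
        tft = morlet_tfr(make_epochs(rng.standard_normal((8, 1, int(7 * FS)))), decim=5)
        labels = np.array([True] * 4 + [False] * 4)
        v = cluster_mean_power(tft, [3], [50, 51], labels=labels,
                               zscore_within_condition=True)
        assert v[labels].mean() == pytest.approx(0.0, abs=1e-9)
        assert v[~labels].mean() == pytest.approx(0.0, abs=1e-9)
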