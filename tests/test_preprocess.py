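"""Filtering, referencing, artifact detection and epoching tests."""

import numpy as np
import pandas as pd
import pytest

from fearext.preprocess import (
    ArtifactMask,
    ChannelInfo,
    Recording,
    bipolar_reference,
    detect_artifacts,
    epoch_and_reject,
    filter_recording,
    _pad_runs,
)

FS = 1000.0


def make_recording(data, shafts=None, fs=FS):
    data = np.atleast_2d(np.asarray(data, float))
    chans = []
    for i in range(data.shape[0]):
        shaft = shafts[i] if shafts else "A"
        chans.append(ChannelInfo(name=f"{shaft}{i+1}", shaft=shaft, contact=i + 1, roi="AMY"))
    events = pd.DataFrame(columns=["sample", "marker", "phase", "trial_index"])
    return Recording(data=data, sampling_rate=fs, channels=chans, events=events)


class TestFilter:
    def test_notch_attenuates_50hz(self):
        t = np.arange(0, 20, 1 / FS)
        rec = make_recording(np.sin(2 * np.pi * 50 * t))
        out = filter_recording(rec)
        core = slice(2000, -2000)  # avoid filter edge transients
        assert np.sqrt((out.data[0, core] ** 2).mean()) < 0.1 * np.sqrt(
            (rec.data[0, core] ** 2).mean()
        )

    def test_passband_preserves_10hz(self):
        t = np.arange(0, 20, 1 / FS)
        rec = make_recording(np.sin(2 * np.pi * 10 * t))
        out = filter_recording(rec)
        core = slice(2000, -2000)
        ratio = np.sqrt((out.data[0, core] ** 2).mean()) / np.sqrt(
            (rec.data[0, core] ** 2).mean()
        )
        assert abs(ratio - 1) < 0.1

    def test_dc_offset_removed(self):
        rec = make_recording(np.full(60_000, 5.0) + np.random.default_rng(0).standard_normal(60_000))
        out = filter_recording(rec)
        assert abs(out.data[0, 20_000:-20_000].mean()) < 0.1

    def test_low_sampling_rate_rejected(self):
        rec = make_recording(np.zeros(1000), fs=400.0)
        with pytest.raises(ValueError, match="sampling rate"):
            filter_recording(rec)


class TestBipolar:
    def test_eight_contact_shaft_gives_seven_channels(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((8, 1000)))
        out = bipolar_reference(rec)
        assert out.n_channels == 7

    def test_common_signal_cancels(self):
        sig = np.random.default_rng(1).standard_normal(1000)
        rec = make_recording(np.tile(sig, (4, 1)))
        out = bipolar_reference(rec)
        assert np.allclose(out.data, 0.0)

    def test_two_shafts_referenced_independently(self):
        rng = np.random.default_rng(2)
        rec = make_recording(rng.standard_normal((10, 500)),
                             shafts=["A"] * 4 + ["B"] * 6)
        out = bipolar_reference(rec)
        assert out.n_channels == 3 + 5

    def test_single_contact_shaft_warns(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((3, 500)),
                             shafts=["A", "A", "B"])
        with pytest.warns(UserWarning, match="single contact"):
            out = bipolar_reference(rec)
        assert out.n_channels == 1


class TestDetector:
    def test_background_noise_rarely_flagged(self):
        # null = the pipeline's own 1/f background (smooth signals rarely
        # trip the amplitude+gradient conjunction)
        from fearext.synthgen import _pink_noise

        rng = np.random.default_rng(0)
        rec = make_recording(_pink_noise(rng, 60_000, 1.3, FS))
        mask = detect_artifacts(rec)
        assert mask.flagged_fraction() < 0.02

    def test_planted_spikes_detected_with_high_sensitivity(self):
        from fearext.synthgen import _pink_noise, inject_artifacts

        rng = np.random.default_rng(1)
        rec = make_recording(50.0 * _pink_noise(rng, 120_000, 1.3, FS))
        spiked, ledger = inject_artifacts(rec, amplitude_sd=50.0, n_events=20, seed=2)
        mask = detect_artifacts(spiked)
        hits = sum(mask.mask[r.channel, r.sample] for r in ledger.itertuples())
        assert hits >= 19

    def test_subthreshold_spikes_add_few_flags(self):
        from fearext.synthgen import _pink_noise, inject_artifacts

        rng = np.random.default_rng(3)
        rec = make_recording(50.0 * _pink_noise(rng, 120_000, 1.3, FS))
        base = detect_artifacts(rec).flagged_fraction()
        spiked, _ = inject_artifacts(rec, amplitude_sd=0.5, n_events=20, seed=2)
        frac = detect_artifacts(spiked).flagged_fraction()
        assert frac - base <= 0.05

    def test_single_spike_padded_one_second(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60_000)
        x[30_000] += 50.0
        mask = detect_artifacts(make_recording(x))
        assert mask.mask[0, 29_000:31_001].all()

    def test_zero_variance_channel_raises_with_name(self):
        rec = make_recording(np.zeros(5_000))
        with pytest.raises(ValueError, match="A1"):
            detect_artifacts(rec)

    def test_low_rate_needs_lower_cutoff(self):
        rec = make_recording(np.random.default_rng(0).standard_normal(5_000), fs=500.0)
        with pytest.raises(ValueError, match="cutoff"):
            detect_artifacts(rec)
        detect_artifacts(rec, hf_cutoff=200.0)  # does not raise

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30_000)
        x[10_000] += 40.0
        shift = 500
        m1 = detect_artifacts(make_recording(x))
        m2 = detect_artifacts(make_recording(np.roll(x, shift)))
        core = slice(2_000, 28_000)
        assert np.array_equal(np.roll(m1.mask[0], shift)[core], m2.mask[0][core])

    def test_padding_idempotent(self):
        flagged = np.zeros(10_000, bool)
        flagged[4_000:4_050] = True
        once = _pad_runs(flagged, 1000)
        twice = _pad_runs(once, 0)
        assert np.array_equal(once, twice)


class TestEpoching:
    @pytest.fixture(scope="class")
    def sim(self):
        from fearext.schedule import DesignConfig, generate_experiment
        from fearext.synthgen import GeneratorConfig, simulate_recording

        design = DesignConfig(reps_per_cue_learning=8, reps_per_cue_test=6,
                              contexts_per_phase={"acquisition": 4, "extinction": 4, "test": 6})
        exp = generate_experiment(design, seed=2)
        rec, _ = simulate_recording(
            exp, GeneratorConfig(sampling_rate=500.0, rois={"AMY": 3}, seed=0),
            phases=("extinction",),
        )
        return exp, bipolar_reference(rec)

    def test_no_mask_rejects_nothing(self, sim):
        exp, rec = sim
        out = epoch_and_reject(rec, exp, mask=None)
        ep = out["AMY"]
        assert len(ep.rejected) == 0
        assert ep.n_trials == 24
        assert ep.data.shape[2] == int(7 * 500) + 1

    def test_artifacts_in_epochs_reject_exactly_those(self, sim):
        exp, rec = sim
        cues = rec.events[rec.events["marker"] == "cue"]["sample"].to_numpy()
        mask = np.zeros(rec.data.shape, bool)
        hit = cues[[2, 5, 9]]
        for s in hit:
            mask[0, s + 100 : s + 120] = True
        am = ArtifactMask(mask=mask, thresholds={}, padding_ms=0.0)
        out = epoch_and_reject(rec, exp, mask=am)
        ep = out["AMY"]
        assert len(ep.rejected) == 3
        assert ep.n_trials == 21
        assert set(ep.rejected["reason"]) == {"artifact overlap"}

    def test_min_trials_flags_condition(self, sim):
        exp, rec = sim
        out = epoch_and_reject(rec, exp, mask=None, min_trials=9)
        ep = out["AMY"]
        # extinction: 8 CS+ trials (CS++ only) < 9 -> flagged
        assert any("CS+" in c for c in ep.excluded_conditions)

    def test_rejection_monotone_in_flagged_samples(self, sim):
        exp, rec = sim
        rng = np.random.default_rng(0)
        base = np.zeros(rec.data.shape, bool)
        idx = rng.integers(0, rec.data.shape[1], 20)
        base[0, idx] = True
        more = base.copy()
        more[0, rng.integers(0, rec.data.shape[1], 40)] = True
        n_base = len(epoch_and_reject(rec, exp, ArtifactMask(base, {}, 0.0))["AMY"].rejected)
        n_more = len(epoch_and_reject(rec, exp, ArtifactMask(more, {}, 0.0))["AMY"].rejected)
        assert n_more >= n_base

    def test_event_count_mismatch_raises(self, sim):
        exp, rec = sim
        bad = rec.events.iloc[:-2]
        from dataclasses import replace

        with pytest.raises(ValueError, match="cue events"):
            epoch_and_reject(replace(rec, events=bad), exp)
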