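"""Synthetic multichannel iEEG and behaviour with plantable ground-truth effects.

The generator emulates the statistical structure the downstream analyses
assume: per-contact 1/f background noise plus a per-shaft common component
(removed by bipolar referencing), cue-specific and context-specific
spectral-spatial signatures expressed as band-limited oscillatory components
during cue/video presentation, an optional theta-band (3-10 Hz) power increase
for currently safe cues late in the extinction cue window, epileptiform-like
biphasic transients, and 1-4 expectancy ratings following a learning curve.

Every planted effect is parameterized and recorded in a GroundTruth object so
recovery tests can compare what the pipeline detects against what was planted.
Signature amplitudes are expressed in units of the background SD; a gain of 1
injects oscillations whose amplitude matches the background RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy.signal.windows import tukey

from .preprocess import ChannelInfo, Recording
from .schedule import PHASES, Experiment, generate_experiment

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "simulate_recording",
    "inject_artifacts",
    "simulate_ratings",
    "SimulatedParticipant",
    "simulate_participant",
    "simulate_cohort",
]

_DEFAULT_ROIS = {"TMP": 8, "AMY": 4, "HPC": 4, "OFC": 4, "lPFC": 4}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic recording.

    ROI values are numbers of physical contacts per (single-shaft) ROI; after
    bipolar referencing an N-contact shaft yields N-1 analysis channels, so the
    defaults approximate the reported group means (TMP ~7, others ~3 channels).
    Gains are in units of the per-channel background SD.
    """

    sampling_rate: float = 1000.0
    rois: dict = field(default_factory=lambda: dict(_DEFAULT_ROIS))
    noise_exponent: float = 1.3
    noise_amplitude: float = 50.0          # µV RMS of the 1/f background
    common_signal_gain: float = 0.5        # per-shaft shared component
    theta_safety_effect: float = 0.0       # CS- extinction theta amplitude (SD units)
    theta_band: tuple = (3.0, 10.0)
    theta_window: tuple = (1.18, 1.75)     # s after cue onset
    theta_rois: tuple = ("AMY",)
    theta_base: float = 0.0                # baseline theta on all extinction trials
    theta_trial_sd: float = 0.0            # trial-to-trial theta amplitude SD
    theta_item_coupling: float = 0.0       # couples item expression to theta fluctuation
    item_pattern_gain: float | dict = 0.0
    item_pattern_roles: tuple | None = None  # restrict item signatures to these roles
    shared_pattern_weight: float = 1.0     # phase-invariant share of the item signature
    phase_pattern_weight: float = 0.5      # phase-specific share of the item signature
    context_pattern_gain: float | dict = 0.0
    pattern_jitter: float = 0.2            # trial-to-trial SD of signature expression
    shared_trial_gain_sd: float = 0.0      # common expression fluctuation across ROIs
    test_phase_reinstatement: dict = field(default_factory=dict)
    # role -> (w_acq, w_ext): expression of learning-phase signatures at test
    n_signature_bands: int = 12
    signature_band_range: tuple = (2.0, 90.0)  # Hz span of the signature bands
    artifact_rate: float = 0.0             # events / minute / channel
    artifact_amplitude_sd: float = 8.0
    inter_phase_gap: float = 5.0           # s
    edge_pad: float = 4.0                  # s before first / after last trial
    seed: int = 0

    def __post_init__(self):
        gains = [self.common_signal_gain, self.pattern_jitter]
        for g in (self.item_pattern_gain, self.context_pattern_gain):
            gains.extend(g.values() if isinstance(g, dict) else [g])
        if any(g < 0 for g in gains):
            raise ValueError("gains must be >= 0")
        if self.sampling_rate <= 200.0:
            raise ValueError("sampling rate must exceed twice the highest analysis frequency (100 Hz)")


@dataclass
class GroundTruth:
    bands: np.ndarray                      # (n_bands + 1,) edges in Hz
    item_templates: dict                   # cue_id -> (contacts, bands), unit norm
    phase_templates: dict                  # (cue_id, phase) -> (contacts, bands)
    context_templates: dict                # context_id -> (contacts, bands)
    theta_loading: np.ndarray              # per-contact loading of the theta burst
    theta_window: tuple
    theta_band: tuple
    trial_modifiers: pd.DataFrame          # per trial: expression gain, theta multiplier
    artifact_ledger: pd.DataFrame | None = None
    config: GeneratorConfig | None = None

    def to_json(self, path=None) -> dict:
        """JSON-serializable dump of every planted parameter and template."""
        import dataclasses
        import json

        obj = {
            "band_edges_hz": self.bands.tolist(),
            "item_templates": {str(k): v.tolist() for k, v in self.item_templates.items()},
            "phase_templates": {f"{c}:{p}": v.tolist()
                                for (c, p), v in self.phase_templates.items()},
            "context_templates": {str(k): v.tolist()
                                  for k, v in self.context_templates.items()},
            "theta_loading": self.theta_loading.tolist(),
            "theta_window_s": list(self.theta_window),
            "theta_band_hz": list(self.theta_band),
            "trial_modifiers": self.trial_modifiers.to_dict(orient="records"),
            "artifact_ledger": (
                self.artifact_ledger.to_dict(orient="records")
                if self.artifact_ledger is not None else None
            ),
            "config": dataclasses.asdict(self.config) if self.config else None,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, default=str)
        return obj


def _pink_noise(rng, n, exponent, fs):
    """Gaussian noise with power spectral density ~ f^-exponent, unit RMS."""
    nfft = sfft.next_fast_len(n)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, nfft)[:n]
    return x / x.std()


def _template(rng, n_contacts, n_bands, sparsity=0.75):
    """Nonnegative sparse channel x band signature, unit Frobenius norm.

    Sparse supports make distinct signatures near-orthogonal in the power
    domain (measured band power scales with the squared amplitude pattern, and
    squared nonnegative patterns with little support overlap decorrelate).
    """
    t = np.abs(rng.standard_normal((n_contacts, n_bands)))
    thresh = np.quantile(t, sparsity)
    t = np.where(t >= thresh, t, 0.0)
    return t / np.linalg.norm(t)


def _band_waveforms(rng, edges, n_samples, fs):
    """One sinusoid per band (random frequency and phase), Tukey-windowed."""
    t = np.arange(n_samples) / fs
    win = tukey(n_samples, 0.25)
    waves = np.empty((len(edges) - 1, n_samples))
    for b in range(len(edges) - 1):
        f = rng.uniform(edges[b], edges[b + 1])
        waves[b] = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) * win
    return waves


def _roi_gain(gain, roi):
    if isinstance(gain, dict):
        return float(gain.get(roi, 0.0))
    return float(gain)


def simulate_recording(
    experiment: Experiment, config: GeneratorConfig | None = None,
    phases: tuple | None = None,
) -> tuple[Recording, GroundTruth]:
    """Continuous multichannel recording spanning all three phases.

    Event markers are placed at video onset, cue onset and (for reinforced
    trials) US onset.  Deterministic for a fixed config seed.  ``phases``
    restricts the recording to a subset of phases (e.g. extinction only) for
    cheap single-phase simulations; the schedules stay untouched.
    """
    config = config or GeneratorConfig()
    phases = tuple(phases) if phases is not None else PHASES
    tm = experiment.design.timing
    if tm.iti < 0 or config.inter_phase_gap < 0:
        raise ValueError("trial timings overlap: inter-trial gap must be >= 0")
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)

    channels = []
    for roi, n_contacts in config.rois.items():
        for k in range(1, n_contacts + 1):
            channels.append(ChannelInfo(name=f"{roi}{k}", shaft=roi, contact=k, roi=roi))
    n_ch = len(channels)
    sd = config.noise_amplitude

    # --- timeline ---------------------------------------------------------
    trial_len = tm.trial_length
    starts = []
    t_cursor = config.edge_pad
    for phase in phases:
        sched = experiment.schedule(phase)
        for trial in sched.trials:
            starts.append((phase, trial, t_cursor))
            t_cursor += trial_len
        t_cursor += config.inter_phase_gap
    total_s = t_cursor - config.inter_phase_gap + config.edge_pad
    n_samples = int(round(total_s * fs))

    # --- background -------------------------------------------------------
    data = np.empty((n_ch, n_samples), dtype=np.float32)
    shaft_common = {}
    for roi in config.rois:
        shaft_common[roi] = _pink_noise(rng, n_samples, config.noise_exponent, fs)
    for i, ch in enumerate(channels):
        x = _pink_noise(rng, n_samples, config.noise_exponent, fs)
        data[i] = sd * (x + config.common_signal_gain * shaft_common[ch.roi])

    # --- ground-truth templates ------------------------------------------
    edges = np.geomspace(*config.signature_band_range, config.n_signature_bands + 1)
    cue_ids = sorted({t.cue_id for t in experiment.acquisition.trials})
    context_ids = sorted(
        {t.context_id for ph in PHASES for t in experiment.schedule(ph).trials}
    )
    item_templates = {c: _template(rng, n_ch, config.n_signature_bands) for c in cue_ids}
    phase_templates = {
        (c, p): _template(rng, n_ch, config.n_signature_bands)
        for c in cue_ids
        for p in PHASES
    }
    context_templates = {
        k: _template(rng, n_ch, config.n_signature_bands) for k in context_ids
    }
    theta_loading = np.abs(rng.standard_normal(n_ch))
    theta_loading /= np.linalg.norm(theta_loading) / np.sqrt(n_ch)

    roi_of = np.array([ch.roi for ch in channels])
    item_gain_ch = np.array([_roi_gain(config.item_pattern_gain, r) for r in roi_of])
    ctx_gain_ch = np.array([_roi_gain(config.context_pattern_gain, r) for r in roi_of])
    theta_ch = np.array([r in config.theta_rois for r in roi_of], dtype=float)

    cue_len = int(round(tm.cue * fs))
    ctx_len = int(round((tm.video_alone + tm.cue) * fs))
    th0 = int(round(config.theta_window[0] * fs))
    th1 = int(round(config.theta_window[1] * fs))

    # --- per-trial expression --------------------------------------------
    mod_rows = []
    events = []
    w_phase = config.phase_pattern_weight
    for phase, trial, t0 in starts:
        s0 = int(round(t0 * fs))
        video_s = s0 + int(round(tm.video_onset * fs))
        cue_s = s0 + int(round(tm.cue_onset * fs))
        events.append((video_s, "video", phase, trial.index))
        events.append((cue_s, "cue", phase, trial.index))
        if trial.us:
            events.append((s0 + int(round(tm.us_onset * fs)), "us", phase, trial.index))

        xi = rng.standard_normal()      # theta fluctuation
        eta = rng.standard_normal()     # ROI-local pattern jitter
        gamma = rng.standard_normal()   # shared across-ROI fluctuation
        e_t = max(
            0.0,
            1.0
            + config.pattern_jitter * eta
            + config.shared_trial_gain_sd * gamma
            + config.theta_item_coupling * xi,
        )
        mod_rows.append(
            {"phase": phase, "index": trial.index, "cue_id": trial.cue_id,
             "expression": e_t, "theta_xi": xi, "shared_gamma": gamma}
        )

        # item signature during cue presentation
        express_item = (
            config.item_pattern_roles is None or trial.role in config.item_pattern_roles
        )
        if np.any(item_gain_ch > 0) and express_item:
            tpl = (
                config.shared_pattern_weight * item_templates[trial.cue_id]
                + w_phase * phase_templates[(trial.cue_id, phase)]
            )
            if phase == "test":
                w = config.test_phase_reinstatement.get(trial.role)
                if w is not None:
                    # weights re-express the phase-specific traces only; the
                    # shared cue signature is common to all phases already
                    w_acq, w_ext = w
                    tpl = (
                        tpl
                        + w_acq * phase_templates[(trial.cue_id, "acquisition")]
                        + w_ext * phase_templates[(trial.cue_id, "extinction")]
                    )
            # unit-normalize the mixed template: planted manipulations change the
            # pattern's direction, not the injected energy
            tpl = tpl / np.linalg.norm(tpl)
            amp = (item_gain_ch * e_t)[:, None] * tpl * sd
            waves = _band_waveforms(rng, edges, cue_len, fs)
            data[:, cue_s : cue_s + cue_len] += (amp @ waves).astype(np.float32)

        # context signature during video + cue
        if np.any(ctx_gain_ch > 0):
            amp = (
                (ctx_gain_ch * max(0.0, 1.0 + config.pattern_jitter * rng.standard_normal()))[:, None]
                * context_templates[trial.context_id]
                * sd
            )
            waves = _band_waveforms(rng, edges, ctx_len, fs)
            data[:, video_s : video_s + ctx_len] += (amp @ waves).astype(np.float32)

        # theta-band component in the late cue window during extinction
        if phase == "extinction" and np.any(theta_ch > 0):
            amp = config.theta_base * (1.0 + config.theta_trial_sd * xi)
            if trial.current_valence == "CS-":
                amp += config.theta_safety_effect
            if amp > 0:
                nw = th1 - th0
                t_ax = np.arange(nw) / fs
                win = tukey(nw, 0.4)
                burst = np.zeros(nw)
                for _ in range(3):
                    f = rng.uniform(*config.theta_band)
                    burst += np.sin(2 * np.pi * f * t_ax + rng.uniform(0, 2 * np.pi))
                burst *= win / np.sqrt(3)
                comp = (amp * sd * theta_ch * theta_loading)[:, None] * burst[None, :]
                data[:, cue_s + th0 : cue_s + th1] += comp.astype(np.float32)

    events_df = pd.DataFrame(events, columns=["sample", "marker", "phase", "trial_index"])
    recording = Recording(
        data=data, sampling_rate=fs, channels=channels, events=events_df
    )
    truth = GroundTruth(
        bands=edges,
        item_templates=item_templates,
        phase_templates=phase_templates,
        context_templates=context_templates,
        theta_loading=theta_loading,
        theta_window=config.theta_window,
        theta_band=config.theta_band,
        trial_modifiers=pd.DataFrame(mod_rows),
        config=config,
    )
    return recording, truth


def inject_artifacts(
    recording: Recording,
    rate: float = 2.0,
    amplitude_sd: float = 8.0,
    seed: int = 0,
    n_events: int | None = None,
    duration_ms: tuple = (5.0, 50.0),
) -> tuple[Recording, pd.DataFrame]:
    """Add biphasic spike transients; returns the new recording and a ledger.

    ``rate`` is in events per minute per channel (Poisson); ``n_events``
    overrides it with an exact total count distributed over random channels.
    Amplitudes are in multiples of each channel's SD.
    """
    rng = np.random.default_rng(seed)
    fs = recording.sampling_rate
    n_ch, n_samp = recording.data.shape
    data = recording.data.copy()
    margin = int(fs)  # keep spikes away from record edges

    if n_events is not None:
        chan = rng.integers(0, n_ch, size=n_events)
    else:
        minutes = n_samp / fs / 60.0
        counts = rng.poisson(rate * minutes, size=n_ch)
        chan = np.repeat(np.arange(n_ch), counts)
    ledger = []
    for c in chan:
        dur = rng.uniform(*duration_ms) / 1000.0
        half = max(2, int(round(dur * fs / 2)))
        center = int(rng.integers(margin, n_samp - margin))
        t = np.arange(-half, half + 1) / half
        spike = np.sin(np.pi * t) * np.hanning(len(t))  # one positive, one negative lobe
        peak = np.abs(spike).max()
        amp = amplitude_sd * data[c].std() / peak
        data[c, center - half : center + half + 1] += (amp * spike).astype(data.dtype)
        ledger.append({"channel": int(c), "sample": center, "duration_ms": dur * 1000.0,
                       "amplitude_sd": amplitude_sd})
    out = replace(recording, data=data)
    return out, pd.DataFrame(ledger, columns=["channel", "sample", "duration_ms", "amplitude_sd"])


def simulate_ratings(
    experiment: Experiment,
    learning_onset: int = 10,
    asymptote_gap: float = 3.0,
    noise_sd: float = 0.5,
    miss_rate: float = 0.08,
    transition_width: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial 1-4 expectancy ratings (4 = safe) with a learning curve.

    Within each learning phase, ratings move from a neutral baseline to a
    role-specific asymptote at ordinal position ``learning_onset`` (within the
    cue's own trial sequence); ``transition_width`` > 0 smooths the changepoint
    with an exponential approach.  During acquisition CS++/CS+- converge to
    threatening and CS-- to safe; during extinction the CS+- cue relearns
    safety from a threatening start.  Test-phase targets encode partial
    renewal (CS++ rated most threatening).  Ratings are rounded and clipped to
    1..4; a ``miss_rate`` fraction of responses is missing (NaN).
    """
    rng = np.random.default_rng(seed)
    base = 2.5
    lo = base - asymptote_gap / 2.0
    hi = base + asymptote_gap / 2.0

    # per (phase, role): (pre-onset target, post-onset target)
    targets = {
        ("acquisition", "CS++"): (base, lo),
        ("acquisition", "CS+-"): (base, lo),
        ("acquisition", "CS--"): (base, hi),
        ("extinction", "CS++"): (lo, lo),
        ("extinction", "CS+-"): (lo, hi),
        ("extinction", "CS--"): (hi, hi),
        ("test", "CS++"): (base - asymptote_gap / 6.0, base - asymptote_gap / 6.0),
        ("test", "CS+-"): (base + asymptote_gap / 6.0, base + asymptote_gap / 6.0),
        ("test", "CS--"): (base + asymptote_gap / 3.0, base + asymptote_gap / 3.0),
    }

    rows = []
    for phase in PHASES:
        sched = experiment.schedule(phase)
        ordinal = {}
        for t in sched.trials:
            k = ordinal.get(t.cue_id, 0) + 1
            ordinal[t.cue_id] = k
            pre, post = targets[(phase, t.role)]
            if k < learning_onset:
                target = pre
            elif transition_width > 0:
                frac = 1.0 - np.exp(-(k - learning_onset + 1) / transition_width)
                target = pre + (post - pre) * frac
            else:
                target = post
            rating = float(np.clip(np.round(target + noise_sd * rng.standard_normal()), 1, 4))
            if rng.random() < miss_rate:
                rating = np.nan
            rows.append(
                {"phase": phase, "index": t.index, "cue_id": t.cue_id, "role": t.role,
                 "valence": t.current_valence, "ordinal": k, "us": t.us, "rating": rating}
            )
    return pd.DataFrame(rows)


@dataclass
class SimulatedParticipant:
    experiment: Experiment
    recording: Recording
    ground_truth: GroundTruth
    ratings: pd.DataFrame
    seed: int


def simulate_participant(
    seed: int = 0,
    design=None,
    config: GeneratorConfig | None = None,
    ratings_kwargs: dict | None = None,
    phases: tuple | None = None,
) -> SimulatedParticipant:
    """Schedules + recording + ratings for one synthetic participant."""
    rng = np.random.default_rng(seed)
    exp_seed, rec_seed, rat_seed, art_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 4))
    experiment = generate_experiment(design, seed=exp_seed)
    config = replace(config or GeneratorConfig(), seed=rec_seed)
    recording, truth = simulate_recording(experiment, config, phases=phases)
    if config.artifact_rate > 0:
        recording, ledger = inject_artifacts(
            recording, rate=config.artifact_rate,
            amplitude_sd=config.artifact_amplitude_sd, seed=art_seed,
        )
        truth.artifact_ledger = ledger
    ratings = simulate_ratings(experiment, seed=rat_seed, **(ratings_kwargs or {}))
    return SimulatedParticipant(experiment, recording, truth, ratings, seed)


def simulate_cohort(
    n_subjects: int,
    seed: int = 0,
    design=None,
    config: GeneratorConfig | None = None,
    ratings_kwargs: dict | None = None,
    per_participant=None,
    phases: tuple | None = None,
) -> list:
    """A cohort of independent synthetic participants.

    ``per_participant(i, rng)`` may return a GeneratorConfig overriding the
    base config for participant ``i`` (used to plant across-participant
    couplings, e.g. between context specificity and reinstatement balance).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        cfg = per_participant(i, rng) if per_participant is not None else config
        out.append(
            simulate_participant(
                seed=int(rng.integers(0, 2**31 - 1)),
                design=design,
                config=cfg,
                ratings_kwargs=ratings_kwargs,
                phases=phases,
            )
        )
    return out
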