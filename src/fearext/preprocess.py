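"""Filtering, bipolar referencing, artifact detection and epoching.

Continuous recordings are band-passed (0.1-200 Hz) with power-line notches,
re-referenced to adjacent-contact bipolar derivations per electrode shaft, and
screened for epileptiform transients with a three-criterion z-score detector
(amplitude, gradient, high-pass-filtered amplitude).  Flagged samples are
padded by +-1 s; 7-s epochs (-3 to 4 s around cue onset) that overlap a
flagged sample on any channel of the analyzed ROI are rejected entirely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelInfo",
    "Recording",
    "ArtifactMask",
    "Epochs",
    "filter_recording",
    "bipolar_reference",
    "detect_artifacts",
    "epoch_and_reject",
    "read_edf",
]


@dataclass(frozen=True)
class ChannelInfo:
    name: str
    shaft: str
    contact: int  # within-shaft order, 1 = deepest
    roi: str


@dataclass
class Recording:
    """channels x samples voltage (µV) with event markers."""

    data: np.ndarray
    sampling_rate: float
    channels: list
    events: pd.DataFrame  # columns: sample, marker, phase, trial_index

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.events) and (
            self.events["sample"].min() < 0
            or self.events["sample"].max() >= self.data.shape[1]
        ):
            raise ValueError("events outside data bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_indices(self, roi: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c.roi == roi], int)

    @property
    def rois(self) -> list:
        seen = []
        for c in self.channels:
            if c.roi not in seen:
                seen.append(c.roi)
        return seen


@dataclass
class ArtifactMask:
    mask: np.ndarray  # bool, channels x samples
    thresholds: dict
    padding_ms: float = 1000.0

    def any_channel(self, channel_idx=None) -> np.ndarray:
        m = self.mask if channel_idx is None else self.mask[channel_idx]
        return m.any(axis=0)

    def flagged_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class Epochs:
    """trials x channels x time voltage around cue onset."""

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    channels: list
    metadata: pd.DataFrame           # one row per retained trial
    rejected: pd.DataFrame           # trial metadata of dropped epochs + reason

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def condition_counts(self, by: str = "valence") -> pd.Series:
        return self.metadata.groupby(by).size()


def _butter_sos(kind, freqs, fs, order=4):
    return signal.butter(order, freqs, btype=kind, fs=fs, output="sos")


def filter_recording(
    recording: Recording,
    highpass: float = 0.1,
    lowpass: float = 200.0,
    notch=((49.0, 51.0), (99.0, 101.0), (149.0, 151.0)),
) -> Recording:
    """Zero-phase Butterworth band-pass plus power-line band-stops.

    Forward-backward 4th-order sections; the notch bands remove the 50 Hz
    mains fundamental and its harmonics.
    """
    fs = recording.sampling_rate
    if fs <= 400:
        raise ValueError(f"sampling rate {fs} Hz too low (must exceed 400 Hz)")
    if fs <= 2 * lowpass:
        raise ValueError("sampling rate must exceed twice the low-pass frequency")
    data = recording.data.astype(float)
    data = signal.sosfiltfilt(_butter_sos("highpass", highpass, fs, order=2), data, axis=1)
    data = signal.sosfiltfilt(_butter_sos("lowpass", lowpass, fs), data, axis=1)
    for lo, hi in notch or ():
        data = signal.sosfiltfilt(_butter_sos("bandstop", (lo, hi), fs), data, axis=1)
    return replace(recording, data=data)


def bipolar_reference(recording: Recording) -> Recording:
    """Adjacent-contact differences within each electrode shaft.

    A shaft with N contacts yields N-1 virtual channels (contact_i minus
    contact_{i+1}); the virtual channel inherits the ROI of its deeper
    contact.  Single-contact shafts produce no output and a warning.
    """
    by_shaft: dict = {}
    for i, ch in enumerate(recording.channels):
        by_shaft.setdefault(ch.shaft, []).append((ch.contact, i, ch))
    rows, chans = [], []
    for shaft, contacts in by_shaft.items():
        contacts.sort()
        if len(contacts) < 2:
            warnings.warn(f"shaft {shaft!r} has a single contact; no bipolar channel")
            continue
        for (c1, i1, ch1), (c2, i2, ch2) in zip(contacts[:-1], contacts[1:]):
            rows.append(recording.data[i1] - recording.data[i2])
            chans.append(
                ChannelInfo(
                    name=f"{ch1.name}-{ch2.name}",
                    shaft=shaft,
                    contact=c1,
                    roi=ch1.roi,
                )
            )
    if not rows:
        raise ValueError("no shaft with >= 2 contacts; cannot re-reference")
    return Recording(
        data=np.vstack(rows),
        sampling_rate=recording.sampling_rate,
        channels=chans,
        events=recording.events,
    )


def _pad_runs(flagged: np.ndarray, pad: int) -> np.ndarray:
    """Extend every run of True by `pad` samples on each side."""
    if not flagged.any():
        return flagged
    edges = np.diff(flagged.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if flagged[0]:
        starts = np.r_[0, starts]
    if flagged[-1]:
        ends = np.r_[ends, flagged.size]
    out = np.zeros_like(flagged)
    for s, e in zip(np.maximum(starts - pad, 0), np.minimum(ends + pad, flagged.size)):
        out[s:e] = True
    return out


def detect_artifacts(
    recording: Recording,
    z_single: float = 6.0,
    z_amplitude: float = 4.0,
    z_auxiliary: float = 3.0,
    hf_cutoff: float = 250.0,
    padding_ms: float = 1000.0,
) -> ArtifactMask:
    """Three-criterion epileptiform-transient detector.

    Per channel, three whole-recording z-scored measures are computed: the
    raw amplitude, the sample-to-sample gradient, and the amplitude after a
    high-pass at ``hf_cutoff`` (250 Hz at the native 1 kHz rate).  A sample is
    flagged if any |z| >= ``z_single``, or if amplitude |z| >= ``z_amplitude``
    together with gradient or high-frequency |z| >= ``z_auxiliary``.  Flagged
    cores are padded by ``padding_ms`` on each side.
    """
    fs = recording.sampling_rate
    if fs <= 2 * hf_cutoff:
        raise ValueError(
            f"hf_cutoff={hf_cutoff} Hz requires sampling rate > {2 * hf_cutoff} Hz; "
            "pass a lower cutoff for reduced-rate data"
        )
    data = recording.data
    sds = data.std(axis=1)
    for i, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(
                f"channel {recording.channels[i].name!r} has zero variance; "
                "z-scores are undefined"
            )

    def zscore(x):
        return (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)

    z_amp = np.abs(zscore(data))
    grad = np.diff(data, axis=1, prepend=data[:, :1])
    z_grad = np.abs(zscore(grad))
    hf = signal.sosfiltfilt(_butter_sos("highpass", hf_cutoff, fs), data, axis=1)
    z_hf = np.abs(zscore(hf))

    core = (
        (z_amp >= z_single)
        | (z_grad >= z_single)
        | (z_hf >= z_single)
        | ((z_amp >= z_amplitude) & ((z_grad >= z_auxiliary) | (z_hf >= z_auxiliary)))
    )
    pad = int(round(padding_ms / 1000.0 * fs))
    mask = np.stack([_pad_runs(row, pad) for row in core])
    return ArtifactMask(
        mask=mask,
        thresholds={
            "z_single": z_single,
            "z_amplitude": z_amplitude,
            "z_auxiliary": z_auxiliary,
            "hf_cutoff": hf_cutoff,
        },
        padding_ms=padding_ms,
    )


def epoch_and_reject(
    recording: Recording,
    experiment,
    mask: ArtifactMask | None = None,
    window: tuple = (-3.0, 4.0),
    min_trials: int = 8,
    rois=None,
) -> dict:
    """Cue-locked epochs per ROI with artifact-based trial rejection.

    Returns a dict ``roi -> Epochs``.  An epoch is rejected for a given ROI if
    any sample of any channel in that ROI is flagged inside the epoch window.
    ``Epochs.metadata['usable']`` reflects the per-valence ``min_trials`` rule:
    ROIs whose retained trial count falls below ``min_trials`` in a valence
    condition are flagged in ``Epochs.excluded_conditions``.
    """
    fs = recording.sampling_rate
    cue_events = recording.events[recording.events["marker"] == "cue"].reset_index(drop=True)
    schedules = experiment.phases if hasattr(experiment, "phases") else experiment
    # phases absent from the events (e.g. single-phase recordings) are skipped;
    # within each present phase the event count must match the schedule
    matched = []
    for phase in cue_events["phase"].unique():
        sched = schedules[phase]
        ev_phase = cue_events[cue_events["phase"] == phase]
        if len(ev_phase) != len(sched.trials):
            raise ValueError(
                f"{len(ev_phase)} cue events in phase {phase!r} but "
                f"{len(sched.trials)} scheduled trials"
            )
        by_index = {t.index: t for t in sched.trials}
        for ev in ev_phase.itertuples():
            matched.append((ev, by_index[ev.trial_index]))

    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    times = np.arange(lo, hi + 1) / fs
    meta_rows = []
    for ev, t in matched:
        meta_rows.append(
            {
                "sample": int(ev.sample),
                "phase": t.phase,
                "index": t.index,
                "cue_id": t.cue_id,
                "role": t.role,
                "valence": t.current_valence,
                "context_id": t.context_id,
                "us": t.us,
            }
        )
    meta = pd.DataFrame(meta_rows)

    rois = rois if rois is not None else recording.rois
    out = {}
    for roi in rois:
        idx = recording.channel_indices(roi)
        if idx.size == 0:
            continue
        roi_flag = mask.any_channel(idx) if mask is not None else None
        keep, dropped = [], []
        for i, row in meta.iterrows():
            s0, s1 = row["sample"] + lo, row["sample"] + hi
            if s0 < 0 or s1 >= recording.n_samples:
                dropped.append((i, "outside recording"))
                continue
            if roi_flag is not None and roi_flag[s0 : s1 + 1].any():
                dropped.append((i, "artifact overlap"))
                continue
            keep.append(i)
        data = np.stack(
            [recording.data[idx, meta.at[i, "sample"] + lo : meta.at[i, "sample"] + hi + 1]
             for i in keep]
        ) if keep else np.zeros((0, idx.size, hi - lo + 1))
        rej = meta.loc[[i for i, _ in dropped]].copy()
        rej["reason"] = [r for _, r in dropped]
        ep = Epochs(
            data=data,
            times=times,
            sampling_rate=fs,
            channels=[recording.channels[i] for i in idx],
            metadata=meta.loc[keep].reset_index(drop=True),
            rejected=rej.reset_index(drop=True),
        )
        counts = ep.metadata.groupby(["phase", "valence"]).size()
        ep.excluded_conditions = sorted(
            str(k) for k, n in counts.items() if n < min_trials
        )
        out[roi] = ep
    return out


def read_edf(path, roi_map=None) -> Recording:
    """Generic EDF reader (thin wrapper over MNE) producing a Recording.

    ``roi_map`` optionally maps channel-name prefixes (shaft labels) to ROI
    names; unmatched channels get roi='unknown'.  Events are left empty; real
    marker extraction is recording-system specific.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose=False)
    chans = []
    for name in raw.ch_names:
        shaft = name.rstrip("0123456789")
        digits = name[len(shaft):]
        contact = int(digits) if digits else 1
        roi = "unknown"
        if roi_map:
            for prefix, r in roi_map.items():
                if name.startswith(prefix):
                    roi = r
                    break
        chans.append(ChannelInfo(name=name, shaft=shaft or name, contact=contact, roi=roi))
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> µV
        sampling_rate=float(raw.info["sfreq"]),
        channels=chans,
        events=pd.DataFrame(columns=["sample", "marker", "phase", "trial_index"]),
    )
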