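"""Variable-cycle Morlet decomposition and theta power analyses.

The frequency grid follows the two-range layout used throughout the analyses:
1-29 Hz in 29 linear steps with 3→6 cycles, and 30-100 Hz in 15 linear steps
with 6→12 cycles (44 frequencies total, which is also the per-channel RSA
feature dimension).  Power is z-scored per channel x frequency against the
mean and SD pooled over all trials of the experiment, removing common signal
unrelated to condition or stimulus identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import stats as fstats

__all__ = [
    "FrequencyGrid",
    "build_grid",
    "TimeFrequencyTensor",
    "morlet_tfr",
    "zscore_power",
    "tf_condition_contrast",
    "cluster_mean_power",
    "TFContrastResult",
]


@dataclass(frozen=True)
class FrequencyGrid:
    frequencies: np.ndarray
    cycles: np.ndarray

    def __len__(self) -> int:
        return len(self.frequencies)

    def band(self, lo: float, hi: float) -> np.ndarray:
        """Indices of grid frequencies within [lo, hi]."""
        f = self.frequencies
        return np.flatnonzero((f >= lo - 1e-9) & (f <= hi + 1e-9))


def build_grid() -> FrequencyGrid:
    freqs = np.concatenate([np.linspace(1, 29, 29), np.linspace(30, 100, 15)])
    cycles = np.concatenate([np.linspace(3, 6, 29), np.linspace(6, 12, 15)])
    return FrequencyGrid(frequencies=freqs, cycles=cycles)


@dataclass
class TimeFrequencyTensor:
    """trials x channels x frequencies x time power with grid metadata."""

    power: np.ndarray
    times: np.ndarray
    grid: FrequencyGrid
    sampling_rate: float            # of the (decimated) time axis
    metadata: pd.DataFrame          # trial metadata aligned with axis 0
    normalization: str = "raw"      # 'raw' | 'zscored'
    reference: str = ""
    valid: np.ndarray | None = None  # (n_freqs, n_times) edge-validity mask

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def time_indices(self, lo: float, hi: float, step: float | None = None) -> np.ndarray:
        idx = np.flatnonzero((self.times >= lo - 1e-9) & (self.times <= hi + 1e-9))
        if step is not None:
            dt = 1.0 / self.sampling_rate
            k = max(1, int(round(step / dt)))
            idx = idx[::k]
        return idx

    def check_valid(self, freq_idx, time_idx) -> None:
        if self.valid is not None and not self.valid[np.ix_(freq_idx, time_idx)].all():
            raise ValueError("requested window intersects wavelet edge-contaminated bins")

    def select(self, phase: str | None = None, trials=None) -> "TimeFrequencyTensor":
        if phase is not None:
            trials = self.metadata.index[self.metadata["phase"] == phase].to_numpy()
        return replace(
            self,
            power=self.power[trials],
            metadata=self.metadata.iloc[trials].reset_index(drop=True),
        )


def morlet_tfr(
    epochs,
    grid: FrequencyGrid | None = None,
    decim: int = 10,
    n_jobs: int = 1,
    edge_sigmas: float = 3.0,
) -> TimeFrequencyTensor:
    """Complex Morlet wavelet power of cue-locked epochs.

    Power is the squared magnitude of the wavelet transform.  Time bins closer
    to an epoch edge than ``edge_sigmas`` wavelet standard deviations
    (sigma_t = cycles / (2 pi f); 3 sigma covers >99% of the wavelet mass)
    are marked invalid in ``valid``; the -3/+4 s epoch leaves the full cue
    window valid down to 1 Hz.
    """
    from mne.time_frequency import tfr_array_morlet

    grid = grid or build_grid()
    fs = epochs.sampling_rate
    power = tfr_array_morlet(
        epochs.data.astype(np.float64),
        sfreq=fs,
        freqs=grid.frequencies,
        n_cycles=grid.cycles,
        output="power",
        decim=decim,
        n_jobs=n_jobs,
        verbose=False,
    ).astype(np.float32)
    times = epochs.times[::decim]
    half_support = edge_sigmas * grid.cycles / (2.0 * np.pi * grid.frequencies)  # s
    valid = (
        (times[None, :] - epochs.times[0] >= half_support[:, None])
        & (epochs.times[-1] - times[None, :] >= half_support[:, None])
    )
    return TimeFrequencyTensor(
        power=power,
        times=times,
        grid=grid,
        sampling_rate=fs / decim,
        metadata=epochs.metadata.reset_index(drop=True),
        normalization="raw",
        valid=valid,
    )


def zscore_power(
    tft: TimeFrequencyTensor,
    reference_window: tuple = (0.0, 1.75),
    reference_trials=None,
    per_timepoint: bool = False,
) -> TimeFrequencyTensor:
    """z-score per channel x frequency against the all-trials reference.

    The reference statistics pool over trials and time points within
    ``reference_window`` (all trials of the experiment by default); with
    ``per_timepoint=True`` the mean and SD are computed per time point instead
    (sensitivity variant).
    """
    if tft.normalization == "zscored":
        raise ValueError("tensor is already z-scored")
    tidx = tft.time_indices(*reference_window)
    ref = tft.power if reference_trials is None else tft.power[reference_trials]
    if ref.shape[0] == 0:
        raise ValueError("reference trial set is empty")
    ref = ref[:, :, :, tidx]
    axes = (0,) if per_timepoint else (0, 3)
    mean = ref.mean(axis=axes, dtype=np.float64)
    sd = ref.std(axis=axes, dtype=np.float64)
    bad = np.argwhere(sd == 0)
    if bad.size:
        ch, fr = bad[0][0], bad[0][1]
        raise ValueError(
            f"zero reference SD at channel index {ch}, frequency index {fr}"
        )
    if per_timepoint:
        full_mean = np.zeros(tft.power.shape[1:], dtype=np.float64)
        full_sd = np.ones(tft.power.shape[1:], dtype=np.float64)
        full_mean[:, :, tidx] = mean
        full_sd[:, :, tidx] = sd
        z = (tft.power - full_mean[None]) / full_sd[None]
    else:
        z = (tft.power - mean[None, :, :, None]) / sd[None, :, :, None]
    return replace(
        tft,
        power=z.astype(np.float32),
        normalization="zscored",
        reference=f"all-trials mean/SD over window {reference_window}"
        + (" per time point" if per_timepoint else ""),
    )


@dataclass
class TFContrastResult:
    t_map: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    test: fstats.ClusterTestResult
    n_participants: int
    excluded: list

    def cluster_bounds(self, cluster) -> dict:
        """Frequency/time extent of a cluster (Hz and s)."""
        fi, ti = np.where(cluster.bins)
        return {
            "fmin": float(self.frequencies[fi.min()]),
            "fmax": float(self.frequencies[fi.max()]),
            "tmin": float(self.times[ti.min()]),
            "tmax": float(self.times[ti.max()]),
        }


def tf_condition_contrast(
    tensors: list,
    labels: list,
    band: tuple = (1.0, 12.0),
    window: tuple = (0.0, 1.75),
    step: float = 0.02,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    min_trials: int = 8,
) -> TFContrastResult:
    """Group CS+ vs CS- time-frequency contrast with cluster correction.

    ``tensors`` holds one z-scored TimeFrequencyTensor per participant and
    ``labels`` a boolean array per participant (True = CS+).  Channels are
    averaged within the ROI; participant condition means are contrasted with a
    paired t-test at each time-frequency bin and corrected with the
    trial-shuffle cluster permutation.  Participants with fewer than
    ``min_trials`` trials in either condition are excluded (and reported).
    """
    data, labs, excluded = [], [], []
    freqs = times = None
    for i, (tft, lab) in enumerate(zip(tensors, labels)):
        lab = np.asarray(lab, bool)
        if lab.all() or (~lab).all():
            raise ValueError(f"participant {i} lacks one of the two conditions")
        if lab.sum() < min_trials or (~lab).sum() < min_trials:
            excluded.append(i)
            continue
        fidx = tft.grid.band(*band)
        tidx = tft.time_indices(*window, step=step)
        tft.check_valid(fidx, tidx)
        maps = tft.power[:, :, fidx][:, :, :, tidx].mean(axis=1)  # avg channels
        data.append(maps.astype(np.float64))
        labs.append(lab)
        if freqs is None:
            freqs, times = tft.grid.frequencies[fidx], tft.times[tidx]
    if len(data) < 2:
        raise ValueError("fewer than 2 participants with enough trials")
    res = fstats.cluster_permutation(
        data, labs, n_perm=n_perm, seed=seed, cluster_alpha=cluster_alpha,
        scheme="trial_shuffle",
    )
    return TFContrastResult(
        t_map=res.t_map, frequencies=freqs, times=times, test=res,
        n_participants=len(data), excluded=excluded,
    )


def cluster_mean_power(
    tft: TimeFrequencyTensor,
    freq_idx,
    time_idx,
    labels=None,
    zscore_within_condition: bool = False,
) -> np.ndarray:
    """Per-trial mean z-scored power within a time-frequency cluster.

    Channels and cluster bins are averaged into one scalar per trial.  With
    ``zscore_within_condition`` the scalars are z-scored separately within the
    two label groups (control against condition-mean-driven correlations).
    """
    freq_idx = np.asarray(freq_idx, int)
    time_idx = np.asarray(time_idx, int)
    if freq_idx.size == 0 or time_idx.size == 0:
        raise ValueError("empty cluster")
    sel = tft.power[:, :, freq_idx][:, :, :, time_idx]
    scal = sel.mean(axis=(1, 2, 3), dtype=np.float64)
    if zscore_within_condition:
        if labels is None:
            raise ValueError("labels required for within-condition z-scoring")
        labels = np.asarray(labels, bool)
        out = np.empty_like(scal)
        for m in (labels, ~labels):
            if m.any():
                sd = scal[m].std()
                out[m] = (scal[m] - scal[m].mean()) / (sd if sd > 0 else 1.0)
        return out
    return scal
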