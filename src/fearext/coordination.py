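"""Cross-ROI coordination of single-trial representational metrics.

Trial-level item-stability or context-specificity series from two regions are
correlated across trials for every pair of time windows (temporal
generalization), giving one rho map per participant.  Group inference tests
Fisher-z rho against zero per bin with 2D cluster correction; the null
re-shuffles the trial order of one region's metric and recomputes the map.
A within-condition z-scoring control removes correlations driven purely by
condition mean differences.  Theta-power-to-metric couplings are assessed the
same way across trials, either within a fixed window or time-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .rsa import rank_normalize
from .stats import ClusterTestResult, cluster_permutation, fisher_z

__all__ = [
    "zscore_within_condition",
    "trial_correlation_map",
    "cross_roi_trial_correlation",
    "theta_metric_correlation",
    "CoordinationResult",
]


def zscore_within_condition(values: np.ndarray, labels) -> np.ndarray:
    """z-score trial values separately within each label group (per column)."""
    labels = np.asarray(labels)
    v = np.asarray(values, float)
    out = np.array(v, copy=True)
    flat = v.ndim == 1
    if flat:
        out = out[:, None]
        v = v[:, None]
    for g in np.unique(labels):
        m = labels == g
        mu = np.nanmean(v[m], axis=0)
        sd = np.nanstd(v[m], axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        out[m] = (v[m] - mu) / sd
    return out[:, 0] if flat else out


def trial_correlation_map(metric_a: np.ndarray, metric_b: np.ndarray) -> np.ndarray:
    """Spearman rho across trials for every (window_a, window_b) pair.

    Trials with a missing value in either metric are dropped.  Shapes:
    (n_trials, n_windows_a) x (n_trials, n_windows_b) -> (n_windows_a, n_windows_b).
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    ok = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
    a, b = a[ok], b[ok]
    if a.shape[0] < 3:
        raise ValueError("need at least 3 complete trials")
    za = rank_normalize(a, axis=0)
    zb = rank_normalize(b, axis=0)
    rho = za.T @ zb
    return np.clip(rho, -1.0, 1.0)


@dataclass
class CoordinationResult:
    mean_map: np.ndarray           # group-mean Fisher-z rho
    test: ClusterTestResult
    centers_a: np.ndarray | None
    centers_b: np.ndarray | None
    n_participants: int
    excluded: list


def cross_roi_trial_correlation(
    metrics_a: list,
    metrics_b: list,
    labels: list | None = None,
    zscore_within: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    min_trials: int = 8,
    centers_a=None,
    centers_b=None,
) -> CoordinationResult:
    """Group-level temporal-generalization coordination between two ROIs.

    ``metrics_a[i]`` and ``metrics_b[i]`` are (n_trials x n_windows) series of
    participant ``i``'s trials common to both ROIs.  Participants with fewer
    than ``min_trials`` complete trials are excluded.
    """
    maps, keep, excluded = [], [], []
    for i, (ma, mb) in enumerate(zip(metrics_a, metrics_b)):
        ma = np.asarray(ma, float)
        mb = np.asarray(mb, float)
        if labels is not None and zscore_within:
            ma = zscore_within_condition(ma, labels[i])
            mb = zscore_within_condition(mb, labels[i])
        ok = ~(np.isnan(ma).any(axis=1) | np.isnan(mb).any(axis=1))
        if ok.sum() < min_trials:
            excluded.append(i)
            continue
        za = rank_normalize(ma[ok], axis=0)
        zb = rank_normalize(mb[ok], axis=0)
        maps.append(fisher_z(np.clip(za.T @ zb, -1, 1)))
        keep.append((za, zb))
    if len(maps) < 2:
        raise ValueError("fewer than 2 participants with enough common trials")
    obs = np.asarray(maps)

    def sampler(rng, k):
        out = np.empty((k,) + obs.shape)
        for p, (za, zb) in enumerate(keep):
            n = za.shape[0]
            for j in range(k):
                perm = rng.permutation(n)
                out[j, p] = fisher_z(np.clip(za.T @ zb[perm], -1, 1))
        return out

    res = cluster_permutation(
        obs, n_perm=n_perm, seed=seed, cluster_alpha=cluster_alpha,
        scheme="sampler", sampler=sampler,
    )
    return CoordinationResult(
        mean_map=obs.mean(axis=0), test=res,
        centers_a=centers_a, centers_b=centers_b,
        n_participants=len(maps), excluded=excluded,
    )


def theta_metric_correlation(
    theta_scalars: list,
    metrics: list,
    mode: str = "window-averaged",
    window_idx=None,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    min_trials: int = 8,
):
    """Across-trial coupling between a theta power scalar and an RSA metric.

    ``theta_scalars[i]`` is (n_trials,), already z-scored within condition by
    the caller where required; ``metrics[i]`` is (n_trials, n_windows).

    mode='window-averaged': the metric is averaged over ``window_idx`` and one
    rho per participant is returned together with the group one-sample t on
    Fisher-z values -> dict with rho array, t, p, df.
    mode='time-resolved': per-window rho, group t vs zero with 1D cluster
    correction (null: theta values shuffled across trials) ->
    CoordinationResult with a (n_windows,) map.
    """
    if mode == "window-averaged":
        rhos = []
        for th, m in zip(theta_scalars, metrics):
            th = np.asarray(th, float)
            vals = np.asarray(m, float)
            if window_idx is not None:
                vals = vals[:, window_idx]
            if vals.ndim > 1:
                vals = vals.mean(axis=1)
            ok = np.isfinite(th) & np.isfinite(vals)
            if ok.sum() < min_trials:
                continue
            rhos.append(sps.spearmanr(th[ok], vals[ok]).statistic)
        rhos = np.asarray(rhos)
        if len(rhos) < 2:
            raise ValueError("fewer than 2 participants with enough trials")
        t, p = sps.ttest_1samp(fisher_z(rhos), 0.0)
        return {"rho": rhos, "t": float(t), "p": float(p), "df": len(rhos) - 1}

    if mode != "time-resolved":
        raise ValueError(f"unknown mode {mode!r}")
    series, keep, excluded = [], [], []
    for i, (th, m) in enumerate(zip(theta_scalars, metrics)):
        th = np.asarray(th, float)
        m = np.asarray(m, float)
        ok = np.isfinite(th) & ~np.isnan(m).any(axis=1)
        if ok.sum() < min_trials:
            excluded.append(i)
            continue
        zt = rank_normalize(th[ok][:, None], axis=0)
        zm = rank_normalize(m[ok], axis=0)
        series.append(fisher_z(np.clip((zt.T @ zm)[0], -1, 1)))
        keep.append((zt, zm))
    if len(series) < 2:
        raise ValueError("fewer than 2 participants with enough trials")
    obs = np.asarray(series)

    def sampler(rng, k):
        out = np.empty((k,) + obs.shape)
        for p, (zt, zm) in enumerate(keep):
            n = zt.shape[0]
            for j in range(k):
                perm = rng.permutation(n)
                out[j, p] = fisher_z(np.clip((zt[perm].T @ zm)[0], -1, 1))
        return out

    res = cluster_permutation(
        obs, n_perm=n_perm, seed=seed, cluster_alpha=cluster_alpha,
        scheme="sampler", sampler=sampler,
    )
    return CoordinationResult(
        mean_map=obs.mean(axis=0), test=res, centers_a=None, centers_b=None,
        n_participants=len(series), excluded=excluded,
    )
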