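"""Spectral-spatial pattern similarity: item stability and context specificity.

Feature vectors concatenate z-scored power over channels x 44 frequencies,
averaged within 500-ms sliding windows stepped every 50 ms (90% overlap).
Trial pairs are compared with Spearman correlations at matching window
centres; rho values are Fisher z-transformed before averaging or group tests.

Item stability is the mean similarity of a cue's pattern across its repeated
presentations; because one contingency class contains two cues, stability is
computed per cue and then averaged across the class's cues before the CS+ vs
CS- contrast (unbalanced-design rule).  Context specificity is the mean
same-context minus different-context pair similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import fisher_z

__all__ = [
    "PatternSeries",
    "SimilaritySeries",
    "build_feature_vectors",
    "rank_normalize",
    "pairwise_spearman",
    "item_stability_series",
    "condition_stability",
    "context_specificity_series",
    "single_trial_item_stability",
    "single_trial_context_specificity",
    "group_item_stability_contrast",
    "group_context_specificity_contrast",
]


@dataclass
class PatternSeries:
    """Per-trial feature vectors per sliding window."""

    vectors: np.ndarray   # (n_trials, n_windows, n_features)
    centers: np.ndarray   # window-centre times (s, relative to lock event)
    lock: str             # 'cue_onset' | 'video_onset'

    @property
    def n_trials(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SimilaritySeries:
    """Pairwise Spearman rho at matching window centres (diagonal = NaN)."""

    rho: np.ndarray       # (n_trials, n_trials, n_windows)
    centers: np.ndarray
    lock: str

    def fisher(self) -> np.ndarray:
        out = fisher_z(self.rho)
        return np.where(np.isnan(self.rho), np.nan, out)


def build_feature_vectors(
    tft,
    window: float = 0.5,
    step: float = 0.05,
    lock: str = "cue_onset",
    span: tuple | None = None,
) -> PatternSeries:
    """Sliding-window channel x frequency power patterns.

    ``span`` is the analysis interval in lock-relative time; defaults to the
    cue presentation (0-1.75 s) for cue lock and the video-alone period
    (0-2 s, i.e. -2..0 s in cue-locked epoch time) for video lock.  Window
    centres are reported at window midpoints (0-500 ms -> 250 ms).
    """
    if lock == "cue_onset":
        offset = 0.0
        span = span or (0.0, 1.75)
    elif lock == "video_onset":
        offset = -2.0
        span = span or (0.0, 2.0)
    else:
        raise ValueError(f"unknown lock {lock!r}")
    n_tr, n_ch, n_f, _ = tft.power.shape
    starts = []
    t0 = span[0]
    while t0 + window <= span[1] + 1e-9:
        starts.append(t0)
        t0 += step
    if not starts:
        raise ValueError("span shorter than one window")
    vecs = np.empty((n_tr, len(starts), n_ch * n_f), dtype=np.float64)
    for w, s in enumerate(starts):
        if s + offset < tft.times[0] - 1e-9 or s + offset + window > tft.times[-1] + 1e-9:
            raise ValueError("window extends beyond the epoch")
        tidx = tft.time_indices(s + offset, s + offset + window)
        vecs[:, w, :] = tft.power[:, :, :, tidx].mean(axis=3).reshape(n_tr, -1)
    centers = np.asarray(starts) + window / 2.0
    return PatternSeries(vectors=vecs, centers=centers, lock=lock)


def rank_normalize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centred, unit-norm ranks along ``axis``; zero-variance rows become NaN."""
    r = sps.rankdata(x, axis=axis).astype(np.float64)
    r -= r.mean(axis=axis, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=axis, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = r / norm
    return np.where(norm == 0, np.nan, out)


def pairwise_spearman(patterns: PatternSeries) -> SimilaritySeries:
    """All-pairs Spearman rho per matching window centre.

    Ties receive average ranks.  Pairs involving a zero-variance vector are
    recorded as NaN (missing), never as zero.  The diagonal (a trial with
    itself) is NaN and excluded from all downstream averages.
    """
    v = patterns.vectors
    n_tr, n_win, n_feat = v.shape
    if n_tr < 2:
        raise ValueError("need at least 2 trials")
    if n_feat < 3:
        raise ValueError("need feature vectors of length >= 3")
    rho = np.empty((n_tr, n_tr, n_win), dtype=np.float64)
    for w in range(n_win):
        z = rank_normalize(v[:, w, :])
        r = z @ z.T
        np.clip(r, -1.0, 1.0, out=r)
        rho[:, :, w] = r
    idx = np.arange(n_tr)
    rho[idx, idx, :] = np.nan
    return SimilaritySeries(rho=rho, centers=patterns.centers, lock=patterns.lock)


def _pair_mean(fz: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean Fisher-z over masked trial pairs per window (NaN pairs dropped)."""
    sel = fz[mask]
    if sel.size == 0:
        return np.full(fz.shape[-1], np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(sel, axis=0)


def item_stability_series(sim: SimilaritySeries, cue_ids) -> dict:
    """Within-item mean Fisher-z similarity per cue, per window centre."""
    cue_ids = np.asarray(cue_ids)
    fz = sim.fisher()
    out = {}
    for cue in np.unique(cue_ids):
        m = cue_ids == cue
        pair_mask = np.triu(np.outer(m, m), k=1)
        out[int(cue)] = _pair_mean(fz, pair_mask)
    return out


def condition_stability(sim: SimilaritySeries, cue_ids, valence) -> dict:
    """Item stability per valence class (CS+ / CS-).

    The class containing two cues is computed per cue and then averaged across
    cues, never by pooling pairs, so each cue contributes equally.
    """
    cue_ids = np.asarray(cue_ids)
    valence = np.asarray(valence)
    per_item = item_stability_series(sim, cue_ids)
    out = {}
    for v in np.unique(valence):
        cues = np.unique(cue_ids[valence == v])
        out[str(v)] = np.mean([per_item[int(c)] for c in cues], axis=0)
    return out


def context_specificity_series(
    sim: SimilaritySeries,
    context_ids,
    cue_ids=None,
    different_cue_only: bool = False,
) -> np.ndarray:
    """Mean Fisher-z(same-context pairs) - mean Fisher-z(different-context pairs).

    By default all trial pairs enter regardless of cue identity; with
    ``different_cue_only`` pairs sharing a cue are excluded from both sets
    (control for the item-identity confound during cue-locked analysis).
    """
    context_ids = np.asarray(context_ids)
    fz = sim.fisher()
    same = np.equal.outer(context_ids, context_ids)
    allowed = np.triu(np.ones_like(same, bool), k=1)
    if different_cue_only:
        if cue_ids is None:
            raise ValueError("cue_ids required when different_cue_only")
        cue_ids = np.asarray(cue_ids)
        allowed &= ~np.equal.outer(cue_ids, cue_ids)
    return _pair_mean(fz, same & allowed) - _pair_mean(fz, ~same & allowed)


def single_trial_item_stability(sim: SimilaritySeries, cue_ids) -> np.ndarray:
    """Mean Fisher-z similarity of each trial to all other same-item trials.

    Returns (n_trials, n_windows); trials whose cue has no other presentation
    are NaN.
    """
    cue_ids = np.asarray(cue_ids)
    fz = sim.fisher()
    same = np.equal.outer(cue_ids, cue_ids)
    np.fill_diagonal(same, False)
    out = np.full((len(cue_ids), fz.shape[-1]), np.nan)
    for t in range(len(cue_ids)):
        if same[t].any():
            with np.errstate(invalid="ignore"):
                out[t] = np.nanmean(fz[t, same[t]], axis=0)
    return out


def single_trial_context_specificity(sim: SimilaritySeries, context_ids) -> np.ndarray:
    """Per-trial same-context minus different-context mean Fisher-z similarity."""
    context_ids = np.asarray(context_ids)
    fz = sim.fisher()
    same = np.equal.outer(context_ids, context_ids)
    np.fill_diagonal(same, False)
    diff = ~np.equal.outer(context_ids, context_ids)
    out = np.full((len(context_ids), fz.shape[-1]), np.nan)
    for t in range(len(context_ids)):
        with np.errstate(invalid="ignore"):
            s = np.nanmean(fz[t, same[t]], axis=0) if same[t].any() else np.nan
            d = np.nanmean(fz[t, diff[t]], axis=0) if diff[t].any() else np.nan
        out[t] = s - d
    return out


# ---------------------------------------------------------------------------
# group-level cluster-corrected contrasts
# ---------------------------------------------------------------------------


def _stability_diff(fz, cue_ids, valence):
    """CS+ minus CS- item stability (per-item-then-average) per window."""
    per_item = {}
    for cue in np.unique(cue_ids):
        m = cue_ids == cue
        per_item[int(cue)] = _pair_mean(fz, np.triu(np.outer(m, m), k=1))
    means = {}
    for v in ("CS+", "CS-"):
        cues = np.unique(cue_ids[valence == v])
        means[v] = np.mean([per_item[int(c)] for c in cues], axis=0)
    return means["CS+"] - means["CS-"]


def group_item_stability_contrast(
    sims: list,
    cue_ids_list: list,
    valence_list: list,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    min_trials: int = 8,
):
    """CS+ vs CS- item-stability contrast, cluster-corrected over window centres.

    The null re-assigns cue labels across trials within each participant
    (keeping the cue->valence mapping) and recomputes the stability
    difference, so under permutation "within-item" pairs are arbitrary pairs.
    Participants with fewer than ``min_trials`` trials in a valence class are
    excluded.  Returns ``(ClusterTestResult, observed participant x window
    diffs, excluded indices)``.
    """
    from .stats import cluster_permutation

    obs, keep, excluded = [], [], []
    for i, (sim, cues, val) in enumerate(zip(sims, cue_ids_list, valence_list)):
        cues = np.asarray(cues)
        val = np.asarray(val)
        counts = [np.sum(val == v) for v in ("CS+", "CS-")]
        if min(counts) < min_trials:
            excluded.append(i)
            continue
        obs.append(_stability_diff(sim.fisher(), cues, val))
        keep.append((sim.fisher(), cues, val))
    if len(obs) < 2:
        raise ValueError("fewer than 2 participants with enough trials")
    obs = np.asarray(obs)

    def sampler(rng, k):
        maps = np.empty((k, len(keep), obs.shape[1]))
        for p, (fz, cues, val) in enumerate(keep):
            n = len(cues)
            for j in range(k):
                perm = rng.permutation(n)
                maps[j, p] = _stability_diff(fz, cues[perm], val[perm])
        return maps

    res = cluster_permutation(
        obs, n_perm=n_perm, seed=seed, cluster_alpha=cluster_alpha,
        scheme="sampler", sampler=sampler,
    )
    return res, obs, excluded


def group_context_specificity_contrast(
    sims: list,
    context_ids_list: list,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    min_trials: int = 8,
    cue_ids_list=None,
    different_cue_only: bool = False,
):
    """Same- vs different-context similarity, cluster-corrected over windows.

    The null permutes context labels across trials within each participant.
    Returns ``(ClusterTestResult, observed participant x window differences,
    excluded indices)``.
    """
    from .stats import cluster_permutation

    obs, keep, excluded = [], [], []
    for i, (sim, ctx) in enumerate(zip(sims, context_ids_list)):
        ctx = np.asarray(ctx)
        if len(ctx) < min_trials:
            excluded.append(i)
            continue
        cues = None if cue_ids_list is None else np.asarray(cue_ids_list[i])
        obs.append(
            context_specificity_series(
                sim, ctx, cue_ids=cues, different_cue_only=different_cue_only
            )
        )
        keep.append((sim, ctx, cues))
    if len(obs) < 2:
        raise ValueError("fewer than 2 participants with enough trials")
    obs = np.asarray(obs)

    def sampler(rng, k):
        maps = np.empty((k, len(keep), obs.shape[1]))
        for p, (sim, ctx, cues) in enumerate(keep):
            n = len(ctx)
            for j in range(k):
                perm = rng.permutation(n)
                maps[j, p] = context_specificity_series(
                    sim, ctx[perm],
                    cue_ids=None if cues is None else cues[perm],
                    different_cue_only=different_cue_only,
                )
        return maps

    res = cluster_permutation(
        obs, n_perm=n_perm, seed=seed, cluster_alpha=cluster_alpha,
        scheme="sampler", sampler=sampler,
    )
    return res, obs, excluded
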