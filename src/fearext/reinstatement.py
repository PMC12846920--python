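"""Cross-phase reinstatement of cue representations and its correlates.

Reinstatement is the pattern similarity between a learning-phase trial and
same-item trials of the test phase.  Differential reinstatement
REINST = REINST_ACQ − REINST_EXT contrasts the reappearance of the fear trace
(acquisition) against the extinction trace; positive values indicate
predominant fear-memory reinstatement.  Trial-level extinction-to-test
reinstatement (same-item minus different-item similarity) is correlated with
test-phase safety ratings within participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .rsa import PatternSeries, rank_normalize
from .stats import ClusterTestResult, fisher_z

__all__ = [
    "cross_phase_similarity",
    "phase_reinstatement",
    "differential_reinstatement",
    "trial_reinstatement",
    "context_vs_reinstatement_correlation",
    "reinstatement_vs_ratings",
]


def cross_phase_similarity(patterns_x: PatternSeries, patterns_test: PatternSeries) -> np.ndarray:
    """Spearman rho between every phase-X trial and every test trial.

    Computed at matching window centres; returns
    (n_trials_x, n_trials_test, n_windows).
    """
    vx, vt = patterns_x.vectors, patterns_test.vectors
    if vx.shape[1:] != vt.shape[1:]:
        raise ValueError("pattern series must share windows and feature length")
    n_win = vx.shape[1]
    out = np.empty((vx.shape[0], vt.shape[0], n_win))
    for w in range(n_win):
        zx = rank_normalize(vx[:, w, :])
        zt = rank_normalize(vt[:, w, :])
        out[:, :, w] = np.clip(zx @ zt.T, -1.0, 1.0)
    return out


def phase_reinstatement(
    sim_xt: np.ndarray,
    cues_x,
    cues_test,
    roles_test,
    window_idx,
) -> dict:
    """Mean Fisher-z same-item similarity per cue role, averaged over trials
    and over the given window indices -> {role: value}."""
    cues_x = np.asarray(cues_x)
    cues_test = np.asarray(cues_test)
    roles_test = np.asarray(roles_test)
    fz = fisher_z(sim_xt)
    out = {}
    for role in np.unique(roles_test):
        cues = np.unique(cues_test[roles_test == role])
        vals = []
        for cue in cues:
            m = np.outer(cues_x == cue, cues_test == cue)
            if m.any():
                vals.append(np.nanmean(fz[m][:, window_idx]))
        out[str(role)] = float(np.mean(vals)) if vals else np.nan
    return out


def differential_reinstatement(reinst_acq: dict, reinst_ext: dict) -> dict:
    """REINST = REINST_ACQ − REINST_EXT per cue role (on the Fisher-z scale)."""
    return {r: reinst_acq[r] - reinst_ext[r] for r in reinst_acq}


def trial_reinstatement(
    sim_et: np.ndarray,
    cues_ext,
    cues_test,
    window_idx,
) -> np.ndarray:
    """Per test trial: same-item minus different-item extinction similarity.

    Similarities are Fisher z-transformed, averaged over extinction trials of
    the same (different) cue and over ``window_idx``.
    """
    cues_ext = np.asarray(cues_ext)
    cues_test = np.asarray(cues_test)
    fz = fisher_z(sim_et)
    out = np.empty(len(cues_test))
    for t, cue in enumerate(cues_test):
        same = cues_ext == cue
        diff = ~same
        s = np.nanmean(fz[same, t][:, window_idx]) if same.any() else np.nan
        d = np.nanmean(fz[diff, t][:, window_idx]) if diff.any() else np.nan
        out[t] = s - d
    return out


def context_vs_reinstatement_correlation(
    context_values: np.ndarray,
    reinst_values: np.ndarray,
    time_resolved: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
):
    """Across-participant Spearman correlation of lPFC context specificity
    with differential reinstatement.

    ``reinst_values`` is (n_participants,) or, time-resolved,
    (n_participants, n_windows); in the latter case the fixed per-participant
    context value is correlated with the REINST time course at every window
    and cluster-corrected (null: participant pairing permuted).
    """
    ctx = np.asarray(context_values, float)
    re = np.asarray(reinst_values, float)
    ok = np.isfinite(ctx) & np.isfinite(re if re.ndim == 1 else re.sum(axis=1))
    ctx, re = ctx[ok], re[ok]
    n = len(ctx)
    if n < 5:
        raise ValueError(f"only {n} participants with both measures; need >= 5")

    if not time_resolved:
        res = sps.spearmanr(ctx, re)
        return {"rho": float(res.statistic), "p": float(res.pvalue), "n": n}

    zc = rank_normalize(ctx[:, None], axis=0)
    zr = rank_normalize(re, axis=0)
    rho = (zc.T @ zr)[0]
    # per-window p from the exact Spearman null, bins p<alpha form clusters
    pvals = np.array([sps.spearmanr(ctx, re[:, w]).pvalue for w in range(re.shape[1])])
    z = fisher_z(np.clip(rho, -1, 1)) * np.sqrt(max(n - 3, 1))

    rng = np.random.default_rng(seed)
    from scipy import ndimage

    def max_mass(zv, pv):
        best = 0.0
        for sgn in (1, -1):
            m = (pv < cluster_alpha) & (sgn * zv > 0)
            lab, nl = ndimage.label(m)
            for i in range(1, nl + 1):
                best = max(best, float(np.abs(zv[lab == i]).sum()))
        return best

    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        r_k = (rank_normalize(ctx[perm][:, None], axis=0).T @ zr)[0]
        z_k = fisher_z(np.clip(r_k, -1, 1)) * np.sqrt(max(n - 3, 1))
        # normal-approximation p for surrogate thresholding
        p_k = 2 * sps.norm.sf(np.abs(z_k))
        null[k] = max_mass(z_k, p_k)

    clusters = []
    sig = pvals < cluster_alpha
    lab, nl = ndimage.label(sig & (z > 0))
    labn, nln = ndimage.label(sig & (z < 0))
    from .stats import Cluster

    for arr, cnt, sgn in ((lab, nl, 1), (labn, nln, -1)):
        for i in range(1, cnt + 1):
            m = arr == i
            mass = float(z[m].sum())
            p = (1.0 + np.sum(null >= abs(mass))) / (1.0 + n_perm)
            clusters.append(Cluster(bins=m, mass=mass, p=float(p), sign=sgn))
    clusters.sort(key=lambda c: -abs(c.mass))
    test = ClusterTestResult(
        clusters=clusters, t_map=z, threshold=cluster_alpha,
        cluster_alpha=cluster_alpha, n_permutations=n_perm,
        scheme="participant_pairing_shuffle", seed=seed, null_max=null,
    )
    return {"rho": rho, "test": test, "n": n}


def reinstatement_vs_ratings(
    trial_values: list,
    ratings: list,
    roles: list,
    outlier_sd: float | None = None,
    min_trials: int = 4,
) -> dict:
    """Within-participant correlation of trial reinstatement with test ratings.

    ``trial_values[i]``, ``ratings[i]`` and ``roles[i]`` are aligned per test
    trial of participant ``i``; trials without a response are dropped, and
    with ``outlier_sd`` trials whose reinstatement deviates more than that
    many SDs from the participant mean are excluded.  Returns per cue role a
    dict with per-participant rho values and the group one-sample t on
    Fisher-z (participants with < ``min_trials`` usable trials, or constant
    ratings, are excluded rather than zero-filled).
    """
    all_roles = sorted({str(r) for rr in roles for r in rr})
    out = {}
    for role in all_roles:
        rhos = []
        for tv, rat, rol in zip(trial_values, ratings, roles):
            tv = np.asarray(tv, float)
            rat = np.asarray(rat, float)
            rol = np.asarray(rol)
            m = (rol == role) & np.isfinite(tv) & np.isfinite(rat)
            if outlier_sd is not None and m.sum() > 1:
                mu, sd = tv[m].mean(), tv[m].std()
                if sd > 0:
                    m &= np.abs(tv - mu) <= outlier_sd * sd
            if m.sum() < min_trials:
                continue
            if np.unique(rat[m]).size < 2 or np.unique(tv[m]).size < 2:
                continue  # correlation undefined
            rhos.append(sps.spearmanr(tv[m], rat[m]).statistic)
        rhos = np.asarray(rhos, float)
        if len(rhos) >= 2:
            t, p = sps.ttest_1samp(fisher_z(rhos), 0.0)
        else:
            t, p = np.nan, np.nan
        out[role] = {"rho": rhos, "t": float(t), "p": float(p), "n": len(rhos)}
    return out
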