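"""Inference machinery: cluster-based permutation tests, signed-rank learning
curves, repeated-measures ANOVA, Fisher z and Bonferroni utilities.

Cluster-based permutation follows the standard max-cluster-mass construction:
bins whose group statistic exceeds a two-tailed cluster-forming threshold are
grouped into sign-homogeneous connected components (adjacency in 1D, 4-neighbourhood
in 2D), the summed statistic of each observed cluster is ranked against the
distribution of the largest surrogate cluster mass obtained by re-shuffling trial
labels within each participant and recomputing the full group map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_z",
    "bonferroni",
    "Cluster",
    "ClusterTestResult",
    "cluster_permutation",
    "signed_rank_test",
    "learning_curve_test",
    "rm_anova_2way",
]

RHO_CLAMP = 1.0 - 1e-12


def fisher_z(rho):
    """Fisher z-transform (atanh) with clamping of |rho| to 1 - 1e-12.

    Clamping keeps perfect correlations finite so they can be averaged and
    t-tested like any other value.
    """
    rho = np.clip(np.asarray(rho, dtype=float), -RHO_CLAMP, RHO_CLAMP)
    return np.arctanh(rho)


def bonferroni(alpha: float, k: int) -> float:
    """Corrected per-comparison alpha for k comparisons."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


# ---------------------------------------------------------------------------
# cluster-based permutation
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    bins: np.ndarray          # boolean mask over the stat map
    mass: float               # summed statistic within the cluster
    p: float                  # permutation-corrected p value
    sign: int                 # +1 / -1

    @property
    def extent(self) -> int:
        return int(self.bins.sum())


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold: float
    cluster_alpha: float
    n_permutations: int
    scheme: str
    seed: int
    null_max: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "scheme": self.scheme,
            "seed": self.seed,
            "cluster_alpha": self.cluster_alpha,
            "threshold": self.threshold,
            "clusters": [
                {
                    "mass": c.mass,
                    "p": c.p,
                    "sign": c.sign,
                    "extent": c.extent,
                    "bins": [list(map(int, idx)) for idx in np.argwhere(c.bins)],
                }
                for c in self.clusters
            ],
        }


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    """t vs zero across axis 0; bins with zero variance or NaN give t = 0."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = ~np.isfinite(t)
    if bad.any():
        t = np.where(bad, 0.0, t)
    return t


_STRUCT_2D = ndimage.generate_binary_structure(2, 1)  # 4-neighbourhood


def _max_cluster_mass(t: np.ndarray, thr: float) -> float:
    """Largest |summed t| over sign-homogeneous suprathreshold components."""
    best = 0.0
    for sign in (1, -1):
        mask = (sign * t) > thr
        if not mask.any():
            continue
        lab, nlab = ndimage.label(mask, structure=_STRUCT_2D if t.ndim == 2 else None)
        if nlab:
            sums = ndimage.sum_labels(np.abs(t), lab, index=np.arange(1, nlab + 1))
            best = max(best, float(sums.max()))
    return best


def _observed_clusters(t: np.ndarray, thr: float) -> list[tuple[np.ndarray, float, int]]:
    out = []
    for sign in (1, -1):
        mask = (sign * t) > thr
        if not mask.any():
            continue
        lab, nlab = ndimage.label(mask, structure=_STRUCT_2D if t.ndim == 2 else None)
        for i in range(1, nlab + 1):
            m = lab == i
            out.append((m, float(t[m].sum()), sign))
    out.sort(key=lambda c: -abs(c[1]))
    return out


def _shuffle_diff_maps(data, labels, rng, n_perm, chunk=250):
    """Yield (chunk, n_part, n_bins) arrays of permuted condition-mean differences.

    Labels are re-shuffled independently within every participant for each
    permutation; participant-level mean(A) - mean(B) maps are recomputed.
    """
    n_part = len(data)
    flat = [d.reshape(d.shape[0], -1) for d in data]
    n_bins = flat[0].shape[1]
    n_a = [int(l.sum()) for l in labels]
    n_b = [len(l) - a for l, a in zip(labels, n_a)]
    totals = [f.sum(axis=0) for f in flat]
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        diffs = np.empty((k, n_part, n_bins))
        for p in range(n_part):
            lab = np.tile(np.asarray(labels[p], dtype=float), (k, 1))
            lab = rng.permuted(lab, axis=1)
            ax = lab @ flat[p]  # (k, n_bins) sums of condition A
            mean_a = ax / n_a[p]
            mean_b = (totals[p] - ax) / n_b[p]
            diffs[:, p, :] = mean_a - mean_b
        yield diffs
        done += k


def cluster_permutation(
    data,
    labels=None,
    *,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    scheme: str = "trial_shuffle",
    sampler=None,
    chunk: int = 250,
) -> ClusterTestResult:
    """Cluster-based permutation test on participant-level maps.

    Parameters
    ----------
    data
        For ``scheme='trial_shuffle'``: a list with one array per participant of
        shape ``(n_trials, *map_shape)``; ``labels`` must give a boolean
        condition indicator per trial and participant.  The observed statistic
        is a one-sample t across participants of the within-participant
        condition-mean difference (equivalent to a paired t).
        For ``scheme='sign_flip'`` or ``scheme='sampler'``: an array
        ``(n_participants, *map_shape)`` of per-participant maps tested against
        zero.
    sampler
        Only for ``scheme='sampler'``: callable ``sampler(rng, k)`` returning
        ``(k, n_participants, *map_shape)`` surrogate participant maps.
    """
    rng = np.random.default_rng(seed)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; corrected p values are coarse")

    if scheme == "trial_shuffle":
        if labels is None:
            raise ValueError("labels required for trial_shuffle scheme")
        if len(data) < 2:
            raise ValueError("need at least 2 participants")
        map_shape = data[0].shape[1:]
        obs_maps = np.stack(
            [
                d[np.asarray(l, bool)].mean(axis=0) - d[~np.asarray(l, bool)].mean(axis=0)
                for d, l in zip(data, labels)
            ]
        )
        null_iter = _shuffle_diff_maps(data, labels, rng, n_perm, chunk)
    else:
        obs_maps = np.asarray(data, dtype=float)
        if obs_maps.ndim < 2 or obs_maps.shape[0] < 2:
            raise ValueError("need at least 2 participants")
        map_shape = obs_maps.shape[1:]
        if scheme == "sign_flip":
            flat = obs_maps.reshape(obs_maps.shape[0], -1)

            def null_gen():
                done = 0
                while done < n_perm:
                    k = min(chunk, n_perm - done)
                    signs = rng.choice([-1.0, 1.0], size=(k, flat.shape[0], 1))
                    yield signs * flat[None, :, :]
                    done += k

            null_iter = null_gen()
        elif scheme == "sampler":
            if sampler is None:
                raise ValueError("sampler required for scheme='sampler'")

            def null_gen():
                done = 0
                while done < n_perm:
                    k = min(chunk, n_perm - done)
                    maps = np.asarray(sampler(rng, k), dtype=float)
                    yield maps.reshape(k, maps.shape[1], -1)
                    done += k

            null_iter = null_gen()
        else:
            raise ValueError(f"unknown scheme {scheme!r}")

    n_part = obs_maps.shape[0]
    df = n_part - 1
    thr = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df))

    t_obs = _one_sample_t(obs_maps.reshape(n_part, -1)).reshape(map_shape)
    nonfinite = ~np.isfinite(t_obs)
    if nonfinite.any():
        logger.info("excluding %d non-finite stat bins from clustering", nonfinite.sum())
        t_obs = np.where(nonfinite, 0.0, t_obs)

    null_max = np.empty(n_perm)
    pos = 0
    for diffs in null_iter:
        k = diffs.shape[0]
        t_null = _one_sample_t(diffs.swapaxes(0, 1))  # (k, n_bins)
        t_null = np.where(np.isfinite(t_null), t_null, 0.0)
        for i in range(k):
            null_max[pos + i] = _max_cluster_mass(t_null[i].reshape(map_shape), thr)
        pos += k

    clusters = []
    for mask, mass, sign in _observed_clusters(t_obs, thr):
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(bins=mask, mass=mass, p=float(p), sign=sign))

    return ClusterTestResult(
        clusters=clusters,
        t_map=t_obs,
        threshold=thr,
        cluster_alpha=cluster_alpha,
        n_permutations=n_perm,
        scheme=scheme,
        seed=seed,
        null_max=null_max,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact tail probabilities
# ---------------------------------------------------------------------------


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of S = sum(sign_i * rank_i) under random signs.

    Ranks may be half-integral (average ties); they are doubled internally so
    the support is integral.  Returns (support, pmf).
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(2 * total + 1)
    pmf[total] = 1.0  # S (doubled) = 0
    for r in r2:
        shifted_up = np.zeros_like(pmf)
        shifted_dn = np.zeros_like(pmf)
        if r > 0:
            shifted_up[r:] = pmf[:-r]
            shifted_dn[:-r] = pmf[r:]
        else:
            shifted_up = shifted_dn = pmf
        pmf = 0.5 * (shifted_up + shifted_dn)
    support = (np.arange(-total, total + 1)) / 2.0
    return support, pmf


def signed_rank_test(x, y=None):
    """Paired Wilcoxon signed-rank test with exact two-sided p value.

    Zero differences are discarded (Wilcoxon's rule); ties receive average
    ranks.  Returns ``(s, z, p)`` where ``s = sum(sign * rank)`` (zero-centred
    statistic), ``z`` its normalized value and ``p`` the exact two-sided tail
    probability computed from the sign-randomization distribution of ``s``.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    s = float(np.sum(np.sign(d) * ranks))
    denom = np.sqrt(np.sum(ranks**2))
    z = s / denom if denom > 0 else 0.0
    support, pmf = _signed_rank_distribution(ranks)
    p = float(pmf[np.abs(support) >= abs(s) - 1e-9].sum())
    return s, float(z), min(p, 1.0)


def _positionwise_signed_rank(a: np.ndarray, b: np.ndarray, min_pairs: int):
    """Per-column signed-rank statistics for two (participants x positions) arrays."""
    n_pos = a.shape[1]
    s = np.zeros(n_pos)
    z = np.zeros(n_pos)
    p = np.ones(n_pos)
    skipped = np.zeros(n_pos, bool)
    lookups = []  # per position (offset_total2, cumulative tail lookup) for permutations
    rank_mats = np.zeros_like(a)
    sign_mats = np.zeros_like(a)
    for j in range(n_pos):
        d = a[:, j] - b[:, j]
        valid = np.isfinite(d) & (d != 0)
        nz = np.isfinite(d).sum()
        if nz < min_pairs:
            skipped[j] = True
            lookups.append(None)
            continue
        dd = d[valid]
        if dd.size == 0:
            lookups.append(None)
            continue
        ranks = sps.rankdata(np.abs(dd))
        rank_mats[valid, j] = ranks
        sign_mats[valid, j] = np.sign(dd)
        s[j] = np.sum(np.sign(dd) * ranks)
        denom = np.sqrt(np.sum(ranks**2))
        z[j] = s[j] / denom if denom > 0 else 0.0
        support, pmf = _signed_rank_distribution(ranks)
        # two-sided tail prob of |S| >= |s| for any s on the doubled-integer grid
        order = np.argsort(np.abs(support), kind="stable")
        absS = np.abs(support[order])
        tail = np.cumsum(pmf[order][::-1])[::-1]
        lookups.append((absS, tail, denom))
        p[j] = float(tail[np.searchsorted(absS, abs(s[j]) - 1e-9)])
    return s, z, p, skipped, rank_mats, sign_mats, lookups


def learning_curve_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    *,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    min_pairs: int = 5,
    per_participant: bool = True,
) -> ClusterTestResult:
    """Trial-position learning-curve comparison between two conditions.

    ``cond_a`` / ``cond_b`` are (participants x ordinal positions) rating
    matrices (NaN = missing response).  A paired Wilcoxon signed-rank test is
    run at every ordinal position (1st trial of condition A vs 1st of B, ...);
    contiguous runs of significant positions are cluster-corrected by randomly
    re-assigning the two condition labels (sign flips of the paired
    differences), independently per participant and position by default
    (``per_participant=True`` flips per participant/position; ``False`` flips
    each position globally across all participants).
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must have identical shape")
    rng = np.random.default_rng(seed)
    s, z, p, skipped, rank_m, sign_m, lookups = _positionwise_signed_rank(a, b, min_pairs)
    n_part, n_pos = a.shape
    if skipped.any():
        logger.info("skipped %d positions with < %d valid pairs", skipped.sum(), min_pairs)

    signed_ranks = rank_m * sign_m  # (n_part, n_pos); zeros where invalid
    if per_participant:
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_part, n_pos))
    else:  # one flip per position, shared by all participants
        flips = np.broadcast_to(
            rng.choice([-1.0, 1.0], size=(n_perm, 1, n_pos)), (n_perm, n_part, n_pos)
        )
    s_null = np.einsum("kpj,pj->kj", flips, signed_ranks)

    # exact per-position p for surrogate statistics, via precomputed tail lookups
    p_null = np.ones((n_perm, n_pos))
    z_null = np.zeros((n_perm, n_pos))
    for j in range(n_pos):
        if lookups[j] is None:
            continue
        absS, tail, denom = lookups[j]
        idx = np.searchsorted(absS, np.abs(s_null[:, j]) - 1e-9)
        p_null[:, j] = tail[np.minimum(idx, len(tail) - 1)]
        z_null[:, j] = s_null[:, j] / denom

    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        null_max[k] = _max_cluster_mass_from_p(z_null[k], p_null[k], cluster_alpha)

    clusters = []
    sig = (p < cluster_alpha) & ~skipped
    lab, nlab = ndimage.label(sig & (z > 0))
    neg, nneg = ndimage.label(sig & (z < 0))
    for labels_arr, count, sgn in ((lab, nlab, 1), (neg, nneg, -1)):
        for i in range(1, count + 1):
            m = labels_arr == i
            mass = float(z[m].sum())
            pc = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
            clusters.append(Cluster(bins=m, mass=mass, p=float(pc), sign=sgn))
    clusters.sort(key=lambda c: -abs(c.mass))

    return ClusterTestResult(
        clusters=clusters,
        t_map=z,
        threshold=float(cluster_alpha),
        cluster_alpha=cluster_alpha,
        n_permutations=n_perm,
        scheme="condition_flip_per_participant" if per_participant else "condition_flip_global",
        seed=seed,
        null_max=null_max,
    )


def _max_cluster_mass_from_p(z: np.ndarray, p: np.ndarray, alpha: float) -> float:
    best = 0.0
    sig = p < alpha
    for sgn in (1, -1):
        mask = sig & (sgn * z > 0)
        if not mask.any():
            continue
        lab, nlab = ndimage.label(mask)
        if nlab:
            sums = ndimage.sum_labels(np.abs(z), lab, index=np.arange(1, nlab + 1))
            best = max(best, float(sums.max()))
    return best


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA
# ---------------------------------------------------------------------------


def rm_anova_2way(table: pd.DataFrame, dv: str = "rating",
                  within: tuple[str, str] = ("cue", "phase"),
                  subject: str = "participant") -> pd.DataFrame:
    """Two-way repeated-measures ANOVA with partial eta squared.

    ``table`` is long-format with one mean value per participant x cell.
    Participants with incomplete cells are dropped listwise.  Returns a frame
    indexed by effect with columns F, df1, df2, p, partial_eta_sq.
    """
    from statsmodels.stats.anova import AnovaRM

    f1, f2 = within
    wide = table.pivot_table(index=subject, columns=[f1, f2], values=dv)
    n_cells = table[f1].nunique() * table[f2].nunique()
    complete = wide.dropna().index if wide.shape[1] == n_cells else wide.index[:0]
    tab = (
        table[table[subject].isin(complete)]
        .groupby([subject, f1, f2], as_index=False)[dv]
        .mean()
    )
    n_subj = tab[subject].nunique()
    if n_subj < 3:
        raise ValueError("need at least 3 participants with complete cells")

    if np.allclose(tab[dv].to_numpy(), tab[dv].to_numpy()[0]):
        effects = [f1, f2, f"{f1}:{f2}"]
        lev1, lev2 = tab[f1].nunique(), tab[f2].nunique()
        dfs = [(lev1 - 1, (lev1 - 1) * (n_subj - 1)),
               (lev2 - 1, (lev2 - 1) * (n_subj - 1)),
               ((lev1 - 1) * (lev2 - 1), (lev1 - 1) * (lev2 - 1) * (n_subj - 1))]
        return pd.DataFrame(
            {"F": 0.0, "df1": [d[0] for d in dfs], "df2": [d[1] for d in dfs],
             "p": 1.0, "partial_eta_sq": 0.0},
            index=pd.Index(effects, name="effect"),
        )

    res = AnovaRM(tab, depvar=dv, subject=subject, within=list(within)).fit()
    out = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"}
    )
    out["partial_eta_sq"] = (out["F"] * out["df1"]) / (out["F"] * out["df1"] + out["df2"])
    out.index = pd.Index([i.replace(" ", "") for i in out.index], name="effect")
    return out[["F", "df1", "df2", "p", "partial_eta_sq"]]


def posthoc_paired_t(table: pd.DataFrame, dv: str, factor: str, subject: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise paired t-tests over factor levels, Bonferroni-corrected."""
    levels = sorted(table[factor].unique())
    wide = table.pivot_table(index=subject, columns=factor, values=dv)
    rows = []
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    corr = bonferroni(alpha, len(pairs))
    for a, b in pairs:
        sub = wide[[a, b]].dropna()
        t, p = sps.ttest_rel(sub[a], sub[b])
        rows.append({"a": a, "b": b, "t": float(t), "p": float(p),
                     "significant": p < corr, "alpha_corrected": corr})
    return pd.DataFrame(rows)
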