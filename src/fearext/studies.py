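"""Reduced-scale validation studies: calibration and planted-effect recovery.

Each function defines a complete simulation study with frozen conditions —
cohort sizes, planted effect strengths, permutation counts — chosen so the
whole battery runs on a single CPU in minutes.  They are used by the test
suite and by ``scripts/acceptance.py``; the studies are the package's own
evidence that the pipeline detects what was planted and stays silent when
nothing was.

Study conditions (500 Hz recordings, 1-2 bipolar channels per ROI, reduced
rep counts, 200-500 permutations) are scaled-down versions of the full design;
the generator's physical defaults (1 kHz, full ROI set) are unchanged.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pipeline import (
    AnalysisConfig,
    cohort_context_specificity,
    cohort_item_stability,
    cohort_reinstatement_coupling,
    cohort_theta_contrast,
    process_participant,
)
from .schedule import DesignConfig, generate_experiment
from .stats import cluster_permutation, learning_curve_test
from .synthgen import GeneratorConfig, simulate_cohort, simulate_ratings

__all__ = [
    "fwer_calibration",
    "null_cohort_rates",
    "effect_recovery",
    "coupling_recovery",
    "behavioral_onset_recovery",
]

THETA_BAND = (3.0, 10.0)
THETA_WINDOW = (1.18, 1.75)


def _overlaps_theta(bounds: dict) -> bool:
    return (
        bounds["fmax"] >= THETA_BAND[0]
        and bounds["fmin"] <= THETA_BAND[1]
        and bounds["tmax"] >= THETA_WINDOW[0]
        and bounds["tmin"] <= THETA_WINDOW[1]
    )


def fwer_calibration(
    n_datasets: int = 1000,
    n_perm: int = 500,
    n_participants: int = 8,
    n_trials: int = 16,
    map_shape: tuple = (4, 6),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error of the cluster permutation under a Gaussian null.

    Independent standard-normal trial maps, arbitrary condition labels; the
    fraction of datasets with any corrected-significant cluster estimates the
    FWER and should sit near the nominal alpha.
    """
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    false_pos = 0
    for _ in range(n_datasets):
        data = [rng.standard_normal((n_trials, *map_shape)) for _ in range(n_participants)]
        labels = [np.r_[np.ones(half, bool), np.zeros(n_trials - half, bool)]
                  for _ in range(n_participants)]
        res = cluster_permutation(
            data, labels, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        false_pos += bool(res.significant(alpha))
    return false_pos / n_datasets


_NULL_DESIGN = DesignConfig(
    reps_per_cue_learning=8, reps_per_cue_test=6,
    contexts_per_phase={"acquisition": 4, "extinction": 4, "test": 6},
)


def null_cohort_rates(
    n_cohorts: int = 100,
    n_participants: int = 4,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Detection rates with every planted effect at zero.

    Full pipeline (simulation, filtering, referencing, epoching, wavelet
    decomposition, z-scoring, contrasts) on extinction-phase recordings with
    all gains zero; each contrast's cluster-detection rate at alpha = 0.05
    should stay near the nominal level.
    """
    rng = np.random.default_rng(seed)
    gen = GeneratorConfig(sampling_rate=500.0, rois={"AMY": 3})
    cfg = AnalysisConfig(n_perm=n_perm, detect_artifacts=False)
    hits = {"theta": 0, "item_stability": 0, "context_specificity": 0}
    for _ in range(n_cohorts):
        sim_seed, test_seed = (int(x) for x in rng.integers(2**31 - 1, size=2))
        parts = simulate_cohort(n_participants, seed=sim_seed, design=_NULL_DESIGN,
                                config=gen, phases=("extinction",))
        cohort = [process_participant(p, cfg) for p in parts]
        theta = cohort_theta_contrast(cohort, cfg=cfg, seed=test_seed)
        hits["theta"] += bool(theta.test.significant(0.05))
        item = cohort_item_stability(cohort, "AMY", cfg=cfg, seed=test_seed)
        hits["item_stability"] += bool(item["test"].significant(0.05))
        ctx = cohort_context_specificity(cohort, "AMY", cfg=cfg, seed=test_seed)
        hits["context_specificity"] += bool(ctx["test"].significant(0.05))
    return {k: v / n_cohorts for k, v in hits.items()}


_RECOVERY_DESIGN = DesignConfig(reps_per_cue_learning=12, reps_per_cue_test=8)


def effect_recovery(
    n_cohorts: int = 20,
    n_participants: int = 8,
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Recovery of the planted extinction effects.

    One cohort family carries three planted effects: a theta-band power
    increase for currently safe cues late in the cue window (AMY), higher
    pattern stability for the consistently threatening cue (AMY), and
    context-specific patterns (lPFC).  Returns the per-effect recovery rate:
    theta requires a significant negative cluster overlapping 3-10 Hz x
    1.18-1.75 s; the RSA effects require a significant cluster of the correct
    sign.
    """
    rng = np.random.default_rng(seed)
    # theta lives alone in AMY: its burst is shared by all CS- trials and
    # would otherwise bleed into the stability contrast of the same ROI
    gen = GeneratorConfig(
        sampling_rate=500.0,
        rois={"AMY": 3, "lPFC": 3},
        theta_safety_effect=1.5,
        item_pattern_gain={"lPFC": 1.5},
        item_pattern_roles=("CS++",),
        context_pattern_gain={"lPFC": 1.0},
    )
    cfg = AnalysisConfig(n_perm=n_perm, detect_artifacts=False)
    hits = {"theta": 0, "item_stability": 0, "context_specificity": 0}
    example_bounds = None
    for _ in range(n_cohorts):
        sim_seed, test_seed = (int(x) for x in rng.integers(2**31 - 1, size=2))
        parts = simulate_cohort(n_participants, seed=sim_seed, design=_RECOVERY_DESIGN,
                                config=gen, phases=("extinction",))
        cohort = [process_participant(p, cfg) for p in parts]

        theta = cohort_theta_contrast(cohort, cfg=cfg, seed=test_seed)
        for c in theta.test.significant(0.05):
            if c.sign == -1 and _overlaps_theta(theta.cluster_bounds(c)):
                hits["theta"] += 1
                if example_bounds is None:
                    example_bounds = theta.cluster_bounds(c)
                break

        item = cohort_item_stability(cohort, "lPFC", cfg=cfg, seed=test_seed)
        hits["item_stability"] += any(c.sign == 1 for c in item["test"].significant(0.05))

        ctx = cohort_context_specificity(cohort, "lPFC", cfg=cfg, seed=test_seed)
        hits["context_specificity"] += any(c.sign == 1 for c in ctx["test"].significant(0.05))
    out = {k: v / n_cohorts for k, v in hits.items()}
    out["example_theta_cluster"] = example_bounds
    return out


_COUPLING_DESIGN = DesignConfig(
    reps_per_cue_learning=10, reps_per_cue_test=10,
    contexts_per_phase={"acquisition": 4, "extinction": 4, "test": 4},
)


def coupling_recovery(
    n_cohorts: int = 20,
    n_participants: int = 12,
    seed: int = 0,
) -> dict:
    """Role-selective context-specificity -> reinstatement coupling.

    Across participants, the lPFC context-pattern gain and the balance of
    fear- vs extinction-trace re-expression at test covary, for the
    contingency-reversal cue (CS+-) only.  A cohort counts as a selective
    recovery when the across-participant Spearman correlation is significant
    for CS+- and not for CS++ or CS--.
    """
    rng = np.random.default_rng(seed)
    base = GeneratorConfig(
        sampling_rate=500.0, rois={"TMP": 3, "lPFC": 3},
        shared_pattern_weight=0.5, phase_pattern_weight=1.0,
    )
    cfg = AnalysisConfig(
        epoch_window=(-2.5, 2.5), detect_artifacts=False,
        lpfc_context_window=(0.2, 1.6),
    )

    def per_part(i, _rng):
        g = i / (n_participants - 1)
        return replace(
            base,
            item_pattern_gain={"TMP": 1.5},
            context_pattern_gain={"lPFC": 0.6 + 1.6 * g},
            test_phase_reinstatement={"CS+-": (2.0 * g, 2.0 * (1.0 - g))},
        )

    selective = detected = 0
    rhos = []
    for _ in range(n_cohorts):
        s = int(rng.integers(2**31 - 1))
        parts = simulate_cohort(n_participants, seed=s, design=_COUPLING_DESIGN,
                                config=base, per_participant=per_part)
        cohort = [process_participant(p, cfg) for p in parts]
        out = cohort_reinstatement_coupling(cohort, cfg=cfg)
        hit = out["CS+-"]["p"] < 0.05
        detected += hit
        selective += hit and out["CS++"]["p"] >= 0.05 and out["CS--"]["p"] >= 0.05
        rhos.append(out["CS+-"]["rho"])
    return {
        "selective_rate": selective / n_cohorts,
        "detection_rate": detected / n_cohorts,
        "mean_rho_cs_plus_minus": float(np.mean(rhos)),
    }


def behavioral_onset_recovery(
    n_cohorts: int = 20,
    n_participants: int = 16,
    learning_onset: int = 10,
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Learning-curve changepoint recovery from simulated ratings.

    Ratings diverge between the consistently threatening and consistently
    safe cues at ordinal position ``learning_onset``; the recovered onset is
    the first position of the significant Wilcoxon cluster.
    """
    rng = np.random.default_rng(seed)
    onsets = []
    for _ in range(n_cohorts):
        mats = {"CS++": [], "CS--": []}
        for _ in range(n_participants):
            s = int(rng.integers(2**31 - 1))
            exp = generate_experiment(seed=s)
            ratings = simulate_ratings(
                exp, learning_onset=learning_onset, noise_sd=0.5,
                miss_rate=0.08, seed=s,
            )
            acq = ratings[ratings["phase"] == "acquisition"]
            for role in mats:
                sub = acq[acq["role"] == role].sort_values("ordinal")
                mats[role].append(sub["rating"].to_numpy())
        a = np.vstack(mats["CS++"])
        b = np.vstack(mats["CS--"])
        res = learning_curve_test(a, b, n_perm=n_perm,
                                  seed=int(rng.integers(2**31 - 1)))
        sig = res.significant(0.05)
        onsets.append(int(np.argwhere(sig[0].bins).min()) + 1 if sig else np.nan)
    onsets = np.asarray(onsets, float)
    ok = np.abs(onsets - learning_onset) <= 3
    return {
        "within_3_rate": float(np.mean(ok)),
        "mean_onset": float(np.nanmean(onsets)),
        "onsets": onsets.tolist(),
    }
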