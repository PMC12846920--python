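"""End-to-end orchestration: simulate -> preprocess -> decompose -> analyze.

`process_participant` turns one (simulated or loaded) participant's continuous
recording into z-scored time-frequency tensors per ROI; the `cohort_*`
functions assemble group-level analyses from a list of processed participants.
`run_pipeline` drives the whole flow from a config mapping and writes a
provenance-stamped report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coordination import cross_roi_trial_correlation, theta_metric_correlation, zscore_within_condition
from .preprocess import bipolar_reference, detect_artifacts, epoch_and_reject, filter_recording
from .reinstatement import (
    context_vs_reinstatement_correlation,
    cross_phase_similarity,
    differential_reinstatement,
    phase_reinstatement,
    reinstatement_vs_ratings,
    trial_reinstatement,
)
from .rsa import (
    build_feature_vectors,
    context_specificity_series,
    group_context_specificity_contrast,
    group_item_stability_contrast,
    pairwise_spearman,
    single_trial_context_specificity,
    single_trial_item_stability,
)
from .spectral import build_grid, cluster_mean_power, morlet_tfr, tf_condition_contrast, zscore_power
from .stats import bonferroni, learning_curve_test, rm_anova_2way
from .synthgen import GeneratorConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ParticipantData",
    "process_participant",
    "cohort_theta_contrast",
    "cohort_item_stability",
    "cohort_context_specificity",
    "cohort_coordination",
    "cohort_theta_coupling",
    "cohort_reinstatement_coupling",
    "cohort_reinstatement_vs_ratings",
    "cohort_learning_curves",
    "cohort_rating_anova",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisConfig:
    rois: tuple | None = None            # None = all ROIs present
    detect_artifacts: bool = True        # disable for clean synthetic data
    epoch_window: tuple = (-3.0, 4.0)    # s around cue onset
    tfr_decim: int = 10                  # -> 100 Hz power time axis at 1 kHz
    theta_band: tuple = (1.0, 12.0)
    contrast_window: tuple = (0.0, 1.75)
    contrast_step: float = 0.02
    rsa_window: float = 0.5
    rsa_step: float = 0.05
    coord_step: float = 0.025            # 95% overlap for coordination maps
    zscore_window: tuple = (0.0, 1.75)
    lpfc_context_window: tuple = (0.8, 1.15)
    tmp_item_window: tuple = (0.65, 1.0)
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    min_trials: int = 8
    min_trials_ratings: int = 4
    n_rois_bonferroni: int = 5
    seed: int = 0


@dataclass
class ParticipantData:
    tensors: dict                        # roi -> z-scored TimeFrequencyTensor
    experiment: object
    ratings: pd.DataFrame | None = None
    excluded: dict = field(default_factory=dict)  # roi -> excluded condition list


def process_participant(participant, cfg: AnalysisConfig | None = None) -> ParticipantData:
    """Filter, re-reference, detect artifacts, epoch, decompose and z-score."""
    cfg = cfg or AnalysisConfig()
    rec = participant.recording
    fs = rec.sampling_rate
    rec = filter_recording(rec)
    rec = bipolar_reference(rec)
    mask = None
    if cfg.detect_artifacts:
        hf_cutoff = 250.0 if fs > 500.0 else 200.0
        mask = detect_artifacts(rec, hf_cutoff=hf_cutoff)
    epochs = epoch_and_reject(
        rec, participant.experiment, mask, window=cfg.epoch_window,
        min_trials=cfg.min_trials, rois=list(cfg.rois) if cfg.rois else None,
    )
    decim = max(1, int(round(fs / 100.0)))
    tensors, excluded = {}, {}
    grid = build_grid()
    for roi, ep in epochs.items():
        if ep.n_trials == 0:
            continue
        tft = morlet_tfr(ep, grid, decim=decim)
        tensors[roi] = zscore_power(tft, reference_window=cfg.zscore_window)
        excluded[roi] = ep.excluded_conditions
    return ParticipantData(
        tensors=tensors,
        experiment=participant.experiment,
        ratings=getattr(participant, "ratings", None),
        excluded=excluded,
    )


def _phase_tensor(data: ParticipantData, roi: str, phase: str):
    tft = data.tensors.get(roi)
    if tft is None:
        return None
    sel = tft.select(phase=phase)
    return sel if sel.n_trials else None


def cohort_theta_contrast(
    cohort: list, roi: str = "AMY", phase: str = "extinction",
    cfg: AnalysisConfig | None = None, band: tuple | None = None, seed=None,
):
    """Group CS+ vs CS- power contrast in one ROI and phase."""
    cfg = cfg or AnalysisConfig()
    tensors, labels = [], []
    for data in cohort:
        tft = _phase_tensor(data, roi, phase)
        if tft is None:
            continue
        tensors.append(tft)
        labels.append((tft.metadata["valence"] == "CS+").to_numpy())
    return tf_condition_contrast(
        tensors, labels,
        band=band or cfg.theta_band,
        window=cfg.contrast_window,
        step=cfg.contrast_step,
        n_perm=cfg.n_perm,
        seed=cfg.seed if seed is None else seed,
        cluster_alpha=cfg.cluster_alpha,
        min_trials=cfg.min_trials,
    )


def _phase_similarity(data, roi, phase, cfg, lock="cue_onset", step=None):
    tft = _phase_tensor(data, roi, phase)
    if tft is None:
        return None
    patterns = build_feature_vectors(
        tft, window=cfg.rsa_window, step=step or cfg.rsa_step, lock=lock
    )
    sim = pairwise_spearman(patterns)
    return sim, tft.metadata


def cohort_item_stability(
    cohort: list, roi: str, phase: str = "extinction",
    cfg: AnalysisConfig | None = None, seed=None,
):
    cfg = cfg or AnalysisConfig()
    sims, cues, vals = [], [], []
    for data in cohort:
        out = _phase_similarity(data, roi, phase, cfg)
        if out is None:
            continue
        sim, meta = out
        sims.append(sim)
        cues.append(meta["cue_id"].to_numpy())
        vals.append(meta["valence"].to_numpy())
    res, obs, excluded = group_item_stability_contrast(
        sims, cues, vals, n_perm=cfg.n_perm,
        seed=cfg.seed if seed is None else seed,
        cluster_alpha=cfg.cluster_alpha, min_trials=cfg.min_trials,
    )
    centers = sims[0].centers if sims else None
    return {"test": res, "diffs": obs, "centers": centers, "excluded": excluded}


def cohort_context_specificity(
    cohort: list, roi: str, phase: str = "extinction", lock: str = "cue_onset",
    cfg: AnalysisConfig | None = None, seed=None, different_cue_only: bool = False,
):
    cfg = cfg or AnalysisConfig()
    sims, ctxs, cues = [], [], []
    for data in cohort:
        out = _phase_similarity(data, roi, phase, cfg, lock=lock)
        if out is None:
            continue
        sim, meta = out
        sims.append(sim)
        ctxs.append(meta["context_id"].to_numpy())
        cues.append(meta["cue_id"].to_numpy())
    res, obs, excluded = group_context_specificity_contrast(
        sims, ctxs, n_perm=cfg.n_perm,
        seed=cfg.seed if seed is None else seed,
        cluster_alpha=cfg.cluster_alpha, min_trials=cfg.min_trials,
        cue_ids_list=cues, different_cue_only=different_cue_only,
    )
    centers = sims[0].centers if sims else None
    return {"test": res, "diffs": obs, "centers": centers, "excluded": excluded}


def _common_trial_metric(sim_meta_a, sim_meta_b, metric_fn_a, metric_fn_b):
    """Align two ROIs' single-trial metrics on the intersection of retained trials."""
    (sim_a, meta_a), (sim_b, meta_b) = sim_meta_a, sim_meta_b
    key_a = list(zip(meta_a["phase"], meta_a["index"]))
    key_b = list(zip(meta_b["phase"], meta_b["index"]))
    common = [k for k in key_a if k in set(key_b)]
    ia = [key_a.index(k) for k in common]
    ib = [key_b.index(k) for k in common]
    ma = metric_fn_a(sim_a, meta_a)[ia]
    mb = metric_fn_b(sim_b, meta_b)[ib]
    labels = meta_a["valence"].to_numpy()[ia]
    return ma, mb, labels


def cohort_coordination(
    cohort: list, roi_a: str, roi_b: str, metric: str = "item-stability",
    phase: str = "extinction", cfg: AnalysisConfig | None = None,
    zscore_within: bool = True, seed=None,
):
    """Cross-ROI temporal-generalization coordination of a single-trial metric."""
    cfg = cfg or AnalysisConfig()

    def metric_fn(sim, meta):
        if metric == "item-stability":
            return single_trial_item_stability(sim, meta["cue_id"].to_numpy())
        if metric == "context-specificity":
            return single_trial_context_specificity(sim, meta["context_id"].to_numpy())
        raise ValueError(f"unknown metric {metric!r}")

    mas, mbs, labs, centers = [], [], [], None
    for data in cohort:
        out_a = _phase_similarity(data, roi_a, phase, cfg, step=cfg.coord_step)
        out_b = _phase_similarity(data, roi_b, phase, cfg, step=cfg.coord_step)
        if out_a is None or out_b is None:
            continue
        ma, mb, labels = _common_trial_metric(out_a, out_b, metric_fn, metric_fn)
        mas.append(ma)
        mbs.append(mb)
        labs.append(labels)
        centers = out_a[0].centers
    return cross_roi_trial_correlation(
        mas, mbs, labels=labs, zscore_within=zscore_within,
        n_perm=cfg.n_perm, seed=cfg.seed if seed is None else seed,
        cluster_alpha=cfg.cluster_alpha, min_trials=cfg.min_trials,
        centers_a=centers, centers_b=centers,
    )


def cohort_theta_coupling(
    cohort: list, theta_cluster: dict, metric: str = "item-stability",
    metric_roi: str = "AMY", theta_roi: str = "AMY", phase: str = "extinction",
    mode: str = "window-averaged", cfg: AnalysisConfig | None = None, seed=None,
):
    """Across-trial correlation of cluster-averaged theta power with an RSA metric.

    ``theta_cluster`` holds ``freq_idx`` and ``time_idx`` into each
    participant's tensor (typically the significant extinction cluster) plus
    the metric averaging window in seconds (``window``).  Theta scalars are
    z-scored within condition; in window-averaged mode the summary p value
    should be Bonferroni-compared across ROIs by the caller.
    """
    cfg = cfg or AnalysisConfig()
    thetas, metrics = [], []
    for data in cohort:
        tft = _phase_tensor(data, theta_roi, phase)
        out = _phase_similarity(data, metric_roi, phase, cfg)
        if tft is None or out is None:
            continue
        sim, meta_m = out
        meta_t = tft.metadata
        key_t = list(zip(meta_t["phase"], meta_t["index"]))
        key_m = list(zip(meta_m["phase"], meta_m["index"]))
        common = [k for k in key_t if k in set(key_m)]
        it = [key_t.index(k) for k in common]
        im = [key_m.index(k) for k in common]
        scal = cluster_mean_power(tft, theta_cluster["freq_idx"], theta_cluster["time_idx"])
        labels = meta_t["valence"].to_numpy()
        scal = zscore_within_condition(scal, labels)[it]
        if metric == "item-stability":
            m = single_trial_item_stability(sim, meta_m["cue_id"].to_numpy())
        else:
            m = single_trial_context_specificity(sim, meta_m["context_id"].to_numpy())
        m = m[im]
        if mode == "window-averaged" and "window" in theta_cluster:
            lo, hi = theta_cluster["window"]
            widx = np.flatnonzero((sim.centers >= lo - 1e-9) & (sim.centers <= hi + 1e-9))
            m = m[:, widx]
        thetas.append(scal)
        metrics.append(m)
    return theta_metric_correlation(
        thetas, metrics, mode=mode, n_perm=cfg.n_perm,
        seed=cfg.seed if seed is None else seed,
        cluster_alpha=cfg.cluster_alpha, min_trials=cfg.min_trials,
    )


def _participant_patterns(data, roi, phase, cfg):
    tft = _phase_tensor(data, roi, phase)
    if tft is None:
        return None
    return build_feature_vectors(tft, window=cfg.rsa_window, step=cfg.rsa_step), tft.metadata


def cohort_reinstatement_coupling(
    cohort: list, ctx_roi: str = "lPFC", reinst_roi: str = "TMP",
    cfg: AnalysisConfig | None = None,
):
    """Across-participant coupling of extinction context specificity with
    differential reinstatement, per cue role."""
    cfg = cfg or AnalysisConfig()
    ctx_vals, reinst_by_role = [], {r: [] for r in ("CS++", "CS+-", "CS--")}
    lo, hi = cfg.lpfc_context_window
    for data in cohort:
        out_ctx = _phase_similarity(data, ctx_roi, "extinction", cfg)
        pat_acq = _participant_patterns(data, reinst_roi, "acquisition", cfg)
        pat_ext = _participant_patterns(data, reinst_roi, "extinction", cfg)
        pat_tst = _participant_patterns(data, reinst_roi, "test", cfg)
        if out_ctx is None or pat_acq is None or pat_ext is None or pat_tst is None:
            ctx_vals.append(np.nan)
            for r in reinst_by_role:
                reinst_by_role[r].append(np.nan)
            continue
        sim_ctx, meta_ctx = out_ctx
        widx = np.flatnonzero((sim_ctx.centers >= lo - 1e-9) & (sim_ctx.centers <= hi + 1e-9))
        series = context_specificity_series(sim_ctx, meta_ctx["context_id"].to_numpy())
        ctx_vals.append(float(np.nanmean(series[widx])))

        (pa, ma), (pe, me), (pt, mt) = pat_acq, pat_ext, pat_tst
        sim_at = cross_phase_similarity(pa, pt)
        sim_et = cross_phase_similarity(pe, pt)
        r_acq = phase_reinstatement(sim_at, ma["cue_id"], mt["cue_id"], mt["role"], widx)
        r_ext = phase_reinstatement(sim_et, me["cue_id"], mt["cue_id"], mt["role"], widx)
        reinst = differential_reinstatement(r_acq, r_ext)
        for r in reinst_by_role:
            reinst_by_role[r].append(reinst.get(r, np.nan))
    out = {}
    for role, vals in reinst_by_role.items():
        out[role] = context_vs_reinstatement_correlation(
            np.asarray(ctx_vals), np.asarray(vals)
        )
    return out


def cohort_reinstatement_vs_ratings(
    cohort: list, roi: str = "TMP", cfg: AnalysisConfig | None = None,
    outlier_sd: float | None = None, min_trials: int | None = None,
):
    """Trial-level extinction-to-test reinstatement vs safety ratings."""
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.tmp_item_window
    values, ratings, roles = [], [], []
    for data in cohort:
        pat_ext = _participant_patterns(data, roi, "extinction", cfg)
        pat_tst = _participant_patterns(data, roi, "test", cfg)
        if pat_ext is None or pat_tst is None or data.ratings is None:
            continue
        (pe, me), (pt, mt) = pat_ext, pat_tst
        sim_et = cross_phase_similarity(pe, pt)
        centers = pe.centers
        widx = np.flatnonzero((centers >= lo - 1e-9) & (centers <= hi + 1e-9))
        tvals = trial_reinstatement(sim_et, me["cue_id"].to_numpy(), mt["cue_id"].to_numpy(), widx)
        test_ratings = data.ratings[data.ratings["phase"] == "test"].set_index("index")["rating"]
        values.append(tvals)
        ratings.append(test_ratings.reindex(mt["index"]).to_numpy())
        roles.append(mt["role"].to_numpy())
    return reinstatement_vs_ratings(
        values, ratings, roles, outlier_sd=outlier_sd,
        min_trials=cfg.min_trials_ratings if min_trials is None else min_trials,
    )


def _rating_matrix(cohort, phase, role):
    """(participants x ordinal positions) rating matrix for one cue role."""
    rows = []
    for data in cohort:
        df = data.ratings
        sub = df[(df["phase"] == phase) & (df["role"] == role)].sort_values("ordinal")
        rows.append(sub["rating"].to_numpy())
    n = max(len(r) for r in rows)
    out = np.full((len(rows), n), np.nan)
    for i, r in enumerate(rows):
        out[i, : len(r)] = r
    return out


def cohort_learning_curves(
    cohort: list, phase: str = "acquisition", pair: tuple = ("CS++", "CS--"),
    cfg: AnalysisConfig | None = None, seed=None,
):
    """Trial-position Wilcoxon comparison of two cue roles' rating curves."""
    cfg = cfg or AnalysisConfig()
    a = _rating_matrix(cohort, phase, pair[0])
    b = _rating_matrix(cohort, phase, pair[1])
    return learning_curve_test(
        a, b, n_perm=cfg.n_perm, seed=cfg.seed if seed is None else seed,
        cluster_alpha=cfg.cluster_alpha,
    )


def cohort_rating_anova(cohort: list):
    """Two-way (cue role x phase) repeated-measures ANOVA on mean ratings."""
    rows = []
    for i, data in enumerate(cohort):
        g = data.ratings.groupby(["role", "phase"])["rating"].mean().reset_index()
        g["participant"] = i
        rows.append(g)
    table = pd.concat(rows, ignore_index=True).rename(columns={"role": "cue"})
    return rm_anova_2way(table)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "n_subjects": 8,
    "seed": 0,
    "design": {},         # DesignConfig overrides
    "generator": {},      # GeneratorConfig overrides
    "analysis": {},       # AnalysisConfig overrides
    "ratings": {},        # simulate_ratings overrides
}

_REQUIRED_GENERATOR_FIELDS = ("rois",)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    """Merge with defaults and check field names; raises naming the bad field."""
    merged = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    unknown = set(merged) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    gen_fields = set(GeneratorConfig.__dataclass_fields__)
    bad = set(merged["generator"]) - gen_fields
    if bad:
        raise ValueError(f"unknown generator fields: {sorted(bad)}")
    ana_fields = set(AnalysisConfig.__dataclass_fields__)
    bad = set(merged["analysis"]) - ana_fields
    if bad:
        raise ValueError(f"unknown analysis fields: {sorted(bad)}")
    from .schedule import DesignConfig

    bad = set(merged["design"]) - set(DesignConfig.__dataclass_fields__)
    if bad:
        raise ValueError(f"unknown design fields: {sorted(bad)}")
    if "rois" in merged["generator"] and not merged["generator"]["rois"]:
        raise ValueError("generator.rois must not be empty")
    return merged


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Simulate a cohort, run the full analysis battery, write a report.

    Returns the report dict; when ``outdir`` is given, writes ``report.json``
    (deterministic for a fixed config) plus tidy TSVs of the main metrics.
    """
    config = validate_config(config)
    chash = _config_hash(config)
    seed = int(config["seed"])
    gen_cfg = GeneratorConfig(**config["generator"])
    ana_kwargs = dict(config["analysis"])
    ana_kwargs["seed"] = ana_kwargs.get("seed", seed)
    for key in ("theta_band", "contrast_window", "zscore_window",
                "lpfc_context_window", "tmp_item_window", "rois"):
        if key in ana_kwargs and isinstance(ana_kwargs[key], list):
            ana_kwargs[key] = tuple(ana_kwargs[key])
    cfg = AnalysisConfig(**ana_kwargs)

    from .schedule import DesignConfig

    design = DesignConfig(**config["design"]) if config["design"] else None
    logger.info("simulating cohort of %d participants (seed %d)", config["n_subjects"], seed)
    participants = simulate_cohort(
        config["n_subjects"], seed=seed, design=design, config=gen_cfg,
        ratings_kwargs=config["ratings"],
    )
    cohort = []
    for i, part in enumerate(participants):
        try:
            cohort.append(process_participant(part, cfg))
        except Exception as err:  # noqa: BLE001 - stage failure must name the stage
            raise RuntimeError(f"preprocessing failed for participant {i}: {err}") from err

    report = {
        "package_version": __version__,
        "config_hash": chash,
        "seed": seed,
        "n_subjects": config["n_subjects"],
        "stages": {},
    }

    rois = cfg.rois or sorted({r for d in cohort for r in d.tensors})
    theta = cohort_theta_contrast(cohort, roi="AMY" if "AMY" in rois else rois[0], cfg=cfg)
    sig = theta.test.significant()
    report["stages"]["theta_contrast"] = {
        "n_participants": theta.n_participants,
        "clusters": theta.test.to_dict()["clusters"],
        "significant_bounds": [theta.cluster_bounds(c) for c in sig],
    }

    roi_item = "AMY" if "AMY" in rois else rois[0]
    item = cohort_item_stability(cohort, roi_item, cfg=cfg)
    report["stages"]["item_stability"] = {
        "roi": roi_item,
        "clusters": item["test"].to_dict()["clusters"],
    }

    roi_ctx = "lPFC" if "lPFC" in rois else rois[-1]
    ctx = cohort_context_specificity(cohort, roi_ctx, cfg=cfg)
    report["stages"]["context_specificity"] = {
        "roi": roi_ctx,
        "clusters": ctx["test"].to_dict()["clusters"],
    }

    lc = cohort_learning_curves(cohort, cfg=cfg)
    report["stages"]["learning_curve"] = {
        "clusters": lc.to_dict()["clusters"],
        "onset_position": int(np.argwhere(lc.significant()[0].bins).min()) + 1
        if lc.significant() else None,
    }
    anova = cohort_rating_anova(cohort)
    report["stages"]["rating_anova"] = anova.reset_index().to_dict(orient="records")
    report["bonferroni_alpha_rois"] = bonferroni(0.05, cfg.n_rois_bonferroni)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        anova.to_csv(outdir / "rating_anova.tsv", sep="\t")
        pd.DataFrame(
            {"centers": item["centers"], "mean_diff": item["diffs"].mean(axis=0)}
        ).to_csv(outdir / f"item_stability_{roi_item}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"centers": ctx["centers"], "mean_diff": ctx["diffs"].mean(axis=0)}
        ).to_csv(outdir / f"context_specificity_{roi_ctx}.tsv", sep="\t", index=False)
    return report
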