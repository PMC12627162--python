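"""End-to-end simulation of the transfer-of-bias study on synthetic cohorts.

One simulated participant goes through the full protocol:

1. pre-assessment: blank-screen viewing (BSV), image viewing (IVT, a set of
   images whose individual exploration biases are balanced around the
   midline), landmark task (LT);
2. training: the closed-loop audio-visual search with 2:1 hemifield-biased
   targets, during which the agent's hemifield prior is updated trial by
   trial;
3. post-assessment: the same three tasks, with the participant's free-
   viewing bias shifted by the learned prior (scaled by an individual
   transfer gain).

The analysis chain then mirrors the human study: event segmentation,
barycenters, sign-corrected shifts, one-sided t-tests, PSE fits,
congruent-bias indices, 500-ms binned learning curves and the gamma GLM.
Everything is driven by one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stats as tstats
from .features import build_feature_vector, FEATURE_NAMES
from .observer import (
    LandmarkDesign,
    Participant,
    RunAndTumbleAgent,
    generate_cohort,
    select_balanced_images,
    simulate_free_viewing,
    simulate_landmark_session,
)
from .preprocessing import DetectorParams, interpolate_gaps, is_valid_trial, \
    segment_trace
from .task_engine import StudyConfig, run_trial, sample_target_sequence

__all__ = ["StudySimParams", "run_participant", "run_study", "analyze_study"]


@dataclass(frozen=True)
class StudySimParams:
    """Problem sizes and task parameters for one simulated study.

    Defaults reproduce the real protocol (600 Hz, 180 training trials,
    1-min BSV, 30 x 5-s images, 88 landmark trials); reduced values are
    used for fast property checks.
    """

    fs: float = 600.0
    n_trials: int = 180
    bsv_duration_s: float = 60.0
    n_images: int = 30
    n_candidate_images: int = 60
    image_duration_s: float = 5.0
    image_bias_sd: float = 1.5
    landmark: LandmarkDesign = field(default_factory=LandmarkDesign)
    detector: DetectorParams = field(default_factory=DetectorParams)
    max_contig_missing_frac: float = 0.4


def _image_biases(sim: StudySimParams, rng: np.random.Generator) -> np.ndarray:
    """Per-image exploration biases for a balanced image set (deg)."""
    candidates = rng.normal(0.0, sim.image_bias_sd, sim.n_candidate_images)
    idx = select_balanced_images(candidates, sim.n_images)
    return candidates[idx]


def _assessment(style, sim: StudySimParams, image_biases: np.ndarray,
                rng: np.random.Generator) -> dict:
    """Run BSV + IVT for one phase; returns traces and segmentations."""
    bsv = simulate_free_viewing(style, sim.bsv_duration_s, sim.fs, rng)
    bsv_seg = segment_trace(bsv, sim.detector) if is_valid_trial(
        bsv, sim.max_contig_missing_frac) else None
    ivt = []
    for b in image_biases:
        st = replace(style, horiz_bias=style.horiz_bias + float(b))
        tr = simulate_free_viewing(st, sim.image_duration_s, sim.fs, rng)
        seg = segment_trace(tr, sim.detector) if is_valid_trial(
            tr, sim.max_contig_missing_frac) else None
        ivt.append((tr, seg))
    return {"bsv": (bsv, bsv_seg), "ivt": ivt}


def run_participant(p: Participant, sim: StudySimParams,
                    image_biases: np.ndarray) -> dict:
    """Simulate one participant's full protocol.

    Returns per-trial binned distances, trial outcomes, per-task shift
    measures, the pre-assessment feature vectors, the congruent-bias
    indices, and the trained hemifield prior.
    """
    ss = np.random.SeedSequence(p.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_pre, rng_train, rng_post, rng_lt = rngs

    config = StudyConfig(bias_side=p.bias_side, n_trials=sim.n_trials,
                         fs=sim.fs, seed=p.seed)
    side_sign = 1.0 if p.bias_side == "right" else -1.0

    pre = _assessment(p.style, sim, image_biases, rng_pre)
    lt_pre = simulate_landmark_session(p.pse_pre, p.lt_slope, sim.landmark,
                                       rng_lt)

    # --- training ---------------------------------------------------------
    agent = RunAndTumbleAgent(p.agent, prior=0.5)
    targets = sample_target_sequence(config, rng_train)
    binned_rows = []
    trial_rows = []
    for i, target in enumerate(targets, start=1):
        rec = run_trial(agent, target, config, rng_train, trial_number=i)
        agent.learn(target, config)
        b = tstats.bin_gaze_target_distance(rec)
        b["pid"] = p.pid
        binned_rows.append(b)
        trial_rows.append({"pid": p.pid, "trial_number": i,
                           "bias_label": rec.bias_label, "found": rec.found,
                           "search_time_s": rec.search_time_s})

    # --- transfer: learned prior shifts the free-viewing bias -------------
    learned_shift = p.transfer_gain * (2.0 * agent.prior - 1.0) * side_sign
    post_style = replace(p.style,
                         horiz_bias=p.style.horiz_bias + learned_shift)
    post = _assessment(post_style, sim, image_biases, rng_post)
    pse_post = p.pse_pre + p.lt_transfer_gain * (2.0 * agent.prior - 1.0) \
        * side_sign
    lt_post = simulate_landmark_session(pse_post, p.lt_slope, sim.landmark,
                                        rng_lt)

    # --- per-task shift measures ------------------------------------------
    shifts = []
    bsv_pre_seg = pre["bsv"][1]
    bsv_post_seg = post["bsv"][1]
    if bsv_pre_seg is not None and bsv_post_seg is not None:
        shifts.append(tstats.ShiftMeasure(
            p.pid, "BSV", tstats.barycenter(bsv_pre_seg.fixations),
            tstats.barycenter(bsv_post_seg.fixations), p.bias_side))
    per_image = []
    for (tr0, s0), (tr1, s1) in zip(pre["ivt"], post["ivt"]):
        if s0 is None or s1 is None or len(s0.fixations) == 0 \
                or len(s1.fixations) == 0:
            continue
        per_image.append(tstats.barycenter(s1.fixations)
                         - tstats.barycenter(s0.fixations))
    if per_image:
        med = tstats.image_shift_collapse(per_image)
        shifts.append(tstats.ShiftMeasure(p.pid, "IVT", 0.0, med, p.bias_side))
    fit_pre = tstats.fit_psychometric(lt_pre["offset_deg"], lt_pre["resp_right"])
    fit_post = tstats.fit_psychometric(lt_post["offset_deg"],
                                       lt_post["resp_right"])
    shifts.append(tstats.ShiftMeasure(p.pid, "LT", fit_pre.pse, fit_post.pse,
                                      p.bias_side))

    # --- baseline features and congruent bias -----------------------------
    features = {}
    congruent = {}
    if bsv_pre_seg is not None:
        features["BSV"] = build_feature_vector(pre["bsv"][0], bsv_pre_seg, "BSV")
        early = bsv_pre_seg.fixations.query("onset_s < 1.0")["x"]
        congruent["BSV"] = tstats.congruent_bias(early, p.bias_side)
    ivt_vectors = [build_feature_vector(tr, seg, "IVT")
                   for tr, seg in pre["ivt"] if seg is not None]
    if ivt_vectors:
        features["IVT"] = pd.concat(ivt_vectors, axis=1).mean(axis=1)
        early_x = np.concatenate([
            seg.fixations.query("onset_s < 1.0")["x"].to_numpy()
            for _, seg in pre["ivt"] if seg is not None])
        congruent["IVT"] = tstats.congruent_bias(early_x, p.bias_side)

    return {
        "binned": pd.concat(binned_rows, ignore_index=True),
        "trials": pd.DataFrame(trial_rows),
        "shifts": shifts,
        "features": features,
        "congruent": congruent,
        "final_prior": agent.prior,
    }


def run_study(cohort: list[Participant], sim: StudySimParams | None = None,
              seed: int = 0) -> dict:
    """Simulate every participant and assemble tidy study-level tables."""
    sim = sim or StudySimParams()
    rng = np.random.default_rng(seed)
    image_biases = _image_biases(sim, rng)
    binned, trials, shift_rows = [], [], []
    feat_rows = {"BSV": {}, "IVT": {}}
    cong_rows = []
    priors = []
    for p in cohort:
        out = run_participant(p, sim, image_biases)
        binned.append(out["binned"])
        trials.append(out["trials"])
        for s in out["shifts"]:
            shift_rows.append({
                "pid": s.participant, "task": s.task, "bias_side": s.bias_side,
                "pre": s.pre_value, "post": s.post_value,
                "raw_shift": s.raw_shift, "signed_shift": s.signed_shift})
        for task, vec in out["features"].items():
            feat_rows[task][p.pid] = vec
        cong_rows.append({"pid": p.pid, **{f"congruent_{k.lower()}": v
                                           for k, v in out["congruent"].items()}})
        priors.append({"pid": p.pid, "bias_side": p.bias_side,
                       "final_prior": out["final_prior"]})
    return {
        "binned": pd.concat(binned, ignore_index=True),
        "trials": pd.concat(trials, ignore_index=True),
        "shifts": pd.DataFrame(shift_rows),
        "features_bsv": pd.DataFrame(feat_rows["BSV"]).T.reindex(
            columns=FEATURE_NAMES),
        "features_ivt": pd.DataFrame(feat_rows["IVT"]).T.reindex(
            columns=FEATURE_NAMES),
        "congruent": pd.DataFrame(cong_rows).set_index("pid"),
        "priors": pd.DataFrame(priors),
        "image_biases": image_biases,
    }


def analyze_study(results: dict, fit_glm: bool = True) -> dict:
    """Pre-registered analyses on a simulated study's tables.

    Returns the three one-sided shift t-tests, the alignment test, and
    (optionally) the gamma-GLM learning model.
    """
    shifts = results["shifts"]
    tests = {}
    for task in ("BSV", "IVT", "LT"):
        vals = shifts.loc[shifts["task"] == task, "signed_shift"].dropna()
        if len(vals) >= 2 and vals.std(ddof=1) > 0:
            tests[task] = tstats.one_sample_t_one_sided(vals)
    piv = shifts.pivot_table(index="pid", columns="task",
                             values="raw_shift", aggfunc="first")
    sides = shifts.drop_duplicates("pid").set_index("pid")["bias_side"]

    def _dir(v):
        return np.where(np.isnan(v), None,
                        np.where(v < 0, "left", "right"))

    alignment = None
    if {"BSV", "IVT"} <= set(piv.columns):
        common = piv.dropna(subset=["BSV", "IVT"])
        if len(common):
            alignment = tstats.alignment_test(
                sides.loc[common.index].to_numpy(),
                _dir(common["IVT"].to_numpy()),
                _dir(common["BSV"].to_numpy()))
    out = {"shift_tests": tests, "alignment": alignment}
    if fit_glm:
        binned = results["binned"]
        # gamma support: drop the rare exactly-on-target zero-distance bins
        binned = binned[binned["median_distance_deg"] > 0]
        out["learning_model"] = tstats.fit_learning_model(binned)
    return out
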