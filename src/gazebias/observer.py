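"""Synthetic observers standing in for human participants.

Three generators cover the study's behavioral repertoire:

* a closed-loop search agent for the AVS task, guided *only* by the scalar
  loudness feedback (a run-and-tumble policy with a learnable hemifield
  prior for its first saccade);
* free-viewing gaze generators with a controllable fixation/saccade style
  ("static": long fixations, large steps; "dynamic": short fixations, small
  steps), a controllable horizontal exploration bias, and blink-like missing
  runs;
* a Bernoulli landmark-task responder driven by a logistic psychometric
  function.

Cohort assembly draws per-participant parameters from population
distributions and performs balanced shuffle randomization into left/right
bias groups.  All randomness flows through seeded ``numpy.random.Generator``
objects, so every generator is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .task_engine import (
    FeedbackParams,
    GazeTrace,
    ScreenGeometry,
    StudyConfig,
    TargetSpec,
    volume_from_distance,
)

__all__ = [
    "AgentParams",
    "RunAndTumbleAgent",
    "ViewerStyleParams",
    "STYLE_STATIC",
    "STYLE_DYNAMIC",
    "LandmarkDesign",
    "Participant",
    "PopulationParams",
    "update_hemifield_prior",
    "simulate_avs_search",
    "simulate_free_viewing",
    "simulate_landmark_session",
    "generate_cohort",
    "select_balanced_images",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentParams:
    """Run-and-tumble search agent parameters.

    The agent alternates fixations (during which it reads the loudness) and
    saccades.  If loudness dropped since the previous fixation it keeps its
    heading (plus small angular jitter); otherwise it tumbles to a fresh
    random heading.  ``prior_strength`` scales how strongly the learned
    hemifield prior biases the *first* saccade direction of a trial.
    """

    saccade_amp_mean: float = 6.0
    saccade_amp_sd: float = 2.0
    fixation_dur_mean: float = 0.18
    fixation_dur_sd: float = 0.05
    prior_learning_rate: float = 0.05
    prior_strength: float = 1.0
    tumble_angle_sd: float = 0.4
    noise_sd: float = 0.05
    skill_learning_rate: float = 0.012
    skill_fix_gain: float = 0.35
    skill_tumble_gain: float = 0.5
    skill_init_gain: float = 4.0

    def __post_init__(self) -> None:
        for name in ("saccade_amp_sd", "fixation_dur_sd", "tumble_angle_sd",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.prior_learning_rate <= 1.0:
            raise ValueError("prior_learning_rate must lie in [0, 1]")


@dataclass(frozen=True)
class ViewerStyleParams:
    """Free-viewing style: fixation-duration and gaze-step distributions.

    Fixation durations are lognormal (``fix_dur_log_mu/sigma`` on the log
    scale, seconds); saccade amplitudes are gamma (shape/scale, degrees).
    ``horiz_bias`` is the stationary mean horizontal fixation position;
    ``early_bias`` is an extra horizontal offset applied to fixations that
    begin within the first second (natural early-viewing bias).  Blinks are
    Poisson events inserting invalid runs.
    """

    fix_dur_log_mu: float = math.log(0.35)
    fix_dur_log_sigma: float = 0.45
    sacc_amp_shape: float = 4.0
    sacc_amp_scale: float = 1.2
    horiz_bias: float = 0.0
    early_bias: float = 0.0
    blink_rate_per_min: float = 12.0
    blink_dur_mean_s: float = 0.12
    recenter_gain: float = 0.35
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.fix_dur_log_sigma < 0 or self.sacc_amp_shape <= 0 \
                or self.sacc_amp_scale <= 0:
            raise ValueError("degenerate style distributions")
        if self.blink_rate_per_min < 0 or self.blink_dur_mean_s < 0:
            raise ValueError("blink parameters must be non-negative")
        if not 0 < self.recenter_gain <= 1:
            raise ValueError("recenter_gain must lie in (0, 1]")


#: Long fixations and large gaze steps ("static" viewing style).
STYLE_STATIC = ViewerStyleParams(
    fix_dur_log_mu=math.log(0.55), fix_dur_log_sigma=0.40,
    sacc_amp_shape=5.0, sacc_amp_scale=1.6)

#: Short fixations and small gaze steps ("dynamic" viewing style).
STYLE_DYNAMIC = ViewerStyleParams(
    fix_dur_log_mu=math.log(0.20), fix_dur_log_sigma=0.40,
    sacc_amp_shape=3.0, sacc_amp_scale=0.8)


@dataclass(frozen=True)
class LandmarkDesign:
    """Landmark (pre-bisected line) task design: 11 offsets x 8 reps."""

    span_deg: float = 0.68
    n_offsets: int = 11
    reps: int = 8
    timeout_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_offsets < 3 or self.n_offsets % 2 == 0:
            raise ValueError("need an odd number of offsets (to include 0)")
        if self.reps < 1:
            raise ValueError("reps must be positive")

    @property
    def offsets(self) -> np.ndarray:
        """Equidistant bisection offsets, symmetric about and including 0."""
        return np.linspace(-self.span_deg, self.span_deg, self.n_offsets)

    @property
    def n_trials(self) -> int:
        return self.n_offsets * self.reps


# ---------------------------------------------------------------------------
# hemifield prior
# ---------------------------------------------------------------------------

def update_hemifield_prior(prior: float, outcome_on_biased_side: bool,
                           rate: float) -> float:
    """Exponential-moving-average update of the biased-hemifield probability.

    ``prior' = (1 - rate) * prior + rate * 1{outcome on biased side}``; with
    a stationary target stream the prior converges to the stream's biased-
    side frequency (2/3 under the standard 90-60-30 distribution).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if not 0.0 <= prior <= 1.0:
        raise ValueError("prior must lie in [0, 1]")
    return (1.0 - rate) * prior + rate * (1.0 if outcome_on_biased_side else 0.0)


# ---------------------------------------------------------------------------
# AVS search agent
# ---------------------------------------------------------------------------

class RunAndTumbleAgent:
    """Loudness-gradient search policy with a learnable hemifield prior.

    The policy is deliberately minimal: it never sees target coordinates,
    only the loudness at its own fixation locations.  ``prior`` is the
    agent's current probability that targets appear on the biased side of
    its configuration; :meth:`learn` applies the EMA update after a trial.
    """

    def __init__(self, params: AgentParams | None = None, prior: float = 0.5,
                 geometry: ScreenGeometry | None = None):
        self.params = params or AgentParams()
        self.prior = float(prior)
        self.geometry = geometry or ScreenGeometry()
        self.n_experienced = 0

    @property
    def skill(self) -> float:
        """Task proficiency in [0, 1): saturating in trials experienced.

        Skill shortens fixations (faster loudness sampling) and tightens
        the tumble scatter, producing the across-trial drop in gaze-target
        distance that indexes task learning.
        """
        return 1.0 - math.exp(-self.params.skill_learning_rate
                              * self.n_experienced)

    def learn(self, target: TargetSpec, config: StudyConfig) -> None:
        on_biased = (target.x < 0) == (config.bias_side == "left")
        self.prior = update_hemifield_prior(
            self.prior, on_biased, self.params.prior_learning_rate)
        self.n_experienced += 1

    def first_heading(self, config: StudyConfig, rng: np.random.Generator) -> float:
        """First-saccade direction, biased toward the believed-rich hemifield.

        With probability ``0.5 + prior_strength*(prior - 0.5)`` (clipped to
        [0,1]) the heading points into the biased hemifield, else the other;
        the angle within the chosen half-plane is uniform.
        """
        p = self.params
        p_biased = float(np.clip(0.5 + p.prior_strength * (self.prior - 0.5), 0, 1))
        to_biased = rng.random() < p_biased
        side_left = (config.bias_side == "left") == to_biased
        ang = rng.uniform(-math.pi / 2, math.pi / 2)
        return math.pi - ang if side_left else ang

    def propose_trace(self, target: TargetSpec, config: StudyConfig,
                      rng: np.random.Generator) -> GazeTrace:
        return simulate_avs_search(self, target, config, rng)


def simulate_avs_search(agent: RunAndTumbleAgent, target: TargetSpec,
                        config: StudyConfig,
                        rng: np.random.Generator) -> GazeTrace:
    """Simulate one AVS search as a full candidate gaze trace.

    Fixation/saccade blocks are planned with the run-and-tumble policy until
    the deadline is covered; the task engine later truncates the trace at
    the first terminal event.  Saccades are 3-sample position ramps; every
    sample gets isotropic Gaussian jitter of ``noise_sd``.
    """
    p = agent.params
    fs = config.fs
    half_w, half_h = agent.geometry.half_extent_deg()
    feedback = config.feedback
    skill = agent.skill
    fix_mean = p.fixation_dur_mean * (1.0 - p.skill_fix_gain * skill)
    tumble_sd = p.tumble_angle_sd * (1.0 - p.skill_tumble_gain * skill)

    pos = np.zeros(2)
    heading = agent.first_heading(config, rng)
    last_loud = volume_from_distance(
        math.hypot(pos[0] - target.x, pos[1] - target.y), feedback)
    n_total = int(round(config.deadline_s * fs)) + 1

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    n_done = 0
    first = True
    while n_done < n_total:
        dur = max(2.0 / fs, rng.normal(fix_mean, p.fixation_dur_sd))
        if first:
            # search-initiation latency: unskilled observers hold the
            # central fixation longer before the first saccade
            dur *= 1.0 + p.skill_init_gain * (1.0 - skill)
        n_fix = min(max(2, int(round(dur * fs))), n_total - n_done)
        xs.append(np.full(n_fix, pos[0]))
        ys.append(np.full(n_fix, pos[1]))
        n_done += n_fix
        if n_done >= n_total:
            break
        d = math.hypot(pos[0] - target.x, pos[1] - target.y)
        loud = volume_from_distance(d, feedback)
        if loud <= 0.0:
            # silence: on target — hold position for the rest of the trial
            n_rest = n_total - n_done
            xs.append(np.full(n_rest, pos[0]))
            ys.append(np.full(n_rest, pos[1]))
            n_done = n_total
            break
        if first:
            first = False  # heading came from the hemifield prior
        elif loud >= 0.999 and math.hypot(pos[0], pos[1]) > 1.0:
            # saturated feedback carries no gradient: fall back toward the
            # screen center (uses only the agent's own gaze position)
            heading = math.atan2(-pos[1], -pos[0]) \
                + rng.normal(0.0, tumble_sd)
        elif loud < last_loud - 1e-12:
            heading += rng.normal(0.0, tumble_sd * 0.25)
        else:
            # tumble: mostly reverse course (the sound got louder), with
            # angular scatter so the policy does not orbit the target
            heading += math.pi + rng.normal(0.0, 2.0 * tumble_sd)
        last_loud = loud
        # step size shrinks with falling loudness: fine search near target
        amp = max(0.3, rng.normal(p.saccade_amp_mean, p.saccade_amp_sd)
                  * (0.25 + 0.75 * loud))
        new = pos + amp * np.array([math.cos(heading), math.sin(heading)])
        new[0] = np.clip(new[0], -half_w, half_w)
        new[1] = np.clip(new[1], -half_h, half_h)
        n_sacc = min(3, n_total - n_done)
        frac = np.arange(1, n_sacc + 1) / (n_sacc + 1)
        xs.append(pos[0] + frac * (new[0] - pos[0]))
        ys.append(pos[1] + frac * (new[1] - pos[1]))
        n_done += n_sacc
        pos = new

    x = np.concatenate(xs)[:n_total]
    y = np.concatenate(ys)[:n_total]
    if p.noise_sd > 0:
        x = x + rng.normal(0.0, p.noise_sd, x.size)
        y = y + rng.normal(0.0, p.noise_sd, y.size)
    t = np.arange(n_total) / fs
    return GazeTrace(t, x, y, fs=fs, geometry=agent.geometry)


# ---------------------------------------------------------------------------
# free viewing
# ---------------------------------------------------------------------------

def simulate_free_viewing(style: ViewerStyleParams, duration_s: float,
                          fs: float = 600.0, rng: np.random.Generator = None,
                          geometry: ScreenGeometry | None = None) -> GazeTrace:
    """Generate a free-viewing gaze trace with the given style.

    Fixation centroids follow a mean-reverting random walk: each step adds
    a gamma-amplitude displacement in a uniform direction plus a pull of
    ``recenter_gain`` toward the anchor ``(horiz_bias, 0)``, so the
    stationary mean horizontal fixation position equals ``horiz_bias``.
    Fixations that begin within the first second get ``early_bias`` added
    to their horizontal position.  Saccades are 3-sample ramps; blinks are
    inserted as invalid runs at a Poisson rate.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng()
    geometry = geometry or ScreenGeometry()
    half_w, half_h = geometry.half_extent_deg()
    n_total = int(round(duration_s * fs))

    anchor = np.array([style.horiz_bias, 0.0])
    pos = anchor + rng.normal(0.0, 1.0, 2)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    n_done = 0
    while n_done < n_total:
        onset_s = n_done / fs
        dur = rng.lognormal(style.fix_dur_log_mu, style.fix_dur_log_sigma)
        n_fix = min(max(3, int(round(dur * fs))), n_total - n_done)
        fx = pos[0] + (style.early_bias if onset_s < 1.0 else 0.0)
        xs.append(np.full(n_fix, np.clip(fx, -half_w, half_w)))
        ys.append(np.full(n_fix, pos[1]))
        n_done += n_fix
        if n_done >= n_total:
            break
        amp = rng.gamma(style.sacc_amp_shape, style.sacc_amp_scale)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        step = amp * np.array([math.cos(ang), math.sin(ang)])
        new = pos + step + style.recenter_gain * (anchor - pos)
        new[0] = np.clip(new[0], -half_w, half_w)
        new[1] = np.clip(new[1], -half_h, half_h)
        n_sacc = min(3, n_total - n_done)
        frac = np.arange(1, n_sacc + 1) / (n_sacc + 1)
        xs.append(xs[-1][-1] + frac * (new[0] - xs[-1][-1]))
        ys.append(pos[1] + frac * (new[1] - pos[1]))
        n_done += n_sacc
        pos = new

    x = np.concatenate(xs)[:n_total]
    y = np.concatenate(ys)[:n_total]
    if style.noise_sd > 0:
        x = x + rng.normal(0.0, style.noise_sd, x.size)
        y = y + rng.normal(0.0, style.noise_sd, y.size)
    valid = np.ones(n_total, dtype=bool)
    n_blinks = rng.poisson(style.blink_rate_per_min * duration_s / 60.0)
    for _ in range(n_blinks):
        b_dur = rng.exponential(style.blink_dur_mean_s)
        b_n = max(1, int(round(b_dur * fs)))
        b_start = rng.integers(0, max(1, n_total - b_n))
        valid[b_start:b_start + b_n] = False
    t = np.arange(n_total) / fs
    return GazeTrace(t, x, y, valid, fs=fs, geometry=geometry)


# ---------------------------------------------------------------------------
# landmark task
# ---------------------------------------------------------------------------

def simulate_landmark_session(pse: float, slope: float,
                              design: LandmarkDesign | None = None,
                              rng: np.random.Generator = None) -> pd.DataFrame:
    """Simulate one landmark session: Bernoulli "right longer" responses.

    For bisection offset ``o`` (positive = transector right of veridical
    center, so the *left* segment is longer), the probability of responding
    "right longer" is ``logistic(slope * (o - pse))``.  Returns a tidy
    DataFrame with columns ``offset_deg`` and ``resp_right``.
    """
    if slope <= 0:
        raise ValueError("psychometric slope must be positive")
    design = design or LandmarkDesign()
    if rng is None:
        rng = np.random.default_rng()
    offsets = np.repeat(design.offsets, design.reps)
    p_right = expit(slope * (offsets - pse))
    resp = rng.random(offsets.size) < p_right
    order = rng.permutation(offsets.size)
    return pd.DataFrame({"offset_deg": offsets[order],
                         "resp_right": resp[order].astype(int)})


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Population distributions for per-participant heterogeneity.

    Natural horizontal biases are normal with a slight leftward mean
    (pseudoneglect); fixation-duration medians are lognormal across
    participants; the learned-prior transfer gain converts the trained
    hemifield prior into a post-training free-viewing bias shift (deg).
    A prior of 2/3 (the 2:1 target distribution) with the default gain of
    1.5 deg yields a mean induced shift of 0.5 deg.
    """

    horiz_bias_mean: float = -0.3
    horiz_bias_sd: float = 1.0
    early_bias_sd: float = 0.8
    fix_dur_med_logmu: float = math.log(0.35)
    fix_dur_med_logsd: float = 0.35
    amp_scale_logmu: float = math.log(1.2)
    amp_scale_logsd: float = 0.25
    pse_sd: float = 0.15
    lt_slope_mean: float = 8.0
    lt_slope_sd: float = 2.0
    transfer_gain: float = 1.5
    transfer_gain_sd: float = 0.9
    lt_transfer_gain: float = 0.0


@dataclass
class Participant:
    """One synthetic participant: group, seeds, and true parameters."""

    pid: int
    bias_side: str
    seed: int
    agent: AgentParams
    style: ViewerStyleParams
    pse_pre: float
    lt_slope: float
    transfer_gain: float
    lt_transfer_gain: float

    def to_row(self) -> dict:
        row = {"pid": self.pid, "bias_side": self.bias_side, "seed": self.seed,
               "pse_pre": self.pse_pre, "lt_slope": self.lt_slope,
               "transfer_gain": self.transfer_gain,
               "lt_transfer_gain": self.lt_transfer_gain}
        row.update({f"agent_{k}": v for k, v in vars(self.agent).items()})
        row.update({f"style_{k}": v for k, v in vars(self.style).items()})
        return row


def generate_cohort(n: int, rng: np.random.Generator,
                    population: PopulationParams | None = None,
                    agent_base: AgentParams | None = None) -> list[Participant]:
    """Assemble a cohort with balanced shuffle randomization.

    Exactly ``n//2`` participants go to each bias group (a warning-free
    extra participant lands in one group when ``n`` is odd); per-participant
    style, agent and landmark parameters are drawn from ``population``.
    The same ``rng`` state always yields the identical cohort.
    """
    if n < 1:
        raise ValueError("cohort size must be positive")
    pop = population or PopulationParams()
    agent_base = agent_base or AgentParams()
    sides = ["left", "right"] * (n // 2)
    if n % 2:
        sides.append("left" if rng.random() < 0.5 else "right")
    sides = [sides[i] for i in rng.permutation(n)]
    cohort = []
    for pid, side in enumerate(sides, start=1):
        style = ViewerStyleParams(
            fix_dur_log_mu=rng.normal(pop.fix_dur_med_logmu, pop.fix_dur_med_logsd),
            sacc_amp_scale=float(np.exp(
                rng.normal(pop.amp_scale_logmu, pop.amp_scale_logsd))),
            horiz_bias=rng.normal(pop.horiz_bias_mean, pop.horiz_bias_sd),
            early_bias=rng.normal(0.0, pop.early_bias_sd),
        )
        cohort.append(Participant(
            pid=pid,
            bias_side=side,
            seed=int(rng.integers(0, 2**31 - 1)),
            agent=agent_base,
            style=style,
            pse_pre=rng.normal(0.0, pop.pse_sd),
            lt_slope=max(2.0, rng.normal(pop.lt_slope_mean, pop.lt_slope_sd)),
            transfer_gain=max(0.0, rng.normal(pop.transfer_gain,
                                              pop.transfer_gain_sd)),
            lt_transfer_gain=pop.lt_transfer_gain,
        ))
    return cohort


def cohort_manifest(cohort: list[Participant]) -> pd.DataFrame:
    """Tidy manifest of a cohort (group, seeds, true parameters)."""
    return pd.DataFrame([p.to_row() for p in cohort])


# ---------------------------------------------------------------------------
# balanced image selection
# ---------------------------------------------------------------------------

def select_balanced_images(candidate_bias_values, k: int) -> np.ndarray:
    """Pick ``k`` image indices whose mean exploration bias is closest to 0.

    Greedy seeding (repeatedly add the candidate bringing the running mean
    closest to zero) followed by single-swap exchange until no swap reduces
    ``|mean|`` — a local optimum under one-element exchanges.
    """
    vals = np.asarray(candidate_bias_values, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > vals.size:
        raise ValueError("k exceeds candidate count")
    chosen: list[int] = []
    remaining = list(range(vals.size))
    total = 0.0
    for _ in range(k):
        best = min(remaining, key=lambda i: abs(total + vals[i]))
        chosen.append(best)
        remaining.remove(best)
        total += vals[best]
    improved = True
    while improved:
        improved = False
        for ci, c in enumerate(chosen):
            for ri, r in enumerate(remaining):
                new_total = total - vals[c] + vals[r]
                if abs(new_total) < abs(total) - 1e-15:
                    chosen[ci], remaining[ri] = r, c
                    total = new_total
                    improved = True
    return np.sort(np.asarray(chosen))
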