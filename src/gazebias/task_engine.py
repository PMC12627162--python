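"""Deterministic core of the closed-loop audio-visual search (AVS) paradigm.

The AVS task asks an observer to find an *invisible* circular target on a
screen using only a continuous auditory signal: tone loudness encodes the
Euclidean distance between the current gaze position and the target center
(silence = on target).  Targets are drawn from a fixed 6 x 3 grid and their
left/right frequency is biased for one hemifield, which is the statistical
regularity the observer can learn.

This module provides the screen geometry, the target grid and biased target
sequences, the distance-to-loudness mapping, and the per-sample trial state
machine (dwell-to-succeed / deadline-to-fail).  Everything here is
deterministic given a seeded ``numpy.random.Generator``.

Coordinates are screen-centered degrees of visual angle, +x rightward,
+y upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ScreenGeometry",
    "GazeSample",
    "GazeTrace",
    "TargetSpec",
    "FeedbackParams",
    "StudyConfig",
    "TrialRecord",
    "TrialState",
    "TrialStatus",
    "px_to_deg",
    "build_target_grid",
    "sample_target_sequence",
    "volume_from_distance",
    "gaze_target_distance",
    "step_trial",
    "run_trial",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenGeometry:
    """Physical monitor description used for pixel <-> degree conversion.

    Defaults describe a 23.8-inch 1920x1080 monitor viewed from 57 cm,
    a standard psychophysics arrangement (at 57 cm, 1 cm on screen subtends
    very nearly 1 degree).
    """

    width_px: int = 1920
    height_px: int = 1080
    diag_inches: float = 23.8
    view_dist_cm: float = 57.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("screen resolution must be positive")
        if self.diag_inches <= 0:
            raise ValueError("diagonal must be positive")
        if self.view_dist_cm <= 0:
            raise ValueError("viewing distance must be positive")

    @property
    def cm_per_px(self) -> float:
        diag_px = math.hypot(self.width_px, self.height_px)
        return self.diag_inches * 2.54 / diag_px

    @property
    def width_deg(self) -> float:
        return px_to_deg(self.width_px, self)

    @property
    def height_deg(self) -> float:
        return px_to_deg(self.height_px, self)

    def half_extent_deg(self) -> tuple[float, float]:
        """Half width/height in degrees; gaze is clamped to this box."""
        return self.width_deg / 2.0, self.height_deg / 2.0


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: time (s from trial onset), position (deg), validity."""

    t: float
    x: float
    y: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("sample time must be non-negative")


class GazeTrace:
    """A uniformly sampled gaze stream backed by numpy arrays.

    Parameters
    ----------
    t, x, y : arrays of equal length
        Seconds from onset and screen-centered degrees.
    valid : bool array
        False for blink-like missing samples; the x/y values of invalid
        samples are not meaningful.
    fs : float
        Nominal sampling rate in Hz.
    geometry : ScreenGeometry, optional
    """

    def __init__(self, t, x, y, valid=None, fs: float = 600.0,
                 geometry: ScreenGeometry | None = None):
        self.t = np.asarray(t, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if valid is None:
            valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(valid, dtype=bool)
        if not (self.t.shape == self.x.shape == self.y.shape == self.valid.shape):
            raise ValueError("t, x, y, valid must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.fs = float(fs)
        self.geometry = geometry

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def samples(self):
        """Iterate as :class:`GazeSample` objects (reference API)."""
        for ti, xi, yi, vi in zip(self.t, self.x, self.y, self.valid):
            yield GazeSample(float(ti), float(xi), float(yi), bool(vi))

    def mirrored_x(self) -> "GazeTrace":
        """The trace reflected about the vertical midline (x -> -x)."""
        return GazeTrace(self.t.copy(), -self.x, self.y.copy(),
                         self.valid.copy(), self.fs, self.geometry)

    def copy(self) -> "GazeTrace":
        return GazeTrace(self.t.copy(), self.x.copy(), self.y.copy(),
                         self.valid.copy(), self.fs, self.geometry)


@dataclass(frozen=True)
class TargetSpec:
    """An invisible circular search target."""

    x: float
    y: float
    radius: float = 4.1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("target radius must be positive")

    def mirrored_x(self) -> "TargetSpec":
        return TargetSpec(-self.x, self.y, self.radius)


@dataclass(frozen=True)
class FeedbackParams:
    """Distance-to-loudness mapping parameters.

    Loudness rises exponentially from silence at the target edge to full
    volume at ``d_max`` (17.8 deg), compensating for roughly logarithmic
    loudness perception.  ``tone_hz`` is carried as metadata only; no audio
    is synthesized.
    """

    d_max: float = 17.8
    tone_hz: float = 440.0
    curve_base: float = math.e
    silence_radius: float = 4.1

    def __post_init__(self) -> None:
        if not self.d_max > self.silence_radius >= 0:
            raise ValueError("require d_max > silence_radius >= 0")
        if self.curve_base <= 1:
            raise ValueError("curve_base must exceed 1")


@dataclass(frozen=True)
class StudyConfig:
    """One participant's AVS training configuration.

    ``zone_counts`` gives trial counts over the three left-to-right
    column-pair zones of the 6x3 grid; the default (90, 60, 30) for a
    left-bias participant puts two thirds of targets left of midline
    (mirrored for right bias).
    """

    bias_side: str = "left"
    n_trials: int = 180
    zone_counts: tuple[int, int, int] | None = None
    dwell_s: float = 0.5
    deadline_s: float = 10.0
    start_fix_s: float = 0.5
    fs: float = 600.0
    seed: int = 0
    target_radius: float = 4.1
    feedback: FeedbackParams = field(default_factory=FeedbackParams)

    def __post_init__(self) -> None:
        if self.bias_side not in ("left", "right"):
            raise ValueError("bias_side must be 'left' or 'right'")
        counts = self.zone_counts
        if counts is None:
            base = _default_zone_counts(self.n_trials)
            counts = base if self.bias_side == "left" else base[::-1]
            object.__setattr__(self, "zone_counts", counts)
        if len(self.zone_counts) != 3 or any(c < 0 for c in self.zone_counts):
            raise ValueError("zone_counts must be three non-negative ints")
        if sum(self.zone_counts) != self.n_trials:
            raise ValueError("zone_counts must sum to n_trials")
        for name in ("dwell_s", "deadline_s", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def mirrored(self) -> "StudyConfig":
        """Exact left/right reflection of this configuration."""
        other = "right" if self.bias_side == "left" else "left"
        return replace(self, bias_side=other, zone_counts=self.zone_counts[::-1])


def _default_zone_counts(n_trials: int) -> tuple[int, int, int]:
    # 3:2:1 biased-to-unbiased gradient; (90, 60, 30) at the standard 180.
    base = n_trials // 6
    counts = [3 * base, 2 * base, base]
    counts[0] += n_trials - sum(counts)
    return tuple(counts)


class TrialStatus(Enum):
    RUNNING = "running"
    SUCCESS = "success"
    TIMEOUT = "timeout"


@dataclass
class TrialState:
    """Mutable per-trial state advanced by :func:`step_trial`."""

    target: TargetSpec
    config: StudyConfig
    status: TrialStatus = TrialStatus.RUNNING
    t: float = 0.0
    dwell_count: int = 0

    @property
    def dwell_needed(self) -> int:
        return int(round(self.config.dwell_s * self.config.fs))


@dataclass
class TrialRecord:
    """Everything recorded for one completed AVS trial."""

    target: TargetSpec
    trace: GazeTrace
    volume_series: np.ndarray
    found: bool
    search_time_s: float
    trial_number: int
    bias_label: str  # "biased" | "unbiased"

    def __post_init__(self) -> None:
        if self.bias_label not in ("biased", "unbiased"):
            raise ValueError("bias_label must be 'biased' or 'unbiased'")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def px_to_deg(px: float, geometry: ScreenGeometry) -> float:
    """Convert an on-screen length in pixels to degrees of visual angle.

    Uses the exact formula ``2*atan((size/2)/view_dist)`` rather than the
    small-angle approximation, so wide extents are not overestimated.
    """
    if geometry.view_dist_cm <= 0:
        raise ValueError("viewing distance must be positive")
    size_cm = px * geometry.cm_per_px
    return math.degrees(2.0 * math.atan2(size_cm / 2.0, geometry.view_dist_cm))


def build_target_grid(
    h_ecc: Sequence[float] = (3.8, 11.4, 19.9),
    v_ecc: Sequence[float] = (0.0, 7.5),
    radius: float = 4.1,
) -> list[TargetSpec]:
    """Build the grid of unique target positions.

    Horizontal eccentricities are mirrored about the midline (each value
    yields +e and -e); vertical eccentricities are mirrored too, with 0
    contributing a single row.  The defaults give the 6 x 3 = 18 position
    grid: x in {+-3.8, +-11.4, +-19.9}, y in {-7.5, 0, +7.5}.
    """
    if any(e <= 0 for e in h_ecc):
        raise ValueError("horizontal eccentricities must be positive")
    if any(e < 0 for e in v_ecc):
        raise ValueError("vertical eccentricities must be non-negative")
    xs = sorted(set([-e for e in h_ecc] + [e for e in h_ecc]))
    ys = sorted(set([-e for e in v_ecc] + [e for e in v_ecc]))
    coords = [(x, y) for x in xs for y in ys]
    if len(set(coords)) != len(coords):  # pragma: no cover - sets dedupe above
        raise ValueError("duplicate target coordinates")
    if len(xs) != 2 * len(h_ecc):
        raise ValueError("duplicate horizontal eccentricities")
    return [TargetSpec(x, y, radius) for x, y in coords]


def zone_of_target(target: TargetSpec, grid: Sequence[TargetSpec]) -> int:
    """Zone index 0/1/2 (left/center/right column pair) of a grid target."""
    xs = sorted({g.x for g in grid})
    if len(xs) % 2 != 0:
        raise ValueError("grid must have an even number of columns")
    per_zone = len(xs) // 3
    col = xs.index(target.x)
    return col // per_zone


def sample_target_sequence(
    config: StudyConfig,
    rng: np.random.Generator,
    grid: Sequence[TargetSpec] | None = None,
) -> list[TargetSpec]:
    """Draw the randomized biased target sequence for one participant.

    Trials are allocated to the three column-pair zones according to
    ``config.zone_counts`` (left-to-right).  Within a zone the count is
    spread as evenly as possible over its 6 grid positions, any remainder
    going to the lowest position indices; the full list is then shuffled
    with ``rng`` so only the order (not the multiset) depends on the seed.
    """
    if grid is None:
        grid = build_target_grid(radius=config.target_radius)
    zones: dict[int, list[TargetSpec]] = {0: [], 1: [], 2: []}
    for tgt in grid:
        zones[zone_of_target(tgt, grid)].append(tgt)
    sequence: list[TargetSpec] = []
    for z, count in enumerate(config.zone_counts):
        positions = sorted(zones[z], key=lambda s: (s.x, s.y))
        n_pos = len(positions)
        base, rem = divmod(count, n_pos)
        for i, pos in enumerate(positions):
            sequence.extend([pos] * (base + (1 if i < rem else 0)))
    perm = rng.permutation(len(sequence))
    return [sequence[i] for i in perm]


def volume_from_distance(d, params: FeedbackParams | None = None):
    """Map gaze-target distance (deg) to loudness in [0, 1].

    Silent for ``d <= silence_radius`` (gaze on target); full volume for
    ``d >= d_max``.  In between, the normalized exponential

        v = (B**u - 1) / (B - 1),   u = (d - r) / (d_max - r)

    with base ``B = curve_base`` — continuous, strictly increasing and
    convex, so loudness changes are compressed near the target.
    Accepts scalars or arrays.
    """
    if params is None:
        params = FeedbackParams()
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be non-negative")
    u = (d_arr - params.silence_radius) / (params.d_max - params.silence_radius)
    u = np.clip(u, 0.0, 1.0)
    v = np.expm1(u * math.log(params.curve_base)) / (params.curve_base - 1.0)
    v = np.clip(v, 0.0, 1.0)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(v)
    return v


def gaze_target_distance(sample: GazeSample, target: TargetSpec) -> float:
    """Euclidean distance (deg) from a valid gaze sample to the target center.

    Returns NaN for invalid (blink) samples.
    """
    if not sample.valid:
        return float("nan")
    return math.hypot(sample.x - target.x, sample.y - target.y)


def step_trial(state: TrialState, sample: GazeSample,
               params: FeedbackParams | None = None) -> tuple[TrialState, float]:
    """Advance the trial state machine by one gaze sample.

    The dwell accumulator counts consecutive in-radius samples and resets
    to zero whenever gaze leaves the target disk; the trial succeeds once
    the accumulated continuous dwell reaches ``dwell_s`` and times out when
    the sample clock reaches ``deadline_s``.  Returns the updated state and
    the loudness for this sample.
    """
    if state.status is not TrialStatus.RUNNING:
        raise RuntimeError("trial already terminated; no further samples accepted")
    if params is None:
        params = state.config.feedback
    d = gaze_target_distance(sample, state.target)
    loud = float("nan") if math.isnan(d) else volume_from_distance(d, params)
    state.t = sample.t
    if not math.isnan(d) and d <= state.target.radius:
        state.dwell_count += 1
    else:
        state.dwell_count = 0
    if state.dwell_count >= state.dwell_needed:
        state.status = TrialStatus.SUCCESS
    elif sample.t >= state.config.deadline_s:
        state.status = TrialStatus.TIMEOUT
    return state, loud


def bias_label_for(target: TargetSpec, bias_side: str) -> str:
    """Whether a target lies in the participant's target-rich hemifield."""
    side = "left" if target.x < 0 else "right"
    return "biased" if side == bias_side else "unbiased"


def _evaluate_trace(trace: GazeTrace, target: TargetSpec,
                    config: StudyConfig) -> tuple[int, bool]:
    """Vectorized terminal-sample search: index of last live sample, found.

    Equivalent to feeding the trace through :func:`step_trial` sample by
    sample (pinned by tests).
    """
    d = np.hypot(trace.x - target.x, trace.y - target.y)
    d[~trace.valid] = np.inf
    inside = d <= target.radius
    need = int(round(config.dwell_s * config.fs))
    # run[i] = length of the consecutive in-radius streak ending at i
    idx = np.arange(len(inside))
    last_out = np.maximum.accumulate(np.where(~inside, idx, -1))
    run = idx - last_out
    run[~inside] = 0
    success_idx = np.nonzero(run >= need)[0]
    timeout_idx = np.nonzero(trace.t >= config.deadline_s)[0]
    s = success_idx[0] if success_idx.size else np.inf
    to = timeout_idx[0] if timeout_idx.size else np.inf
    end = min(s, to, len(inside) - 1)
    found = s <= to and np.isfinite(s)
    return int(end), bool(found)


def run_trial(
    agent,
    target: TargetSpec,
    config: StudyConfig,
    rng: np.random.Generator,
    trial_number: int = 1,
    fast: bool = True,
) -> TrialRecord:
    """Run one closed-loop AVS trial with an agent policy.

    The agent proposes a full candidate gaze trace (its policy may only use
    the scalar loudness feedback, never target coordinates); the engine then
    truncates it at the first terminal event (continuous dwell reached, or
    deadline).  ``fast=False`` drives :func:`step_trial` sample by sample
    instead of the vectorized evaluator — same result, reference path.
    """
    trace = agent.propose_trace(target, config, rng)
    if not np.all(np.isfinite(trace.x[trace.valid])) or not np.all(
            np.isfinite(trace.y[trace.valid])):
        raise ValueError("agent emitted non-finite gaze coordinates")
    if fast:
        end, found = _evaluate_trace(trace, target, config)
    else:
        state = TrialState(target=target, config=config)
        end = len(trace) - 1
        found = False
        for i, sample in enumerate(trace.samples()):
            state, _ = step_trial(state, sample)
            if state.status is not TrialStatus.RUNNING:
                end = i
                found = state.status is TrialStatus.SUCCESS
                break
    sl = slice(0, end + 1)
    live = GazeTrace(trace.t[sl], trace.x[sl], trace.y[sl], trace.valid[sl],
                     trace.fs, trace.geometry)
    d = np.hypot(live.x - target.x, live.y - target.y)
    vol = volume_from_distance(d, config.feedback)
    vol = np.where(live.valid, vol, np.nan)
    search_time = float(live.t[-1]) + 1.0 / config.fs if len(live) else 0.0
    return TrialRecord(
        target=target,
        trace=live,
        volume_series=np.asarray(vol, dtype=float),
        found=found,
        search_time_s=min(search_time, config.deadline_s),
        trial_number=trial_number,
        bias_label=bias_label_for(target, config.bias_side),
    )
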