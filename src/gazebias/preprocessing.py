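"""Gaze cleaning and oculomotor event detection.

Pipeline: (1) judge trial validity from the longest contiguous missing run
(*before* any interpolation), (2) fill interior blink gaps by linear
interpolation, (3) detect saccades with the Engbert–Kliegl velocity-threshold
algorithm (median-based per-axis thresholds combined in an elliptic
criterion), (4) refine the complementary fixations with Hooge-style
merge-then-discard selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_engine import GazeTrace

__all__ = [
    "DetectorParams",
    "EventSegmentation",
    "interpolate_gaps",
    "is_valid_trial",
    "compute_velocity",
    "detect_saccades_ek",
    "refine_fixations_hooge",
    "segment_trace",
]

FIX_COLUMNS = ["onset_s", "offset_s", "x", "y", "duration_s"]
SACC_COLUMNS = ["onset_s", "offset_s", "amplitude_deg", "peak_velocity_deg_s"]


@dataclass(frozen=True)
class DetectorParams:
    """Velocity-threshold detector parameters.

    ``lam`` multiplies the per-axis median-based velocity spread to give the
    threshold (6 is the standard published choice); candidate saccades
    shorter than ``min_sacc_dur_s`` are dropped.  The refinement pass merges
    fixations closer than ``merge_gap_s`` in time and ``merge_dist_deg`` in
    space, then discards fixations shorter than ``min_fix_dur_s``.
    """

    lam: float = 6.0
    min_sacc_dur_s: float = 0.012
    smooth_window: int = 5
    merge_gap_s: float = 0.075
    merge_dist_deg: float = 0.5
    min_fix_dur_s: float = 0.060

    def __post_init__(self) -> None:
        if self.smooth_window not in (3, 5):
            raise ValueError("smooth_window must be 3 or 5 (odd kernel)")
        for name in ("lam", "min_sacc_dur_s", "merge_gap_s",
                     "merge_dist_deg", "min_fix_dur_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EventSegmentation:
    """Alternating fixations and saccades derived from one trace.

    ``fixations``: DataFrame with onset_s, offset_s, x, y (centroid),
    duration_s.  ``saccades``: DataFrame with onset_s, offset_s,
    amplitude_deg, peak_velocity_deg_s.  Events are time-ordered and
    non-overlapping; together with invalid time they tile the trace.
    """

    fixations: pd.DataFrame
    saccades: pd.DataFrame
    trace_duration_s: float = 0.0
    invalid_s: float = 0.0

    def __post_init__(self) -> None:
        for frame, cols in ((self.fixations, FIX_COLUMNS),
                            (self.saccades, SACC_COLUMNS)):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"missing event columns: {sorted(missing)}")

    def mirrored_x(self) -> "EventSegmentation":
        fix = self.fixations.copy()
        fix["x"] = -fix["x"]
        return EventSegmentation(fix, self.saccades.copy(),
                                 self.trace_duration_s, self.invalid_s)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def interpolate_gaps(trace: GazeTrace) -> GazeTrace:
    """Fill interior invalid runs by linear interpolation against time.

    Valid samples are untouched; interpolated samples are marked valid.
    Leading/trailing gaps (no flanking valid sample on one side) stay
    invalid.  An all-invalid trace is an error.
    """
    valid = trace.valid
    if not valid.any():
        raise ValueError("cannot interpolate an all-invalid trace")
    if valid.all():
        return trace.copy()
    t, x, y = trace.t, trace.x.copy(), trace.y.copy()
    first, last = np.nonzero(valid)[0][[0, -1]]
    interior = ~valid
    interior[:first] = False
    interior[last + 1:] = False
    x[interior] = np.interp(t[interior], t[valid], trace.x[valid])
    y[interior] = np.interp(t[interior], t[valid], trace.y[valid])
    new_valid = valid | interior
    return GazeTrace(t.copy(), x, y, new_valid, trace.fs, trace.geometry)


def longest_invalid_run(valid: np.ndarray) -> int:
    """Length of the longest run of consecutive invalid samples."""
    if valid.all():
        return 0
    inv = ~valid
    idx = np.arange(inv.size)
    last_valid = np.maximum.accumulate(np.where(valid, idx, -1))
    run = idx - last_valid
    run[valid] = 0
    return int(run.max())


def is_valid_trial(trace: GazeTrace,
                   max_contig_missing_frac: float = 0.4) -> bool:
    """Reliability rule: reject a trial whose longest *contiguous* missing
    run exceeds the given fraction of its samples (strict >); judged before
    interpolation.  Scattered missing data of any total amount passes as
    long as no single run is that long.
    """
    if len(trace) == 0:
        return False
    return longest_invalid_run(trace.valid) <= max_contig_missing_frac * len(trace)


# ---------------------------------------------------------------------------
# velocity and saccade detection
# ---------------------------------------------------------------------------

def compute_velocity(trace: GazeTrace, smooth_window: int = 5) -> np.ndarray:
    """Per-sample velocity (deg/s), shape (n, 2), via the smoothed
    centered-difference kernel

        v[i] = (x[i+2] + x[i+1] - x[i-1] - x[i-2]) * fs / 6

    (window 3 uses the plain centered difference).  Endpoints fall back to
    shortened one-sided differences.  Requires an interpolated, uniformly
    sampled trace.
    """
    n = len(trace)
    if n < smooth_window:
        raise ValueError("trace shorter than the velocity window")
    fs = trace.fs
    v = np.empty((n, 2))
    for j, pos in enumerate((trace.x, trace.y)):
        if smooth_window == 5:
            core = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) * fs / 6.0
            v[2:-2, j] = core
            v[1, j] = (pos[2] - pos[0]) * fs / 2.0
            v[-2, j] = (pos[-1] - pos[-3]) * fs / 2.0
        else:
            v[1:-1, j] = (pos[2:] - pos[:-2]) * fs / 2.0
        v[0, j] = (pos[1] - pos[0]) * fs
        v[-1, j] = (pos[-1] - pos[-2]) * fs
    return v


def _ek_thresholds(v: np.ndarray, lam: float) -> np.ndarray:
    """Median-based velocity spread per axis, floored away from zero."""
    med = np.median(v, axis=0)
    msd = np.sqrt(np.maximum(np.median(v ** 2, axis=0) - med ** 2, 0.0))
    floor = 1e-9 + 1e-9 * np.abs(med)
    return lam * np.maximum(msd, floor)


def detect_saccades_ek(trace: GazeTrace,
                       params: DetectorParams | None = None,
                       refine: bool = False) -> EventSegmentation:
    """Engbert–Kliegl velocity-threshold saccade detection.

    A sample is saccadic when ``(vx/ηx)² + (vy/ηy)² > 1`` with per-axis
    thresholds ``η = λ·σ`` and σ the median-based velocity spread.  Runs of
    saccadic samples at least ``min_sacc_dur_s`` long become saccades;
    the complementary intervals become fixations (centroid = mean position).
    Only valid samples participate; invalid runs break events.  With
    ``refine=True`` the Hooge pass is applied to the fixations.
    """
    params = params or DetectorParams()
    v = compute_velocity(trace, params.smooth_window)
    eta = _ek_thresholds(v[trace.valid], params.lam)
    crit = (v[:, 0] / eta[0]) ** 2 + (v[:, 1] / eta[1]) ** 2
    saccadic = (crit > 1.0) & trace.valid
    fixational = (~saccadic) & trace.valid

    fs = trace.fs
    min_sacc_n = max(1, int(round(params.min_sacc_dur_s * fs)))
    speed = np.hypot(v[:, 0], v[:, 1])

    sacc_rows = []
    for start, stop in _runs(saccadic):
        if stop - start < min_sacc_n:
            fixational[start:stop] = True  # too short: treat as fixational
            continue
        amp = float(np.hypot(trace.x[stop - 1] - trace.x[start],
                             trace.y[stop - 1] - trace.y[start]))
        sacc_rows.append((trace.t[start], trace.t[stop - 1] + 1.0 / fs, amp,
                          float(speed[start:stop].max())))
    fix_rows = []
    for start, stop in _runs(fixational):
        dur = (stop - start) / fs
        fix_rows.append((trace.t[start], trace.t[stop - 1] + 1.0 / fs,
                         float(trace.x[start:stop].mean()),
                         float(trace.y[start:stop].mean()), dur))

    seg = EventSegmentation(
        fixations=pd.DataFrame(fix_rows, columns=FIX_COLUMNS),
        saccades=pd.DataFrame(sacc_rows, columns=SACC_COLUMNS),
        trace_duration_s=trace.duration_s,
        invalid_s=float((~trace.valid).sum()) / fs,
    )
    return refine_fixations_hooge(seg, params) if refine else seg


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs in a boolean array."""
    if mask.size == 0:
        return
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        yield int(start), int(stop)


# ---------------------------------------------------------------------------
# fixation refinement
# ---------------------------------------------------------------------------

def refine_fixations_hooge(seg: EventSegmentation,
                           params: DetectorParams | None = None
                           ) -> EventSegmentation:
    """Hooge-style fixation selection: merge, then discard.

    Consecutive fixations separated by less than ``merge_gap_s`` whose
    centroids are within ``merge_dist_deg`` are merged (duration-weighted
    centroid); fixations still shorter than ``min_fix_dur_s`` are then
    discarded.  Both passes repeat to a fixed point, which makes the whole
    operation idempotent.
    """
    params = params or DetectorParams()
    fix = seg.fixations.sort_values("onset_s").reset_index(drop=True)
    while True:
        merged = _merge_pass(fix, params)
        kept = merged[merged["duration_s"] >= params.min_fix_dur_s
                      ].reset_index(drop=True)
        if len(kept) == len(fix) and (len(kept) == 0 or
                                      np.allclose(kept["onset_s"], fix["onset_s"])):
            fix = kept
            break
        fix = kept
    return EventSegmentation(fix, seg.saccades.copy(),
                             seg.trace_duration_s, seg.invalid_s)


def _merge_pass(fix: pd.DataFrame, params: DetectorParams) -> pd.DataFrame:
    if len(fix) < 2:
        return fix.copy()
    rows = [fix.iloc[0].to_dict()]
    for _, row in fix.iloc[1:].iterrows():
        prev = rows[-1]
        gap = row["onset_s"] - prev["offset_s"]
        dist = np.hypot(row["x"] - prev["x"], row["y"] - prev["y"])
        if gap < params.merge_gap_s and dist < params.merge_dist_deg:
            w1, w2 = prev["duration_s"], row["duration_s"]
            total = w1 + w2
            prev["x"] = (prev["x"] * w1 + row["x"] * w2) / total
            prev["y"] = (prev["y"] * w1 + row["y"] * w2) / total
            prev["offset_s"] = row["offset_s"]
            prev["duration_s"] = prev["duration_s"] + row["duration_s"] + gap
        else:
            rows.append(row.to_dict())
    return pd.DataFrame(rows, columns=FIX_COLUMNS)


def segment_trace(trace: GazeTrace,
                  params: DetectorParams | None = None) -> EventSegmentation:
    """Convenience: interpolate gaps, detect, refine — the standard chain."""
    clean = interpolate_gaps(trace)
    return detect_saccades_ek(clean, params, refine=True)
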