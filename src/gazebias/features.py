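"""Oculomotor feature extraction and PCA "viewing style" reduction.

Twelve features summarize the spatiotemporal character of one viewing
record: fixation counts and durations (overall and in early/late windows),
gaze-step statistics (Euclidean distances between successive samples),
horizontal/vertical gaze-flip rates (direction inversions of successive
per-axis displacements), and saccade amplitude/rate.  Feature matrices are
z-scored and reduced with PCA; the leading components separate "static"
observers (long fixations, large steps) from "dynamic" ones (short
fixations, small steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocessing import EventSegmentation
from .task_engine import GazeTrace

__all__ = [
    "FEATURE_NAMES",
    "PcaResult",
    "gaze_steps",
    "gaze_flip_rate",
    "build_feature_vector",
    "pca_reduce",
]

#: Canonical order of the 12 oculomotor features.
FEATURE_NAMES = [
    "n_fixations",
    "mean_fix_dur_s",
    "total_fix_dur_s",
    "mean_fix_dur_first_window_s",
    "mean_fix_dur_last_window_s",
    "mean_gaze_step_deg",
    "sd_gaze_step_deg",
    "max_gaze_step_deg",
    "flip_rate_horizontal_per_s",
    "flip_rate_vertical_per_s",
    "mean_saccade_amp_deg",
    "saccade_rate_per_s",
]

#: Early/late fixation-duration windows (seconds) per task.  BSV uses the
#: first and last 15 s of the 1-min record; IVT uses the first and last
#: quarter (1.25 s) of each 5-s image presentation.
TASK_WINDOWS = {"BSV": 15.0, "IVT": 1.25}


def gaze_steps(trace: GazeTrace) -> np.ndarray:
    """Euclidean distances between successive *valid* gaze samples (deg).

    Pairs with an invalid member are skipped; fewer than two valid samples
    yield an empty array.
    """
    v = trace.valid
    if v.sum() < 2:
        return np.empty(0)
    pair_ok = v[:-1] & v[1:]
    dx = np.diff(trace.x)[pair_ok]
    dy = np.diff(trace.y)[pair_ok]
    return np.hypot(dx, dy)


def gaze_flip_rate(trace: GazeTrace, axis: str = "horizontal") -> float:
    """Direction-inversion rate (flips/s) of successive per-axis displacements.

    Zero displacements are transparent: each nonzero displacement is
    compared with the last preceding nonzero one.  The count is divided by
    the valid-trace duration (number of valid samples / fs).
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    pos = trace.x if axis == "horizontal" else trace.y
    v = trace.valid
    if v.sum() < 3:
        return 0.0
    pair_ok = v[:-1] & v[1:]
    d = np.diff(pos)[pair_ok]
    signs = np.sign(d)
    signs = signs[signs != 0.0]
    if signs.size < 2:
        return 0.0
    flips = int(np.sum(signs[1:] != signs[:-1]))
    return flips / (v.sum() / trace.fs)


def build_feature_vector(trace: GazeTrace, seg: EventSegmentation,
                         task: str = "BSV") -> pd.Series:
    """All 12 features for one viewing record.

    Windowed fixation-duration features average over fixations whose onset
    falls in the first/last window for the task.  With no fixations the
    counts are 0 and the duration features are NaN (such records are later
    excluded listwise from PCA).
    """
    if task not in TASK_WINDOWS:
        raise ValueError(f"unknown task {task!r}; expected one of {list(TASK_WINDOWS)}")
    win = TASK_WINDOWS[task]
    t_end = float(trace.t[-1]) + 1.0 / trace.fs if len(trace) else 0.0
    fix = seg.fixations
    steps = gaze_steps(trace)
    dur_total = trace.duration_s if len(trace) else np.nan

    def _mean_dur(mask) -> float:
        sel = fix.loc[mask, "duration_s"]
        return float(sel.mean()) if len(sel) else np.nan

    n_fix = len(fix)
    sacc = seg.saccades
    values = {
        "n_fixations": float(n_fix),
        "mean_fix_dur_s": _mean_dur(np.ones(n_fix, dtype=bool)) if n_fix else np.nan,
        "total_fix_dur_s": float(fix["duration_s"].sum()) if n_fix else np.nan,
        "mean_fix_dur_first_window_s": _mean_dur(fix["onset_s"] < win)
        if n_fix else np.nan,
        "mean_fix_dur_last_window_s": _mean_dur(fix["onset_s"] >= t_end - win)
        if n_fix else np.nan,
        "mean_gaze_step_deg": float(steps.mean()) if steps.size else np.nan,
        "sd_gaze_step_deg": float(steps.std(ddof=1)) if steps.size > 1 else np.nan,
        "max_gaze_step_deg": float(steps.max()) if steps.size else np.nan,
        "flip_rate_horizontal_per_s": gaze_flip_rate(trace, "horizontal"),
        "flip_rate_vertical_per_s": gaze_flip_rate(trace, "vertical"),
        "mean_saccade_amp_deg": float(sacc["amplitude_deg"].mean())
        if len(sacc) else np.nan,
        "saccade_rate_per_s": len(sacc) / dur_total if dur_total else np.nan,
    }
    return pd.Series(values, index=FEATURE_NAMES, name=task)


@dataclass
class PcaResult:
    """PCA of a participants x features matrix.

    ``loadings``: features x components (unit-norm columns; the
    largest-magnitude loading of each component is positive).  ``scores``:
    participants x components.  ``explained_variance_fraction`` is
    non-increasing and sums to <= 1.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    dropped_features: list[str]


def pca_reduce(matrix: pd.DataFrame, k: int = 3) -> PcaResult:
    """Standardize features (z-score) and keep the top-``k`` components.

    Operating on z-scored columns makes this a PCA of the correlation
    structure, appropriate for features with heterogeneous units.  Constant
    columns are dropped with a warning; rows with undefined entries must be
    removed by the caller.
    """
    X = matrix.astype(float)
    if X.isna().any().any():
        raise ValueError("feature matrix contains undefined entries; "
                         "exclude incomplete rows first")
    if len(X) < k + 1:
        raise ValueError("need at least k+1 participants")
    sd = X.std(ddof=1)
    dropped = list(X.columns[sd == 0.0])
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}")
        X = X.drop(columns=dropped)
    Z = (X - X.mean()) / X.std(ddof=1)
    pca = PCA(n_components=min(k, Z.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T.copy()  # features x k, unit-norm columns
    for j in range(loadings.shape[1]):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        dropped_features=dropped,
    )
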