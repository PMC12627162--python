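"""Plain-text interchange formats.

Gaze traces travel as CSV with header ``t,x,y,valid`` (seconds, degrees,
degrees, 0/1) plus a JSON sidecar holding the sampling rate, screen
geometry and trial metadata.  Event tables, feature tables and analysis
results are tidy CSVs; study configs are YAML; density maps are a numeric
grid CSV with a JSON header file.

The long-format binned CSV written by :func:`write_binned` doubles as the
adapter contract for an external mixed-model backend: any engine that reads
columns ``pid, trial_number, bias_label, time_bin_center_s,
median_distance_deg`` and writes a coefficient CSV with columns
``term, factor, estimate, se, chi2, p`` can stand in for the built-in
fixed-effects gamma GLM.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import EventSegmentation, FIX_COLUMNS, SACC_COLUMNS
from .stats import DensityMap
from .task_engine import FeedbackParams, GazeTrace, ScreenGeometry, StudyConfig

__all__ = [
    "write_trace", "read_trace", "write_events", "read_events",
    "write_binned", "read_coefficients", "load_study_config",
    "dump_study_config", "write_density_map",
]


def write_trace(trace: GazeTrace, path, metadata: dict | None = None) -> None:
    """Write a trace CSV and its JSON sidecar (same stem, .json suffix)."""
    path = Path(path)
    df = pd.DataFrame({"t": trace.t, "x": trace.x, "y": trace.y,
                       "valid": trace.valid.astype(int)})
    df.to_csv(path, index=False, float_format="%.6f")
    side = {"fs": trace.fs, "n_samples": len(trace)}
    if trace.geometry is not None:
        side["geometry"] = vars(trace.geometry).copy()
    if metadata:
        side["metadata"] = metadata
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_trace(path) -> GazeTrace:
    """Read a trace CSV; fs and geometry come from the JSON sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(path.with_suffix(".json").read_text())
    geom = None
    if "geometry" in side:
        geom = ScreenGeometry(**side["geometry"])
    return GazeTrace(df["t"], df["x"], df["y"], df["valid"].astype(bool),
                     fs=side["fs"], geometry=geom)


def write_events(seg: EventSegmentation, path) -> None:
    """Write fixations and saccades as one long CSV.

    Columns: onset,offset,type,x,y,amplitude,duration (x/y/duration for
    fixations, amplitude for saccades; absent fields are empty).
    """
    fix = seg.fixations.rename(columns={
        "onset_s": "onset", "offset_s": "offset", "duration_s": "duration"})
    fix["type"] = "fixation"
    sac = seg.saccades.rename(columns={
        "onset_s": "onset", "offset_s": "offset", "amplitude_deg": "amplitude"})
    sac["type"] = "saccade"
    cols = ["onset", "offset", "type", "x", "y", "amplitude", "duration"]
    frames = [f.reindex(columns=cols) for f in (fix, sac) if len(f)]
    if frames:
        both = pd.concat(frames, ignore_index=True)
    else:
        both = pd.DataFrame(columns=cols)
    both.sort_values("onset").to_csv(path, index=False, float_format="%.6f")


def read_events(path) -> EventSegmentation:
    df = pd.read_csv(path)
    fix = df[df["type"] == "fixation"].rename(columns={
        "onset": "onset_s", "offset": "offset_s", "duration": "duration_s"})
    sac = df[df["type"] == "saccade"].rename(columns={
        "onset": "onset_s", "offset": "offset_s", "amplitude": "amplitude_deg"})
    if "peak_velocity_deg_s" not in sac.columns:
        sac = sac.assign(peak_velocity_deg_s=np.nan)
    return EventSegmentation(
        fix.reindex(columns=FIX_COLUMNS).reset_index(drop=True),
        sac.reindex(columns=SACC_COLUMNS).reset_index(drop=True))


def write_binned(binned: pd.DataFrame, path) -> None:
    """Long-format binned gaze-target distances (mixed-model adapter input)."""
    cols = ["pid", "trial_number", "bias_label", "time_bin_center_s",
            "median_distance_deg"]
    binned.reindex(columns=cols).to_csv(path, index=False,
                                        float_format="%.6f")


def read_coefficients(path) -> pd.DataFrame:
    """Coefficient table from any learning-model backend (adapter output)."""
    df = pd.read_csv(path)
    required = {"term", "factor", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coefficient CSV missing columns: {sorted(missing)}")
    return df.set_index("term")


def load_study_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fb = raw.pop("feedback", None)
    if fb is not None:
        raw["feedback"] = FeedbackParams(**fb)
    if "zone_counts" in raw and raw["zone_counts"] is not None:
        raw["zone_counts"] = tuple(raw["zone_counts"])
    return StudyConfig(**raw)


def dump_study_config(config: StudyConfig, path) -> None:
    data = {
        "bias_side": config.bias_side, "n_trials": config.n_trials,
        "zone_counts": list(config.zone_counts), "dwell_s": config.dwell_s,
        "deadline_s": config.deadline_s, "start_fix_s": config.start_fix_s,
        "fs": config.fs, "seed": config.seed,
        "target_radius": config.target_radius,
        "feedback": vars(config.feedback).copy(),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_density_map(dmap: DensityMap, path) -> None:
    """Grid CSV plus a JSON header with edges and bandwidth."""
    path = Path(path)
    np.savetxt(path, dmap.grid, delimiter=",", fmt="%.8e")
    header = {"bandwidth": dmap.bandwidth,
              "x_edges": dmap.x_edges.tolist(),
              "y_edges": dmap.y_edges.tolist()}
    path.with_suffix(".json").write_text(json.dumps(header))
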