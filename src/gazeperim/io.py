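"""Serialization of sessions, gaze logs, and miniature fixtures.

Interchange formats are plain text: CSV for pointwise fields, trial logs
and gaze logs, JSON for summaries and configs.  Conventions (stated in
file headers where applicable): angles in right-eye-format visual-field
degrees, times in seconds, luminance in cd/m^2, dB to 2 decimal places,
0-based trial indices.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import GazeStream
from .config import RunConfig, config_hash, to_dict
from .grid import TestGrid, build_grid, grid_to_frame
from .observer import HillModel, ObserverBehavior, normative_mean, sample_cohort
from .session import SessionConfig, TestResult, run_session
from .stats import CohortResults

__all__ = [
    "write_results",
    "read_results_frame",
    "write_gaze_log",
    "read_gaze_log",
    "make_fixtures",
]

RESULT_COLUMNS = ["x_deg", "y_deg", "role", "dls_db", "n_presentations", "terminated"]
TRIAL_COLUMNS = ["index", "type", "x_deg", "y_deg", "stimulus_db",
                 "placement_x_px", "placement_y_px", "outcome", "viewing_distance_cm"]
GAZE_COLUMNS = ["t_s", "x", "y", "valid", "distance_cm"]


def result_to_frame(result: TestResult) -> pd.DataFrame:
    frame = grid_to_frame(result.grid)[["x_deg", "y_deg", "role"]].copy()
    frame["dls_db"] = np.round(result.estimates, 2)
    frame["n_presentations"] = result.n_presentations
    frame["terminated"] = result.terminated
    return frame


def trials_to_frame(result: TestResult) -> pd.DataFrame:
    rows = []
    for t in result.trials:
        rows.append({
            "index": t.index,
            "type": t.type,
            "x_deg": t.location[0] if t.location else np.nan,
            "y_deg": t.location[1] if t.location else np.nan,
            "stimulus_db": np.nan if t.stimulus_db is None else round(t.stimulus_db, 2),
            "placement_x_px": t.placement_px[0] if t.placement_px else np.nan,
            "placement_y_px": t.placement_px[1] if t.placement_px else np.nan,
            "outcome": t.outcome,
            "viewing_distance_cm": round(t.viewing_distance_cm, 2),
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_results(result: TestResult, out_dir: str | Path,
                  prefix: str = "session",
                  config: RunConfig | None = None) -> dict[str, Path]:
    """Write one session's results, trial log, and summary JSON.

    Returns a manifest of the files written.  The summary carries a
    provenance block (config hash, seed, package version).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["results"] = out_dir / f"{prefix}_results.csv"
    result_to_frame(result).to_csv(files["results"], index=False)

    files["trials"] = out_dir / f"{prefix}_trials.csv"
    trials_to_frame(result).to_csv(files["trials"], index=False)

    summary = {
        "provenance": {
            "package": "gazeperim",
            "version": __version__,
            "seed": result.seed,
            "config_hash": config_hash(config) if config is not None else None,
        },
        "eye": result.grid.eye,
        "n_locations": len(result.grid),
        "mean_sensitivity_db": _ms_or_none(result),
        "n_trials_by_type": result.n_trials_by_type,
        "fp_rate_est": result.fp_rate_est,
        "fn_rate_est": result.fn_rate_est,
        "n_unmeasured": int(result.unmeasured.sum()),
    }
    files["summary"] = out_dir / f"{prefix}_summary.json"
    files["summary"].write_text(json.dumps(summary, indent=2) + "\n")
    return files


def _ms_or_none(result: TestResult) -> float | None:
    from .stats import mean_sensitivity

    vals = result.estimates
    if np.isnan(vals).any():
        mask = np.array([l.role == "test" for l in result.grid]) & ~np.isnan(vals)
        if not mask.any():
            return None
        return round(float(vals[mask].mean()), 2)
    return round(mean_sensitivity(vals, result.grid), 2)


def read_results_frame(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"results file {path} lacks columns {sorted(missing)}")
    return frame


def write_gaze_log(stream: GazeStream, path: str | Path,
                   distance_cm: float = 60.0) -> None:
    """Gaze-log CSV dialect: t_s, x, y, valid, distance_cm (deg, s, cm)."""
    d = stream.distance_cm if stream.distance_cm is not None \
        else np.full(len(stream), distance_cm)
    pd.DataFrame({
        "t_s": stream.t, "x": stream.x, "y": stream.y,
        "valid": stream.valid.astype(int), "distance_cm": d,
    }).to_csv(path, index=False)


def read_gaze_log(path: str | Path) -> GazeStream:
    frame = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"gaze log {path} lacks columns {sorted(missing)}")
    return GazeStream(frame.t_s.to_numpy(), frame.x.to_numpy(),
                      frame.y.to_numpy(), frame.valid.to_numpy().astype(bool),
                      frame.distance_cm.to_numpy())


def make_fixtures(seed: int = 0, n_observers: int = 4,
                  grid: TestGrid | None = None) -> CohortResults:
    """Deterministic miniature cohort: 2 runs x 2 simulated "devices".

    Device "A" uses the default behaviour; device "B" mimics a second
    instrument by doubling the frequency-of-seeing slope (noisier
    psychometric behaviour).  Sessions run in direct-response mode for
    speed; the same seed yields identical fixtures.
    """
    grid = grid or build_grid("right")
    hill = HillModel()
    session_cfg = SessionConfig(response_mode="direct")
    behaviors = {
        "A": ObserverBehavior(),
        "B": ObserverBehavior(fos_slope=2.5),
    }
    values: dict[str, np.ndarray] = {}
    for d_idx, (name, behavior) in enumerate(behaviors.items()):
        observers = sample_cohort(n_observers, hill, grid, behavior, seed)
        runs = np.empty((n_observers, 2, len(grid)))
        for i, obs in enumerate(observers):
            for run in range(2):
                run_seed = (seed * 1_000_003 + d_idx * 10_007 + i * 101 + run) % (2**31)
                res = run_session(obs, grid, run_seed, session=session_cfg,
                                  normative_hill=hill)
                est = res.estimates.copy()
                # rare unmeasured points are imputed with the normative value
                # so downstream MS/repeatability stay defined
                for j, loc in enumerate(grid):
                    if np.isnan(est[j]):
                        est[j] = 0.0 if loc.role == "blind_spot" else \
                            normative_mean(hill, loc.x, loc.y)
                runs[i, run] = est
        values[name] = runs
    return CohortResults(values, grid)
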