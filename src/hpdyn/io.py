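"""CSV/JSON readers and writers for trajectories, ROIs, dwells and results.

Trajectory CSV header: ``track_id,frame,x_um,y_um,cell_id`` (optional
``state``); ROI CSV: ``cell_id,cx_um,cy_um,r_um``; dwell CSV:
``tau_tl_s,tau_int_s,n_frames``.  Writers emit ``# key=value`` comment
headers (acquisition metadata and the run's config hash) that readers
consume; numeric columns are written with full float precision so
write -> read round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bsl import RatePosterior
from .dwell import DwellDataset, DwellFit
from .ripley import HeatmapImage, RipleyResult
from .simulate import TrajectorySet
from .statehmm import MobilityModel

TRAJ_COLUMNS = ["track_id", "frame", "x_um", "y_um", "cell_id"]
ROI_COLUMNS = ["cell_id", "cx_um", "cy_um", "r_um"]
DWELL_COLUMNS = ["tau_tl_s", "tau_int_s", "n_frames"]


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    return df, meta


def write_trajectories(data: TrajectorySet, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    meta = {
        "dt_frame_s": repr(data.dt_frame),
        "sigma_loc_um": repr(data.sigma_loc),
        "seed": data.seed,
        "config_hash": config_hash,
    }
    cols = TRAJ_COLUMNS + (["state"] if data.has_ground_truth else [])
    _write_csv(data.df[cols], path, meta)
    _write_csv(data.rois[ROI_COLUMNS], path.with_suffix(".rois.csv"), meta)


def read_trajectories(path: str | Path, roi_path: str | Path | None = None) -> TrajectorySet:
    """Read a trajectory CSV (+ sidecar ROI CSV); frames are sorted within
    tracks, and malformed rows are reported with their line position."""
    path = Path(path)
    df, meta = _read_csv(path)
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicated (track_id, frame) at data row {row} "
            f"(track {df['track_id'].iloc[row]}, frame {df['frame'].iloc[row]})"
        )
    df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
    if roi_path is None:
        roi_path = path.with_suffix(".rois.csv")
    rois, _ = _read_csv(Path(roi_path))
    missing = set(ROI_COLUMNS) - set(rois.columns)
    if missing:
        raise ValueError(f"{roi_path}: missing columns {sorted(missing)}")
    return TrajectorySet(
        df=df,
        dt_frame=float(meta.get("dt_frame_s", 0.04)),
        sigma_loc=float(meta.get("sigma_loc_um", 0.0)),
        rois=rois,
        seed=int(meta["seed"]) if meta.get("seed", "None") not in ("None", "") else None,
    )


def write_dwells(data: DwellDataset, path: str | Path, config_hash: str = "") -> None:
    _write_csv(
        data.observations[DWELL_COLUMNS], Path(path),
        {"seed": data.seed, "config_hash": config_hash},
    )


def read_dwells(path: str | Path) -> DwellDataset:
    df, meta = _read_csv(Path(path))
    missing = set(DWELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    seed = meta.get("seed", "None")
    return DwellDataset(df, seed=int(seed) if seed not in ("None", "") else None)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def mobility_model_to_dict(model: MobilityModel, config_hash: str = "") -> dict:
    return {
        "config_hash": config_hash,
        "K": model.K,
        "D_um2_s": model.D,
        "D_sd_um2_s": model.D_sd,
        "pi": model.pi,
        "T_frame": model.T_frame,
        "dt_frame_s": model.dt_frame,
        "sigma_loc_um": model.sigma_loc,
        "log_marginal": model.log_marginal,
        "n_steps": model.n_steps,
        "diagnostics": {k: v for k, v in model.diagnostics.items()},
    }


def rate_posterior_to_dict(post: RatePosterior, config_hash: str = "") -> dict:
    return {
        "config_hash": config_hash,
        "pairs": [list(p) for p in post.pairs],
        "rates_per_s": post.rates,
        "hdi95_per_s": post.hdi95,
        "acceptance_rate": post.acceptance_rate,
        "warnings": post.warnings_,
    }


def dwell_fit_to_dict(fit: DwellFit, config_hash: str = "") -> dict:
    return {
        "config_hash": config_hash,
        "k_diss_per_s": fit.k_diss,
        "k_diss_se_per_s": fit.k_diss_se,
        "k_bleaching_per_s": fit.k_bleaching,
        "k_bleaching_se_per_s": fit.k_bleaching_se,
        "mean_dwell_s": fit.mean_dwell,
        "per_interval": fit.per_interval.to_dict(orient="list"),
        "flags": fit.flags,
    }


def write_ripley(result: RipleyResult, path: str | Path, config_hash: str = "") -> None:
    df = pd.DataFrame(
        {
            "r_um": result.r_grid,
            "H": result.H,
            "H_norm": result.H_norm,
            "sim_mean": result.sim_mean,
            "sim_lo": result.sim_envelope[0],
            "sim_hi": result.sim_envelope[1],
        }
    )
    _write_csv(df, Path(path), {"state": result.state, "config_hash": config_hash})


def write_heatmap(img: HeatmapImage, path: str | Path, config_hash: str = "") -> None:
    """Plain-text matrix with a commented header (portable, diffable)."""
    path = Path(path)
    header = (
        f"config_hash={config_hash}\n"
        f"extent_um={list(img.extent)}\n"
        f"pixel_um={img.pixel_um}\n"
        f"total_intensity={img.total_intensity}"
    )
    np.savetxt(path, img.image, header=header, fmt="%.6e")


def read_config_file(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)
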