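"""Orchestration of the full analysis with recorded, derivable seeds.

simulate (or load) -> infer mobility states -> infer rate constants ->
dwell-time analysis -> Ripley clustering -> heatmap rendering.  Every stage
draws its randomness from a seed derived deterministically from the root
seed and the stage label, so a rerun with the same config and seed
reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .bsl import BslConfig, ObservedTransitions, infer_rate_constants
from .dwell import detect_stationary_dwells, fit_dissociation
from .ripley import normalized_H, render_heatmap
from .simulate import SimConfig, TrajectorySet, simulate_trajectories
from .statehmm import HmmConfig, infer_states, select_K

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed", "config_hash"]

VERSION = "0.1.0"
log = logging.getLogger("hpdyn.pipeline")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: root seed combined with a stable hash
    of the stage label (kept below 2**31)."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Full-run configuration.

    Exactly one of ``input_trajectories`` (CSV path) or ``sim`` must be
    provided.  Stages may be disabled individually.
    """

    out_dir: str = "hpdyn_out"
    seed: int = 0
    input_trajectories: str | None = None
    sim: SimConfig | None = None
    hmm: HmmConfig = field(default_factory=HmmConfig)
    bsl: BslConfig = field(default_factory=BslConfig)
    dwell_r_stat: float | None = None
    ripley_state: int | None = 0
    ripley_n_reps: int = 50
    heatmap_cell: int | None = 0
    stages: tuple[str, ...] = ("simulate", "states", "rates", "dwell", "ripley", "heatmap")

    def validate(self) -> None:
        if (self.input_trajectories is None) == (self.sim is None):
            raise ValueError("provide exactly one of input_trajectories or sim")


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str]
    wall_time_s: dict[str, float]


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the analysis configuration (dataclasses -> canonical
    JSON); the output directory is excluded so identical analyses written to
    different locations hash identically."""

    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    payload = enc(config)
    payload.pop("out_dir", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the requested stages in order; any stage failure raises a
    stage-tagged error and earlier outputs are retained on disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    outputs: dict[str, str] = {}
    times: dict[str, float] = {}

    def _run(stage, fn):
        log.info("stage %s: derived seed %d from root seed %d",
                 stage, stage_seed(config.seed, stage), config.seed)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        times[stage] = time.perf_counter() - t0
        log.info("stage %s finished in %.1f s", stage, times[stage])

    # --- trajectories -----------------------------------------------------
    data: TrajectorySet
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))

        def _simulate():
            nonlocal data
            data = simulate_trajectories(sim_cfg)
            p = out / "trajectories.csv"
            hio.write_trajectories(data, p, config_hash=chash)
            outputs["trajectories"] = str(p)
            outputs["rois"] = str(p.with_suffix(".rois.csv"))

        _run("simulate", _simulate)
    else:

        def _load():
            nonlocal data
            data = hio.read_trajectories(config.input_trajectories)

        _run("load", _load)

    model = None
    if "states" in config.stages:

        def _states():
            nonlocal model
            hcfg = dataclasses.replace(config.hmm, seed=stage_seed(config.seed, "states"))
            if hcfg.K is None:
                hcfg = dataclasses.replace(hcfg, K=select_K(data, hcfg))
            model = infer_states(data, hcfg)
            p = out / "mobility_model.json"
            hio.write_json(hio.mobility_model_to_dict(model, chash), p)
            outputs["mobility_model"] = str(p)

        _run("states", _states)

    if "rates" in config.stages and model is not None and model.K > 1:

        def _rates():
            bcfg = dataclasses.replace(config.bsl, seed=stage_seed(config.seed, "rates"))
            obs = ObservedTransitions(
                T_frame=model.T_frame, dt_exp=data.dt_frame, n_obs=model.n_steps
            )
            post = infer_rate_constants(obs, bcfg)
            p = out / "rate_posterior.json"
            hio.write_json(hio.rate_posterior_to_dict(post, chash), p)
            outputs["rate_posterior"] = str(p)
            ps = out / "rate_samples.csv"
            import pandas as pd

            samples = pd.DataFrame(
                post.samples, columns=[f"k_{i}{j}" for i, j in post.pairs]
            )
            with open(ps, "w") as fh:
                fh.write(f"# config_hash={chash}\n")
                samples.to_csv(fh, index=False)
            outputs["rate_samples"] = str(ps)

        _run("rates", _rates)

    if "dwell" in config.stages:

        def _dwell():
            dwells = detect_stationary_dwells(data, r_stat=config.dwell_r_stat)
            p = out / "dwells.csv"
            hio.write_dwells(dwells, p, config_hash=chash)
            outputs["dwells"] = str(p)
            if len(dwells.intervals) >= 2:
                fit = fit_dissociation(dwells)
                pf = out / "dwell_fit.json"
                hio.write_json(hio.dwell_fit_to_dict(fit, chash), pf)
                outputs["dwell_fit"] = str(pf)

        _run("dwell", _dwell)

    if "ripley" in config.stages:

        def _ripley():
            res = normalized_H(
                data,
                state=config.ripley_state if data.has_ground_truth else None,
                n_reps=config.ripley_n_reps,
                seed=stage_seed(config.seed, "ripley"),
            )
            p = out / "ripley.csv"
            hio.write_ripley(res, p, config_hash=chash)
            outputs["ripley"] = str(p)

        _run("ripley", _ripley)

    if "heatmap" in config.stages and config.heatmap_cell is not None:

        def _heatmap():
            img = render_heatmap(data, cell_id=config.heatmap_cell)
            p = out / "heatmap.txt"
            hio.write_heatmap(img, p, config_hash=chash)
            outputs["heatmap"] = str(p)

        _run("heatmap", _heatmap)

    manifest = RunManifest(
        version=VERSION, config_hash=chash, seed=config.seed,
        outputs=outputs, wall_time_s=times,
    )
    hio.write_json(dataclasses.asdict(manifest), out / "manifest.json")
    for f in outputs.values():
        assert Path(f).exists()
    return manifest
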