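"""Synthetic single-molecule trajectory and time-lapse dwell generators.

Emulates photoactivated single-molecule tracking of heterochromatin proteins
in a fission-yeast nucleus: K-state Brownian motion with per-frame Markov
switching between mobility states, confinement in a circular nucleus,
Gaussian localization error, geometric photobleaching, and time-lapse
acquisition (fixed integration time, variable dark delays).

Units throughout: positions in micrometres, times in seconds, diffusion
coefficients in um^2/s, rates in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dwell import DwellDataset

__all__ = [
    "SimConfig",
    "TimeLapseConfig",
    "TrajectorySet",
    "stationary_distribution",
    "simulate_trajectories",
    "simulate_timelapse_dwells",
    "resample_matched_trajectories",
]

#: Imaging frame interval of the tracking experiments (40 ms exposure).
DEFAULT_DT_FRAME = 0.04
#: Integration time of time-lapse acquisitions (200 ms).
DEFAULT_TAU_INT = 0.2
#: Localization precision per coordinate typical of PAmCherry in yeast.
DEFAULT_SIGMA_LOC = 0.02
#: Nucleus radius used for confinement; the fission-yeast nucleus is ~1 um.
DEFAULT_R_NUC = 1.0


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Solves pi @ T = pi with sum(pi) = 1 via the null space of (T' - I).
    """
    T = np.asarray(T, dtype=float)
    K = T.shape[0]
    A = np.vstack([T.T - np.eye(K), np.ones((1, K))])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _check_stochastic(T: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < -atol) or np.any(T > 1 + atol):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("each transition-matrix row must sum to 1 (within 1e-12)")
    return T


@dataclass
class SimConfig:
    """Configuration of the multi-state diffusive trajectory simulator.

    Parameters
    ----------
    K : number of mobility states.
    D : per-state diffusion coefficients, um^2/s, length K.
    T_frame : K x K per-frame (dt_frame) transition probability matrix.
    dt_frame : frame interval, s.
    sigma_loc : localization error s.d. per coordinate, um.
    R_nuc : nucleus radius, um; ``None`` disables confinement.
    p_bleach : per-frame photobleaching probability (geometric track length).
    n_tracks : number of tracks to generate (after the min_len filter).
    min_len : minimum retained track length in frames (>= 2).
    max_len : hard cap on track length in frames (relevant when p_bleach ~ 0).
    n_cells : number of cells the tracks are distributed over.
    seed : RNG seed.
    """

    K: int = 2
    D: Sequence[float] = (0.007, 0.13)
    T_frame: Sequence[Sequence[float]] = ((0.99, 0.01), (0.1233, 0.8767))
    dt_frame: float = DEFAULT_DT_FRAME
    sigma_loc: float = DEFAULT_SIGMA_LOC
    R_nuc: float | None = DEFAULT_R_NUC
    p_bleach: float = 0.05
    n_tracks: int = 1000
    min_len: int = 2
    max_len: int = 500
    n_cells: int = 8
    seed: int = 0

    def validate(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if D.shape != (self.K,):
            raise ValueError("D must have length K")
        if np.any(D < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        T = _check_stochastic(np.asarray(self.T_frame, dtype=float))
        if T.shape != (self.K, self.K):
            raise ValueError("T_frame must be K x K")
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be > 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.R_nuc is not None and self.R_nuc <= 0:
            raise ValueError("R_nuc must be > 0")
        if not 0 <= self.p_bleach < 1:
            raise ValueError("p_bleach must be in [0, 1)")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2 (a track needs one step)")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if np.all(D == 0) and self.sigma_loc == 0 and self.p_bleach == 1:
            raise ValueError("degenerate configuration: no motion, no noise, instant bleaching")


@dataclass
class TimeLapseConfig:
    """Configuration of the time-lapse dwell simulator.

    tau_TL = tau_int + tau_delay for each entry of ``tau_delays``.  A bound
    molecule survives frame-to-frame with probability
    exp(-k_diss_true * tau_TL) * exp(-k_bleach_true * tau_int): dissociation
    acts over the whole interval, photobleaching only during integration.
    """

    tau_int: float = DEFAULT_TAU_INT
    tau_delays: Sequence[float] = (0.0, 0.3, 0.8, 1.8, 3.8)
    k_diss_true: float = 0.26
    k_bleach_true: float = 1.5
    n_molecules: int = 10_000
    max_frames: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.tau_int <= 0:
            raise ValueError("tau_int must be > 0")
        if len(self.tau_delays) == 0:
            raise ValueError("tau_delays must be non-empty")
        if np.any(np.asarray(self.tau_delays, dtype=float) < 0):
            raise ValueError("delays must be >= 0")
        if self.k_diss_true < 0 or self.k_bleach_true < 0:
            raise ValueError("rates must be >= 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass
class TrajectorySet:
    """Localization records grouped into tracks, with acquisition metadata.

    ``df`` has columns ``track_id, frame, x_um, y_um, cell_id`` (frames
    strictly increasing within a track) plus an optional ``state`` column of
    ground-truth per-step labels (the state governing the displacement that
    starts at that frame; -1 on each track's final localization).
    ``rois`` has columns ``cell_id, cx_um, cy_um, r_um``.
    """

    df: pd.DataFrame
    dt_frame: float
    sigma_loc: float
    rois: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = self.df.groupby("track_id", sort=False)["frame"].size()
        if (counts < 2).any():
            raise ValueError("every track must have >= 2 localizations")
        missing = set(self.df["cell_id"].unique()) - set(self.rois["cell_id"])
        if missing:
            raise ValueError(f"cells without an ROI: {sorted(missing)}")

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    @property
    def n_localizations(self) -> int:
        return len(self.df)

    @property
    def has_ground_truth(self) -> bool:
        return "state" in self.df.columns

    def steps(self) -> pd.DataFrame:
        """Per-step table of displacements between consecutive frames.

        Columns: track_id, cell_id, frame, x_um, y_um (step start), dx, dy,
        length, and state (ground-truth label if present, else -1).  Steps
        spanning a frame gap are excluded.
        """
        df = self.df.sort_values(["track_id", "frame"], kind="mergesort")
        g = df.groupby("track_id", sort=False)
        out = df.copy()
        out["dx"] = g["x_um"].shift(-1) - df["x_um"]
        out["dy"] = g["y_um"].shift(-1) - df["y_um"]
        out["dframe"] = g["frame"].shift(-1) - df["frame"]
        out = out[out["dframe"] == 1].drop(columns="dframe")
        out["length"] = np.hypot(out["dx"], out["dy"])
        if "state" not in out.columns:
            out["state"] = -1
        return out.reset_index(drop=True)


def _draw_track_lengths(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Geometric (per-frame bleaching) lengths conditioned on >= min_len."""
    if cfg.p_bleach == 0:
        return np.full(cfg.n_tracks, cfg.max_len, dtype=np.int64)
    # memoryless: L >= min_len given survival of the first min_len-1 frames
    extra = rng.geometric(cfg.p_bleach, size=cfg.n_tracks) - 1
    return np.minimum(cfg.min_len + extra, cfg.max_len).astype(np.int64)


def _cell_layout(n_cells: int, R: float) -> pd.DataFrame:
    """Non-overlapping circular nucleus ROIs on a grid, all of radius R."""
    pitch = 4.0 * R
    cx = pitch * (np.arange(n_cells) % 4)
    cy = pitch * (np.arange(n_cells) // 4)
    return pd.DataFrame(
        {"cell_id": np.arange(n_cells), "cx_um": cx, "cy_um": cy, "r_um": R}
    )


def simulate_trajectories(config: SimConfig) -> TrajectorySet:
    """Simulate confined multi-state Brownian trajectories.

    Each track: initial state drawn from the stationary distribution of
    ``T_frame``; per-frame state switching by ``T_frame``; per-frame true
    displacement per coordinate ~ Normal(0, 2*D_state*dt_frame); steps that
    would exit the nucleus circle are rejection-resampled; the observed
    position adds Normal(0, sigma_loc^2) noise per coordinate (resampled if
    it would fall outside the nucleus, so confined localizations stay inside
    the ROI exactly); track length is geometric with parameter ``p_bleach``,
    conditioned on >= ``min_len``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    D = np.asarray(config.D, dtype=float)
    T = np.asarray(config.T_frame, dtype=float)
    pi0 = stationary_distribution(T)
    confined = config.R_nuc is not None
    R = config.R_nuc if confined else np.inf

    lengths = _draw_track_lengths(rng, config)
    rois = _cell_layout(config.n_cells, R if confined else DEFAULT_R_NUC)
    cell_of_track = rng.integers(0, config.n_cells, size=config.n_tracks)

    step_sd = np.sqrt(2.0 * D * config.dt_frame)
    cum_T = np.cumsum(T, axis=1)

    recs_track, recs_frame, recs_x, recs_y, recs_cell, recs_state = [], [], [], [], [], []
    for tid in range(config.n_tracks):
        L = lengths[tid]
        cid = cell_of_track[tid]
        cx = rois.loc[cid, "cx_um"]
        cy = rois.loc[cid, "cy_um"]
        # states for the L-1 steps; the initial state also labels step 0
        states = np.empty(L, dtype=np.int64)
        states[0] = np.searchsorted(np.cumsum(pi0), rng.random())
        u = rng.random(L - 1)
        for t in range(1, L):
            states[t] = np.searchsorted(cum_T[states[t - 1]], u[t - 1])
        # initial position uniform in the nucleus disk
        if confined:
            r0 = R * np.sqrt(rng.random())
            th0 = 2 * np.pi * rng.random()
            x, y = cx + r0 * np.cos(th0), cy + r0 * np.sin(th0)
        else:
            x, y = cx, cy
        xs = np.empty(L)
        ys = np.empty(L)
        xs[0], ys[0] = x, y
        for t in range(1, L):
            sd = step_sd[states[t - 1]]
            while True:
                nx = xs[t - 1] + sd * rng.standard_normal()
                ny = ys[t - 1] + sd * rng.standard_normal()
                if not confined or (nx - cx) ** 2 + (ny - cy) ** 2 <= R * R:
                    break
            xs[t], ys[t] = nx, ny
        # observed = true + localization noise, kept inside the ROI
        if config.sigma_loc > 0:
            ox = np.empty(L)
            oy = np.empty(L)
            for t in range(L):
                while True:
                    ex = xs[t] + config.sigma_loc * rng.standard_normal()
                    ey = ys[t] + config.sigma_loc * rng.standard_normal()
                    if not confined or (ex - cx) ** 2 + (ey - cy) ** 2 <= R * R:
                        break
                ox[t], oy[t] = ex, ey
        else:
            ox, oy = xs, ys
        recs_track.append(np.full(L, tid))
        recs_frame.append(np.arange(L))
        recs_x.append(ox)
        recs_y.append(oy)
        recs_cell.append(np.full(L, cid))
        step_labels = np.empty(L, dtype=np.int64)
        step_labels[: L - 1] = states[:-1]  # label of the step starting here
        step_labels[L - 1] = -1
        recs_state.append(step_labels)

    df = pd.DataFrame(
        {
            "track_id": np.concatenate(recs_track),
            "frame": np.concatenate(recs_frame),
            "x_um": np.concatenate(recs_x),
            "y_um": np.concatenate(recs_y),
            "cell_id": np.concatenate(recs_cell),
            "state": np.concatenate(recs_state),
        }
    )
    return TrajectorySet(
        df=df,
        dt_frame=config.dt_frame,
        sigma_loc=config.sigma_loc,
        rois=rois,
        seed=config.seed,
    )


def simulate_timelapse_dwells(config: TimeLapseConfig) -> DwellDataset:
    """Simulate time-lapse dwell observations (frame counts per molecule).

    For each dark delay, a molecule is detected in frame 1 and survives to
    each subsequent frame with probability
    exp(-k_diss_true*tau_TL) * exp(-k_bleach_true*tau_int), so the emitted
    frame count n >= 1 is geometric.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    tls = []
    for delay in config.tau_delays:
        tau_tl = config.tau_int + float(delay)
        p_surv = np.exp(-config.k_diss_true * tau_tl - config.k_bleach_true * config.tau_int)
        if p_surv >= 1.0:
            n = np.full(config.n_molecules, config.max_frames, dtype=np.int64)
        else:
            n = rng.geometric(1.0 - p_surv, size=config.n_molecules)
            n = np.minimum(n, config.max_frames)
        frames.append(n)
        tls.append(np.full(config.n_molecules, tau_tl))
    obs = pd.DataFrame(
        {
            "tau_tl_s": np.concatenate(tls),
            "tau_int_s": config.tau_int,
            "n_frames": np.concatenate(frames),
        }
    )
    return DwellDataset(obs, seed=config.seed)


def resample_matched_trajectories(
    data: TrajectorySet, n_reps: int, seed: int | None = None
) -> list[TrajectorySet]:
    """Trajectory-matched null replicates for clustering normalization.

    Each replicate keeps the number of tracks, every track's length, and the
    per-cell ROI assignment of ``data``; steps are built by drawing step
    lengths with replacement from the pooled empirical step-length
    distribution and directions uniform on [0, 2pi); steps that would leave
    the ROI are redrawn.  Track starting points are uniform in their ROI, so
    per-cell density is preserved in expectation.
    """
    steps = data.steps()
    if len(steps) < 10:
        raise ValueError("need >= 10 steps for a stable empirical step-length distribution")
    pool = steps["length"].to_numpy()
    rng = np.random.default_rng(seed)
    roi = data.rois.set_index("cell_id")
    track_info = (
        data.df.groupby("track_id", sort=False)
        .agg(n=("frame", "size"), cell_id=("cell_id", "first"))
        .reset_index()
    )
    reps = []
    for _ in range(n_reps):
        recs_track, recs_frame, recs_x, recs_y, recs_cell = [], [], [], [], []
        for tid, L, cid in track_info[["track_id", "n", "cell_id"]].itertuples(index=False):
            cx, cy, R = roi.loc[cid, ["cx_um", "cy_um", "r_um"]]
            r0 = R * np.sqrt(rng.random())
            th0 = 2 * np.pi * rng.random()
            xs = np.empty(L)
            ys = np.empty(L)
            xs[0], ys[0] = cx + r0 * np.cos(th0), cy + r0 * np.sin(th0)
            for t in range(1, L):
                while True:
                    s = pool[rng.integers(len(pool))]
                    th = 2 * np.pi * rng.random()
                    nx = xs[t - 1] + s * np.cos(th)
                    ny = ys[t - 1] + s * np.sin(th)
                    if (nx - cx) ** 2 + (ny - cy) ** 2 <= R * R:
                        break
                xs[t], ys[t] = nx, ny
            recs_track.append(np.full(L, tid))
            recs_frame.append(np.arange(L))
            recs_x.append(xs)
            recs_y.append(ys)
            recs_cell.append(np.full(L, cid))
        df = pd.DataFrame(
            {
                "track_id": np.concatenate(recs_track),
                "frame": np.concatenate(recs_frame),
                "x_um": np.concatenate(recs_x),
                "y_um": np.concatenate(recs_y),
                "cell_id": np.concatenate(recs_cell),
            }
        )
        reps.append(
            TrajectorySet(
                df=df,
                dt_frame=data.dt_frame,
                sigma_loc=data.sigma_loc,
                rois=data.rois.copy(),
            )
        )
    return reps


def subset_by_state(data: TrajectorySet, state: int, labels: np.ndarray | None = None) -> TrajectorySet:
    """Restrict a TrajectorySet to maximal runs of steps in one mobility state.

    ``labels`` are per-step labels aligned with ``data.steps()`` rows; if
    omitted, the ground-truth ``state`` column is used.  Each maximal run of
    consecutive steps in ``state`` becomes its own track (a run of m steps
    keeps its m+1 localizations).
    """
    steps = data.steps()
    lab = steps["state"].to_numpy() if labels is None else np.asarray(labels)
    if len(lab) != len(steps):
        raise ValueError("labels must align with data.steps() rows")
    sel = lab == state
    recs = []
    new_tid = 0
    for tid, grp in steps.assign(sel=sel).groupby("track_id", sort=False):
        flags = grp["sel"].to_numpy()
        if not flags.any():
            continue
        # maximal runs of consecutive selected steps
        edges = np.flatnonzero(np.diff(np.concatenate([[0], flags.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            run = grp.iloc[a:b]
            n = len(run)
            rows = pd.DataFrame(
                {
                    "track_id": new_tid,
                    "frame": np.arange(n + 1),
                    "x_um": np.concatenate([run["x_um"].to_numpy(), [run["x_um"].iloc[-1] + run["dx"].iloc[-1]]]),
                    "y_um": np.concatenate([run["y_um"].to_numpy(), [run["y_um"].iloc[-1] + run["dy"].iloc[-1]]]),
                    "cell_id": run["cell_id"].iloc[0],
                }
            )
            recs.append(rows)
            new_tid += 1
    if not recs:
        raise ValueError(f"no steps in state {state}")
    return TrajectorySet(
        df=pd.concat(recs, ignore_index=True),
        dt_frame=data.dt_frame,
        sigma_loc=data.sigma_loc,
        rois=data.rois.copy(),
    )
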