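"""Photobleaching-corrected dissociation kinetics from time-lapse dwell times.

A bound molecule imaged with integration time tau_int and time-lapse
interval tau_TL = tau_int + tau_delay is observed for n consecutive frames;
its measured residence time is tau_measured = (n - 1) * tau_TL.  The
apparent decay rate k_app_diss of the residence-time distribution mixes the
true dissociation rate with photobleaching.  Because photobleaching only
acts during the (fixed) integration time, the two separate linearly:

    k_app_diss * tau_TL = k_diss * tau_TL + k_bleaching * tau_int

so a weighted regression of k_app*tau_TL on tau_TL gives k_diss as the
slope and k_bleaching * tau_int as the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import statsmodels.api as sm

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import TrajectorySet

__all__ = [
    "DwellDataset",
    "DwellFit",
    "fit_apparent_rate",
    "fit_dissociation",
    "detect_stationary_dwells",
    "mean_dwell_time",
]


def mean_dwell_time(k_diss: float) -> float:
    """Mean chromatin-bound dwell time implied by an exponential model, 1/k_diss."""
    if k_diss <= 0:
        raise ValueError("k_diss must be > 0")
    return 1.0 / k_diss


@dataclass
class DwellDataset:
    """Residence-time observations at one or more time-lapse intervals.

    ``observations`` columns: ``tau_tl_s, tau_int_s, n_frames`` (one row per
    molecule).  ``tau_measured`` is the derived (n-1)*tau_TL per observation.
    """

    observations: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        obs = self.observations
        req = {"tau_tl_s", "tau_int_s", "n_frames"}
        if not req.issubset(obs.columns):
            raise ValueError(f"observations must have columns {sorted(req)}")
        if (obs["n_frames"] < 1).any():
            raise ValueError("n_frames must be >= 1")
        if (obs["tau_int_s"] <= 0).any() or (obs["tau_tl_s"] < obs["tau_int_s"] - 1e-12).any():
            raise ValueError("need tau_TL >= tau_int > 0")

    @property
    def tau_measured(self) -> np.ndarray:
        o = self.observations
        return ((o["n_frames"] - 1) * o["tau_tl_s"]).to_numpy(dtype=float)

    @property
    def intervals(self) -> np.ndarray:
        return np.sort(self.observations["tau_tl_s"].unique())


@dataclass
class DwellFit:
    """Result of the two-term photobleaching-corrected dissociation fit."""

    per_interval: pd.DataFrame  # tau_tl_s, k_app, k_app_se, n_used
    k_diss: float
    k_diss_se: float
    k_bleaching: float
    k_bleaching_se: float
    flags: list[str] = field(default_factory=list)

    @property
    def mean_dwell(self) -> float:
        """Mean dwell time 1/k_diss (the identity mean_dwell * k_diss = 1)."""
        return mean_dwell_time(self.k_diss)


def fit_apparent_rate(
    dwells: DwellDataset | pd.DataFrame,
    tau_tl: float | None = None,
    method: str = "decay",
) -> tuple[float, float]:
    """Apparent dissociation rate at a single time-lapse interval.

    Observations with n_frames == 1 carry no measurable dwell and are
    excluded; at least 10 multi-frame observations are required.

    method="decay" (default)
        Fits the residence-time distribution to exp(-k_app * tau_measured),
        honouring the frame quantization of tau_measured: with geometric
        frame counts the distribution decays by a factor p per interval, so
        k_app = -ln(p_hat) / tau_TL with p_hat = 1 - 1/mean(n - 1 | n >= 2).
        Unbiased for frame-quantized dwells of any coarseness.
    method="mean"
        Continuous-exponential MLE k_app = 1/mean(tau_measured > 0); biased
        low when k_app * tau_TL is not small.

    Returns (k_app, standard error).
    """
    obs = dwells.observations if isinstance(dwells, DwellDataset) else dwells
    if tau_tl is not None:
        obs = obs[np.isclose(obs["tau_tl_s"], tau_tl)]
    tls = obs["tau_tl_s"].unique()
    if len(tls) != 1:
        raise ValueError("fit_apparent_rate needs observations at a single tau_TL")
    tau = float(tls[0])
    m_frames = obs.loc[obs["n_frames"] >= 2, "n_frames"].to_numpy(dtype=float)
    if len(m_frames) == 0:
        raise ValueError("all observations are single-frame: no measurable dwells")
    if len(m_frames) < 10:
        raise ValueError("need >= 10 multi-frame observations")
    m = len(m_frames)
    if method == "mean":
        tau_meas = (m_frames - 1) * tau
        k = 1.0 / tau_meas.mean()
        return k, k / np.sqrt(m)
    if method != "decay":
        raise ValueError(f"unknown method {method!r}")
    mbar = (m_frames - 1).mean()  # mean of a geometric(1-p) on {1, 2, ...}
    p = 1.0 - 1.0 / mbar
    if p <= 0:  # every dwell exactly 2 frames: decay faster than resolvable
        p = 1.0 / (2.0 * m)  # vanishing survival; rate dominated by 1/tau
    k = -np.log(p) / tau
    # delta method through p_hat = 1 - 1/mean(n-1)
    var_mbar = p / ((1 - p) ** 2 * m)
    se = np.sqrt(var_mbar) * (1 - p) ** 2 / (p * tau)
    return float(k), float(se)


def regress_apparent(
    tau_tl: np.ndarray,
    k_app: np.ndarray,
    k_app_se: np.ndarray,
    tau_int: float,
) -> tuple[float, float, float, float]:
    """Two-term weighted regression separating dissociation and bleaching.

    Regresses y = k_app*tau_TL on x = tau_TL with weights 1/var(y)
    propagated from the per-interval exponential fits; returns
    (k_diss, k_diss_se, k_bleaching, k_bleaching_se).  With exact inputs
    k_app = k_d + k_b*tau_int/tau_TL the slope and intercept are recovered
    exactly (the relationship is linear in tau_TL).
    """
    x = np.asarray(tau_tl, dtype=float)
    y = np.asarray(k_app, dtype=float) * x
    var_y = (np.asarray(k_app_se, dtype=float) * x) ** 2
    var_y = np.where(var_y > 0, var_y, np.min(var_y[var_y > 0]) if (var_y > 0).any() else 1.0)
    model = sm.WLS(y, sm.add_constant(x), weights=1.0 / var_y).fit()
    intercept, slope = model.params
    se_intercept, se_slope = model.bse
    return float(slope), float(se_slope), float(intercept / tau_int), float(se_intercept / tau_int)


def fit_dissociation(data: DwellDataset, method: str = "decay") -> DwellFit:
    """Separate true dissociation from photobleaching across intervals.

    Fits k_app at each tau_TL, then the weighted regression of
    ``regress_apparent``.  Slope -> k_diss; intercept / tau_int ->
    k_bleaching.
    """
    intervals = data.intervals
    if len(intervals) < 2:
        raise ValueError("need >= 2 distinct tau_TL values")
    tau_int = float(data.observations["tau_int_s"].iloc[0])
    if not np.allclose(data.observations["tau_int_s"], tau_int):
        raise ValueError("tau_int must be identical across observations")
    rows = []
    for tau in intervals:
        sub = data.observations[np.isclose(data.observations["tau_tl_s"], tau)]
        k, se = fit_apparent_rate(sub, method=method)
        rows.append({"tau_tl_s": tau, "k_app": k, "k_app_se": se,
                     "n_used": int((sub["n_frames"] >= 2).sum())})
    per = pd.DataFrame(rows)

    slope, se_slope, k_bleach, k_bleach_se = regress_apparent(
        per["tau_tl_s"].to_numpy(), per["k_app"].to_numpy(),
        per["k_app_se"].to_numpy(), tau_int,
    )
    flags: list[str] = []
    if slope <= 0:
        flags.append("non-positive dissociation slope")
        warnings.warn("fitted dissociation slope is non-positive", stacklevel=2)
    if k_bleach < -3 * k_bleach_se:
        flags.append("significantly negative photobleaching intercept")
    return DwellFit(
        per_interval=per,
        k_diss=slope,
        k_diss_se=se_slope,
        k_bleaching=k_bleach,
        k_bleaching_se=k_bleach_se,
        flags=flags,
    )


def detect_stationary_dwells(data: "TrajectorySet", r_stat: float | None = None) -> DwellDataset:
    """Extract stationary-signal dwells from trajectories.

    A dwell is a maximal run of consecutive frames in which every
    localization lies within ``r_stat`` of the run's first localization
    (no gap frames allowed).  Default r_stat is 3 * sigma_loc.  Runs are
    emitted as (tau_TL = tau_int = dt_frame, n_frames) observations.
    """
    if r_stat is None:
        r_stat = 3.0 * data.sigma_loc
    if r_stat <= 0:
        raise ValueError("r_stat must be > 0")
    counts = []
    df = data.df.sort_values(["track_id", "frame"], kind="mergesort")
    for _, grp in df.groupby("track_id", sort=False):
        x = grp["x_um"].to_numpy()
        y = grp["y_um"].to_numpy()
        fr = grp["frame"].to_numpy()
        i = 0
        n = len(grp)
        while i < n:
            j = i + 1
            while (
                j < n
                and fr[j] - fr[j - 1] == 1
                and (x[j] - x[i]) ** 2 + (y[j] - y[i]) ** 2 <= r_stat**2
            ):
                j += 1
            counts.append(j - i)
            i = j
    obs = pd.DataFrame(
        {
            "tau_tl_s": data.dt_frame,
            "tau_int_s": data.dt_frame,
            "n_frames": np.asarray(counts, dtype=np.int64),
        }
    )
    return DwellDataset(obs)
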