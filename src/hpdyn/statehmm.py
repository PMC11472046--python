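"""Bayesian inference of diffusive mobility states from trajectories.

A finite-K hidden Markov model over single-molecule steps: each step
d = (dx, dy) between consecutive frames is emitted, given hidden state k,
with independent coordinates Normal(0, s_k^2) where

    s_k^2 = 2 * D_k * dt_frame + 2 * sigma_loc^2

(free 2-D diffusion blurred by localization error at both endpoints; the
small noise covariance between consecutive steps is deliberately ignored).
States switch between frames with a per-frame transition matrix.  Inference
is a Gibbs sampler alternating forward-filtering backward-sampling of the
step labels, conjugate inverse-gamma updates of the per-state variances,
and Dirichlet updates of the transition rows.  States are relabeled in
ascending diffusion coefficient every sweep, making output deterministic
for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .simulate import TrajectorySet, stationary_distribution

__all__ = ["HmmConfig", "MobilityModel", "infer_states", "select_K", "occupancy_and_transitions"]


@dataclass
class HmmConfig:
    """Sampler configuration.

    ``alpha`` is the Dirichlet concentration for transition rows and the
    initial-state distribution; (``a0``, ``b0_scale``) set the inverse-gamma
    prior on per-coordinate step variances, with scale b0 = b0_scale *
    mean squared displacement (a weak data-scaled prior).
    """

    K: int | None = None
    K_range: Sequence[int] = (1, 2, 3, 4, 5)
    iterations: int = 1200
    burn_in: int = 300
    alpha: float = 1.0
    a0: float = 2.0
    b0_scale: float = 0.5
    rhat_threshold: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        if self.iterations <= self.burn_in or self.burn_in < 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class MobilityModel:
    """Posterior summary of a K-state mobility model.

    D, D_sd: posterior mean and s.d. of per-state diffusion coefficients
    (um^2/s, ascending); pi: weight fractions (posterior mean fraction of
    steps assigned to each state); T_frame: posterior-mean per-frame
    transition matrix; log_marginal: step log-likelihood at the posterior
    means (used for model selection); diagnostics: chain settings,
    split-chain R-hat per state variance, convergence flag, and the
    stationary distribution of T_frame for comparison with pi.
    """

    K: int
    D: np.ndarray
    D_sd: np.ndarray
    pi: np.ndarray
    T_frame: np.ndarray
    dt_frame: float
    sigma_loc: float
    log_marginal: float
    n_steps: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.D) >= -1e-12), "states must be ordered by D"
        assert abs(self.pi.sum() - 1) < 1e-9
        assert np.allclose(self.T_frame.sum(axis=1), 1.0, atol=1e-9)

    @property
    def n_params(self) -> int:
        return self.K + self.K * (self.K - 1) + (self.K - 1)


@njit(cache=True)
def _ffbs(loglik, starts, T, pi0, u, labels):  # pragma: no cover - numba
    """Forward-filter backward-sample labels for all tracks.

    loglik: (n_steps, K) per-step emission log-likelihoods; starts: track
    boundary offsets (len n_tracks+1); u: one uniform per step.  Fills
    ``labels`` in place and returns the total log marginal likelihood.
    """
    K = loglik.shape[1]
    total = 0.0
    alpha = np.empty((loglik.shape[0], K))
    for tr in range(starts.shape[0] - 1):
        a, b = starts[tr], starts[tr + 1]
        # forward pass, normalized
        for t in range(a, b):
            mx = loglik[t, 0]
            for k in range(1, K):
                if loglik[t, k] > mx:
                    mx = loglik[t, k]
            s = 0.0
            for k in range(K):
                if t == a:
                    pred = pi0[k]
                else:
                    pred = 0.0
                    for j in range(K):
                        pred += alpha[t - 1, j] * T[j, k]
                alpha[t, k] = pred * np.exp(loglik[t, k] - mx)
                s += alpha[t, k]
            for k in range(K):
                alpha[t, k] /= s
            total += np.log(s) + mx
        # backward sampling
        t = b - 1
        c = 0.0
        z = K - 1
        for k in range(K):
            c += alpha[t, k]
            if u[t] <= c:
                z = k
                break
        labels[t] = z
        for t in range(b - 2, a - 1, -1):
            s = 0.0
            for k in range(K):
                s += alpha[t, k] * T[k, labels[t + 1]]
            c = 0.0
            z = K - 1
            for k in range(K):
                c += alpha[t, k] * T[k, labels[t + 1]] / s
                if u[t] <= c:
                    z = k
                    break
            labels[t] = z
    return total


def emission_loglik(d2: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Per-step emission log-likelihood matrix.

    d2: squared step magnitudes dx^2 + dy^2; per state with per-coordinate
    variance v: log N(dx; 0, v) + log N(dy; 0, v) = -log(2 pi v) - d2/(2 v).
    """
    v = variances[None, :]
    return -np.log(2 * np.pi * v) - d2[:, None] / (2 * v)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain R-hat of a single scalar chain (split into two halves)."""
    n = len(chains) // 2
    if n < 2:
        return np.nan
    halves = np.stack([chains[:n], chains[len(chains) - n:]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (n * w)))


def _prepare_steps(data: TrajectorySet) -> tuple[np.ndarray, np.ndarray]:
    steps = data.steps()
    d2 = (steps["dx"].to_numpy() ** 2 + steps["dy"].to_numpy() ** 2).astype(float)
    sizes = steps.groupby("track_id", sort=False).size().to_numpy()
    starts = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
    return d2, starts


def infer_states(data: TrajectorySet, config: HmmConfig) -> MobilityModel:
    """Gibbs sampler for the fixed-K mobility-state HMM."""
    config.validate()
    if config.K is None:
        raise ValueError("config.K must be set (use select_K for model selection)")
    K = config.K
    d2, starts = _prepare_steps(data)
    n = len(d2)
    if n < 1000:
        warnings.warn(f"only {n} steps; >= 1000 recommended for robust inference", stacklevel=2)
    if n < 2 * K:
        raise ValueError(f"K={K} exceeds the support of {n} steps")
    rng = np.random.default_rng(config.seed)
    dt, sig = data.dt_frame, data.sigma_loc

    # initialize labels by quantiles of the squared displacement (ascending)
    order = np.argsort(np.argsort(d2))
    labels = (order * K // n).astype(np.int64)
    b0 = config.b0_scale * d2.mean() / 2.0  # per-coordinate scale

    n_keep = config.iterations - config.burn_in
    keep_v = np.empty((n_keep, K))
    keep_T = np.empty((n_keep, K, K))
    keep_occ = np.empty((n_keep, K))
    variances = np.empty(K)
    T = np.full((K, K), 1.0 / K)
    pi0 = np.full(K, 1.0 / K)

    for it in range(config.iterations):
        # (b) per-state variance, conjugate inverse-gamma update
        for k in range(K):
            mask = labels == k
            nk = 2 * mask.sum()  # two coordinates per step
            ssq = d2[mask].sum()
            shape = config.a0 + nk / 2.0
            scale = b0 + ssq / 2.0
            variances[k] = scale / rng.gamma(shape)
        # relabel ascending in variance (hence in D) before label sampling
        perm = np.argsort(variances, kind="stable")
        variances = variances[perm]
        inv = np.empty(K, dtype=np.int64)
        inv[perm] = np.arange(K)
        labels = inv[labels]
        T = T[np.ix_(perm, perm)]
        pi0 = pi0[perm]
        # (c) transition rows and initial distribution, Dirichlet updates
        first = labels[starts[:-1]]
        counts = np.zeros((K, K))
        src = labels[:-1].copy()
        dst = labels[1:]
        boundary = np.zeros(n, dtype=bool)
        boundary[starts[1:-1]] = True  # first step of each later track
        ok = ~boundary[1:]
        np.add.at(counts, (src[ok], dst[ok]), 1)
        for k in range(K):
            T[k] = rng.dirichlet(config.alpha + counts[k])
        pi0 = rng.dirichlet(config.alpha + np.bincount(first, minlength=K))
        # (a) labels via FFBS
        ll = emission_loglik(d2, variances)
        u = rng.random(n)
        _ffbs(ll, starts, T, pi0, u, labels)
        if it >= config.burn_in:
            j = it - config.burn_in
            keep_v[j] = variances
            keep_T[j] = T
            keep_occ[j] = np.bincount(labels, minlength=K) / n

    v_mean = keep_v.mean(axis=0)
    v_sd = keep_v.std(axis=0, ddof=1) if n_keep > 1 else np.zeros(K)
    D = np.maximum(0.0, (v_mean / 2.0 - sig**2) / dt)
    D_sd = v_sd / (2.0 * dt)
    pi = keep_occ.mean(axis=0)
    pi = pi / pi.sum()
    T_mean = keep_T.mean(axis=0)
    T_mean = T_mean / T_mean.sum(axis=1, keepdims=True)

    # marginal step likelihood at the posterior means (forward pass only)
    tmp_labels = np.zeros(n, dtype=np.int64)
    log_marg = _ffbs(
        emission_loglik(d2, v_mean), starts, T_mean,
        stationary_distribution(T_mean), np.zeros(n), tmp_labels,
    )

    rhats = np.array([_split_rhat(keep_v[:, k]) for k in range(K)])
    converged = bool(np.all(np.nan_to_num(rhats, nan=1.0) < config.rhat_threshold))
    if not converged:
        warnings.warn(f"chains not converged: split R-hat = {np.round(rhats, 3)}", stacklevel=2)
    sep = np.diff(D) / np.maximum(D[:-1], 1e-12) if K > 1 else np.array([])
    if K > 1 and np.any(sep < 0.1):
        warnings.warn("two states have nearly identical D; consider merging (smaller K)", stacklevel=2)
    diagnostics = {
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "split_rhat": rhats,
        "converged": converged,
        "pi_sd": keep_occ.std(axis=0, ddof=1) if n_keep > 1 else np.zeros(K),
        "T_sd": keep_T.std(axis=0, ddof=1) if n_keep > 1 else np.zeros((K, K)),
        "stationary_of_T": stationary_distribution(T_mean),
        "seed": config.seed,
    }
    return MobilityModel(
        K=K, D=D, D_sd=D_sd, pi=pi, T_frame=T_mean, dt_frame=dt,
        sigma_loc=sig, log_marginal=float(log_marg), n_steps=n,
        diagnostics=diagnostics,
    )


def select_K(data: TrajectorySet, config: HmmConfig) -> int:
    """Choose the state count by BIC on the marginal step likelihood.

    Fits each K in ``config.K_range`` and returns the K minimizing
    BIC = -2 * log_marginal + n_params * ln(n_steps); ties (within 1e-9)
    break toward smaller K.
    """
    config.validate()
    best_K, best_bic = None, np.inf
    for K in sorted(config.K_range):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = infer_states(data, replace(config, K=K))
        bic = -2.0 * model.log_marginal + model.n_params * np.log(model.n_steps)
        if bic < best_bic - 1e-9:
            best_K, best_bic = K, bic
    return int(best_K)


def occupancy_and_transitions(model: MobilityModel) -> pd.DataFrame:
    """Summary table: D_k +/- s.d., pi_k, and per-frame transition rows."""
    rows = {}
    rows["state"] = np.arange(model.K)
    rows["D_um2_s"] = model.D
    rows["D_sd_um2_s"] = model.D_sd
    rows["pi"] = model.pi
    for j in range(model.K):
        rows[f"P_to_{j}"] = model.T_frame[:, j]
    return pd.DataFrame(rows)
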