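"""Minimal trajectory-decoding paradigm: a linear tuning model generates
multi-channel observation streams from 2-D pen trajectories, a Kalman filter
decodes position, and Pearson correlation scores trajectory fidelity.

This is a synthetic stand-in for a handwriting-reconstruction task on a
restricted dataset: trajectories are smoothed random-walk pen strokes, the
observations are continuous envelope-like features (96 channels, 50 ms bins)
rather than spike counts, and the decoder is a standard constant-velocity
Kalman filter.  Its purpose is to expose how distortion injected into the
observation streams degrades the decoded-trajectory correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuningModel",
    "TrajectoryScore",
    "default_tuning_model",
    "make_strokes",
    "trajectory_states",
    "simulate_observations",
    "kalman_decode",
    "pearson_cc",
    "score_trajectory",
]


@dataclass
class TuningModel:
    """Linear-Gaussian state-space tuning: obs = H s + N(0, R),
    s_{t+1} = A s_t + N(0, Q), state s = (x, y, vx, vy)."""

    H: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)
    A: np.ndarray = field(repr=False)
    Q: np.ndarray = field(repr=False)
    bin_s: float = 0.05

    def __post_init__(self) -> None:
        n_state = self.A.shape[0]
        if self.A.shape != (n_state, n_state) or self.Q.shape != (n_state, n_state):
            raise ValueError("A and Q must be square and consistent")
        if self.H.shape[1] != n_state:
            raise ValueError("H columns must match the state dimension")
        n_ch = self.H.shape[0]
        if self.R.shape != (n_ch, n_ch):
            raise ValueError("R must be channels x channels")
        for name, m in (("R", self.R), ("Q", self.Q)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-12:
                raise ValueError(f"{name} must be positive semi-definite")


@dataclass(frozen=True)
class TrajectoryScore:
    cc_x: float
    cc_y: float

    @property
    def cc_mean(self) -> float:
        return 0.5 * (self.cc_x + self.cc_y)


def default_tuning_model(
    n_channels: int = 96, bin_s: float = 0.05, obs_noise: float = 2.0, seed: int = 12345
) -> TuningModel:
    """Constant-velocity transition, random Gaussian channel loadings, and
    isotropic observation noise sized for a high-but-imperfect single-trial
    decode (CC ~ 0.98 on the default strokes)."""
    dt = bin_s
    A = np.array(
        [[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
    )
    q = 0.1
    Q = np.diag([1e-6, 1e-6, q * dt, q * dt])
    rng = np.random.default_rng(seed)
    H = rng.standard_normal((n_channels, 4))
    R = obs_noise**2 * np.eye(n_channels)
    return TuningModel(H=H, R=R, A=A, Q=Q, bin_s=bin_s)


def make_strokes(
    n_trials: int = 15, n_bins: int = 60, seed: int = 0
) -> list[np.ndarray]:
    """Smoothed random-walk pen strokes, one (n_bins x 2) array per trial,
    standardized to zero mean and unit variance per axis."""
    rng = np.random.default_rng(seed)
    strokes = []
    for _ in range(n_trials):
        steps = rng.standard_normal((n_bins + 40, 2))
        # moving-average smoothing produces pen-stroke-like curvature
        kernel = np.hanning(21)
        kernel /= kernel.sum()
        vel = np.column_stack(
            [np.convolve(steps[:, i], kernel, mode="same") for i in range(2)]
        )
        pos = np.cumsum(vel, axis=0)[40:]
        pos -= pos.mean(axis=0)
        sd = pos.std(axis=0)
        sd[sd == 0] = 1.0
        strokes.append(pos / sd)
    return strokes


def trajectory_states(trajectory: np.ndarray, bin_s: float) -> np.ndarray:
    """Stack (x, y, vx, vy) per bin; velocity by first differences."""
    pos = np.asarray(trajectory, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("trajectory must be n_bins x 2")
    vel = np.gradient(pos, bin_s, axis=0)
    return np.hstack([pos, vel])


def simulate_observations(
    trajectory: np.ndarray, model: TuningModel, seed: int = 0
) -> np.ndarray:
    """Channel x bin observation matrix obs = H s + N(0, R)."""
    states = trajectory_states(trajectory, model.bin_s)
    clean = model.H @ states.T
    rng = np.random.default_rng(seed)
    if np.any(model.R):
        chol = np.linalg.cholesky(model.R + 1e-12 * np.eye(len(model.R)))
        clean = clean + chol @ rng.standard_normal(clean.shape)
    return clean


def kalman_decode(observations: np.ndarray, model: TuningModel) -> np.ndarray:
    """Standard predict/update Kalman recursion; returns n_bins x 2 decoded
    positions.  The state is initialized diffusely at zero."""
    obs = np.asarray(observations, dtype=float)
    n_ch, n_bins = obs.shape
    if n_ch != model.H.shape[0]:
        raise ValueError("observation channels do not match the model")
    n_state = model.A.shape[0]
    x = np.zeros(n_state)
    P = np.eye(n_state) * 10.0
    H, R, A, Q = model.H, model.R, model.A, model.Q
    out = np.zeros((n_bins, n_state))
    for t in range(n_bins):
        # predict
        x = A @ x
        P = A @ P @ A.T + Q
        # update
        S = H @ P @ H.T + R
        K = np.linalg.solve(S, H @ P).T
        innov = obs[:, t] - H @ x
        x = x + K @ innov
        P = (np.eye(n_state) - K @ H) @ P
        out[t] = x
    return out[:, :2]


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation coefficient of two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: correlation undefined")
    am = a - a.mean()
    bm = b - b.mean()
    return float(am @ bm / math.sqrt((am @ am) * (bm @ bm)))


def score_trajectory(decoded: np.ndarray, reference: np.ndarray) -> TrajectoryScore:
    return TrajectoryScore(
        cc_x=pearson_cc(decoded[:, 0], reference[:, 0]),
        cc_y=pearson_cc(decoded[:, 1], reference[:, 1]),
    )
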