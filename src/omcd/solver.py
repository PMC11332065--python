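"""Finite-horizon optimal stopping over the value-mode difference.

Backward induction (Bellman recursion) over a discretized state
``dmu = mu1 - mu2``: at each decision time the controller compares the
net benefit of stopping now with the expected optimal net benefit of
continuing one more step, where the one-step transition is a Gaussian
random walk kernel (variance ``2*gamma*kappa`` per step in the generic
model, or a time-varying variance for ideal controllers that know the
true decision process).

The optimal rule is state-wise ("stop iff stop-value >= continuation
value", ties stop); because both quantities are monotone in |dmu|, it
reduces to a time-indexed critical mode difference ``dmu_star(t)``, a
net-benefit threshold ``omega_star(t)`` and -- when the benefit is
R * confidence -- an equivalent confidence threshold ``omega_P(t)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.linalg import toeplitz
from scipy.stats import norm

from .core import MCDParams, confidence, precision_growth

__all__ = [
    "StateGrid",
    "TransitionKernel",
    "ThresholdPolicy",
    "build_grid",
    "stationary_kernel",
    "time_varying_kernel",
    "gaussian_step_matrix",
    "confidence_benefit",
    "max_value_benefit",
    "solve_optimal_stopping",
    "confidence_threshold",
    "apply_policy",
]


@dataclass(frozen=True)
class StateGrid:
    """Uniform symmetric grid over the value-mode difference dmu."""

    points: np.ndarray
    center: float
    half_width: float
    degenerate: bool = False  # gamma == 0: single-point (deterministic) state

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def spacing(self) -> float:
        if self.n < 2:
            return 0.0
        return float(self.points[1] - self.points[0])


def build_grid(
    params: MCDParams, n_points: int = 513, width_mult: float = 6.0
) -> StateGrid:
    """Discretize dmu over ``dmu0 +/- width_mult * sqrt(2*gamma*kappa*T)``.

    The default span (6 standard deviations of the terminal-state
    dispersion) keeps the probability mass escaping the grid below 1e-6.
    ``gamma == 0`` yields a degenerate single-point grid (the state never
    moves) and flags the analytic fast path.
    """
    if width_mult <= 0:
        raise ValueError("width_mult must be > 0")
    center = params.delta_mu0
    if params.gamma == 0:
        return StateGrid(
            points=np.array([center]), center=center, half_width=0.0, degenerate=True
        )
    if n_points < 33 or n_points % 2 == 0:
        raise ValueError("n_points must be an odd integer >= 33")
    half_width = width_mult * np.sqrt(2.0 * params.gamma * params.kappa * params.T)
    pts = np.linspace(center - half_width, center + half_width, n_points)
    return StateGrid(points=pts, center=center, half_width=float(half_width))


def gaussian_step_matrix(grid: StateGrid, step_var: float) -> np.ndarray:
    """Row-stochastic matrix of a Gaussian step N(x_i, step_var) on the grid.

    Each row integrates the Gaussian density over grid cells (cell edges
    at midpoints, outer cells absorbing the tails), which is exact even
    when the step standard deviation is smaller than the cell width.
    Rows are renormalized to sum to 1 within 1e-10.
    """
    n = grid.n
    if step_var < 0:
        raise ValueError("step variance must be >= 0")
    if step_var == 0.0 or n == 1:
        return np.eye(n)
    sd = np.sqrt(step_var)
    h = grid.spacing
    # Cell edge j - state i distance depends only on (j - i): build the
    # whole matrix from one vector of CDF values (Toeplitz structure).
    m = np.arange(-n, n + 1)
    cdf = norm.cdf((m + 0.5) * h / sd)  # Phi at edge offsets
    pm = cdf[1:] - cdf[:-1]  # interior cell mass for offsets -n..n-1
    col = pm[n - 1 :: -1]  # offsets 0,-1,...,-(n-1)
    row = pm[n - 1 : 2 * n - 1]  # offsets 0,1,...,n-1
    P = toeplitz(col, row)
    # outer cells absorb the tails
    P[:, 0] = cdf[n - np.arange(n)]  # Phi((0 - i + 0.5) h / sd)
    P[:, -1] = 1.0 - cdf[2 * n - 1 - np.arange(n) - 1]
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass(frozen=True)
class TransitionKernel:
    """One-step transition matrices of dmu, possibly time-indexed.

    ``matrices[s]`` is the transition from time ``s`` to ``s + 1``
    (``s = 0 .. T-1``) for a non-stationary kernel; a stationary kernel
    stores a single matrix.
    """

    grid: StateGrid
    matrices: np.ndarray  # (n, n) if stationary else (T, n, n)
    stationary: bool = True

    def step_matrix(self, s: int) -> np.ndarray:
        """Transition matrix from time s to s + 1."""
        if self.stationary:
            return self.matrices
        return self.matrices[s]


def stationary_kernel(grid: StateGrid, gamma: float, kappa: float) -> TransitionKernel:
    """Stationary random-walk kernel: dmu(t) ~ N(dmu(t-1), 2*gamma*kappa)."""
    if gamma < 0 or kappa <= 0:
        raise ValueError("need gamma >= 0 and kappa > 0")
    step_var = 2.0 * gamma * kappa
    if 0 < step_var and np.sqrt(step_var) < grid.spacing:
        warnings.warn(
            f"step sd {np.sqrt(step_var):.3g} below cell width {grid.spacing:.3g}; "
            "rows stay exact by cell integration, but consider a finer grid",
            RuntimeWarning,
            stacklevel=2,
        )
    P = gaussian_step_matrix(grid, step_var)
    return TransitionKernel(grid=grid, matrices=P, stationary=True)


def time_varying_kernel(grid: StateGrid, step_vars: Sequence[float]) -> TransitionKernel:
    """Kernel with a per-step Gaussian increment variance (length T)."""
    mats = np.stack([gaussian_step_matrix(grid, v) for v in step_vars])
    return TransitionKernel(grid=grid, matrices=mats, stationary=False)


def confidence_benefit(
    params: MCDParams, sigma_of_t: Optional[Callable[[int], tuple]] = None
) -> Callable:
    """Benefit term R * P_c(dmu, t) with variances from the precision law.

    ``sigma_of_t`` overrides the default Eq-3-style variance schedule
    (used by ideal controllers that know the true variance dynamics);
    it maps t to the pair (sigma1(t), sigma2(t)).
    """
    if sigma_of_t is None:

        def sigma_of_t(t):
            return tuple(precision_growth(params, params.kappa * t))

    def benefit(x, t):
        s1, s2 = sigma_of_t(t)
        return params.R * confidence(x, s1, s2)

    benefit.is_confidence = True
    return benefit


def max_value_benefit(params: MCDParams) -> Callable:
    """Benefit term R * E[value of the chosen option].

    The chosen option is the higher-mode one, so its expected value is
    ``mean(mu0) + |dmu|/2`` (the mode sum is a martingale, hence its
    expectation stays at the prior mean).  Independent of the belief
    variances, hence of type-1 effort efficacy.
    """
    mu_bar0 = 0.5 * (params.mu0[0] + params.mu0[1])

    def benefit(x, t):
        return params.R * (mu_bar0 + 0.5 * np.abs(np.asarray(x, dtype=float)))

    benefit.is_confidence = False
    return benefit


@dataclass
class ThresholdPolicy:
    """Time-indexed optimal stopping thresholds (t = 1..T).

    ``omega_star[t-1]`` is the net-benefit threshold, ``omega_P[t-1]``
    the equivalent confidence threshold (confidence benefits only) and
    ``delta_mu_star[t-1]`` the critical |dmu| beyond which stopping is
    optimal.  ``flags[t-1]`` records threshold pathologies:
    "ok", "stop_everywhere" (dmu_star = 0), "continue_everywhere"
    (dmu_star = inf) or "multiple_crossings".
    """

    times: np.ndarray
    omega_star: np.ndarray
    omega_P: Optional[np.ndarray]
    delta_mu_star: np.ndarray
    grid: StateGrid
    params: MCDParams
    is_confidence: bool = True
    value_function: Optional[np.ndarray] = None  # Q*(x, t), shape (T, n)
    stop_value: Optional[np.ndarray] = None  # S(x, t), shape (T, n)
    flags: Optional[List[str]] = None

    @property
    def T(self) -> int:
        return len(self.times)

    # -- application -------------------------------------------------

    def stop_times(self, conf: np.ndarray, delta_mu: np.ndarray) -> np.ndarray:
        """First stopping time for each trajectory (vectorized).

        ``conf`` and ``delta_mu`` have shape (n_traj, T + 1), columns
        indexed by decision time 0..T.  Confidence-benefit policies stop
        the first time confidence reaches ``omega_P(t)``; other policies
        threshold |dmu - dmu0| against ``delta_mu_star(t)``.  Ties stop;
        the horizon forces a stop at T.
        """
        conf = np.atleast_2d(conf)
        delta_mu = np.atleast_2d(delta_mu)
        if conf.shape[1] < self.T + 1:
            raise ValueError(
                f"trajectory covers {conf.shape[1] - 1} steps, horizon is {self.T}"
            )
        if self.is_confidence and self.omega_P is not None:
            crossed = conf[:, 1 : self.T + 1] >= self.omega_P[None, :]
        else:
            dev = np.abs(delta_mu[:, 1 : self.T + 1] - self.grid.center)
            crossed = dev >= self.delta_mu_star[None, :]
        any_cross = crossed.any(axis=1)
        first = np.argmax(crossed, axis=1) + 1
        return np.where(any_cross, first, self.T).astype(int)

    # -- serialization -----------------------------------------------

    def to_json(self) -> str:
        payload = {
            "times": self.times.tolist(),
            "omega_star": self.omega_star.tolist(),
            "omega_P": None if self.omega_P is None else self.omega_P.tolist(),
            "delta_mu_star": self.delta_mu_star.tolist(),
            "is_confidence": self.is_confidence,
            "flags": self.flags,
            "grid": {
                "n_points": self.grid.n,
                "center": self.grid.center,
                "half_width": self.grid.half_width,
                "degenerate": self.grid.degenerate,
            },
            "params": {
                "R": self.params.R,
                "alpha": self.params.alpha,
                "nu": self.params.nu,
                "beta": self.params.beta,
                "gamma": self.params.gamma,
                "kappa": self.params.kappa,
                "mu0": list(self.params.mu0),
                "sigma0": list(self.params.sigma0),
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdPolicy":
        d = json.loads(text)
        g = d["grid"]
        if g["degenerate"]:
            grid = StateGrid(
                points=np.array([g["center"]]),
                center=g["center"],
                half_width=0.0,
                degenerate=True,
            )
        else:
            grid = StateGrid(
                points=np.linspace(
                    g["center"] - g["half_width"],
                    g["center"] + g["half_width"],
                    g["n_points"],
                ),
                center=g["center"],
                half_width=g["half_width"],
            )
        return cls(
            times=np.array(d["times"], dtype=int),
            omega_star=np.array(d["omega_star"], dtype=float),
            omega_P=None if d["omega_P"] is None else np.array(d["omega_P"], dtype=float),
            delta_mu_star=np.array(d["delta_mu_star"], dtype=float),
            grid=grid,
            params=MCDParams(**d["params"]),
            is_confidence=d["is_confidence"],
            flags=d["flags"],
        )


def _extract_threshold(x, center, D, benefit, cost_t, t):
    """Critical |dmu| where stop value first dominates continuation.

    Scans the positive branch of the (symmetric) grid for the sign
    change of D = stop - continuation and interpolates linearly.
    Returns (dmu_star, stop_value_at_crossing, flag).
    """
    pos = x >= center - 1e-12
    xp = x[pos] - center
    Dp = D[pos]
    nonneg = Dp >= 0
    if nonneg.all():
        flag = "stop_everywhere"
        xc = 0.0
    elif not nonneg.any():
        return np.inf, np.inf, "continue_everywhere"
    else:
        i = int(np.argmax(nonneg))  # first index with D >= 0
        if i == 0:
            xc = 0.0
        else:
            d0, d1 = Dp[i - 1], Dp[i]
            xc = xp[i - 1] + (xp[i] - xp[i - 1]) * (0.0 - d0) / (d1 - d0)
        flag = "ok" if nonneg[i:].all() else "multiple_crossings"
    sval = float(np.asarray(benefit(center + xc, t))) - cost_t
    return float(xc), sval, flag


def solve_optimal_stopping(
    params: MCDParams,
    kernel: TransitionKernel,
    benefit: Optional[Callable] = None,
) -> ThresholdPolicy:
    """Backward induction for the optimal stopping thresholds.

    At each time t the stop value is ``S(x, t) = benefit(x, t) -
    alpha*(kappa*t)**nu`` and the continuation value is the kernel
    expectation of the optimal net benefit one step ahead; stopping is
    forced at the horizon.  Expectations are deterministic matrix-vector
    products.  ``benefit`` defaults to ``R * P_c`` with the precision
    law; any finite benefit(x, t) works (e.g. :func:`max_value_benefit`).
    """
    if benefit is None:
        benefit = confidence_benefit(params)
    is_conf = bool(getattr(benefit, "is_confidence", False))
    T = params.T
    x = kernel.grid.points
    center = kernel.grid.center
    n = len(x)
    costs = np.asarray(params.cost(np.arange(T + 1)))

    S = np.empty((T, n))
    for t in range(1, T + 1):
        S[t - 1] = np.asarray(benefit(x, t), dtype=float) - costs[t]
        if not np.all(np.isfinite(S[t - 1])):
            raise ValueError(f"benefit is not finite on the grid at t={t}")

    Q = np.empty((T, n))
    Q[T - 1] = S[T - 1]  # forced stop at the horizon
    omega_star = np.empty(T)
    omega_P = np.empty(T) if is_conf else None
    dmu_star = np.empty(T)
    flags: List[str] = [""] * T

    # terminal threshold: every state stops; the threshold is the lowest
    # attainable stop value, at dmu = dmu0 (the symmetry center)
    dmu_star[T - 1] = 0.0
    bT = float(np.asarray(benefit(center, T)))
    omega_star[T - 1] = bT - costs[T]
    if is_conf:
        omega_P[T - 1] = bT / params.R
    flags[T - 1] = "ok"

    for t in range(T - 1, 0, -1):
        M = kernel.step_matrix(t)  # transition t -> t + 1
        cont = M @ Q[t]  # E[Q*(., t+1) | x at t]
        Q[t - 1] = np.maximum(S[t - 1], cont)
        dmu_star[t - 1], omega_star[t - 1], flags[t - 1] = _extract_threshold(
            x, center, S[t - 1] - cont, benefit, costs[t], t
        )
        if is_conf:
            if np.isinf(omega_star[t - 1]):
                omega_P[t - 1] = np.inf
            else:
                omega_P[t - 1] = (
                    float(np.asarray(benefit(center + dmu_star[t - 1], t))) / params.R
                )

    return ThresholdPolicy(
        times=np.arange(1, T + 1),
        omega_star=omega_star,
        omega_P=omega_P,
        delta_mu_star=dmu_star,
        grid=kernel.grid,
        params=params,
        is_confidence=is_conf,
        value_function=Q,
        stop_value=S,
        flags=flags,
    )


def confidence_threshold(policy: ThresholdPolicy, params: MCDParams) -> np.ndarray:
    """Confidence form of the net-benefit threshold:
    ``omega_P(t) = (omega_star(t) + alpha*(kappa*t)**nu) / R``.
    """
    if not policy.is_confidence:
        raise ValueError(
            "confidence thresholds only exist for confidence-based benefits"
        )
    costs = np.asarray(params.cost(policy.times))
    return (policy.omega_star + costs) / params.R


def apply_policy(trajectory, policy: ThresholdPolicy, params: MCDParams) -> int:
    """First decision time at which the policy stops on a trajectory.

    Confidence-benefit policies stop when P_c(t) >= omega_P(t)
    (thresholds are defined per integer step; no interpolation in t);
    the horizon forces a stop.  The trajectory must cover t = 1..T.
    """
    conf = np.asarray(trajectory.confidence_series())
    dmu = np.asarray(trajectory.delta_mu)
    if conf.shape[0] < params.T + 1:
        raise ValueError(
            f"trajectory covers {conf.shape[0] - 1} steps, horizon is {params.T}"
        )
    return int(policy.stop_times(conf[None, :], dmu[None, :])[0])
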