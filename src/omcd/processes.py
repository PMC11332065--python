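"""Generative simulators of the value computations the controller monitors.

Three scenarios produce stochastic trajectories of the per-option value
beliefs (mu_i(t), sigma_i(t)):

* ``generic``   -- the controller's own working model: deterministic
  precision growth plus a zero-drift Gaussian random walk on the modes.
* ``denoising`` -- Bayesian filtering of noisy signals y(t) = V + eps
  centered on a hidden value V; the posterior mean is a martingale with
  a hidden drift toward V, and the posterior variance shrinks
  deterministically.
* ``attributes`` -- option value is a weighted sum of Gaussian
  attributes disclosed one per time step in a uniformly random order;
  uncertainty vanishes exactly when all attributes are disclosed.

The module also provides the analytic effort-efficacy calibrations that
map each scenario's parameters onto the controller's (beta, gamma), and
the scenario-specific "ideal" stopping policies that exploit the true
transition statistics instead of the controller's agnostic kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .core import MCDParams, confidence
from .solver import (
    StateGrid,
    ThresholdPolicy,
    TransitionKernel,
    build_grid,
    confidence_benefit,
    gaussian_step_matrix,
    solve_optimal_stopping,
    stationary_kernel,
    time_varying_kernel,
)

__all__ = [
    "DenoisingParams",
    "AttributeParams",
    "ValueTrajectory",
    "TrajectoryBatch",
    "simulate_generic",
    "simulate_generic_batch",
    "simulate_denoising",
    "simulate_denoising_batch",
    "denoising_efficacies",
    "simulate_attributes",
    "simulate_attributes_batch",
    "attribute_efficacies",
    "ideal_kernel_denoising",
    "ideal_policy_denoising",
    "ideal_policy_attributes",
    "ideal_policy_attributes_1d",
    "IdealAttributePolicy",
    "controller_params_denoising",
    "controller_params_attributes",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------
# containers


@dataclass
class TrajectoryBatch:
    """Stacked value-belief trajectories for n trials over t = 0..T.

    ``mu`` has shape (n, T+1, 2); ``sigma`` is (n, T+1, 2) or a shared
    (1, T+1, 2).  ``hidden_value_diff`` (n,) is present when the
    scenario defines a ground-truth value difference.
    """

    mu: np.ndarray
    sigma: np.ndarray
    scenario: str
    seed: Optional[int] = None
    hidden_value_diff: Optional[np.ndarray] = None
    disclosure_order: Optional[np.ndarray] = None  # (n, k), attributes only
    hidden_V: Optional[np.ndarray] = None  # (n, 2), denoising only
    signals: Optional[np.ndarray] = None  # (n, T, 2) noisy inputs, denoising only
    attributes: Optional[np.ndarray] = None  # (n, 2, k), attributes only

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    @property
    def T(self) -> int:
        return self.mu.shape[1] - 1

    @property
    def delta_mu(self) -> np.ndarray:
        """(n, T+1) mode differences mu1 - mu2."""
        return self.mu[:, :, 0] - self.mu[:, :, 1]

    def confidence_matrix(self) -> np.ndarray:
        """(n, T+1) decision confidence at every time step."""
        return np.asarray(
            confidence(self.delta_mu, self.sigma[:, :, 0], self.sigma[:, :, 1])
        )

    def trajectory(self, i: int) -> "ValueTrajectory":
        sig = self.sigma[0] if self.sigma.shape[0] == 1 else self.sigma[i]
        return ValueTrajectory(
            mu=self.mu[i],
            sigma=sig,
            scenario=self.scenario,
            seed=self.seed,
            hidden_value_diff=(
                None
                if self.hidden_value_diff is None
                else float(self.hidden_value_diff[i])
            ),
            disclosure_order=(
                None if self.disclosure_order is None else self.disclosure_order[i]
            ),
        )


@dataclass
class ValueTrajectory:
    """One trial's belief trajectory: mu, sigma of shape (T+1, 2)."""

    mu: np.ndarray
    sigma: np.ndarray
    scenario: str = "generic"
    seed: Optional[int] = None
    hidden_value_diff: Optional[float] = None
    disclosure_order: Optional[np.ndarray] = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 2:
            raise ValueError("mu and sigma must both have shape (T+1, 2)")
        if np.any(self.sigma < 0):
            raise ValueError("belief variances must be >= 0")

    @property
    def T(self) -> int:
        return self.mu.shape[0] - 1

    @property
    def delta_mu(self) -> np.ndarray:
        return self.mu[:, 0] - self.mu[:, 1]

    def confidence_series(self) -> np.ndarray:
        return np.asarray(
            confidence(self.delta_mu, self.sigma[:, 0], self.sigma[:, 1])
        )


# ---------------------------------------------------------------------
# generic random-walk scenario (the controller's working model)


def simulate_generic_batch(params: MCDParams, n: int, rng_seed) -> TrajectoryBatch:
    """n trajectories of the controller's own generative assumptions.

    Modes follow independent zero-drift random walks with per-step
    variance ``gamma * kappa`` per option (so dmu increments have
    variance ``2*gamma*kappa``); variances follow the precision law
    deterministically.  No hidden ground-truth value is defined.
    """
    rng = _rng(rng_seed)
    T = params.T
    steps = rng.normal(0.0, np.sqrt(params.gamma * params.kappa), size=(n, T, 2))
    mu = np.empty((n, T + 1, 2))
    mu[:, 0, :] = params.mu0
    np.cumsum(steps, axis=1, out=mu[:, 1:, :])
    mu[:, 1:, :] += np.asarray(params.mu0)
    z = params.kappa * np.arange(T + 1)
    sigma = (1.0 / (1.0 / np.asarray(params.sigma0) + params.beta * z[:, None]))[None]
    return TrajectoryBatch(mu=mu, sigma=sigma, scenario="generic", seed=_seed_of(rng_seed))


def _seed_of(rng_seed) -> Optional[int]:
    return rng_seed if isinstance(rng_seed, (int, np.integer)) else None


def simulate_generic(params: MCDParams, rng_seed) -> ValueTrajectory:
    return simulate_generic_batch(params, 1, rng_seed).trajectory(0)


# ---------------------------------------------------------------------
# Bayesian value denoising


@dataclass(frozen=True)
class DenoisingParams:
    """Bayesian value-denoising scenario.

    Per option, a hidden value V ~ N(mu0, sigma0) emits noisy signals
    y(t) = V + eps, eps ~ N(0, Sigma), one per time step.  ``hidden_V``
    fixes the pair of true values instead of sampling them.
    """

    mu0: float = 0.0
    sigma0: float = 10.0
    Sigma: float = 100.0
    kappa: float = 0.01
    hidden_V: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.sigma0 <= 0 or self.Sigma <= 0:
            raise ValueError("sigma0 and Sigma must be > 0")
        if not (0 < self.kappa <= 1):
            raise ValueError("kappa must be in (0, 1]")

    @property
    def T(self) -> int:
        return int(round(1.0 / self.kappa))

    def posterior_variance(self, t) -> np.ndarray:
        """sigma(t) = 1 / (1/sigma0 + t/Sigma), exact for all t."""
        t = np.asarray(t, dtype=float)
        return 1.0 / (1.0 / self.sigma0 + t / self.Sigma)


def simulate_denoising_batch(dp: DenoisingParams, n: int, rng_seed) -> TrajectoryBatch:
    """n trials of Bayesian filtering of noisy value signals.

    Posterior mean: mu(t) = mu0 + sum(y(t') - mu0) / (Sigma/sigma0 + t);
    posterior variance is deterministic.  Records the hidden value
    difference V1 - V2 per trial.
    """
    rng = _rng(rng_seed)
    T = dp.T
    if dp.hidden_V is not None:
        V = np.broadcast_to(np.asarray(dp.hidden_V, dtype=float), (n, 2)).copy()
    else:
        V = rng.normal(dp.mu0, np.sqrt(dp.sigma0), size=(n, 2))
    y = V[:, None, :] + rng.normal(0.0, np.sqrt(dp.Sigma), size=(n, T, 2))
    pe = np.cumsum(y - dp.mu0, axis=1)  # summed prediction errors
    t = np.arange(1, T + 1, dtype=float)
    mu = np.empty((n, T + 1, 2))
    mu[:, 0, :] = dp.mu0
    mu[:, 1:, :] = dp.mu0 + pe / (dp.Sigma / dp.sigma0 + t)[None, :, None]
    sigma = np.repeat(
        dp.posterior_variance(np.arange(T + 1))[None, :, None], 2, axis=2
    )
    return TrajectoryBatch(
        mu=mu,
        sigma=sigma,
        scenario="denoising",
        seed=_seed_of(rng_seed),
        hidden_value_diff=V[:, 0] - V[:, 1],
        hidden_V=V,
        signals=y,
    )


def simulate_denoising(dp: DenoisingParams, rng_seed) -> ValueTrajectory:
    return simulate_denoising_batch(dp, 1, rng_seed).trajectory(0)


def denoising_efficacies(dp: DenoisingParams) -> Tuple[float, float]:
    """Analytic (beta, gamma) calibration of the controller to denoising.

    beta = 1 / (kappa * Sigma): exact, since the posterior precision
    grows by 1/Sigma per signal.  gamma averages the per-unit-resource
    magnitude of mode change, E[delta(t)^2] / (kappa * t) with
    E[delta(t)^2] = t * (Sigma + t*sigma0) / (Sigma/sigma0 + t)**2,
    over all admissible decision times.
    """
    beta = 1.0 / (dp.kappa * dp.Sigma)
    t = np.arange(1, dp.T + 1, dtype=float)
    gamma = float(
        np.mean((dp.Sigma + t * dp.sigma0) / ((dp.Sigma / dp.sigma0 + t) ** 2 * dp.kappa))
    )
    return beta, gamma


def controller_params_denoising(
    dp: DenoisingParams, R: float = 1.0, alpha: float = 0.1, nu: float = 2.0
) -> MCDParams:
    """MCD parameterization matching a denoising scenario (calibrated)."""
    beta, gamma = denoising_efficacies(dp)
    return MCDParams(
        R=R,
        alpha=alpha,
        nu=nu,
        beta=beta,
        gamma=gamma,
        kappa=dp.kappa,
        mu0=(dp.mu0, dp.mu0),
        sigma0=(dp.sigma0, dp.sigma0),
    )


def ideal_kernel_denoising(dp: DenoisingParams, grid: StateGrid) -> TransitionKernel:
    """True (time-varying) transition kernel of dmu under denoising.

    The posterior mean is a martingale whose step variance is the drop
    in posterior variance, so the dmu increment from t to t+1 is
    N(0, 2*(sigma(t) - sigma(t+1))); the per-step variances telescope to
    2*(sigma0 - sigma(T)).
    """
    s = dp.posterior_variance(np.arange(dp.T + 1))
    step_vars = 2.0 * (s[:-1] - s[1:])
    return time_varying_kernel(grid, step_vars)


def ideal_policy_denoising(
    dp: DenoisingParams,
    R: float = 1.0,
    alpha: float = 0.1,
    nu: float = 2.0,
    n_points: int = 513,
    width_mult: float = 6.0,
) -> ThresholdPolicy:
    """Optimal stopping under the true denoising transition statistics.

    Uses the exact time-varying kernel; the variance schedule needs no
    correction because the calibrated beta reproduces the posterior
    variance exactly.
    """
    params = controller_params_denoising(dp, R=R, alpha=alpha, nu=nu)
    grid = build_grid(params, n_points=n_points, width_mult=width_mult)
    kernel = ideal_kernel_denoising(dp, grid)
    return solve_optimal_stopping(params, kernel)


# ---------------------------------------------------------------------
# progressive attribute integration


@dataclass(frozen=True)
class AttributeParams:
    """Progressive attribute-integration scenario.

    Option value is sum_k w_k * x_k with attributes x_k ~ N(eta_k,
    varsigma_k) drawn independently per option; attributes are disclosed
    one per time step in a uniformly random order shared by both
    options, so kappa = 1/k and T = k.
    """

    k: int
    eta: np.ndarray = 1.0
    varsigma: np.ndarray = 1.0
    w: np.ndarray = 1.0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least k = 2 attributes")
        for name in ("eta", "varsigma", "w"):
            v = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (self.k,)
            ).copy()
            object.__setattr__(self, name, v)
        if np.any(self.varsigma <= 0):
            raise ValueError("attribute variances must be > 0")

    @property
    def T(self) -> int:
        return self.k

    @property
    def kappa(self) -> float:
        return 1.0 / self.k

    @property
    def mu0(self) -> float:
        """Prior value mode sum_k w_k * eta_k."""
        return float(np.sum(self.w * self.eta))

    @property
    def sigma0(self) -> float:
        """Prior value variance sum_k w_k**2 * varsigma_k."""
        return float(np.sum(self.w**2 * self.varsigma))

    @property
    def homogeneous(self) -> bool:
        wv = self.w**2 * self.varsigma
        return bool(np.allclose(wv, wv[0], rtol=1e-12, atol=0.0))


def simulate_attributes_batch(ap: AttributeParams, n: int, rng_seed) -> TrajectoryBatch:
    """n trials of attribute disclosure in uniformly random order.

    Per trial: both options' attributes are drawn, one permutation
    governs the disclosure order for both options.  Belief moments are
    accumulated so that sigma(T) = 0 and mu(T) = sum_k w_k x_k hold to
    machine precision.
    """
    rng = _rng(rng_seed)
    k = ap.k
    x = rng.normal(ap.eta, np.sqrt(ap.varsigma), size=(n, 2, k))
    perms = rng.permuted(np.broadcast_to(np.arange(k), (n, k)), axis=1)
    w_p = ap.w[perms]  # (n, k) weights in disclosure order
    wv_p = w_p**2 * ap.varsigma[perms]
    eta_p = ap.eta[perms]
    x_p = np.take_along_axis(x, perms[:, None, :], axis=2)  # (n, 2, k)

    # remaining-uncertainty form: sigma(t) = sum over undisclosed wv
    rem = np.concatenate(
        [np.cumsum(wv_p[:, ::-1], axis=1)[:, ::-1], np.zeros((n, 1))], axis=1
    )  # (n, k+1); rem[:, t] = sum of terms t..k-1, rem[:, k] = 0 exactly
    sigma = np.repeat(rem[:, :, None], 2, axis=2)

    # mu(t) = sum_disclosed w*x + sum_undisclosed w*eta  (per option)
    wx = w_p[:, None, :] * x_p  # (n, 2, k)
    weta = (w_p * eta_p)[:, None, :]
    disclosed = np.concatenate(
        [np.zeros((n, 2, 1)), np.cumsum(wx, axis=2)], axis=2
    )  # (n, 2, k+1)
    remaining = np.concatenate(
        [np.cumsum(weta[:, :, ::-1], axis=2)[:, :, ::-1], np.zeros((n, 1, 1))], axis=2
    )  # (n, 1, k+1), same for both options
    mu = np.transpose(disclosed + remaining, (0, 2, 1))  # (n, T+1, 2)
    return TrajectoryBatch(
        mu=mu,
        sigma=sigma,
        scenario="attributes",
        seed=_seed_of(rng_seed),
        hidden_value_diff=mu[:, -1, 0] - mu[:, -1, 1],
        disclosure_order=perms,
        attributes=x,
    )


def simulate_attributes(ap: AttributeParams, rng_seed) -> ValueTrajectory:
    return simulate_attributes_batch(ap, 1, rng_seed).trajectory(0)


def attribute_efficacies(ap: AttributeParams) -> Tuple[float, float]:
    """Analytic (beta, gamma) calibration to attribute integration.

    gamma = sigma0 exactly (permutation-averaged mode-change variance is
    (t/k) * sigma0 = gamma * z).  beta averages the expected precision
    gain per unit resource, 1 / (kappa * sigma0 * (k - t)), over
    t = 1..k-1 (the horizon itself is excluded: disclosed-everything
    precision is infinite).
    """
    gamma = ap.sigma0
    t = np.arange(1, ap.k, dtype=float)
    beta = float(np.mean(1.0 / (ap.kappa * ap.sigma0 * (ap.k - t))))
    return beta, gamma


def controller_params_attributes(
    ap: AttributeParams, R: float = 1.0, alpha: float = 3.0, nu: float = 4.0
) -> MCDParams:
    """MCD parameterization matching an attribute scenario (calibrated)."""
    beta, gamma = attribute_efficacies(ap)
    return MCDParams(
        R=R,
        alpha=alpha,
        nu=nu,
        beta=beta,
        gamma=gamma,
        kappa=ap.kappa,
        mu0=(ap.mu0, ap.mu0),
        sigma0=(ap.sigma0, ap.sigma0),
    )


class IdealAttributePolicy:
    """Exact stopping rule under the true attribute-disclosure process.

    The sufficient state is (disclosed attribute set, dmu): conditional
    on the disclosed set, the remaining uncertainty is known and the
    next disclosure is uniform over the undisclosed attributes.  The
    policy is solved by backward induction over attribute subsets
    (bitmasks) and reduced, per subset, to a critical |dmu| threshold.
    With homogeneous attributes the subset only matters through its
    size, so the rule collapses onto a one-dimensional time-indexed
    threshold.
    """

    MAX_K = 16

    def __init__(
        self,
        ap: AttributeParams,
        R: float = 1.0,
        alpha: float = 3.0,
        nu: float = 4.0,
        n_points: int = 257,
        width_mult: float = 6.0,
    ):
        if ap.k > self.MAX_K:
            raise ValueError(
                f"subset enumeration limited to k <= {self.MAX_K}, got k = {ap.k}"
            )
        self.ap = ap
        self.label = "ideal"
        self.R, self.alpha, self.nu = float(R), float(alpha), float(nu)
        k = ap.k
        wv = ap.w**2 * ap.varsigma  # per-attribute dmu half-variances
        sigma0 = ap.sigma0
        half_width = width_mult * np.sqrt(2.0 * sigma0)
        if n_points < 33 or n_points % 2 == 0:
            raise ValueError("n_points must be an odd integer >= 33")
        x = np.linspace(-half_width, half_width, n_points)
        self.grid = StateGrid(points=x, center=0.0, half_width=float(half_width))

        # one step matrix per distinct attribute variance
        mats: Dict[float, np.ndarray] = {}
        for v in wv:
            key = float(v)
            if key not in mats:
                mats[key] = gaussian_step_matrix(self.grid, 2.0 * key)

        costs = alpha * (np.arange(k + 1) / k) ** nu
        full = (1 << k) - 1

        def stop_values(mask: int, t: int) -> np.ndarray:
            rem = float(np.sum(wv[[j for j in range(k) if not mask & (1 << j)]]))
            return self.R * np.asarray(confidence(x, rem, rem)) - costs[t]

        # backward over subset cardinality
        self.thresholds: Dict[int, float] = {full: 0.0}
        level: Dict[int, np.ndarray] = {full: stop_values(full, k)}
        from itertools import combinations

        for t in range(k - 1, -1, -1):
            new_level: Dict[int, np.ndarray] = {}
            for idx in combinations(range(k), t):
                mask = sum(1 << j for j in idx)
                S = stop_values(mask, t)
                cont = np.zeros(n_points)
                undisclosed = [j for j in range(k) if not mask & (1 << j)]
                for j in undisclosed:
                    cont += mats[float(wv[j])] @ level[mask | (1 << j)]
                cont /= len(undisclosed)
                new_level[mask] = np.maximum(S, cont)
                if t >= 1:  # decisions start at t = 1
                    self.thresholds[mask] = self._threshold(x, S - cont)
                else:
                    self.start_value = new_level[mask]
            level = new_level

    @staticmethod
    def _threshold(x: np.ndarray, D: np.ndarray) -> float:
        pos = x >= -1e-12
        xp, Dp = x[pos], D[pos]
        nonneg = Dp >= 0
        if nonneg.all():
            return 0.0
        if not nonneg.any():
            return np.inf
        i = int(np.argmax(nonneg))
        if i == 0:
            return 0.0
        d0, d1 = Dp[i - 1], Dp[i]
        return float(xp[i - 1] + (xp[i] - xp[i - 1]) * (0.0 - d0) / (d1 - d0))

    def stop_times(self, batch: TrajectoryBatch, params=None) -> np.ndarray:
        """First stop time per trial, given each trial's disclosure order."""
        if batch.disclosure_order is None:
            raise ValueError("batch lacks disclosure orders (not an attribute batch)")
        k = self.ap.k
        dmu = batch.delta_mu
        out = np.full(batch.n, k, dtype=int)
        for i in range(batch.n):
            mask = 0
            for t in range(1, k + 1):
                mask |= 1 << int(batch.disclosure_order[i, t - 1])
                if abs(dmu[i, t]) >= self.thresholds[mask]:
                    out[i] = t
                    break
        return out


def ideal_policy_attributes_1d(
    ap: AttributeParams,
    R: float = 1.0,
    alpha: float = 3.0,
    nu: float = 4.0,
    n_points: int = 257,
    width_mult: float = 6.0,
) -> ThresholdPolicy:
    """One-dimensional ideal rule for homogeneous attributes.

    With equal w**2 * varsigma the remaining uncertainty is
    deterministic in t (sigma(t) = sigma0 * (1 - t/k)) and the dmu
    increments are stationary with variance 2*sigma0/k, so the exact
    rule is a time-indexed threshold solved on a single dmu grid.
    """
    if not ap.homogeneous:
        raise ValueError("1-D ideal rule requires homogeneous attributes")
    params = controller_params_attributes(ap, R=R, alpha=alpha, nu=nu)
    sigma0 = ap.sigma0
    half_width = width_mult * np.sqrt(2.0 * sigma0)
    x = np.linspace(-half_width, half_width, n_points)
    grid = StateGrid(points=x, center=0.0, half_width=float(half_width))
    kernel = stationary_kernel(grid, gamma=sigma0, kappa=ap.kappa)

    def sigma_of_t(t):
        s = sigma0 * (1.0 - t / ap.k)
        return (max(s, 0.0), max(s, 0.0))

    benefit = confidence_benefit(params, sigma_of_t=sigma_of_t)
    return solve_optimal_stopping(params, kernel, benefit)


def ideal_policy_attributes(
    ap: AttributeParams,
    R: float = 1.0,
    alpha: float = 3.0,
    nu: float = 4.0,
    n_points: int = 257,
    width_mult: float = 6.0,
) -> IdealAttributePolicy:
    """Exact ideal stopping rule over (disclosed set, dmu) states."""
    return IdealAttributePolicy(
        ap, R=R, alpha=alpha, nu=nu, n_points=n_points, width_mult=width_mult
    )
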