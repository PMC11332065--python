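"""Cost/benefit model of resource allocation to a two-alternative decision.

The controller represents the values of two options as Gaussian beliefs
N(mu_i, sigma_i).  Investing an amount ``z`` of (normalized) cognitive
resources (i) sharpens the beliefs at rate ``beta`` (type-1 effort
efficacy) and (ii) perturbs their modes with variance ``gamma * z``
(type-2 effort efficacy).  Decision confidence is the probability that
the chosen (higher-mode) option truly has the higher value, obtained by
a moment-matching sigmoid approximation to the Gaussian CDF.  The
controller weighs ``R *`` confidence against an effort cost
``alpha * z**nu``.

This module houses the parameterization, the confidence mapping, the
folded-normal forecast of the mode gap, the expected-confidence forecast
and the prospective (pre-committed) optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "MCDParams",
    "ValueBelief",
    "sigmoid",
    "confidence",
    "precision_growth",
    "anticipated_mode_gap",
    "expected_confidence",
    "effort_cost",
    "net_benefit",
    "prospective_optimum",
]

#: sigmoid slope matching the standard normal CDF: s(pi*x/sqrt(3)) ~ Phi(x)
_PI_OVER_SQRT3 = np.pi / np.sqrt(3.0)


def sigmoid(x):
    """Standard logistic sigmoid 1 / (1 + exp(-x)), overflow-safe."""
    return expit(x)


def _as_pair(v, name: str) -> Tuple[float, float]:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1:
        return (float(arr[0]), float(arr[0]))
    if arr.size == 2:
        return (float(arr[0]), float(arr[1]))
    raise ValueError(f"{name} must be a scalar or a pair, got size {arr.size}")


@dataclass(frozen=True)
class MCDParams:
    """Decision parameters of the metacognitive controller.

    Parameters
    ----------
    R : float
        Decision importance; weight on confidence in the benefit term
        (utility units).  Must be positive.
    alpha : float
        Unitary effort cost (utility units), >= 0.
    nu : float
        Cost power; the cost of investing ``z`` resources is
        ``alpha * z**nu``.  Must be positive.
    beta : float
        Type-1 effort efficacy: precision gained per unit resource, >= 0.
    gamma : float
        Type-2 effort efficacy: variance of the value-mode perturbation
        per unit resource, >= 0.
    kappa : float
        Effort intensity, resources spent per time step (0 < kappa <= 1).
        The temporal horizon is ``T = round(1 / kappa)``.
    mu0 : scalar or pair
        Prior value modes of the two options.
    sigma0 : scalar or pair
        Prior value variances of the two options (> 0).
    """

    R: float = 1.0
    alpha: float = 0.2
    nu: float = 0.5
    beta: float = 1.0
    gamma: float = 4.0
    kappa: float = 0.01
    mu0: Tuple[float, float] = (0.0, 0.0)
    sigma0: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        object.__setattr__(self, "mu0", _as_pair(self.mu0, "mu0"))
        object.__setattr__(self, "sigma0", _as_pair(self.sigma0, "sigma0"))
        if not self.R > 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not (0 < self.kappa <= 1):
            raise ValueError(f"kappa must be in (0, 1], got {self.kappa}")
        if min(self.sigma0) <= 0:
            raise ValueError(f"sigma0 components must be > 0, got {self.sigma0}")
        if self.T < 1:
            raise ValueError("horizon T = round(1/kappa) must be >= 1")

    @property
    def T(self) -> int:
        """Temporal horizon: number of steps to exhaust the resource budget."""
        return int(round(1.0 / self.kappa))

    @property
    def delta_mu0(self) -> float:
        """Prior mode difference mu0[0] - mu0[1]."""
        return self.mu0[0] - self.mu0[1]

    def cost(self, t):
        """Effort cost alpha * (kappa*t)**nu accrued by decision time t."""
        return self.alpha * (self.kappa * np.asarray(t, dtype=float)) ** self.nu

    def replace(self, **kwargs) -> "MCDParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class ValueBelief:
    """Gaussian value beliefs (mu_i, sigma_i) held at decision time t."""

    mu: Tuple[float, float]
    sigma: Tuple[float, float]
    t: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mu", _as_pair(self.mu, "mu"))
        object.__setattr__(self, "sigma", _as_pair(self.sigma, "sigma"))
        if min(self.sigma) < 0:
            raise ValueError("belief variances must be >= 0")
        if self.t < 0:
            raise ValueError("belief time must be >= 0")

    @property
    def delta_mu(self) -> float:
        return self.mu[0] - self.mu[1]

    @property
    def confidence(self) -> float:
        return float(confidence(self.delta_mu, self.sigma[0], self.sigma[1]))


def confidence(delta_mu, sigma1, sigma2):
    """Probability that the higher-mode option truly has the higher value.

    Moment-matching approximation s(pi*|dmu| / sqrt(3*(s1+s2))) to the
    Gaussian CDF Phi(|dmu| / sqrt(s1+s2)); accurate to ~0.01 absolute.
    Lies in [0.5, 1).  Degenerate conventions: zero total variance with
    nonzero ``delta_mu`` gives the limit 1.0; 0/0 gives 0.5.
    """
    delta_mu = np.asarray(delta_mu, dtype=float)
    total = np.asarray(sigma1, dtype=float) + np.asarray(sigma2, dtype=float)
    if np.any(total < 0):
        raise ValueError("total variance must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = _PI_OVER_SQRT3 * np.abs(delta_mu) / np.sqrt(total)
    # 0/0 -> nan -> 0.5 ; d/0 -> inf -> 1.0
    arg = np.where(np.isnan(arg), 0.0, arg)
    out = expit(arg)
    if out.ndim == 0:
        return float(out)
    return out


def precision_growth(params: MCDParams, z):
    """Belief variances after investing z resources: 1/(1/sigma0 + beta*z).

    Returns an array of shape ``z.shape + (2,)`` (or ``(2,)`` for scalar z).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("resources z must be >= 0")
    s0 = np.asarray(params.sigma0)
    return 1.0 / (1.0 / s0 + params.beta * z[..., None])


def anticipated_mode_gap(delta_mu0, gamma, z):
    """Forecast moments of the absolute mode difference |dmu(z)|.

    After investing ``z`` resources the mode difference is
    ``dmu0 + delta`` with ``delta ~ N(0, 2*gamma*z)``, so |dmu(z)| is
    folded-normal.  Returns its mean and variance, using the sigmoid
    stand-in for the Gaussian CDF (the model's own approximation) and
    |dmu0| throughout (the folded normal is symmetric in the sign of its
    location).

    The mean is >= |dmu0| and nondecreasing in z; ``gamma*z == 0``
    returns ``(|dmu0|, 0)``.
    """
    d0 = abs(float(delta_mu0))
    gz = float(gamma) * float(z)
    if gz < 0:
        raise ValueError("gamma * z must be >= 0")
    if gz == 0.0:
        return d0, 0.0
    mean = 2.0 * np.sqrt(gz / np.pi) * np.exp(-(d0**2) / (4.0 * gz)) + d0 * (
        2.0 * expit(np.pi * d0 / np.sqrt(6.0 * gz)) - 1.0
    )
    var = 2.0 * gz + d0**2 - mean**2
    return float(mean), float(max(var, 0.0))


def expected_confidence(params: MCDParams, z) -> float:
    """Forecast E[P_c] after investing z resources (before observing them).

    Writes confidence as s(x) with x = pi * lambda * |dmu(z)|,
    lambda = 1/sqrt(3*(sigma1(z)+sigma2(z))), and approximates E[s(x)]
    for Gaussian-moment x by s(E[x] / sqrt(1 + (1/2) * Var[x]**(3/4))).
    Reduces exactly to the current confidence at z = 0, and is
    nondecreasing in z whenever beta > 0 or gamma > 0.
    """
    z = float(z)
    if not (0 <= z <= 1 + 1e-12):
        raise ValueError("resources z must lie in [0, 1]")
    mean_gap, var_gap = anticipated_mode_gap(params.delta_mu0, params.gamma, z)
    s1, s2 = precision_growth(params, z)
    lam = 1.0 / np.sqrt(3.0 * (s1 + s2))
    m = np.pi * lam * mean_gap
    v = (np.pi * lam) ** 2 * var_gap
    return float(expit(m / np.sqrt(1.0 + 0.5 * v**0.75)))


def effort_cost(params: MCDParams, z):
    """Cost of investing z resources: alpha * z**nu."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("resources z must be >= 0")
    out = params.alpha * z**params.nu
    return float(out) if out.ndim == 0 else out


def net_benefit(params: MCDParams, belief: ValueBelief) -> float:
    """Realized net benefit of stopping at the belief's decision time.

    R * P_c(belief) - alpha * (kappa * t)**nu.  The "continue" branch
    (worth 0 until stopping) is handled by the stopping solver.
    """
    if belief.t > params.T:
        raise ValueError(f"belief time {belief.t} exceeds horizon {params.T}")
    return params.R * belief.confidence - float(params.cost(belief.t))


def prospective_optimum(params: MCDParams) -> Tuple[float, float]:
    """Pre-committed resource investment maximizing expected net benefit.

    Exhaustively evaluates R * E[P_c](z) - alpha*z**nu on the admissible
    grid z in {0, kappa, 2*kappa, ..., 1} and returns
    ``(z_hat, expected_net_benefit)`` for the smallest maximizer (least
    effort on ties).
    """
    zs = params.kappa * np.arange(params.T + 1)
    vals = np.array(
        [params.R * expected_confidence(params, z) - effort_cost(params, z) for z in zs]
    )
    i = int(np.argmax(vals))  # argmax returns the first (smallest-z) maximizer
    return float(zs[i]), float(vals[i])
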