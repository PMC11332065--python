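"""Single-trial and batch evaluation of stopping policies.

A trial applies a policy to one simulated belief trajectory and records
when deliberation stopped, the resources invested, the confidence and
net benefit at stopping, the choice (sign of the mode difference) and
-- when the scenario defines one -- whether the choice agrees with the
hidden value difference.  Batches evaluate several policies on the
*same* trajectories (paired comparison), which removes between-path
Monte-Carlo variance from policy contrasts.

Reference policies:

* prospective -- commits to the pre-computed optimal investment z_hat,
  regardless of how the trajectory unfolds;
* oracle -- retrospectively stops at the realized net-benefit apex, a
  per-path upper bound no online policy can beat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import MCDParams, prospective_optimum
from .processes import (
    AttributeParams,
    DenoisingParams,
    TrajectoryBatch,
    ValueTrajectory,
    simulate_attributes_batch,
    simulate_denoising_batch,
    simulate_generic_batch,
)
from .solver import ThresholdPolicy

__all__ = [
    "TrialRecord",
    "OnlinePolicy",
    "ProspectivePolicy",
    "OraclePolicy",
    "run_trial",
    "prospective_trial",
    "oracle_trial",
    "run_batch",
    "RECORD_COLUMNS",
]

#: fixed column order of trial-record tables
RECORD_COLUMNS = [
    "policy_label",
    "trial",
    "stop_time",
    "z_invested",
    "confidence_at_stop",
    "choice",
    "net_benefit",
    "hidden_value_diff",
    "value_consistent",
    "seed",
]


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one policy applied to one trajectory."""

    policy_label: str
    stop_time: int
    z_invested: float
    confidence_at_stop: float
    choice: int
    net_benefit: float
    hidden_value_diff: Optional[float] = None
    value_consistent: Optional[bool] = None
    seed: Optional[int] = None
    trial: int = 0


class OnlinePolicy:
    """Reactive policy: stop when confidence crosses its threshold."""

    def __init__(self, policy: ThresholdPolicy, label: str = "omcd"):
        self.policy = policy
        self.label = label

    def stop_times(self, batch: TrajectoryBatch, params: MCDParams) -> np.ndarray:
        return self.policy.stop_times(batch.confidence_matrix(), batch.delta_mu)


class ProspectivePolicy:
    """Pre-committed policy: always stop after z_hat / kappa steps.

    A zero optimal investment is clamped to the minimal admissible
    decision time t = 1 (where, with beta = 0, confidence still equals
    the prior confidence).
    """

    def __init__(self, params: MCDParams, label: str = "prospective"):
        z_hat, expected = prospective_optimum(params)
        self.z_hat = z_hat
        self.expected_net_benefit = expected
        self.t_star = max(1, int(round(z_hat / params.kappa)))
        self.label = label

    def stop_times(self, batch: TrajectoryBatch, params: MCDParams) -> np.ndarray:
        return np.full(batch.n, self.t_star, dtype=int)


class OraclePolicy:
    """Retrospective upper bound: stop at the net-benefit apex.

    Picks the earliest maximizer of R*P_c(t) - alpha*(kappa*t)**nu over
    t = 1..T on each realized path.
    """

    def __init__(self, label: str = "oracle"):
        self.label = label

    def stop_times(self, batch: TrajectoryBatch, params: MCDParams) -> np.ndarray:
        t = np.arange(1, params.T + 1)
        nb = params.R * batch.confidence_matrix()[:, 1:] - np.asarray(params.cost(t))
        return np.argmax(nb, axis=1) + 1  # argmax -> earliest maximizer


PolicyLike = Union[OnlinePolicy, ProspectivePolicy, OraclePolicy]


def _records(
    batch: TrajectoryBatch,
    stops: np.ndarray,
    params: MCDParams,
    label: str,
    rng: np.random.Generator,
    seed: Optional[int],
) -> pd.DataFrame:
    n = batch.n
    idx = np.arange(n)
    conf = batch.confidence_matrix()[idx, stops]
    dmu_stop = batch.delta_mu[idx, stops]
    choice = np.sign(dmu_stop).astype(int)
    ties = choice == 0
    if ties.any():  # dmu exactly 0 at stop: choose uniformly
        choice[ties] = rng.choice([-1, 1], size=int(ties.sum()))
    nb = params.R * conf - np.asarray(params.cost(stops))
    if batch.hidden_value_diff is not None:
        hidden = batch.hidden_value_diff
        consistent = (choice * np.sign(hidden)) > 0
    else:
        hidden = np.full(n, np.nan)
        consistent = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "policy_label": label,
            "trial": idx,
            "stop_time": stops,
            "z_invested": params.kappa * stops,
            "confidence_at_stop": conf,
            "choice": choice,
            "net_benefit": nb,
            "hidden_value_diff": hidden,
            "value_consistent": consistent,
            "seed": seed if seed is not None else np.nan,
        },
        columns=RECORD_COLUMNS,
    )


def _single(batch: TrajectoryBatch, stops, params, label, seed=None) -> TrialRecord:
    df = _records(
        batch, np.asarray(stops), params, label, np.random.default_rng(seed), seed
    ).iloc[0]
    return TrialRecord(
        policy_label=label,
        stop_time=int(df.stop_time),
        z_invested=float(df.z_invested),
        confidence_at_stop=float(df.confidence_at_stop),
        choice=int(df.choice),
        net_benefit=float(df.net_benefit),
        hidden_value_diff=None if np.isnan(df.hidden_value_diff) else float(df.hidden_value_diff),
        value_consistent=None if pd.isna(df.value_consistent) else bool(df.value_consistent),
        seed=seed,
    )


def _as_batch(trajectory: ValueTrajectory) -> TrajectoryBatch:
    return TrajectoryBatch(
        mu=trajectory.mu[None],
        sigma=trajectory.sigma[None],
        scenario=trajectory.scenario,
        seed=trajectory.seed,
        hidden_value_diff=(
            None
            if trajectory.hidden_value_diff is None
            else np.array([trajectory.hidden_value_diff])
        ),
        disclosure_order=(
            None
            if trajectory.disclosure_order is None
            else trajectory.disclosure_order[None]
        ),
    )


def run_trial(
    trajectory: ValueTrajectory,
    policy: ThresholdPolicy,
    params: MCDParams,
    seed: Optional[int] = None,
) -> TrialRecord:
    """Apply a threshold policy to one trajectory and record the outcome."""
    if trajectory.T < params.T:
        raise ValueError(
            f"trajectory horizon {trajectory.T} shorter than params horizon {params.T}"
        )
    batch = _as_batch(trajectory)
    stops = OnlinePolicy(policy).stop_times(batch, params)
    return _single(batch, stops, params, "omcd", seed)


def prospective_trial(
    trajectory: ValueTrajectory, params: MCDParams, seed: Optional[int] = None
) -> TrialRecord:
    """Evaluate the pre-committed investment on one trajectory."""
    batch = _as_batch(trajectory)
    stops = ProspectivePolicy(params).stop_times(batch, params)
    return _single(batch, stops, params, "prospective", seed)


def oracle_trial(
    trajectory: ValueTrajectory, params: MCDParams, seed: Optional[int] = None
) -> TrialRecord:
    """Evaluate the retrospective apex policy on one trajectory."""
    batch = _as_batch(trajectory)
    stops = OraclePolicy().stop_times(batch, params)
    return _single(batch, stops, params, "oracle", seed)


def make_batch(scenario, n_trials: int, seed) -> TrajectoryBatch:
    """Simulate a trajectory batch from a scenario specification.

    ``scenario`` is either a tuple ("generic"|"denoising"|"attributes",
    params-object) or a bare :class:`MCDParams` (generic scenario).
    """
    if isinstance(scenario, MCDParams):
        scenario = ("generic", scenario)
    kind, p = scenario
    if kind == "generic":
        return simulate_generic_batch(p, n_trials, seed)
    if kind == "denoising":
        return simulate_denoising_batch(p, n_trials, seed)
    if kind == "attributes":
        return simulate_attributes_batch(p, n_trials, seed)
    raise ValueError(f"unknown scenario kind: {kind!r}")


def run_batch(
    scenario,
    policies: Sequence[PolicyLike],
    params: MCDParams,
    n_trials: int,
    seed: int,
) -> pd.DataFrame:
    """Evaluate every policy on the same n_trials simulated trajectories.

    Returns a long-format table (one row per trial x policy) with the
    fixed column order :data:`RECORD_COLUMNS`.  Deterministic given the
    seed: trajectories and tie-break draws derive from it.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    traj_seed, tie_seed = ss.spawn(2)
    if isinstance(scenario, TrajectoryBatch):
        batch = scenario
    else:
        batch = make_batch(scenario, n_trials, np.random.default_rng(traj_seed))
    frames = []
    for pol in policies:
        stops = np.asarray(pol.stop_times(batch, params), dtype=int)
        frames.append(
            _records(batch, stops, params, pol.label, np.random.default_rng(tie_seed), seed)
        )
    return pd.concat(frames, ignore_index=True)
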