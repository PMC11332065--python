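"""Seeded reference artifacts for regression testing.

Writes a small, reproducible bundle: one solved threshold policy at the
reference decision parameters, 20 trajectories per scenario (long CSV)
and their trial records, plus a JSON sidecar of parameters and seeds.
Byte-identical across runs with the same seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .core import MCDParams
from .processes import (
    AttributeParams,
    DenoisingParams,
    TrajectoryBatch,
    simulate_attributes_batch,
    simulate_denoising_batch,
    simulate_generic_batch,
)
from .trials import OnlinePolicy, OraclePolicy, ProspectivePolicy, run_batch
from .experiments import solve_online_policy

__all__ = ["make_fixtures"]

_FLOAT_FMT = "%.17g"  # bit-stable float round trips


def _trajectory_table(batch: TrajectoryBatch) -> pd.DataFrame:
    rows = []
    conf = batch.confidence_matrix()
    for i in range(batch.n):
        sig = batch.sigma[0] if batch.sigma.shape[0] == 1 else batch.sigma[i]
        for t in range(batch.T + 1):
            for opt in (0, 1):
                rows.append(
                    {
                        "trial": i,
                        "t": t,
                        "option": opt + 1,
                        "mu": batch.mu[i, t, opt],
                        "sigma": sig[t, opt],
                        "confidence": conf[i, t],
                    }
                )
    return pd.DataFrame(rows)


def make_fixtures(seed: int, out_dir) -> Dict[str, Path]:
    """Generate the reference fixture bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    params = MCDParams()
    online = solve_online_policy(params)
    paths["policy"] = out / "policy_reference.json"
    paths["policy"].write_text(online.policy.to_json())

    dp = DenoisingParams()
    ap = AttributeParams(k=10)
    scenarios = {
        "generic": (("generic", params), params),
        "denoising": (("denoising", dp), None),
        "attributes": (("attributes", ap), None),
    }
    meta = {
        "seed": seed,
        "n_trials": 20,
        "mcd": {
            "R": params.R, "alpha": params.alpha, "nu": params.nu,
            "beta": params.beta, "gamma": params.gamma, "kappa": params.kappa,
            "mu0": list(params.mu0), "sigma0": list(params.sigma0),
        },
        "denoising": {"mu0": dp.mu0, "sigma0": dp.sigma0, "Sigma": dp.Sigma,
                      "kappa": dp.kappa},
        "attributes": {"k": ap.k, "eta": ap.eta.tolist(),
                       "varsigma": ap.varsigma.tolist(), "w": ap.w.tolist()},
    }
    from .trials import make_batch

    for name, (scen, _) in scenarios.items():
        batch = make_batch(scen, 20, np.random.default_rng(seed))
        tab = _trajectory_table(batch)
        p = out / f"trajectories_{name}.csv"
        tab.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths[f"trajectories_{name}"] = p

    records = run_batch(
        ("generic", params),
        [online, ProspectivePolicy(params), OraclePolicy()],
        params,
        20,
        seed,
    )
    paths["records"] = out / "trial_records_generic.csv"
    records.to_csv(paths["records"], index=False, float_format=_FLOAT_FMT)

    paths["meta"] = out / "fixtures_meta.json"
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
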