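"""YAML run configuration: validation, defaults, reproducible echo.

One documented format: a YAML mapping with optional blocks ``mcd``,
``denoising``, ``attributes``, ``solver`` and ``experiment`` plus the
top-level keys ``scenario`` and ``out_dir``.  Unknown keys are rejected
by name; every run writes back the fully-resolved configuration so that
it re-loads to an identical object.  Floats round-trip bit-exactly
(serialized at full precision).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .core import MCDParams
from .processes import AttributeParams, DenoisingParams

__all__ = ["RunConfig", "load_config", "dump_config"]

_MCD_KEYS = {"R", "alpha", "nu", "beta", "gamma", "kappa", "mu0", "sigma0"}
_DENOISING_KEYS = {"mu0", "sigma0", "Sigma", "kappa", "hidden_V"}
_ATTRIBUTE_KEYS = {"k", "eta", "varsigma", "w"}
_SOLVER_KEYS = {"n_points", "width_mult"}
_EXPERIMENT_KEYS = {"n_trials", "n_settings", "seed"}
_TOP_KEYS = {
    "scenario",
    "out_dir",
    "mcd",
    "denoising",
    "attributes",
    "solver",
    "experiment",
}


@dataclass
class RunConfig:
    """Fully-resolved run configuration."""

    scenario: str = "generic"
    mcd: Dict = field(default_factory=dict)
    denoising: Optional[Dict] = None
    attributes: Optional[Dict] = None
    n_points: int = 513
    width_mult: float = 6.0
    n_trials: int = 500
    n_settings: int = 200
    seed: int = 0
    out_dir: str = "."

    def params(self) -> MCDParams:
        return MCDParams(**self.mcd)

    def denoising_params(self) -> DenoisingParams:
        d = dict(self.denoising or {})
        if "hidden_V" in d and d["hidden_V"] is not None:
            d["hidden_V"] = tuple(d["hidden_V"])
        return DenoisingParams(**d)

    def attribute_params(self) -> AttributeParams:
        return AttributeParams(**(self.attributes or {}))

    def resolved(self) -> Dict:
        """Plain mapping echoing every resolved setting."""
        return {
            "scenario": self.scenario,
            "out_dir": self.out_dir,
            "mcd": dict(self.mcd),
            "denoising": None if self.denoising is None else dict(self.denoising),
            "attributes": None if self.attributes is None else dict(self.attributes),
            "solver": {"n_points": self.n_points, "width_mult": self.width_mult},
            "experiment": {
                "n_trials": self.n_trials,
                "n_settings": self.n_settings,
                "seed": self.seed,
            },
        }


def _check_keys(block: Dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block '{where}' "
            f"(allowed: {sorted(allowed)})"
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Fills defaults, rejects unknown keys by name, and validates every
    parameter block by constructing the corresponding parameter objects
    (so invariant violations surface with the offending key's name).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, _TOP_KEYS, "<top level>")
    mcd = raw.get("mcd") or {}
    _check_keys(mcd, _MCD_KEYS, "mcd")
    denoising = raw.get("denoising")
    if denoising is not None:
        _check_keys(denoising, _DENOISING_KEYS, "denoising")
    attributes = raw.get("attributes")
    if attributes is not None:
        _check_keys(attributes, _ATTRIBUTE_KEYS, "attributes")
    solver = raw.get("solver") or {}
    _check_keys(solver, _SOLVER_KEYS, "solver")
    experiment = raw.get("experiment") or {}
    _check_keys(experiment, _EXPERIMENT_KEYS, "experiment")

    cfg = RunConfig(
        scenario=raw.get("scenario", "generic"),
        mcd=mcd,
        denoising=denoising,
        attributes=attributes,
        n_points=int(solver.get("n_points", 513)),
        width_mult=float(solver.get("width_mult", 6.0)),
        n_trials=int(experiment.get("n_trials", 500)),
        n_settings=int(experiment.get("n_settings", 200)),
        seed=int(experiment.get("seed", 0)),
        out_dir=str(raw.get("out_dir", ".")),
    )
    if cfg.scenario not in ("generic", "denoising", "attributes"):
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    # validate parameter blocks eagerly so errors name the offending key
    try:
        cfg.params()
    except TypeError as e:
        raise ValueError(f"invalid 'mcd' block: {e}") from e
    if cfg.denoising is not None:
        cfg.denoising_params()
    if cfg.attributes is not None:
        cfg.attribute_params()
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    """Write the resolved configuration echo (YAML, full float precision)."""
    Path(path).write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))
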