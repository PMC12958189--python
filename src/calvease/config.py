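"""YAML configuration: variance components, cutpoints, solver and simulation settings.

Schema (all sections optional; sensible national defaults fill the gaps)::

    model: smgs                 # smgs | smat
    variance_components:
      sigma2_s: 0.0223
      cov_sm: 0.0113
      sigma2_m: 0.0224
      sigma2_hys: 0.216
    thresholds: [-1.14, -0.63, 0.0]
    solver:
      outer_tol: 1.0e-6
      inner_tol: 1.0e-10
      max_outer: 1000
      max_inner: 10000
      damping: false
    simulation:
      n_service_sires: 300
      ...                       # any SimConfig field
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .evaluate import ModelSpec, default_model_specs
from .liability import Thresholds
from .model import VarianceComponents
from .simulate import SimConfig
from .solvers import SolverOptions

__all__ = ["load_config", "model_spec_from_config", "solver_options_from_config",
           "sim_config_from_config"]


def load_config(path) -> dict:
    if path is None:
        return {}
    if hasattr(path, "read"):
        return yaml.safe_load(path) or {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def model_spec_from_config(cfg: dict, mode: str) -> ModelSpec:
    """Model spec from config, defaulting to the national parameter sets."""
    default = default_model_specs()[mode]
    vc_cfg = cfg.get("variance_components")
    cuts = cfg.get("thresholds")
    vc = (
        VarianceComponents(model=mode, **{k: float(v) for k, v in vc_cfg.items()})
        if vc_cfg
        else default.vc
    )
    t = Thresholds(cuts) if cuts is not None else default.thresholds
    return ModelSpec(vc=vc, thresholds=t)


def solver_options_from_config(cfg: dict) -> SolverOptions:
    sub = cfg.get("solver", {})
    allowed = {f.name for f in fields(SolverOptions)}
    unknown = set(sub) - allowed
    if unknown:
        raise ValueError(f"unknown solver option(s): {sorted(unknown)}")
    return SolverOptions(**sub)


def sim_config_from_config(cfg: dict) -> SimConfig:
    sub = dict(cfg.get("simulation", {}))
    allowed = {f.name for f in fields(SimConfig)}
    unknown = set(sub) - allowed
    if unknown:
        raise ValueError(f"unknown simulation option(s): {sorted(unknown)}")
    if "cuts" in sub:
        sub["cuts"] = tuple(sub["cuts"])
    return SimConfig(**sub)
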