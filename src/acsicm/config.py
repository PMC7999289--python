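"""Run configuration: YAML-backed, schema-validated, CLI-overridable."""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .model import InputError

_SCHEMA = {
    # model
    "K": int,
    "beta": float,
    "a_E": float, "b_E": float, "a_M": float, "b_M": float,
    "a_alpha": float, "b_alpha": float, "a_a": float, "b_a": float,
    "sigma2_mu1": float, "sigma2_A": float,
    # spatial
    "dims": (list, tuple),
    "j_clusters": int,
    # ICM
    "tol": float,
    "max_sweeps": int,
    # ACS
    "q0": float, "tau0": float, "rho": float,
    "n_ants": int, "max_outer": int, "outer_tol": float,
    "deposit_on": str,
    # run
    "seed": int,
}


@dataclasses.dataclass
class RunConfig:
    K: int = 4
    beta: float = 0.3
    a_E: float = 2.0
    b_E: float = 1.0
    a_M: float = 2.0
    b_M: float = 1.0
    a_alpha: float = 2.0
    b_alpha: float = 1.0
    a_a: float = 2.0
    b_a: float = 1.0
    sigma2_mu1: float = 10.0
    sigma2_A: float = 1.0
    dims: Tuple[int, int, int] = (3, 3, 3)
    j_clusters: Optional[int] = None  # None -> J = P (no clustering)
    tol: float = 1e-4
    max_sweeps: int = 100
    q0: float = 0.43
    tau0: float = 0.05
    rho: float = 0.64
    n_ants: int = 10
    max_outer: int = 10
    outer_tol: float = 1e-3
    deposit_on: str = "all_time_best"
    seed: int = 0

    def hyper(self):
        from .model import Hyperparameters

        return Hyperparameters(
            K=self.K, beta=self.beta,
            a_E=self.a_E, b_E=self.b_E, a_M=self.a_M, b_M=self.b_M,
            a_alpha=self.a_alpha, b_alpha=self.b_alpha, a_a=self.a_a, b_a=self.b_a,
            sigma2_mu1=self.sigma2_mu1, sigma2_A=self.sigma2_A,
        )

    def icm_settings(self):
        from .icm import IcmSettings

        return IcmSettings(tol=self.tol, max_sweeps=self.max_sweeps)

    def tuning(self):
        from .acs import AcsTuning

        return AcsTuning(
            q0=self.q0, tau0=self.tau0, rho=self.rho, n_ants=self.n_ants,
            max_outer=self.max_outer, outer_tol=self.outer_tol,
            seed=self.seed, deposit_on=self.deposit_on,
        )


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Load a YAML config, rejecting unknown keys, then apply CLI overrides."""
    raw = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise InputError(f"config {path} must be a YAML mapping")
        raw.update(loaded)
    for k, v in overrides.items():
        if v is not None:
            raw[k] = v
    unknown = set(raw) - set(_SCHEMA) - {"j_clusters"}
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "dims" in raw:
        raw["dims"] = tuple(int(d) for d in raw["dims"])
    return RunConfig(**raw)
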