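"""Readers, writers and config parsing.

All tabular files are plain CSV: comma delimiter, '.' decimal, header row,
UTF-8.  Time series carry two columns ``time,value`` with times in days,
strictly increasing.  A single YAML config file drives simulation, fitting
and sweeps; CLI flags override config values.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .harness import (
    DEFAULT_PRIORS,
    IL10_DEFAULT,
    MACROPHAGE_DEFAULT,
    NoiseSpec,
    ProfileSpec,
    ScenarioSpec,
)
from .inference import GammaPrior, MCMCConfig, NoiseVariancePrior, ProposalSpec
from .models import DEFAULT_GRID, InputSignal, ObservedSeries, TimeGrid, tgf_beta_model

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "load_config",
    "RunConfig",
]


def _read_two_columns(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["time", "value"]:
        raise ValueError(f"{path}: expected header 'time,value', got {list(df.columns)}")
    df.columns = cols
    t = pd.to_numeric(df["time"], errors="raise").to_numpy(dtype=float)
    v = pd.to_numeric(df["value"], errors="raise").to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    return t, v


def read_timeseries(path, kind: str = "observed"):
    """Read a two-column ``time,value`` CSV.

    ``kind='observed'`` returns an `ObservedSeries` (uniform grid enforced);
    ``kind='input'`` returns an `InputSignal` (any strictly increasing
    times, linear interpolation).
    """
    t, v = _read_two_columns(path)
    if kind == "observed":
        return ObservedSeries(times=t, values=v)
    if kind == "input":
        return InputSignal(t, v)
    raise ValueError("kind must be 'observed' or 'input'")


def write_timeseries(path, times, values) -> None:
    """Write a ``time,value`` CSV at full float precision (round-trips)."""
    df = pd.DataFrame({"time": np.asarray(times, float), "value": np.asarray(values, float)})
    df.to_csv(path, index=False, float_format="%.17g")


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


class RunConfig:
    """Structured view of a YAML run configuration.

    Sections (all optional unless a command needs them): ``model``
    (constants a/H/x0, ``estimate`` list, ``fixed`` values, ``truth`` for
    simulation), ``grid``, ``profiles`` (parametric specs or CSV paths),
    ``noise``, ``priors``, ``noise_prior``, ``proposal``, ``chain``,
    ``scenario``, and a global ``seed``.
    """

    def __init__(self, cfg: Mapping, base_dir: str = ".") -> None:
        self.cfg = dict(cfg)
        self.base_dir = base_dir

    # -- pieces ---------------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.cfg.get("seed", 0))

    def grid(self) -> TimeGrid:
        g = self.cfg.get("grid")
        if g is None:
            return DEFAULT_GRID
        return TimeGrid(t0=float(g.get("t0", 0.0)), h=float(g["h"]), m=int(g["m"]))

    def model_constants(self) -> dict[str, float]:
        m = self.cfg.get("model", {})
        return {
            "a": float(m.get("a", 15.0)),
            "H": float(m.get("H", 2.0)),
            "x0": float(m.get("x0", 0.21)),
        }

    def model(self):
        m = self.cfg.get("model", {})
        estimate = tuple(m.get("estimate", ("V", "K")))
        fixed = {k: float(v) for k, v in m.get("fixed", {}).items()}
        return tgf_beta_model(estimate=estimate, **fixed, **self.model_constants())

    def truth(self) -> dict[str, float]:
        truth = self.cfg.get("model", {}).get("truth")
        if truth is None:
            raise ValueError("config needs model.truth (true V and K) for simulation")
        return {k: float(v) for k, v in truth.items()}

    def _profile(self, key: str, default: ProfileSpec):
        entry = self.cfg.get("profiles", {}).get(key)
        if entry is None:
            return default
        if isinstance(entry, str):  # CSV path with tabulated values
            return read_timeseries(os.path.join(self.base_dir, entry), kind="input")
        return ProfileSpec(**{k: float(v) for k, v in entry.items()})

    def profile_specs(self) -> tuple[ProfileSpec, ProfileSpec]:
        il10 = self._profile("il10", IL10_DEFAULT)
        mphi = self._profile("macrophage", MACROPHAGE_DEFAULT)
        for name, p in (("il10", il10), ("macrophage", mphi)):
            if not isinstance(p, ProfileSpec):
                raise ValueError(f"profiles.{name}: this command needs a parametric spec")
        return il10, mphi

    def input_signals(self):
        from .harness import profile_function

        out = []
        for key, default in (("il10", IL10_DEFAULT), ("macrophage", MACROPHAGE_DEFAULT)):
            p = self._profile(key, default)
            out.append(p if isinstance(p, InputSignal) else profile_function(p))
        return tuple(out)

    def noise(self, seed: int | None = None) -> NoiseSpec:
        n = self.cfg.get("noise", {})
        return NoiseSpec(
            sigma2=float(n.get("sigma2", 0.0)),
            seed=self.seed if seed is None else seed,
        )

    def priors(self) -> dict[str, GammaPrior]:
        out = dict(DEFAULT_PRIORS)
        for name, p in self.cfg.get("priors", {}).items():
            out[name] = GammaPrior(eta=float(p["eta"]), beta=float(p["beta"]))
        return out

    def noise_prior(self) -> NoiseVariancePrior:
        p = self.cfg.get("noise_prior", {})
        return NoiseVariancePrior(
            eta2=float(p.get("eta2", 2.0)), beta2=float(p.get("beta2", 10.0))
        )

    def proposal(self) -> ProposalSpec:
        p = self.cfg.get("proposal", {})
        return ProposalSpec(eta1=float(p.get("eta1", 2.0)), beta1=float(p.get("beta1", 0.5)))

    def chain_config(self, seed: int | None = None) -> MCMCConfig:
        c = self.cfg.get("chain", {})
        return MCMCConfig(
            n_iter=int(c.get("n_iter", 2000)),
            burn_in=int(c.get("burn_in", 1500)),
            seed=self.seed if seed is None else seed,
            update_scheme=str(c.get("scheme", "componentwise")),
        )

    def scenario(self, replicates: int | None = None, seed: int | None = None) -> ScenarioSpec:
        s = self.cfg.get("scenario")
        if s is None:
            raise ValueError("config needs a 'scenario' section for sweeps")
        il10, mphi = self.profile_specs()
        consts = self.model_constants()
        return ScenarioSpec(
            which=s["which"],
            settings=tuple({k: float(v) for k, v in m.items()} for m in s["settings"]),
            noise_levels=tuple(float(v) for v in s.get("noise_levels", (0.0, 0.1, 0.5, 1.0, 10.0))),
            replicates=int(s.get("replicates", 20)) if replicates is None else replicates,
            base_seed=self.seed if seed is None else seed,
            grid=self.grid(),
            il10=il10,
            mphi=mphi,
            a=consts["a"],
            H=consts["H"],
            x0=consts["x0"],
            include_ls=s.get("include_ls"),
        )
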