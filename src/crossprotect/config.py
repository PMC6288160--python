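"""Run configuration: defaults, YAML overrides and validation.

A run configuration bundles model parameters, protocol parameters, the
per-command settings blocks and the RNG seed.  Unknown keys are rejected
so typos fail loudly, and every command writes the fully resolved
configuration next to its outputs for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .params import (
    ModelParams,
    ProtocolParams,
    _DEFAULT_MODEL,
)

__all__ = ["RunConfig", "load_config", "BifurcationConfig", "SurvivalConfig", "LyapunovConfig"]


@dataclass
class BifurcationConfig:
    m_start: float = 0.0
    m_stop: float = 0.25
    m_step: float = 0.002
    n_days: int = 1000
    n_last: int = 50
    tol: float = 0.1

    def m_grid(self) -> np.ndarray:
        n = int(round((self.m_stop - self.m_start) / self.m_step)) + 1
        return self.m_start + self.m_step * np.arange(n)


@dataclass
class SurvivalConfig:
    m_grid: list = field(
        default_factory=lambda: sorted(
            set(np.round(np.arange(0.0, 0.1501, 0.01), 4))
            | {0.04, 0.05, 0.06, 0.07}
        )
    )
    n_runs: int = 300
    horizon: int = 10
    threshold: int = 10
    jitter_cv: float = 0.1


@dataclass
class LyapunovConfig:
    m_start: float = 0.02
    m_stop: float = 0.06
    m_step: float = 0.002
    n_days: int = 2000
    transient: int = 200
    embedding_dim: int = 4
    delay: int = 1
    theiler: int = 6
    fit_start: int = 1
    fit_stop: int = 10
    benign: bool = False  # run the scan in the benign condition instead

    def m_grid(self) -> np.ndarray:
        n = int(round((self.m_stop - self.m_start) / self.m_step)) + 1
        return self.m_start + self.m_step * np.arange(n)


@dataclass
class SimulateConfig:
    n_days: int = 100
    N1_init: float = 500.0
    N2_init: float = 500.0


@dataclass
class RunConfig:
    model: ModelParams
    protocol: ProtocolParams
    simulate: SimulateConfig
    bifurcation: BifurcationConfig
    survival: SurvivalConfig
    lyapunov: LyapunovConfig
    rng_seed: int = 0
    out_dir: Path = Path("crossprotect-out")

    def resolved_dict(self) -> dict:
        def as_plain(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: as_plain(getattr(obj, f.name))
                    for f in fields(obj)
                }
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, np.ndarray):
                return [float(v) for v in obj]
            if isinstance(obj, (list, tuple)):
                return [as_plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return as_plain(self)

    def write_resolved(self, directory: Union[str, Path]) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "config.resolved.yaml"
        path.write_text(yaml.safe_dump(self.resolved_dict(), sort_keys=False))
        return path


def _merge_block(cls, defaults: dict, overrides: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown keys in '{context}' block: {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(overrides)
    return cls(**merged)


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults plus a YAML override file.

    An empty (or absent) file yields the full defaults.  The file may
    contain top-level blocks ``model``, ``protocol``, ``simulate``,
    ``bifurcation``, ``survival``, ``lyapunov`` and scalars ``rng_seed``
    and ``out_dir``; unknown keys anywhere raise ``ValueError``, as do
    values violating the parameter invariants.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    known_blocks = {
        "model", "protocol", "simulate", "bifurcation", "survival",
        "lyapunov", "rng_seed", "out_dir",
    }
    unknown = set(raw) - known_blocks
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    model = _merge_block(
        ModelParams, _DEFAULT_MODEL, raw.get("model") or {}, "model"
    )
    proto_defaults = {
        f.name: f.default for f in fields(ProtocolParams)
    }
    protocol = _merge_block(
        ProtocolParams, proto_defaults, raw.get("protocol") or {}, "protocol"
    )
    cfg = RunConfig(
        model=model,
        protocol=protocol,
        simulate=_merge_block(SimulateConfig, {}, raw.get("simulate") or {}, "simulate"),
        bifurcation=_merge_block(
            BifurcationConfig, {}, raw.get("bifurcation") or {}, "bifurcation"
        ),
        survival=_merge_block(SurvivalConfig, {}, raw.get("survival") or {}, "survival"),
        lyapunov=_merge_block(LyapunovConfig, {}, raw.get("lyapunov") or {}, "lyapunov"),
        rng_seed=int(raw.get("rng_seed", 0)),
        out_dir=Path(raw.get("out_dir", "crossprotect-out")),
    )
    return cfg
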