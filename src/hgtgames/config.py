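"""Configuration loading, validation and serialisation.

One schema is shared by every subcommand (JSON or YAML, keyed sections)::

    preset: region_II          # optional: expand a named preset first
    rates:                     # FixedRates fields
      r_A: 1.8
      r_B: 1.0
      a_AA: 0.1
      a_AB: 0.1
      a_BA: 0.1
      a_BB: 0.1
      gamma: 0.0
    environment:
      omega: 5.0
      oscillations:            # harmonic components, zero-mean by design
        - {target: gamma, k: 1, cos: 0.0, sin: 0.5}
        - {target: r_A,   k: 1, cos: -1.6, sin: 0.0}
    run:
      p_A0: 0.5
      N0: 1.0
      t_end: 200.0
      seed: 0

Unknown keys anywhere are a hard error (no silent typo tolerance), and
every violated invariant is reported with the field name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .environment import EnvironmentSpec, OscillatorySignal
from .model import FixedRates
from .presets import get_preset

__all__ = ["ConfigError", "RunSpec", "load_config", "config_to_dict", "write_config"]

_OSC_TARGETS = ("r_A", "r_B", "gamma")
_RUN_DEFAULTS = {"p_A0": 0.5, "N0": 1.0, "t_end": 200.0, "seed": 0}


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass(frozen=True)
class RunSpec:
    """Fully validated run specification with defaults applied."""

    env: EnvironmentSpec
    p_A0: float = 0.5
    N0: float = 1.0
    t_end: float = 200.0
    seed: int = 0
    echo: dict = field(default_factory=dict)

    @property
    def rates(self) -> FixedRates:
        return self.env.base

    @property
    def digest(self) -> str:
        """Provenance hash of the normalised configuration."""
        blob = json.dumps(self.echo, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _reject_unknown(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _signals_from_oscillations(entries) -> dict:
    acc = {t: [] for t in _OSC_TARGETS}
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise ConfigError(f"oscillations[{i}] must be a mapping")
        _reject_unknown(entry, ("target", "k", "cos", "sin"), f"oscillations[{i}]")
        target = entry.get("target")
        if target not in _OSC_TARGETS:
            raise ConfigError(
                f"oscillations[{i}].target must be one of {_OSC_TARGETS}, got {target!r}"
            )
        k = int(entry.get("k", 1))
        if k < 1:
            raise ConfigError(f"oscillations[{i}].k must be >= 1 (zero-mean signal)")
        acc[target].append((k, float(entry.get("cos", 0.0)), float(entry.get("sin", 0.0))))
    return {
        t: OscillatorySignal(harmonics=tuple(v)) if v else OscillatorySignal.zero()
        for t, v in acc.items()
    }


def _spec_from_dict(raw: dict) -> RunSpec:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _reject_unknown(raw, ("preset", "rates", "environment", "run"), "configuration")

    if "preset" in raw:
        preset = get_preset(str(raw["preset"]))
        env = preset.env
    else:
        env = None

    if "rates" in raw or env is None:
        rates_sec = raw.get("rates")
        if rates_sec is None:
            raise ConfigError("configuration needs a 'rates' section or a 'preset'")
        try:
            base = FixedRates.from_dict(rates_sec)
        except ValueError as exc:
            raise ConfigError(f"rates: {exc}") from None
    else:
        base = env.base

    env_sec = raw.get("environment")
    if env_sec is not None:
        _reject_unknown(env_sec, ("omega", "oscillations"), "environment")
        signals = _signals_from_oscillations(env_sec.get("oscillations", []))
        omega = float(env_sec.get("omega", env.omega if env else 5.0))
        try:
            env = EnvironmentSpec(
                base=base,
                osc_rA=signals["r_A"],
                osc_rB=signals["r_B"],
                osc_gamma=signals["gamma"],
                omega=omega,
            )
        except ValueError as exc:
            raise ConfigError(f"environment: {exc}") from None
    elif env is None:
        env = EnvironmentSpec(base=base)
    elif "rates" in raw:
        env = EnvironmentSpec(
            base=base,
            osc_rA=env.osc_rA,
            osc_rB=env.osc_rB,
            osc_gamma=env.osc_gamma,
            omega=env.omega,
        )

    run_sec = dict(_RUN_DEFAULTS)
    if "run" in raw:
        _reject_unknown(raw["run"], _RUN_DEFAULTS, "run")
        run_sec.update(raw["run"])
    p_A0, N0, t_end = float(run_sec["p_A0"]), float(run_sec["N0"]), float(run_sec["t_end"])
    if not 0.0 <= p_A0 <= 1.0:
        raise ConfigError("run.p_A0 must lie in [0, 1]")
    if N0 < 0:
        raise ConfigError("run.N0 must be non-negative")
    if t_end <= 0:
        raise ConfigError("run.t_end must be positive")

    spec = RunSpec(
        env=env, p_A0=p_A0, N0=N0, t_end=t_end, seed=int(run_sec["seed"]), echo={}
    )
    object.__setattr__(spec, "echo", config_to_dict(spec))
    return spec


def load_config(path) -> RunSpec:
    """Load and validate a JSON/YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    return _spec_from_dict(raw)


def _signal_entries(target: str, sig: OscillatorySignal) -> list:
    if sig.is_tabulated:
        raise ConfigError("tabulated signals are not serialisable to config files")
    return [
        {"target": target, "k": k, "cos": a, "sin": b} for k, a, b in sig.harmonics
    ]


def config_to_dict(spec: RunSpec) -> dict:
    """Normalised plain-dict echo of a run specification."""
    osc = (
        _signal_entries("r_A", spec.env.osc_rA)
        + _signal_entries("r_B", spec.env.osc_rB)
        + _signal_entries("gamma", spec.env.osc_gamma)
    )
    return {
        "rates": spec.env.base.to_dict(),
        "environment": {"omega": float(spec.env.omega), "oscillations": osc},
        "run": {
            "p_A0": spec.p_A0,
            "N0": spec.N0,
            "t_end": spec.t_end,
            "seed": spec.seed,
        },
    }


def write_config(spec: RunSpec, path) -> None:
    """Serialise a run specification (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(spec), sort_keys=True))
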