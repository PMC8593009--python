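"""Run-configuration files: parsing, validation, defaults and hashing.

One YAML format serves every command.  Unknown or missing required keys are
reported by name; all defaults that were filled in are available on the
parsed config (and echoed by the CLI) so a run is fully reconstructable.  A
stable hash of the effective configuration is embedded in every artifact
together with the seed.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .agents import AgentParams, ScriptedAction, ScriptedAgent, StochasticAgent
from .scheduler import StageCriteria
from .tasks import (FiveCSRTTParams, FiveCSWMParams, HabituationParams,
                    OptoSchedule, attach_opto_schedule, build_5csrtt,
                    build_5cswm, build_habituation, make_challenge)

__all__ = [
    "RunConfig",
    "ConfigError",
    "parse_config",
    "dump_config",
    "build_task",
    "build_agent",
    "load_script_csv",
    "load_agent_params",
    "load_criteria",
]

PARADIGMS = ("habituation", "5csrtt", "5cswm")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated session configuration with defaults filled."""

    paradigm: str
    seed: int
    duration_min: float = 30.0
    stage: str = "baseline"
    params: dict = field(default_factory=dict)
    agent: dict = field(default_factory=dict)
    script: Optional[str] = None
    challenge: Optional[dict] = None
    opto: Optional[dict] = None
    out_dir: str = "."
    filled_defaults: list = field(default_factory=list)

    @property
    def duration_ms(self) -> int:
        return int(round(self.duration_min * 60_000))

    def config_hash(self) -> str:
        """Stable hash of the scientific configuration (output location and
        bookkeeping excluded)."""
        d = asdict(self)
        d.pop("filled_defaults", None)
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_KNOWN = {"paradigm", "seed", "duration_min", "stage", "params", "agent",
          "script", "challenge", "opto", "out_dir"}
_REQUIRED = {"paradigm", "seed"}
_DEFAULTS = {"duration_min": 30.0, "stage": "baseline", "params": {},
             "agent": {}, "script": None, "challenge": None, "opto": None,
             "out_dir": "."}


def parse_config(source: Union[str, Path, dict]) -> RunConfig:
    """Parse and validate a YAML config file (or an equivalent dict)."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
    unknown = set(raw) - _KNOWN
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    missing = _REQUIRED - set(raw)
    if missing:
        raise ConfigError(f"missing required config key(s): {', '.join(sorted(missing))}")
    filled = [k for k in _DEFAULTS if k not in raw]
    merged = {**_DEFAULTS, **raw}
    cfg = RunConfig(paradigm=str(merged["paradigm"]), seed=int(merged["seed"]),
                    duration_min=float(merged["duration_min"]),
                    stage=str(merged["stage"]), params=dict(merged["params"] or {}),
                    agent=dict(merged["agent"] or {}), script=merged["script"],
                    challenge=merged["challenge"], opto=merged["opto"],
                    out_dir=str(merged["out_dir"]), filled_defaults=sorted(filled))
    if cfg.paradigm not in PARADIGMS:
        raise ConfigError(f"unknown paradigm {cfg.paradigm!r}; expected one of {PARADIGMS}")
    if cfg.duration_min <= 0:
        raise ConfigError("duration_min must be positive")
    return cfg


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    d = asdict(cfg)
    d.pop("filled_defaults", None)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


_PARAM_TYPES = {"habituation": HabituationParams, "5csrtt": FiveCSRTTParams,
                "5cswm": FiveCSWMParams}
_BUILDERS = {"habituation": build_habituation, "5csrtt": build_5csrtt,
             "5cswm": build_5cswm}


def build_task(cfg: RunConfig):
    """Build the configured state machine; returns (machine, task_params)."""
    cls = _PARAM_TYPES[cfg.paradigm]
    try:
        params = cls(**cfg.params)
    except TypeError as exc:
        raise ConfigError(f"bad task params for {cfg.paradigm}: {exc}") from None
    if cfg.challenge is not None:
        if cfg.paradigm != "5csrtt":
            raise ConfigError("challenges are defined for the 5csrtt paradigm only")
        params = make_challenge(params, cfg.challenge.get("kind", ""),
                                cfg.challenge.get("magnitude"))
    machine = _BUILDERS[cfg.paradigm](params)
    if cfg.opto is not None:
        try:
            sched = OptoSchedule(**cfg.opto)
        except TypeError as exc:
            raise ConfigError(f"bad opto schedule: {exc}") from None
        attach_opto_schedule(machine, sched)
    return machine, params


def build_agent(cfg: RunConfig):
    if cfg.script is not None:
        return ScriptedAgent(load_script_csv(cfg.script))
    try:
        return StochasticAgent(AgentParams(**cfg.agent))
    except TypeError as exc:
        raise ConfigError(f"bad agent params: {exc}") from None


def load_agent_params(path: Union[str, Path]) -> AgentParams:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    try:
        return AgentParams(**raw)
    except TypeError as exc:
        raise ConfigError(f"bad agent parameter file {path}: {exc}") from None


def load_script_csv(path: Union[str, Path]) -> list[ScriptedAction]:
    """Load a scripted-action file: CSV with columns time_ms, action, hole."""
    actions = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), 2):
            hole = row.get("hole")
            actions.append(ScriptedAction(int(row["time_ms"]), row["action"].strip(),
                                          int(hole) if hole not in (None, "") else None))
    return actions


def load_criteria(path: Union[str, Path]) -> dict[str, StageCriteria]:
    """Load a per-stage criteria file: ``{stage: {threshold: value, ...}}``."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    out = {}
    for stage, spec in raw.items():
        try:
            out[str(stage)] = StageCriteria(**(spec or {}))
        except TypeError as exc:
            raise ConfigError(f"bad criteria for stage {stage!r}: {exc}") from None
    return out
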